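"""Weight expression by any binned per-gene metric, not just gene age.

Any continuous gene-level statistic (nucleotide diversity, Tajima's D,
F statistics, adaptation scores) can be quantile-binned with get_bins and
dropped in wherever age classes go: the resulting per-cell index is then a
'transcriptome metric index' over those bins.
"""

import numpy as np

from phylotei import ExpressionMatrix, get_bins, get_tei
from phylotei.simulate import make_counts

rng = np.random.default_rng(5)
genes = [f"g{i}" for i in range(30)]
tajimas_d = {g: float(rng.normal(0, 1.5)) for g in genes}

bins, dropped = get_bins(tajimas_d, n_bins=4, method="quantile")
print("bin sizes (quantile binning, near equal):")
print(bins.value_counts().sort_index().to_string())

sim = make_counts(n_cells=20, gene_ps={g: 1 for g in genes}, seed=5)
expr = ExpressionMatrix(sim.matrix, sim.cell_names, sim.gene_names)
result = get_tei(expr, bins)
print(f"\nper-cell index over D bins, first 5 cells: {np.round(result.tei[:5], 3)}")
print("High values mean the cell's expression is dominated by genes in the")
print("upper bins of the metric (here: high Tajima's D).")
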