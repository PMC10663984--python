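"""Orthogroup parsing, age-class extraction and continuity scores."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from phylotei import (
    continuity_score,
    extract_orthomap,
    get_lineage,
    load_lineage_tsv,
    read_member_table,
    read_orthofinder,
    read_orthomap,
    write_orthomap,
)
from phylotei.errors import ConfigError, ParseError, SchemaError
from phylotei.orthogroups import Orthomap, OrthomapRecord
from phylotei.simulate import make_orthogroups, make_taxonomy, oracle_group_age

from conftest import path_taxonomy_tsv


TOY_TREE = [(1, 1, "root"), (2, 1, "cladeQA"), (3, 2, "Q"), (4, 2, "A"), (5, 1, "B")]


@pytest.fixture
def toy():
    tax = load_lineage_tsv(path_taxonomy_tsv(TOY_TREE))
    return tax, get_lineage(tax, 3)


class TestReadOrthofinder:
    def test_cells_split_and_empty_cells(self):
        src = io.StringIO("Orthogroup\tA\tB\nOG1\tg1, g2\t\n")
        table = read_orthofinder(src, {"A": 10, "B": 20})
        assert table.groups["OG1"]["A"] == ["g1", "g2"]
        assert table.groups["OG1"]["B"] == []

    def test_unknown_species_label_is_config_error(self):
        src = io.StringIO("Orthogroup\tA\tC\nOG1\tg1\tg2\n")
        with pytest.raises(ConfigError, match="C"):
            read_orthofinder(src, {"A": 10, "B": 20})

    def test_duplicate_orthogroup_id_is_parse_error(self):
        src = io.StringIO("Orthogroup\tA\nOG1\tg1\nOG1\tg2\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_orthofinder(src, {"A": 10})

    def test_fixture_group_count_matches_generator(self):
        tree = make_taxonomy(n_species=3, depth=3, seed=5)
        ogs = make_orthogroups(tree, tree.species[0], n_groups=12, seed=5)
        table = read_orthofinder(
            io.StringIO(ogs.orthofinder_tsv()),
            {label: t for t, label in ogs.species_labels.items()},
        )
        assert table.n_groups == 12


class TestReadMemberTable:
    def test_two_species_row(self):
        table = read_member_table(io.StringIO("OG1\t9606.p1,7955.p2\n"))
        assert table.species_taxids == {"9606": 9606, "7955": 7955}
        assert table.groups["OG1"]["9606"] == ["p1"]

    def test_split_at_first_dot_only(self):
        table = read_member_table(io.StringIO("OG1\t9606.ENSP00.1\n"))
        assert table.groups["OG1"]["9606"] == ["ENSP00.1"]

    def test_token_without_dot_is_parse_error(self):
        with pytest.raises(ParseError, match="p1"):
            read_member_table(io.StringIO("OG1\tp1\n"))

    def test_cross_format_equivalence(self):
        """Member-table parse carries the same group content as the
        OrthoFinder parse of the same generated table."""
        tree = make_taxonomy(n_species=5, depth=4, seed=9)
        ogs = make_orthogroups(tree, tree.species[1], n_groups=15, seed=9)
        of = read_orthofinder(
            io.StringIO(ogs.orthofinder_tsv()),
            {label: t for t, label in ogs.species_labels.items()},
        )
        mt = read_member_table(io.StringIO(ogs.member_table()))
        for og in of.groups:
            by_taxid_of = {
                of.species_taxids[s]: sorted(ids)
                for s, ids in of.groups[og].items()
                if ids
            }
            by_taxid_mt = {
                mt.species_taxids[s]: sorted(ids)
                for s, ids in mt.groups[og].items()
                if ids
            }
            assert by_taxid_of == by_taxid_mt


class TestExtractOrthomap:
    def test_query_only_group_gets_tip_class(self, toy):
        tax, lin = toy
        src = io.StringIO("Orthogroup\tQ\tA\tB\nOG1\tq1\t\t\n")
        om = extract_orthomap(
            read_orthofinder(src, {"Q": 3, "A": 4, "B": 5}), tax, 3
        )
        assert om.records[0].psnum == len(lin) == 3
        assert om.records[0].pscontinuity == 1.0

    def test_toy_tree_age_assignment(self, toy):
        tax, _ = toy
        src = io.StringIO(
            "Orthogroup\tQ\tA\tB\n"
            "OG1\tq1\t\tb1\n"   # {Q,B}: LCA at root -> 1
            "OG2\tq2\ta1\t\n"   # {Q,A}: LCA at cladeQA -> 2
            "OG3\tq3\t\t\n"     # {Q}: tip -> 3
        )
        om = extract_orthomap(read_orthofinder(src, {"Q": 3, "A": 4, "B": 5}), tax, 3)
        by_gene = {r.seq_id: r.psnum for r in om.records}
        assert by_gene == {"q1": 1, "q2": 2, "q3": 3}
        # brute-force cross-check against the path-intersection oracle
        parent_of = {t: p for t, p, _ in TOY_TREE}
        assert oracle_group_age(parent_of, 3, [3, 5]) == 1
        assert oracle_group_age(parent_of, 3, [3, 4]) == 2
        assert oracle_group_age(parent_of, 3, [3]) == 3

    def test_group_without_query_contributes_nothing(self, toy):
        tax, _ = toy
        src = io.StringIO("Orthogroup\tQ\tA\tB\nOG1\t\ta1\tb1\n")
        om = extract_orthomap(read_orthofinder(src, {"Q": 3, "A": 4, "B": 5}), tax, 3)
        assert om.records == []

    def test_query_not_in_table_is_config_error(self, toy):
        tax, _ = toy
        src = io.StringIO("Orthogroup\tA\tB\nOG1\ta1\tb1\n")
        with pytest.raises(ConfigError):
            extract_orthomap(read_orthofinder(src, {"A": 4, "B": 5}), tax, 3)

    def test_multi_group_gene_keeps_oldest_class_with_warning(self, toy):
        tax, _ = toy
        table = read_member_table(
            io.StringIO("OG1\t3.q1\nOG2\t3.q1,5.b1\n")  # q1 twice: tip vs root
        )
        with pytest.warns(UserWarning, match="q1"):
            om = extract_orthomap(table, tax, 3)
        assert len(om.records) == 1
        assert om.records[0].psnum == 1

    def test_records_of_one_group_share_the_triple(self, bundle_parsed):
        _, _, om = bundle_parsed
        per_group = {}
        for r in om.records:
            triple = (r.psnum, r.psname, r.pscontinuity)
            per_group.setdefault(r.orthogroup_id, set()).add(triple)
        assert all(len(v) == 1 for v in per_group.values())

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_brute_force_oracle_on_random_tables(self, seed):
        tree = make_taxonomy(n_species=6, depth=4, seed=seed)
        query = tree.species[seed % len(tree.species)]
        ogs = make_orthogroups(tree, query, n_groups=20, seed=seed)
        tax = load_lineage_tsv(io.StringIO(tree.lineage_tsv()))
        om = extract_orthomap(
            read_member_table(io.StringIO(ogs.member_table())), tax, query
        )
        parent_of = tree.parent_of
        by_group = {r.orthogroup_id: r.psnum for r in om.records}
        for og, members in ogs.groups.items():
            expected = oracle_group_age(parent_of, query, list(members))
            assert by_group[og] == expected == ogs.true_age[og]

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_adding_a_member_never_makes_a_group_younger(self, seed):
        """Age monotonicity: inserting one more member species can only keep
        or decrease (make older) the group's class."""
        tree = make_taxonomy(n_species=7, depth=4, seed=seed)
        query = tree.species[0]
        parent_of = tree.parent_of
        others = [s for s in tree.species if s != query]
        base = others[: 1 + seed % len(others)]
        added = others[seed % len(others)]
        before = oracle_group_age(parent_of, query, [query] + base)
        after = oracle_group_age(parent_of, query, [query] + base + [added])
        assert after <= before


class TestContinuityScore:
    def test_query_only_group_is_one(self, toy):
        tax, lin = toy
        assert continuity_score(set(), lin, tax, len(lin)) == 1.0

    def test_full_occupancy_is_one(self, toy):
        tax, lin = toy
        # members branching at psnum 1 (B) and 2 (A); L=3 -> positions {1,2}
        assert continuity_score({4, 5}, lin, tax, 1) == 1.0

    def test_partial_occupancy_fraction(self):
        # lineage of length 4; members branch at positions 1 and 3 only
        tax = load_lineage_tsv(
            path_taxonomy_tsv(
                [
                    (1, 1, "root"), (2, 1, "n2"), (3, 2, "n3"), (4, 3, "Q"),
                    (5, 1, "at1"), (6, 3, "at3"),
                ]
            )
        )
        lin = get_lineage(tax, 4)
        score = continuity_score({5, 6}, lin, tax, 1)
        assert score == pytest.approx(2 / 3)

    def test_out_of_range_ps_is_error(self, toy):
        tax, lin = toy
        with pytest.raises(Exception, match="outside"):
            continuity_score(set(), lin, tax, len(lin) + 1)

    def test_score_always_in_unit_interval(self, bundle_parsed):
        _, _, om = bundle_parsed
        assert all(0.0 <= r.pscontinuity <= 1.0 for r in om.records)


class TestOrthomapIO:
    def make_orthomap(self):
        records = [
            OrthomapRecord("g2", "OG2", 1, "root", 0.5),
            OrthomapRecord("g1", "OG1", 1, "root", 1.0),
            OrthomapRecord("g3", "OG3", 2, "clade", 1.0),
        ]
        return Orthomap(records, query_taxid=3)

    def test_empty_orthomap_writes_header_only(self):
        buf = io.StringIO()
        write_orthomap(Orthomap([], 3), buf)
        assert buf.getvalue() == "seqID\tOrthogroup\tPSnum\tPSname\tPScontinuity\n"

    def test_rows_sorted_by_psnum_then_group_then_seqid(self):
        buf = io.StringIO()
        write_orthomap(self.make_orthomap(), buf)
        lines = buf.getvalue().splitlines()
        assert len(lines) == 4
        assert [l.split("\t")[0] for l in lines[1:]] == ["g1", "g2", "g3"]

    def test_round_trip_reproduces_records(self):
        buf = io.StringIO()
        write_orthomap(self.make_orthomap(), buf)
        buf.seek(0)
        records = read_orthomap(buf)
        as_tuples = {(r.seq_id, r.orthogroup_id, r.psnum, r.psname, r.pscontinuity)
                     for r in records}
        assert as_tuples == {
            ("g1", "OG1", 1, "root", 1.0),
            ("g2", "OG2", 1, "root", 0.5),
            ("g3", "OG3", 2, "clade", 1.0),
        }

    def test_two_column_file_fills_placeholders(self):
        records = read_orthomap(io.StringIO("seqID\tPSnum\ng1\t4\n"))
        assert records[0].psnum == 4 and records[0].psname == ""

    def test_missing_mandatory_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="PSnum"):
            read_orthomap(io.StringIO("seqID\tage\ng1\t4\n"))

    def test_non_integer_psnum_is_parse_error(self):
        with pytest.raises(ParseError, match="abc"):
            read_orthomap(io.StringIO("seqID\tPSnum\ng1\tabc\n"))
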