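"""Readers/writers, identifier mapping and domain-type invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bionereval import (
    AssociationTable,
    DiseaseNetwork,
    EmptyInputError,
    FormatError,
    IdMapping,
    ValidationError,
    apply_id_mapping,
    read_association_table,
    read_category_maps,
    read_id_mapping,
    read_network,
    write_association_table,
    write_category_maps,
    write_network,
)
from bionereval.model import CategoryMap


class TestAssociationTableIO:
    def test_duplicate_rows_are_collapsed(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("disease_id\tentity_id\nd1\tt1\nd1\tt1\nd1\tt2\n")
        table = read_association_table(p, "x")
        assert len(table) == 2
        assert table.entity_sets() == {"d1": frozenset({"t1", "t2"})}

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("disease_id\tsomething\nd1\tt1\n")
        with pytest.raises(FormatError, match="entity_id"):
            read_association_table(p, "x")

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("disease_id\tentity_id\n")
        with pytest.raises(EmptyInputError):
            read_association_table(p, "x")

    def test_comma_delimiter_and_default_entity_type(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("disease_id,entity_id\nd1,t1\n")
        table = read_association_table(p, "x")
        assert table.records == frozenset({("d1", "t1", "term")})

    def test_round_trip(self, tmp_path, toy_table):
        p = tmp_path / "a.tsv"
        write_association_table(toy_table, p)
        assert read_association_table(p, "toy") == toy_table

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.text(alphabet="abcd", min_size=1, max_size=4).map(lambda s: "D" + s),
            st.sets(
                st.text(alphabet="xyz", min_size=1, max_size=4).map(lambda s: "E" + s),
                min_size=1,
                max_size=5,
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_round_trip_property(self, tmp_path_factory, mapping):
        table = AssociationTable.from_pairs("h", mapping)
        p = tmp_path_factory.mktemp("assoc") / "t.tsv"
        write_association_table(table, p)
        assert read_association_table(p, "h") == table


class TestAssociationTableInvariants:
    def test_rejects_empty_identifiers(self):
        with pytest.raises(ValidationError):
            AssociationTable("x", frozenset({("", "t1", "term")}))

    def test_rejects_duplicate_pairs_with_differing_type(self):
        with pytest.raises(ValidationError):
            AssociationTable(
                "x", frozenset({("d1", "t1", "term"), ("d1", "t1", "gene")})
            )

    def test_rejects_unknown_entity_type(self):
        with pytest.raises(ValidationError):
            AssociationTable("x", frozenset({("d1", "t1", "symptom")}))


class TestIdMapping:
    def test_rename(self):
        t = AssociationTable.from_pairs("x", [("dA", "t1")])
        out = apply_id_mapping(t, IdMapping({"dA": "c1"}))
        assert out.entity_sets() == {"c1": frozenset({"t1"})}

    def test_merge_unions_entity_sets(self):
        t = AssociationTable.from_pairs("x", [("dA", "t1"), ("dB", "t1"), ("dB", "t2")])
        out = apply_id_mapping(t, IdMapping({"dA": "c1", "dB": "c1"}))
        assert out.entity_sets() == {"c1": frozenset({"t1", "t2"})}

    def test_drop_vs_keep_unmapped(self):
        t = AssociationTable.from_pairs("x", [("dA", "t1")])
        assert len(apply_id_mapping(t, IdMapping({}), drop_unmapped=True)) == 0
        kept = apply_id_mapping(t, IdMapping({}), drop_unmapped=False)
        assert kept == t

    def test_idempotent_on_canonical_ids(self):
        t = AssociationTable.from_pairs("x", [("c1", "t1"), ("c2", "t2")])
        identity = IdMapping({"c1": "c1", "c2": "c2"})
        once = apply_id_mapping(t, identity)
        assert apply_id_mapping(once, identity) == once

    def test_read_id_mapping(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("source_id\tcanonical_id\ndA\tc1\ndB\tc2\n")
        assert read_id_mapping(p).pairs == {"dA": "c1", "dB": "c2"}


class TestNetworkIO:
    def test_round_trip_edgelist(self, tmp_path):
        net = DiseaseNetwork.from_edges(
            [("d1", "d2", 0.123456789012345), ("d2", "d3", 1.0)],
            source_id="s",
            threshold_percentile=95.0,
            build_seed=7,
        )
        p = tmp_path / "net.tsv"
        write_network(net, p)
        back = read_network(p)
        assert back == net
        assert back.source_id == "s"
        assert back.threshold_percentile == 95.0
        assert back.build_seed == 7

    def test_round_trip_graphml(self, tmp_path):
        net = DiseaseNetwork.from_edges(
            [("d1", "d2", 0.25)], source_id="g", threshold_percentile=95.0
        )
        p = tmp_path / "net.graphml"
        write_network(net, p)
        back = read_network(p)
        assert back == net and back.threshold_percentile == 95.0

    def test_self_loop_row_rejected(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("d1\td1\t0.5\n")
        with pytest.raises(ValidationError, match="self-loop"):
            read_network(p)

    def test_out_of_range_weight_rejected(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("d1\td2\t1.5\n")
        with pytest.raises(ValidationError, match="weight"):
            read_network(p)

    def test_constructor_rejects_bad_weight_and_self_loop(self):
        with pytest.raises(ValidationError):
            DiseaseNetwork.from_edges([("a", "b", 0.0)])
        with pytest.raises(ValidationError):
            DiseaseNetwork.from_edges([("a", "a", 0.5)])


class TestCategoryMaps:
    def test_one_map_per_system(self, tmp_path):
        p = tmp_path / "cats.tsv"
        p.write_text(
            "disease_id\tsystem_id\tcategory_id\n"
            "d1\tMeSH\tC04\nd2\tMeSH\tC10\nd1\tDO\t162\n"
        )
        maps = read_category_maps(p)
        assert set(maps) == {"MeSH", "DO"}
        assert len(maps["MeSH"]) == 2 and len(maps["DO"]) == 1

    def test_conflicting_assignment_names_disease(self, tmp_path):
        p = tmp_path / "cats.tsv"
        p.write_text(
            "disease_id\tsystem_id\tcategory_id\nd1\tMeSH\tC04\nd1\tMeSH\tC10\n"
        )
        with pytest.raises(ValidationError, match="d1"):
            read_category_maps(p)

    def test_round_trip(self, tmp_path):
        maps = [CategoryMap("MeSH", {"d1": "C04", "d2": "C10"})]
        p = tmp_path / "cats.tsv"
        write_category_maps(maps, p)
        assert read_category_maps(p)["MeSH"].assignments == maps[0].assignments
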