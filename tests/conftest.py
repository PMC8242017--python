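import pytest

from bionereval import AssociationTable, DiseaseNetwork


@pytest.fixture
def toy_table() -> AssociationTable:
    """Three diseases; d1/d2 share one term, d3 is isolated."""
    return AssociationTable.from_pairs(
        "toy", {"d1": {"t1", "t2"}, "d2": {"t2", "t3"}, "d3": {"t9"}}
    )


@pytest.fixture
def triangle() -> DiseaseNetwork:
    return DiseaseNetwork.from_edges(
        [("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5)], source_id="triangle"
    )


@pytest.fixture
def two_triangles() -> DiseaseNetwork:
    """Two disjoint triangles — the classic 2-community toy graph."""
    return DiseaseNetwork.from_edges(
        [
            ("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
            ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0),
        ],
        source_id="two_triangles",
    )
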