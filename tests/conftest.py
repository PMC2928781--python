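import pytest

from tetrakit.io import Marker, MarkerMap, SporeRecord, Tetrad, TetradDataset


@pytest.fixture
def small_map() -> MarkerMap:
    """Two chromosomes; one centromere-linked marker each; MAT on chr1."""
    return MarkerMap(
        [
            Marker("A", "chr1", 0.0, is_centromere_linked=False),
            Marker("B", "chr1", 10.0, is_centromere_linked=True),
            Marker("MAT", "chr1", 25.0, is_mating_type=True),
            Marker("C", "chr2", 0.0, is_centromere_linked=True),
            Marker("D", "chr2", 20.0),
        ]
    )


def make_tetrad(tetrad_id, calls_per_spore, marker_names, viable=None):
    """Build a Tetrad from per-spore call tuples (in marker order)."""
    spores = []
    for k, sid in enumerate("abcd"):
        v = True if viable is None else viable[k]
        alleles = {
            name: ("NONE" if not v else calls_per_spore[k][i])
            for i, name in enumerate(marker_names)
        }
        spores.append(SporeRecord(tetrad_id, sid, v, alleles))
    return Tetrad(tetrad_id, spores)


@pytest.fixture
def make_dataset(small_map):
    names = small_map.names

    def _make(per_tetrad_calls, viable=None, strain="test"):
        tetrads = [
            make_tetrad(f"T{i+1}", calls, names, viable=None if viable is None else viable[i])
            for i, calls in enumerate(per_tetrad_calls)
        ]
        return TetradDataset(strain, small_map, tetrads)

    return _make


# a parental-ditype spore pattern for the 5-marker small_map
PD_CALLS = [
    ("P1", "P1", "P1", "P1", "P1"),
    ("P1", "P1", "P1", "P1", "P1"),
    ("P2", "P2", "P2", "P2", "P2"),
    ("P2", "P2", "P2", "P2", "P2"),
]


@pytest.fixture
def pd_calls():
    return [tuple(row) for row in PD_CALLS]
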