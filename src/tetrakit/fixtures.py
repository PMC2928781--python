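"""Bundled published count tables for the SK1 Msh4-Msh5 strain panels.

The study published tallies, not raw tetrads, so these fixtures carry
per-interval PD/TT/NPD and parental/recombinant spore counts (plus the
printed summary statistics for regression checks) rather than
reconstructed dissection tables.  Observed double-crossover counts cannot
be recovered from marginal tallies and are stored as printed.

Fixture names:

* ``table1_eay``  — 57-allele spore-viability / chromosome-XV map panel
* ``table2_nhy``  — per-interval spore and tetrad tallies, chromosomes
  III/VII/VIII, 16 genotypes
* ``table4_coc``  — coefficient-of-coincidence table (printed values)
* ``table5_npd``  — NPD-ratio table (printed values)
* ``nhy_marker_map`` / ``nhy_intervals`` / ``nhy_interval_pairs`` —
  marker map and interval configuration for the NHY strains
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .io import MarkerMap, read_marker_map
from .linkage import IntervalTally, SporeTally

_TABLES = {
    "table1_eay": "table1_eay.tsv",
    "table2_nhy": "table2_nhy.tsv",
    "table4_coc": "table4_coc.tsv",
    "table5_npd": "table5_npd.tsv",
    "nhy_marker_map": "nhy_marker_map.tsv",
    "nhy_intervals": "nhy_intervals.tsv",
    "nhy_interval_pairs": "nhy_interval_pairs.tsv",
}

# the eight scored intervals in map order
NHY_INTERVALS = [
    ("III", "HIS4", "LEU2"),
    ("III", "LEU2", "CEN3"),
    ("III", "CEN3", "MAT"),
    ("VII", "TRP5", "CYH2"),
    ("VII", "CYH2", "MET13"),
    ("VII", "MET13", "LYS5"),
    ("VIII", "CEN8", "THR1"),
    ("VIII", "THR1", "CUP1"),
]

NHY_INTERVAL_PAIRS = [
    ("III", "HIS4", "LEU2", "CEN3"),
    ("III", "LEU2", "CEN3", "MAT"),
    ("VII", "TRP5", "CYH2", "MET13"),
    ("VII", "CYH2", "MET13", "LYS5"),
    ("VIII", "CEN8", "THR1", "CUP1"),
]


def fixture_path(name: str) -> Path:
    if name not in _TABLES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_TABLES)}"
        )
    return Path(resources.files("tetrakit").joinpath("data", _TABLES[name]))


def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled fixture as a DataFrame (see module docstring)."""
    return pd.read_csv(fixture_path(name), sep="\t")


def nhy_marker_map() -> MarkerMap:
    return read_marker_map(fixture_path("nhy_marker_map"))


def interval_name(a: str, b: str) -> str:
    return f"{a}-{b}"


def interval_tally(table2: pd.DataFrame, genotype: str, a: str, b: str) -> IntervalTally:
    """Tetrad PD/TT/NPD tally for one genotype and interval of table2_nhy."""
    row = _row(table2, genotype, a, b)
    return IntervalTally((a, b), float(row.PD), float(row.TT), float(row.NPD))


def spore_tally(table2: pd.DataFrame, genotype: str, a: str, b: str) -> SporeTally:
    row = _row(table2, genotype, a, b)
    return SporeTally(float(row.parental), float(row.recombinant))


def _row(table2: pd.DataFrame, genotype: str, a: str, b: str):
    sel = table2[
        (table2.genotype == genotype) & (table2.interval == interval_name(a, b))
    ]
    if len(sel) != 1:
        raise KeyError(f"no unique row for {genotype!r} {a}-{b}")
    return sel.iloc[0]
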