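"""Data model and I/O for yeast tetrad dissection tables and marker maps.

A dissected tetrad is four spore clones from one meiosis. Each spore is
genotyped at a panel of two-allele markers; calls are recorded by parental
origin (``P1``/``P2``), with ``BOTH`` for a disomic spore that carries both
homologs of a chromosome and ``NONE`` for a missing call (dead spores carry
``NONE`` everywhere: an inviable spore cannot be genotyped).

File formats are plain UTF-8 TSV:

* dissection table: ``tetrad_id  spore_id  viable  <marker1> ... <markerK>``
* marker map: ``marker  chromosome  position_cM  is_centromere_linked  is_mating_type``
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

ALLELE_TOKENS = ("P1", "P2", "BOTH", "NONE")
SPORE_IDS = ("a", "b", "c", "d")


class TetradIOError(ValueError):
    """Malformed dissection table or marker map."""


class UndefinedRateError(ValueError):
    """A rate was requested over an empty denominator."""


@dataclass(frozen=True)
class Marker:
    name: str
    chromosome: str
    position_cM: float
    is_centromere_linked: bool = False
    is_mating_type: bool = False


@dataclass
class MarkerMap:
    """Ordered markers with chromosome assignment and genetic positions."""

    markers: list[Marker]

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise TetradIOError("duplicate marker names in map")
        if sum(m.is_mating_type for m in self.markers) > 1:
            raise TetradIOError("at most one mating-type marker allowed")
        for m in self.markers:
            if m.position_cM < 0:
                raise TetradIOError(f"negative position for marker {m.name}")
        for chrom in {m.chromosome for m in self.markers}:
            pos = [m.position_cM for m in self.markers if m.chromosome == chrom]
            if any(b < a for a, b in zip(pos, pos[1:])):
                raise TetradIOError(
                    f"marker positions not non-decreasing on chromosome {chrom}"
                )
        self._by_name = {m.name: m for m in self.markers}

    def __iter__(self):
        return iter(self.markers)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Marker:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"marker {name!r} not in map") from None

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def chromosome_markers(self, chromosome: str) -> list[Marker]:
        return [m for m in self.markers if m.chromosome == chromosome]

    def mating_type_marker(self) -> Marker | None:
        for m in self.markers:
            if m.is_mating_type:
                return m
        return None

    def centromere_markers(self) -> list[Marker]:
        return [m for m in self.markers if m.is_centromere_linked]


@dataclass
class SporeRecord:
    """One dissected spore clone: viability plus per-marker allele calls."""

    tetrad_id: str
    spore_id: str
    viable: bool
    alleles: dict[str, str]

    def validate(self, marker_names: Sequence[str]) -> None:
        if self.spore_id not in SPORE_IDS:
            raise TetradIOError(
                f"tetrad {self.tetrad_id}: spore id {self.spore_id!r} not in a-d"
            )
        for name in marker_names:
            call = self.alleles.get(name)
            if call not in ALLELE_TOKENS:
                raise TetradIOError(
                    f"tetrad {self.tetrad_id} spore {self.spore_id}: "
                    f"bad allele call {call!r} at {name}"
                )
        if not self.viable and any(
            self.alleles[n] != "NONE" for n in marker_names
        ):
            raise TetradIOError(
                f"tetrad {self.tetrad_id} spore {self.spore_id}: "
                "dead spore must have all calls NONE"
            )


@dataclass
class Tetrad:
    tetrad_id: str
    spores: list[SporeRecord]

    def __post_init__(self) -> None:
        if len(self.spores) != 4:
            raise TetradIOError(
                f"tetrad {self.tetrad_id}: expected 4 spores, got {len(self.spores)}"
            )
        ids = [s.spore_id for s in self.spores]
        if len(set(ids)) != 4:
            raise TetradIOError(f"tetrad {self.tetrad_id}: duplicate spore ids")

    @property
    def n_viable(self) -> int:
        return sum(s.viable for s in self.spores)

    @property
    def viable_spores(self) -> list[SporeRecord]:
        return [s for s in self.spores if s.viable]


@dataclass
class TetradDataset:
    strain: str
    marker_map: MarkerMap
    tetrads: list[Tetrad]

    def __post_init__(self) -> None:
        names = self.marker_map.names
        for t in self.tetrads:
            for s in t.spores:
                s.validate(names)

    def __len__(self) -> int:
        return len(self.tetrads)


class SegregationClass(enum.Enum):
    """Per-marker segregation pattern of a tetrad (P1:P2 among 4 spores)."""

    TWO_TWO = "2:2"
    THREE_ONE = "3:1"
    ONE_THREE = "1:3"
    FOUR_ZERO = "4:0"
    ZERO_FOUR = "0:4"
    UNSCORABLE = "unscorable"


ABERRANT_CLASSES = frozenset(
    {
        SegregationClass.THREE_ONE,
        SegregationClass.ONE_THREE,
        SegregationClass.FOUR_ZERO,
        SegregationClass.ZERO_FOUR,
    }
)

_COUNT_TO_CLASS = {
    (2, 2): SegregationClass.TWO_TWO,
    (3, 1): SegregationClass.THREE_ONE,
    (1, 3): SegregationClass.ONE_THREE,
    (4, 0): SegregationClass.FOUR_ZERO,
    (0, 4): SegregationClass.ZERO_FOUR,
}


def classify_marker_segregation(tetrad: Tetrad, marker: str) -> SegregationClass:
    """Classify P1:P2 segregation at one marker.

    Scorable only in four-spore-viable tetrads with clean parental calls;
    a ``BOTH`` (disomic) or ``NONE`` call among the viable spores makes the
    marker unscorable, as does spore death.
    """
    if tetrad.n_viable < 4:
        return SegregationClass.UNSCORABLE
    calls = [s.alleles[marker] for s in tetrad.spores]
    if any(c not in ("P1", "P2") for c in calls):
        return SegregationClass.UNSCORABLE
    key = (calls.count("P1"), calls.count("P2"))
    return _COUNT_TO_CLASS[key]


def aberrant_rate(dataset: TetradDataset, marker: str) -> float:
    """Percent of four-spore-viable tetrads with non-2:2 segregation at *marker*.

    The denominator is the number of four-spore-viable tetrads, the
    convention used when gene-conversion (non-Mendelian segregation)
    frequencies are reported from dissection data.
    """
    if marker not in dataset.marker_map:
        raise KeyError(f"marker {marker!r} not in map")
    complete = [t for t in dataset.tetrads if t.n_viable == 4]
    if not complete:
        raise UndefinedRateError("no four-spore-viable tetrads")
    n_aberrant = sum(
        classify_marker_segregation(t, marker) in ABERRANT_CLASSES for t in complete
    )
    return 100.0 * n_aberrant / len(complete)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_MAP_HEADER = ["marker", "chromosome", "position_cM", "is_centromere_linked", "is_mating_type"]


def read_marker_map(path: str | Path) -> MarkerMap:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != _MAP_HEADER:
        raise TetradIOError(f"{path}: bad marker-map header")
    markers = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) != 5:
            raise TetradIOError(f"{path}:{i}: expected 5 fields, got {len(f)}")
        try:
            markers.append(
                Marker(f[0], f[1], float(f[2]), f[3] == "1", f[4] == "1")
            )
        except ValueError as exc:
            raise TetradIOError(f"{path}:{i}: {exc}") from None
    return MarkerMap(markers)


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_MAP_HEADER) + "\n")
        for m in marker_map:
            fh.write(
                f"{m.name}\t{m.chromosome}\t{m.position_cM:g}\t"
                f"{int(m.is_centromere_linked)}\t{int(m.is_mating_type)}\n"
            )


def read_tetrad_table(path: str | Path, map_path: str | Path) -> TetradDataset:
    """Load a dissection table against a marker map.

    Raises :class:`TetradIOError` naming the offending line for malformed
    rows, unknown marker columns, tetrads without exactly four spores, and
    duplicate (tetrad, spore) pairs.
    """
    marker_map = read_marker_map(map_path)
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise TetradIOError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[:3] != ["tetrad_id", "spore_id", "viable"]:
        raise TetradIOError(f"{path}: bad dissection-table header")
    marker_cols = header[3:]
    for name in marker_cols:
        if name not in marker_map:
            raise TetradIOError(f"{path}: unknown marker column {name!r}")
    if set(marker_cols) != set(marker_map.names):
        missing = set(marker_map.names) - set(marker_cols)
        raise TetradIOError(f"{path}: missing marker columns {sorted(missing)}")

    groups: dict[str, list[SporeRecord]] = {}
    order: list[str] = []
    seen: set[tuple[str, str]] = set()
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) != 3 + len(marker_cols):
            raise TetradIOError(
                f"{path}:{i}: expected {3 + len(marker_cols)} fields, got {len(f)}"
            )
        tid, sid, viable = f[0], f[1], f[2]
        if viable not in ("0", "1"):
            raise TetradIOError(f"{path}:{i}: viable must be 0 or 1, got {viable!r}")
        if (tid, sid) in seen:
            raise TetradIOError(f"{path}:{i}: duplicate spore {sid!r} in tetrad {tid!r}")
        seen.add((tid, sid))
        alleles = dict(zip(marker_cols, f[3:]))
        for name, call in alleles.items():
            if call not in ALLELE_TOKENS:
                raise TetradIOError(
                    f"{path}:{i}: bad allele token {call!r} in column {name}"
                )
        if tid not in groups:
            groups[tid] = []
            order.append(tid)
        groups[tid].append(SporeRecord(tid, sid, viable == "1", alleles))

    tetrads = []
    for tid in order:
        spores = groups[tid]
        if len(spores) != 4:
            raise TetradIOError(
                f"{path}: tetrad {tid!r} has {len(spores)} spore rows, expected 4"
            )
        tetrads.append(Tetrad(tid, spores))
    return TetradDataset(path.stem, marker_map, tetrads)


def write_tetrad_table(dataset: TetradDataset, path: str | Path) -> None:
    """Emit the canonical TSV dialect; round-trips through read_tetrad_table."""
    names = dataset.marker_map.names
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["tetrad_id", "spore_id", "viable"] + names) + "\n")
        for t in dataset.tetrads:
            for s in t.spores:
                calls = [s.alleles[n] for n in names]
                fh.write(
                    "\t".join([t.tetrad_id, s.spore_id, str(int(s.viable))] + calls)
                    + "\n"
                )
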