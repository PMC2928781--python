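"""Meiosis simulator emitting dissection data in the canonical format.

The model, per bivalent (homolog pair) and meiosis:

* **Crossover placement.**  A two-pathway mixture.  The interfering pathway
  is a stationary counting (chi-square) renewal process: precursor events
  fall as Poisson with intensity 2(m+1)(1-f) per Morgan and every (m+1)-th
  precursor matures into a crossover, with the phase randomized so the
  process is stationary.  The non-interfering pathway adds independent
  Poisson crossovers at 2f per Morgan.  With f the non-interfering fraction,
  total crossover intensity is 2 per Morgan regardless of m and f, so a
  bivalent of genetic length L Morgans receives 2L crossovers on average
  (each crossover involves two of four chromatids, hence 2 per Morgan of
  map length).  m = 0 reduces exactly to the Poisson no-interference null.

* **Chromatid choice.**  Each crossover joins one chromatid from each
  homolog, picked uniformly and independently (no chromatid interference).

* **Gene conversion.**  With probability g per marker per meiosis, one
  uniformly chosen chromatid's allele at that marker is overwritten with
  the opposite allele, producing 3:1 / 1:3 segregation.

* **Nondisjunction and spore death.**  A bivalent that received zero
  crossovers has no chiasma to direct Meiosis I and nondisjoins with
  probability ``ndj_prob_e0``, sending both homologs to one pole: two
  spores end up disomic and two nullisomic for that chromosome.
  Nullisomy is always lethal; disomy is lethal unless the chromosome is
  flagged ``disome_viable`` (chromosome III disomes survive and, carrying
  both MAT alleles, are non-maters).  Dead spores are emitted with all
  calls NONE, as in real dissections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Marker, MarkerMap, SporeRecord, Tetrad, TetradDataset, SPORE_IDS


@dataclass
class ChromosomeSpec:
    """Physical layout of one simulated chromosome.

    Positions are in Morgans from the left telomere; ``centromere_m`` must
    lie within [0, length_m].  ``marker_pos_m`` must be increasing.
    """

    name: str
    length_m: float
    centromere_m: float
    marker_names: list[str]
    marker_pos_m: list[float]
    disome_viable: bool = False
    centromere_marker: str | None = None  # marker flagged centromere-linked
    mating_type_marker: str | None = None

    def __post_init__(self) -> None:
        if self.length_m < 0:
            raise ValueError("negative chromosome length")
        if not 0 <= self.centromere_m <= max(self.length_m, 0):
            raise ValueError("centromere outside chromosome")
        if len(self.marker_names) != len(self.marker_pos_m):
            raise ValueError("marker names/positions length mismatch")
        if any(
            b <= a for a, b in zip(self.marker_pos_m, self.marker_pos_m[1:])
        ):
            raise ValueError("marker positions must be strictly increasing")


@dataclass
class SimParams:
    """Simulation parameters; defaults are wild-type-like SK1 settings."""

    chromosomes: list[ChromosomeSpec]
    interference_m: int = 3
    noninterfering_fraction: float = 0.2
    conversion_prob: float = 0.01
    ndj_prob_e0: float = 0.5
    n_tetrads: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interference_m < 0:
            raise ValueError("interference order m must be >= 0")
        for p, nm in (
            (self.noninterfering_fraction, "noninterfering_fraction"),
            (self.conversion_prob, "conversion_prob"),
            (self.ndj_prob_e0, "ndj_prob_e0"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1]")
        if self.n_tetrads < 0:
            raise ValueError("n_tetrads must be >= 0")

    def marker_map(self) -> MarkerMap:
        markers = []
        for c in self.chromosomes:
            for name, pos in zip(c.marker_names, c.marker_pos_m):
                markers.append(
                    Marker(
                        name,
                        c.name,
                        position_cM=100.0 * (pos - c.marker_pos_m[0]),
                        is_centromere_linked=(name == c.centromere_marker),
                        is_mating_type=(name == c.mating_type_marker),
                    )
                )
        return MarkerMap(markers)


@dataclass
class MeiosisTruth:
    """Ground truth emitted alongside each simulated tetrad."""

    tetrad_id: str
    crossovers: dict[str, list[tuple[float, int, int]]]  # chrom -> (pos, i, j)
    conversions: list[tuple[str, int]]  # (marker, chromatid index)
    ndj_chromosomes: list[str]
    spore_ploidy: dict[str, tuple[int, int, int, int]]  # chrom -> per-spore copy no.


def simulate_bivalent(
    length_m: float,
    m: int,
    noninterfering_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample crossover positions (Morgans) on one bivalent.

    Returns a sorted array combining the interfering counting-process
    crossovers with the independent Poisson (non-interfering) ones.
    Expected total count is 2 * length_m.
    """
    if length_m < 0:
        raise ValueError("negative length")
    if length_m == 0:
        return np.empty(0)
    f = noninterfering_fraction
    out = []
    if f < 1.0:
        # precursors at 2(m+1)(1-f) per Morgan; every (m+1)-th is a crossover,
        # phase-randomized so the renewal process is stationary
        rate = 2.0 * (m + 1) * (1.0 - f)
        k = rng.poisson(rate * length_m)
        if k:
            precursors = np.sort(rng.random(k)) * length_m
            phase = rng.integers(0, m + 1)
            idx = np.arange(k)
            out.append(precursors[(idx + phase) % (m + 1) == m])
    if f > 0.0:
        k = rng.poisson(2.0 * f * length_m)
        if k:
            out.append(rng.random(k) * length_m)
    if not out:
        return np.empty(0)
    return np.sort(np.concatenate(out))


def _segregate_chromosome(
    spec: ChromosomeSpec,
    params: SimParams,
    rng: np.random.Generator,
    truth_xo: list,
    truth_conv: list,
):
    """Simulate one bivalent through both meiotic divisions.

    Returns (calls, ploidy): ``calls[s][k]`` is spore s's allele token at
    marker k (before viability masking), ploidy is per-spore copy number.
    Spores are the four meiotic products in fixed order: (0, 1) are the
    Meiosis II products of pole 1 and (2, 3) of pole 2, so under normal
    disjunction (0, 1) and (2, 3) are sister-spore pairs.
    """
    k = len(spec.marker_names)
    pos = spec.marker_pos_m
    xovers = simulate_bivalent(
        spec.length_m, params.interference_m, params.noninterfering_fraction, rng
    )
    events = []
    for x in xovers:
        i = int(rng.integers(0, 2))
        j = int(rng.integers(2, 4))
        truth_xo.append((float(x), i, j))
        events.append((float(x), i, j))

    # Final chromatids are identified by their centromere: 0,1 carry the
    # homolog-1 (P1) centromere, 2,3 homolog-2 (P2).  Each arm is resolved
    # by walking outward from the centromere and switching strands at every
    # crossover that involves the strand currently being followed.
    alleles = [[0] * k for _ in range(4)]
    for left_arm in (False, True):
        if left_arm:
            marker_idx = [
                idx for idx in range(k) if pos[idx] < spec.centromere_m
            ][::-1]
            arm = sorted(
                (e for e in events if e[0] < spec.centromere_m), reverse=True
            )
        else:
            marker_idx = [idx for idx in range(k) if pos[idx] >= spec.centromere_m]
            arm = sorted(e for e in events if e[0] >= spec.centromere_m)
        cur = [0, 1, 2, 3]  # strand currently followed by each chromatid
        e = 0
        for idx in marker_idx:
            while e < len(arm) and (
                arm[e][0] > pos[idx] if left_arm else arm[e][0] < pos[idx]
            ):
                _, i, j = arm[e]
                for c in range(4):
                    if cur[c] == i:
                        cur[c] = j
                    elif cur[c] == j:
                        cur[c] = i
                e += 1
            for c in range(4):
                alleles[c][idx] = 1 if cur[c] < 2 else 2
    # single-chromatid, single-marker gene conversion
    g = params.conversion_prob
    if g > 0:
        for idx in range(k):
            if rng.random() < g:
                c = int(rng.integers(0, 4))
                alleles[c][idx] = 3 - alleles[c][idx]
                truth_conv.append((spec.marker_names[idx], c))

    ndj = len(xovers) == 0 and rng.random() < params.ndj_prob_e0
    tok = {1: "P1", 2: "P2"}
    if not ndj:
        calls = [[tok[alleles[s][idx]] for idx in range(k)] for s in range(4)]
        return calls, (1, 1, 1, 1), False
    # MI nondisjunction: both homologs to one pole; the two spores of that
    # pole each receive one chromatid of each homolog, the other two none
    pole = int(rng.integers(0, 2))
    pairs = [(0, 2), (1, 3)]
    calls = [["NONE"] * k for _ in range(4)]
    ploidy = [0, 0, 0, 0]
    for slot, (c1, c2) in enumerate(pairs):
        s = 2 * pole + slot
        ploidy[s] = 2
        for idx in range(k):
            a1, a2 = alleles[c1][idx], alleles[c2][idx]
            calls[s][idx] = tok[a1] if a1 == a2 else "BOTH"
    return calls, tuple(ploidy), True


def simulate_tetrad(
    params: SimParams, rng: np.random.Generator, tetrad_id: str = "T1"
) -> tuple[Tetrad, MeiosisTruth]:
    """Simulate one meiosis and package it as a dissected tetrad."""
    truth = MeiosisTruth(tetrad_id, {}, [], [], {})
    all_calls: dict[str, list[str]] = {}  # marker -> per-spore call
    dead = [False] * 4
    for spec in params.chromosomes:
        xo: list = []
        calls, ploidy, ndj = _segregate_chromosome(
            spec, params, rng, xo, truth.conversions
        )
        truth.crossovers[spec.name] = xo
        truth.spore_ploidy[spec.name] = ploidy
        if ndj:
            truth.ndj_chromosomes.append(spec.name)
        for s in range(4):
            if ploidy[s] == 0 or (ploidy[s] == 2 and not spec.disome_viable):
                dead[s] = True
        for idx, name in enumerate(spec.marker_names):
            all_calls[name] = [calls[s][idx] for s in range(4)]
    marker_names = [
        name for spec in params.chromosomes for name in spec.marker_names
    ]
    spores = []
    for s in range(4):
        alleles = {
            name: ("NONE" if dead[s] else all_calls[name][s])
            for name in marker_names
        }
        spores.append(SporeRecord(tetrad_id, SPORE_IDS[s], not dead[s], alleles))
    return Tetrad(tetrad_id, spores), truth


def simulate_dataset(
    params: SimParams, strain: str = "simulated"
) -> tuple[TetradDataset, list[MeiosisTruth]]:
    """Simulate ``params.n_tetrads`` meioses; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    marker_map = params.marker_map()
    tetrads, truths = [], []
    for i in range(params.n_tetrads):
        t, tr = simulate_tetrad(params, rng, tetrad_id=f"T{i + 1}")
        tetrads.append(t)
        truths.append(tr)
    return TetradDataset(strain, marker_map, tetrads), truths


def write_truth_table(truths: list[MeiosisTruth], path: str | Path) -> None:
    """Serialize per-tetrad ground truth as TSV (one row per tetrad)."""
    chroms = list(truths[0].crossovers) if truths else []
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["tetrad_id"]
        for c in chroms:
            cols += [f"xo_{c}", f"ploidy_{c}"]
        cols += ["ndj_chromosomes", "conversions"]
        fh.write("\t".join(cols) + "\n")
        for tr in truths:
            row = [tr.tetrad_id]
            for c in chroms:
                xo = ";".join(
                    f"{p:.6f}:{i}:{j}" for p, i, j in tr.crossovers[c]
                )
                row += [xo or ".", ",".join(map(str, tr.spore_ploidy[c]))]
            row.append(",".join(tr.ndj_chromosomes) or ".")
            row.append(
                ";".join(f"{m}:{c}" for m, c in tr.conversions) or "."
            )
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Ready-made parameter sets
# ---------------------------------------------------------------------------

def nhy_like_chromosomes() -> list[ChromosomeSpec]:
    """Chromosomes III, VII, VIII with the marker spacing of the SK1
    mapping strains (wild-type map distances), plus unassayed flanks.

    Lengths and centromere placements are order-of-magnitude choices for
    SK1; only the marker spacing is calibrated to real map data.
    """
    return [
        ChromosomeSpec(
            name="III",
            length_m=1.15,
            centromere_m=0.499,
            marker_names=["HIS4", "LEU2", "CEN3", "MAT"],
            marker_pos_m=[0.300, 0.438, 0.499, 0.648],
            disome_viable=True,  # III disomes survive as non-maters
            centromere_marker="CEN3",
            mating_type_marker="MAT",
        ),
        ChromosomeSpec(
            name="VII",
            length_m=4.0,
            centromere_m=1.10,
            marker_names=["TRP5", "CYH2", "MET13", "LYS5"],
            marker_pos_m=[1.000, 1.360, 1.453, 1.664],
            centromere_marker=None,
        ),
        ChromosomeSpec(
            name="VIII",
            length_m=2.0,
            centromere_m=0.750,
            marker_names=["CEN8", "THR1", "CUP1"],
            marker_pos_m=[0.750, 0.965, 1.212],
            centromere_marker="CEN8",
        ),
    ]


def wild_type_params(n_tetrads: int = 500, seed: int = 0, **overrides) -> SimParams:
    """Wild-type-like dissection experiment: interfering crossovers
    (m=3, 20% non-interfering), ~1% conversion per marker, and MI
    nondisjunction of half of the achiasmate bivalents."""
    kwargs = dict(
        chromosomes=nhy_like_chromosomes(),
        interference_m=3,
        noninterfering_fraction=0.2,
        conversion_prob=0.01,
        ndj_prob_e0=0.5,
        n_tetrads=n_tetrads,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimParams(**kwargs)


def msh45_null_params(n_tetrads: int = 500, seed: int = 0, **overrides) -> SimParams:
    """msh4/msh5-null-like settings: ~2.4-fold reduced map lengths, no
    interference (residual crossovers are interference-free), elevated
    conversion."""
    chroms = nhy_like_chromosomes()
    scaled = []
    s = 1.0 / 2.4
    for c in chroms:
        scaled.append(
            ChromosomeSpec(
                name=c.name,
                length_m=c.length_m * s,
                centromere_m=c.centromere_m * s,
                marker_names=list(c.marker_names),
                marker_pos_m=[p * s for p in c.marker_pos_m],
                disome_viable=c.disome_viable,
                centromere_marker=c.centromere_marker,
                mating_type_marker=c.mating_type_marker,
            )
        )
    kwargs = dict(
        chromosomes=scaled,
        interference_m=0,
        noninterfering_fraction=1.0,
        conversion_prob=0.03,
        ndj_prob_e0=0.5,
        n_tetrads=n_tetrads,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimParams(**kwargs)


def single_interval_params(
    length_cM: float,
    n_tetrads: int,
    seed: int = 0,
    interference_m: int = 0,
    noninterfering_fraction: float = 0.0,
    flank_m: float = 0.25,
    **overrides,
) -> SimParams:
    """One chromosome with two markers spanning ``length_cM``; handy for
    calibration studies.  Flanking unassayed regions keep the renewal
    process's boundary away from the markers."""
    d = length_cM / 100.0
    spec = ChromosomeSpec(
        name="chr1",
        length_m=d + 2 * flank_m,
        centromere_m=flank_m,
        marker_names=["A", "B"],
        marker_pos_m=[flank_m, flank_m + d],
        centromere_marker="A",
    )
    kwargs = dict(
        chromosomes=[spec],
        interference_m=interference_m,
        noninterfering_fraction=noninterfering_fraction,
        conversion_prob=0.0,
        ndj_prob_e0=0.0,
        n_tetrads=n_tetrads,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimParams(**kwargs)


def multi_marker_params(
    marker_cM: list[float],
    n_tetrads: int,
    seed: int = 0,
    interference_m: int = 0,
    noninterfering_fraction: float = 0.0,
    flank_m: float = 0.25,
    **overrides,
) -> SimParams:
    """One chromosome with markers at the given cumulative cM positions."""
    names = [f"M{i}" for i in range(1, len(marker_cM) + 1)]
    pos = [flank_m + c / 100.0 for c in marker_cM]
    spec = ChromosomeSpec(
        name="chr1",
        length_m=pos[-1] + flank_m,
        centromere_m=flank_m,
        marker_names=names,
        marker_pos_m=pos,
        centromere_marker=names[0],
    )
    kwargs = dict(
        chromosomes=[spec],
        interference_m=interference_m,
        noninterfering_fraction=noninterfering_fraction,
        conversion_prob=0.0,
        ndj_prob_e0=0.0,
        n_tetrads=n_tetrads,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimParams(**kwargs)
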