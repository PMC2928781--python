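"""Interval classification and genetic map distances from tetrads and spores.

For a pair of linked markers, each complete tetrad falls into one of three
classes — parental ditype (PD), tetratype (TT), nonparental ditype (NPD) —
whose relative frequencies encode the crossover count in the interval.
The Perkins estimator converts the tally into a map distance in
centimorgans, correcting for double crossovers via NPDs:

    cM = 100 * (TT/2 + 3*NPD) / n,   n = PD + TT + NPD

Its standard error is obtained by the delta method on the multinomial
(TT, NPD) frequencies.  The single-spore route simply scores the percent
of recombinant spores, with a Wilson score interval on the proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .io import (
    ABERRANT_CLASSES,
    MarkerMap,
    SegregationClass,
    Tetrad,
    TetradDataset,
    classify_marker_segregation,
)

PD, TT, NPD, EXCLUDED = "PD", "TT", "NPD", "EXCLUDED"


class EmptyTallyError(ValueError):
    """No scorable tetrads (or spores) for the requested estimate."""


@dataclass
class IntervalTally:
    """PD/TT/NPD counts for one marker interval.

    Counts are reals, not ints: published tallies occasionally carry
    half-integer spore counts from ambiguous scoring, and downstream
    estimators are agnostic to integrality.
    """

    interval: tuple[str, str]
    pd: float
    tt: float
    npd: float

    def __post_init__(self) -> None:
        if min(self.pd, self.tt, self.npd) < 0:
            raise ValueError("negative tetrad counts")

    @property
    def n(self) -> float:
        return self.pd + self.tt + self.npd

    @property
    def recombinant(self) -> float:
        """Tetrads carrying at least one detected crossover (TT + NPD)."""
        return self.tt + self.npd


@dataclass
class SporeTally:
    parental: float
    recombinant: float

    @property
    def total(self) -> float:
        return self.parental + self.recombinant


@dataclass
class MapEstimate:
    cM: float
    se_cM: float | None = None
    ci_cM: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.ci_cM is not None:
            lo, hi = self.ci_cM
            if not (lo <= self.cM <= hi):
                raise ValueError("point estimate outside its confidence interval")


def _check_interval(marker_map: MarkerMap, interval: tuple[str, str]) -> str:
    a, b = interval
    ma, mb = marker_map[a], marker_map[b]
    if ma.chromosome != mb.chromosome:
        raise ValueError(
            f"interval markers {a}/{b} lie on different chromosomes "
            f"({ma.chromosome} vs {mb.chromosome})"
        )
    return ma.chromosome


def classify_interval(
    tetrad: Tetrad, marker_map: MarkerMap, interval: tuple[str, str]
) -> str:
    """Classify one tetrad as PD/TT/NPD for a marker interval.

    Tetrads that are not four-spore viable, or that segregate aberrantly
    (non-2:2) at *any* marker of the interval's chromosome, are EXCLUDED:
    a conversion event anywhere on the chromosome makes crossover classes
    ambiguous, and excluding per chromosome keeps every interval of a
    chromosome scored over the same tetrad set.
    """
    chrom = _check_interval(marker_map, interval)
    for m in marker_map.chromosome_markers(chrom):
        cls = classify_marker_segregation(tetrad, m.name)
        if cls is not SegregationClass.TWO_TWO:
            return EXCLUDED
    a, b = interval
    n_rec = sum(
        (s.alleles[a] != s.alleles[b]) for s in tetrad.spores
    )
    # with both markers 2:2 the recombinant-spore count is 0, 2 or 4
    return {0: PD, 2: TT, 4: NPD}[n_rec]


def tally_interval(dataset: TetradDataset, interval: tuple[str, str]) -> IntervalTally:
    """Sum classify_interval over a dataset, dropping EXCLUDED tetrads."""
    counts = {PD: 0, TT: 0, NPD: 0}
    for t in dataset.tetrads:
        cls = classify_interval(t, dataset.marker_map, interval)
        if cls != EXCLUDED:
            counts[cls] += 1
    tally = IntervalTally(tuple(interval), counts[PD], counts[TT], counts[NPD])
    if tally.n == 0:
        raise EmptyTallyError(f"no scorable tetrads for interval {interval}")
    return tally


def perkins_distance(tally: IntervalTally) -> MapEstimate:
    """Perkins map distance with its delta-method standard error."""
    if tally.n <= 0:
        raise EmptyTallyError("empty tally")
    cm = 100.0 * (tally.tt / 2.0 + 3.0 * tally.npd) / tally.n
    return MapEstimate(cM=cm, se_cM=perkins_se(tally))


def perkins_se(tally: IntervalTally) -> float:
    """Multinomial delta-method SE of the Perkins estimator, in cM.

    With t = TT/n and v = NPD/n the estimator is 100*(t/2 + 3v); the
    delta method on the multinomial covariance of (t, v) gives

        SE = 100 * sqrt[ (t(1-t)/4 + 9v(1-v) - 3tv) / n ]
    """
    n = tally.n
    if n <= 0:
        raise EmptyTallyError("empty tally")
    t = tally.tt / n
    v = tally.npd / n
    var = (t * (1.0 - t) / 4.0 + 9.0 * v * (1.0 - v) - 3.0 * t * v) / n
    return 100.0 * math.sqrt(max(var, 0.0))


def spore_rf(tally: SporeTally, confidence: float = 0.95) -> MapEstimate:
    """Single-spore map distance: percent recombinant spores, Wilson CI."""
    if tally.total <= 0:
        raise EmptyTallyError("no spores")
    cm = 100.0 * tally.recombinant / tally.total
    ci = wilson_ci(tally.recombinant, tally.total, confidence)
    return MapEstimate(cM=cm, ci_cM=ci)


def wilson_ci(
    recombinant: float, total: float, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval (no continuity correction) on the recombinant
    proportion, scaled to cM (x100)."""
    if total <= 0:
        raise EmptyTallyError("no spores")
    if not 0 <= recombinant <= total:
        raise ValueError("recombinant count outside [0, total]")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    lo, hi = proportion_confint(
        recombinant, total, alpha=1.0 - confidence, method="wilson"
    )
    # clamp floating-point dust at the boundaries (e.g. lo = 4e-17 at k=0)
    lo = 0.0 if recombinant == 0 else min(max(lo, 0.0), 1.0)
    hi = 1.0 if recombinant == total else min(max(hi, 0.0), 1.0)
    return (100.0 * lo, 100.0 * hi)


def chromosome_map_sum(
    dataset: TetradDataset,
    intervals: list[tuple[str, str]],
    route: str = "tetrad",
) -> float:
    """Sum per-interval map distances over *intervals* by the chosen route.

    route="tetrad" sums Perkins estimates; route="spore" sums recombinant
    spore frequencies over all viable spores (a spore is scored whenever
    both marker calls are clean parental alleles, regardless of tetrad
    completeness).
    """
    if not intervals:
        raise ValueError("empty interval list")
    if route == "tetrad":
        return sum(
            perkins_distance(tally_interval(dataset, iv)).cM for iv in intervals
        )
    if route == "spore":
        total = 0.0
        for iv in intervals:
            tally = spore_tally(dataset, iv)
            total += spore_rf(tally).cM
        return total
    raise ValueError(f"unknown route {route!r}")


def spore_tally(dataset: TetradDataset, interval: tuple[str, str]) -> SporeTally:
    """Count parental vs recombinant viable spores for an interval."""
    _check_interval(dataset.marker_map, interval)
    a, b = interval
    par = rec = 0
    for t in dataset.tetrads:
        for s in t.viable_spores:
            ca, cb = s.alleles[a], s.alleles[b]
            if ca in ("P1", "P2") and cb in ("P1", "P2"):
                if ca == cb:
                    par += 1
                else:
                    rec += 1
    if par + rec == 0:
        raise EmptyTallyError(f"no scorable spores for interval {interval}")
    return SporeTally(par, rec)
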