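"""Strain-level statistics: spore-viability profiles, nondisjunction
signatures, Fisher-exact strain comparisons, and the viability-versus-
crossover threshold surface.

Meiosis I nondisjunction of a homolog pair leaves two spores disomic and
two nullisomic for that chromosome.  In yeast only a few disomes are
tolerated; a chromosome-III disome is viable and carries both mating-type
alleles, so it fails to mate ("non-mater").  Two-spore-viable tetrads in
which both survivors are non-maters are therefore the genetic signature of
chromosome-III nondisjunction, and survivors that agree at every
centromere-linked marker are inferred to be sister spores.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import TetradDataset


class ConfigurationError(ValueError):
    """The dataset/marker map lacks information required by a statistic."""


@dataclass
class ViabilityProfile:
    counts_by_viable_spores: tuple[int, int, int, int, int]  # index 0..4
    percent_viable: float


@dataclass
class NdjSignature:
    two_spore_tetrads: int
    nonmater_two_spore_fraction: float  # percent of 2-spore-viable tetrads
    sister_two_spore_fraction: float


def viability_profile(dataset: TetradDataset) -> ViabilityProfile:
    """Tally tetrads by number of viable spores; percent viability is over
    all dissected spores, including those of 0-viable tetrads."""
    counts = [0, 0, 0, 0, 0]
    for t in dataset.tetrads:
        counts[t.n_viable] += 1
    total = sum(counts)
    if total == 0:
        raise ValueError("empty dataset")
    viable_spores = sum(k * c for k, c in enumerate(counts))
    return ViabilityProfile(tuple(counts), 100.0 * viable_spores / (4 * total))


def ndj_signature(dataset: TetradDataset) -> NdjSignature:
    """Nondisjunction signature among two-spore-viable tetrads.

    Non-mater: both viable spores call BOTH at the mating-type marker.
    Sister pair: the viable spores agree at every centromere-linked marker.
    """
    mat = dataset.marker_map.mating_type_marker()
    if mat is None:
        raise ConfigurationError("no mating-type marker in map")
    cen_markers = [m.name for m in dataset.marker_map.centromere_markers()]
    two_spore = [t for t in dataset.tetrads if t.n_viable == 2]
    if not two_spore:
        return NdjSignature(0, 0.0, 0.0)
    nonmater = sister = 0
    for t in two_spore:
        s1, s2 = t.viable_spores
        if s1.alleles[mat.name] == "BOTH" and s2.alleles[mat.name] == "BOTH":
            nonmater += 1
        if cen_markers and all(
            s1.alleles[m] == s2.alleles[m] for m in cen_markers
        ):
            sister += 1
    n = len(two_spore)
    return NdjSignature(n, 100.0 * nonmater / n, 100.0 * sister / n)


def fisher_exact_2x2(a: float, b: float, c: float, d: float) -> float:
    """Two-tailed Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The two-tailed p sums hypergeometric probabilities of all tables with
    the observed margins that are no more probable than the observed one.
    Degenerate tables (a zero margin) return p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative counts")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def threshold_surface(
    strains: list[tuple[str, float, float]], viability_cutoff: float = 0.0
) -> pd.DataFrame:
    """Order strains by total map distance and tag those whose spore
    viability falls below *viability_cutoff* (percent).

    *strains* is a list of (label, total_cM, percent_viable).  The result
    is the (cM, SV) scatter underlying a threshold analysis: viability
    stays high until crossing over drops below some map-distance level.
    """
    if not strains:
        raise ValueError("no strains")
    df = pd.DataFrame(strains, columns=["label", "total_cM", "percent_viable"])
    df = df.sort_values("total_cM", kind="mergesort").reset_index(drop=True)
    df["below_cutoff"] = df["percent_viable"] < viability_cutoff
    return df
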