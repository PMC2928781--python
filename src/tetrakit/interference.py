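"""Crossover-interference statistics for tetrad data.

Two classical tests are provided:

* **Coefficient of coincidence (COC)** across a pair of adjacent intervals:
  the ratio of observed double-crossover tetrads to the number expected if
  crossovers in the two intervals occurred independently.  Significance is
  assessed with a continuity-corrected normal approximation to the binomial.

* **NPD ratio** within a single interval: observed nonparental ditypes
  divided by those expected under random (no-interference) crossing over.
  Expected NPDs come either from Papazian's closed-form formula (driven by
  the tetratype frequency alone) or from a one-parameter maximum-likelihood
  fit of the Poisson exchange model to the full (PD, TT, NPD) tally, with a
  chi-square goodness-of-fit test.

Both statistics are < 1 under positive interference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize, stats

from .linkage import EXCLUDED, NPD, TT, IntervalTally, classify_interval
from .io import MarkerMap, TetradDataset


class ModelInfeasibleError(ValueError):
    """The no-interference model cannot reproduce the observed tally."""


@dataclass
class COCResult:
    dco_obs: float
    dco_exp: float
    coc: float
    p_two_tailed: float
    interference_called: bool


@dataclass
class NPDRatioResult:
    npd_obs: float
    npd_exp: float
    ratio: float
    x_hat: float
    chi2: float
    p: float
    method: str

    @property
    def interference_called(self) -> bool:
        return self.p < 0.05 and self.ratio < 1.0


def _check_adjacent(
    marker_map: MarkerMap, interval1: tuple[str, str], interval2: tuple[str, str]
) -> None:
    chrom1 = marker_map[interval1[0]].chromosome
    chrom2 = marker_map[interval2[0]].chromosome
    if chrom1 != chrom2:
        raise ValueError("interval pair spans two chromosomes")
    if interval1[1] != interval2[0]:
        raise ValueError(
            f"intervals {interval1} and {interval2} are not adjacent "
            "(must share their middle marker)"
        )


def count_dco(
    dataset: TetradDataset,
    interval1: tuple[str, str],
    interval2: tuple[str, str],
) -> int:
    """Number of tetrads with a detected crossover (TT or NPD) in both of
    two adjacent intervals.  A tetrad counts once however many exchanges
    it carries."""
    _check_adjacent(dataset.marker_map, interval1, interval2)
    n = 0
    for t in dataset.tetrads:
        c1 = classify_interval(t, dataset.marker_map, interval1)
        c2 = classify_interval(t, dataset.marker_map, interval2)
        if c1 in (TT, NPD) and c2 in (TT, NPD):
            n += 1
    return n


def expected_dco(tally1: IntervalTally, tally2: IntervalTally) -> float:
    """Expected double-crossover tetrads under independence: R1*R2/n with
    Ri the crossover-containing (TT+NPD) tetrads of interval i, both
    tallied over the same n tetrads."""
    if abs(tally1.n - tally2.n) > 1e-9:
        raise ValueError(
            f"tallies cover different tetrad sets (n={tally1.n} vs {tally2.n})"
        )
    if tally1.n <= 0:
        raise ValueError("empty tallies")
    return tally1.recombinant * tally2.recombinant / tally1.n


def coc_test(dco_obs: float, dco_exp: float, n: float) -> COCResult:
    """Coefficient of coincidence with a two-tailed binomial test.

    The observed DCO count is referred to Binomial(n, dco_exp/n) through
    the continuity-corrected normal approximation:

        z = (|obs - exp| - 0.5) / sqrt(n p0 (1-p0)),  p = 2(1 - Phi(z))

    Interference is called when p < 0.05 and COC < 1 (only a deficit of
    double crossovers indicates interference).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if dco_exp < 0:
        raise ValueError("expected DCO must be non-negative")
    if dco_exp == 0:
        if dco_obs > 0:
            raise ModelInfeasibleError(
                "observed double crossovers with zero expected: COC undefined"
            )
        return COCResult(dco_obs, 0.0, float("nan"), 1.0, False)
    coc = dco_obs / dco_exp
    p0 = dco_exp / n
    if p0 >= 1.0:
        raise ValueError("expected DCO count exceeds n")
    num = abs(dco_obs - dco_exp) - 0.5
    if num <= 0:
        p = 1.0
    else:
        z = num / math.sqrt(n * p0 * (1.0 - p0))
        p = 2.0 * stats.norm.sf(z)
    return COCResult(dco_obs, dco_exp, coc, p, p < 0.05 and coc < 1.0)


def no_interference_probs(x: float) -> tuple[float, float, float]:
    """(pPD, pTT, pNPD) for an interval under Poisson(x) exchanges per
    meiosis and no chromatid interference.

    Each exchange picks one of the four nonsister chromatid pairs uniformly.
    The classical solution of the resulting three-state chain is

        pTT  = (2/3) (1 - e^{-3x/2})
        pNPD = 1/6 + (1/3) e^{-3x/2} - (1/2) e^{-x}
        pPD  = pNPD + e^{-x}

    so at x=0 the tetrad is surely PD, and as x grows the classes approach
    the 1/6 : 2/3 : 1/6 equilibrium.
    """
    if x < 0:
        raise ValueError("mean exchange count must be >= 0")
    e32 = math.exp(-1.5 * x)
    e1 = math.exp(-x)
    p_tt = (2.0 / 3.0) * (1.0 - e32)
    p_npd = 1.0 / 6.0 + e32 / 3.0 - e1 / 2.0
    p_pd = p_npd + e1
    return (p_pd, p_tt, p_npd)


def papazian_expected_npd(tally: IntervalTally) -> float:
    """Papazian's expected NPD count under no interference, from the
    tetratype frequency T = TT/n alone:

        E[NPD] = n/2 * [ (1 - T) - (1 - 3T/2)^{2/3} ]

    Feasible only for T < 2/3 (the maximum tetratype frequency the random
    exchange model can produce).
    """
    if tally.n <= 0:
        raise ValueError("empty tally")
    T = tally.tt / tally.n
    if T >= 2.0 / 3.0:
        raise ModelInfeasibleError(
            f"tetratype frequency {T:.3f} >= 2/3: no-interference model infeasible"
        )
    return tally.n * 0.5 * ((1.0 - T) - (1.0 - 1.5 * T) ** (2.0 / 3.0))


def _neg_loglik(x: float, tally: IntervalTally) -> float:
    p_pd, p_tt, p_npd = no_interference_probs(x)
    ll = 0.0
    for count, p in ((tally.pd, p_pd), (tally.tt, p_tt), (tally.npd, p_npd)):
        if count > 0:
            if p <= 0:
                return float("inf")
            ll += count * math.log(p)
    return -ll


def fit_exchange_mean(tally: IntervalTally) -> float:
    """Maximum-likelihood mean exchange count x under the no-interference
    model, by bounded scalar search on x in [1e-6, 20]."""
    res = optimize.minimize_scalar(
        _neg_loglik,
        bounds=(1e-6, 20.0),
        args=(tally,),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"exchange-mean fit did not converge: {res.message}")
    return float(res.x)


def npd_ratio_test(tally: IntervalTally, method: str = "mle") -> NPDRatioResult:
    """NPD-ratio interference test on a single interval.

    method="papazian": expected NPDs from the tetratype frequency
    (moment estimate); x_hat is the implied exchange mean and the
    chi-square compares the full tally against the model at that x.

    method="mle": x_hat maximizes the multinomial likelihood of
    (PD, TT, NPD); expected NPD = n*pNPD(x_hat); chi-square goodness of
    fit with 1 degree of freedom (3 classes - 1 - 1 fitted parameter).
    """
    if method not in ("papazian", "mle"):
        raise ValueError(f"unknown method {method!r}")
    n = tally.n
    if n <= 0:
        raise ValueError("empty tally")
    if method == "papazian":
        npd_exp = papazian_expected_npd(tally)
        T = tally.tt / n
        # exchange mean implied by the tetratype frequency
        x_hat = -math.log(1.0 - 1.5 * T) / 1.5 if T > 0 else 0.0
    else:
        x_hat = fit_exchange_mean(tally)
        npd_exp = n * no_interference_probs(x_hat)[2]
    if npd_exp <= 0:
        if tally.npd > 0:
            raise ModelInfeasibleError("zero expected NPDs with observed NPDs")
        return NPDRatioResult(tally.npd, 0.0, float("nan"), x_hat, 0.0, 1.0, method)
    expected = [n * p for p in no_interference_probs(x_hat)]
    observed = [tally.pd, tally.tt, tally.npd]
    chi2 = sum(
        (o - e) ** 2 / e for o, e in zip(observed, expected) if e > 0
    )
    p = float(stats.chi2.sf(chi2, df=1))
    return NPDRatioResult(
        tally.npd, npd_exp, tally.npd / npd_exp, x_hat, chi2, p, method
    )
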