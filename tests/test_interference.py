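"""COC and NPD-ratio interference statistics."""

import math

import numpy as np
import pytest

from tetrakit.fixtures import interval_tally, load_fixture
from tetrakit.interference import (
    ModelInfeasibleError,
    _neg_loglik,
    coc_test,
    count_dco,
    expected_dco,
    fit_exchange_mean,
    no_interference_probs,
    npd_ratio_test,
    papazian_expected_npd,
)
from tetrakit.io import Marker, MarkerMap, TetradDataset
from tetrakit.linkage import IntervalTally

from conftest import make_tetrad


@pytest.fixture(scope="module")
def table2():
    return load_fixture("table2_nhy")


@pytest.fixture
def map3():
    return MarkerMap(
        [Marker("A", "1", 0.0), Marker("B", "1", 10.0), Marker("C", "1", 20.0)]
    )


class TestCountDco:
    def test_hand_built_counts(self, map3):
        pd_row = [("P1",) * 3, ("P1",) * 3, ("P2",) * 3, ("P2",) * 3]
        # TT in both intervals (single exchange per interval, 3-strand)
        dco = [
            ("P1", "P1", "P1"),
            ("P1", "P2", "P1"),
            ("P2", "P1", "P2"),
            ("P2", "P2", "P2"),
        ]
        tetrads = [make_tetrad(f"T{i}", pd_row, ["A", "B", "C"]) for i in range(3)]
        tetrads += [make_tetrad(f"D{i}", dco, ["A", "B", "C"]) for i in range(2)]
        ds = TetradDataset("t", map3, tetrads)
        assert count_dco(ds, ("A", "B"), ("B", "C")) == 2

    def test_all_parental_counts_zero(self, map3):
        pd_row = [("P1",) * 3, ("P1",) * 3, ("P2",) * 3, ("P2",) * 3]
        ds = TetradDataset(
            "t", map3, [make_tetrad(f"T{i}", pd_row, ["A", "B", "C"]) for i in range(5)]
        )
        assert count_dco(ds, ("A", "B"), ("B", "C")) == 0

    def test_non_adjacent_intervals_rejected(self, map3):
        ds = TetradDataset("t", map3, [])
        with pytest.raises(ValueError, match="adjacent"):
            count_dco(ds, ("A", "B"), ("A", "C"))


class TestExpectedDco:
    @pytest.mark.parametrize(
        "geno, iv1, iv2, expected",
        [
            ("wild-type", ("HIS4", "LEU2"), ("LEU2", "CEN3"), 17.5),
            ("wild-type", ("CEN8", "THR1"), ("THR1", "CUP1"), 107.2),
            ("msh4-R676W", ("HIS4", "LEU2"), ("LEU2", "CEN3"), 16.2),
        ],
    )
    def test_published_values(self, table2, geno, iv1, iv2, expected):
        t1 = interval_tally(table2, geno, *iv1)
        t2 = interval_tally(table2, geno, *iv2)
        assert expected_dco(t1, t2) == pytest.approx(expected, abs=0.05)

    def test_no_crossovers_means_zero(self):
        t1 = IntervalTally(("A", "B"), 100, 0, 0)
        t2 = IntervalTally(("B", "C"), 80, 20, 0)
        assert expected_dco(t1, t2) == 0.0

    def test_unequal_n_rejected(self):
        t1 = IntervalTally(("A", "B"), 100, 0, 0)
        t2 = IntervalTally(("B", "C"), 80, 20, 1)
        with pytest.raises(ValueError, match="different tetrad sets"):
            expected_dco(t1, t2)


class TestCocTest:
    def test_strong_interference_called(self):
        res = coc_test(67, 107.2, 538)
        assert res.coc == pytest.approx(0.625, abs=0.001)
        assert res.p_two_tailed < 1e-4
        assert res.interference_called

    def test_weak_deficit_not_called(self):
        res = coc_test(14, 16.2, 679)
        assert res.coc == pytest.approx(0.864, abs=0.001)
        assert res.p_two_tailed == pytest.approx(0.667, abs=0.01)
        assert not res.interference_called

    def test_published_p_for_wild_type_chromosome_iii(self):
        res = coc_test(5, 17.489, 556)
        assert res.p_two_tailed == pytest.approx(0.004, abs=0.001)
        assert res.interference_called

    def test_observed_equal_expected(self):
        res = coc_test(20, 20.0, 500)
        assert res.coc == 1.0
        assert res.p_two_tailed == 1.0
        assert not res.interference_called

    def test_excess_never_called_interference(self):
        res = coc_test(60, 30.0, 500)
        assert res.p_two_tailed < 0.05
        assert res.coc > 1
        assert not res.interference_called

    def test_zero_expected_with_observed_is_error(self):
        with pytest.raises(ModelInfeasibleError):
            coc_test(3, 0.0, 500)


class TestNullModel:
    def test_boundaries(self):
        assert no_interference_probs(0.0) == (1.0, 0.0, 0.0)
        ppd, ptt, pnpd = no_interference_probs(60.0)
        assert ppd == pytest.approx(1 / 6, abs=1e-9)
        assert ptt == pytest.approx(2 / 3, abs=1e-9)
        assert pnpd == pytest.approx(1 / 6, abs=1e-9)

    @pytest.mark.parametrize("x", [0.01, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0])
    def test_probabilities_sum_to_one(self, x):
        assert sum(no_interference_probs(x)) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("x", [0.25, 0.5, 1.0, 2.0])
    def test_matches_monte_carlo_oracle(self, x):
        """Brute-force oracle: Poisson exchange counts, uniform nonsister
        chromatid pairs, tetrad class read off the four two-marker spores."""
        n = 200_000
        rng = np.random.default_rng(int(x * 1000) + 7)
        counts = rng.poisson(x, size=n)
        b = np.tile(np.array([1, 1, 2, 2]), (n, 1))  # distal-marker alleles
        for k in range(1, counts.max() + 1):
            active = counts >= k
            na = active.sum()
            if na == 0:
                break
            i = rng.integers(0, 2, size=na)
            j = rng.integers(2, 4, size=na)
            rows = np.nonzero(active)[0]
            bi = b[rows, i]
            b[rows, i] = b[rows, j]
            b[rows, j] = bi
        origin = np.array([1, 1, 2, 2])
        nrec = (b != origin).sum(axis=1)
        p_hat = np.array([(nrec == 0).mean(), (nrec == 2).mean(), (nrec == 4).mean()])
        p_theory = np.array(no_interference_probs(x))
        se = np.sqrt(p_theory * (1 - p_theory) / n)
        assert np.all(np.abs(p_hat - p_theory) < 3 * se + 1e-12)


class TestPapazian:
    def test_zero_tetratypes(self):
        assert papazian_expected_npd(IntervalTally(("A", "B"), 100, 0, 0)) == 0.0

    def test_direct_formula_value(self):
        # wild-type TRP5-CYH2 tally: T = 337/543
        tally = IntervalTally(("A", "B"), 197, 337, 9)
        assert papazian_expected_npd(tally) == pytest.approx(57.3, abs=0.05)

    def test_infeasible_tetratype_frequency(self):
        with pytest.raises(ModelInfeasibleError):
            papazian_expected_npd(IntervalTally(("A", "B"), 10, 90, 0))

    @pytest.mark.parametrize("T", [0.05, 0.2, 0.4, 0.6])
    def test_agrees_with_null_model_at_matched_tetratype_frequency(self, T):
        """Papazian's formula equals n*pNPD(x) at the x whose pTT equals T."""
        n = 1000.0
        tally = IntervalTally(("A", "B"), n * (1 - T), n * T, 0.0)
        x = -math.log(1 - 1.5 * T) / 1.5
        _, ptt, pnpd = no_interference_probs(x)
        assert ptt == pytest.approx(T, abs=1e-12)
        assert papazian_expected_npd(tally) == pytest.approx(n * pnpd, abs=1e-8)


class TestNpdRatio:
    def test_mle_likelihood_beats_moment_estimate(self, table2):
        for geno in ["wild-type", "msh4-R676W"]:
            for iv in [("TRP5", "CYH2"), ("CEN8", "THR1"), ("THR1", "CUP1")]:
                tally = interval_tally(table2, geno, *iv)
                x_mle = fit_exchange_mean(tally)
                T = tally.tt / tally.n
                x_moment = -math.log(1 - 1.5 * T) / 1.5
                assert _neg_loglik(x_mle, tally) <= _neg_loglik(x_moment, tally) + 1e-9

    def test_interference_flagged_on_published_interval(self, table2):
        tally = interval_tally(table2, "wild-type", "TRP5", "CYH2")
        res = npd_ratio_test(tally, method="mle")
        assert res.ratio < 1
        assert res.p < 0.05
        assert res.interference_called

    def test_observed_equal_expected_gives_unit_ratio(self):
        # build a tally lying exactly on the null model at x = 0.5
        ppd, ptt, pnpd = no_interference_probs(0.5)
        n = 10000
        tally = IntervalTally(("A", "B"), n * ppd, n * ptt, n * pnpd)
        res = npd_ratio_test(tally, method="mle")
        assert res.ratio == pytest.approx(1.0, abs=1e-3)
        assert res.p > 0.9

    def test_papazian_and_mle_agree_on_null_data(self):
        ppd, ptt, pnpd = no_interference_probs(0.7)
        n = 5000
        tally = IntervalTally(("A", "B"), n * ppd, n * ptt, n * pnpd)
        r1 = npd_ratio_test(tally, method="papazian")
        r2 = npd_ratio_test(tally, method="mle")
        assert r1.npd_exp == pytest.approx(r2.npd_exp, rel=1e-3)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            npd_ratio_test(IntervalTally(("A", "B"), 10, 5, 0), method="bogus")
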