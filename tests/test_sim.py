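"""Meiosis simulator: moments, interference, conversion, nondisjunction."""

import math

import numpy as np
import pytest

from tetrakit.io import aberrant_rate
from tetrakit.linkage import classify_interval, perkins_distance, tally_interval
from tetrakit.sim import (
    ChromosomeSpec,
    SimParams,
    multi_marker_params,
    simulate_bivalent,
    simulate_dataset,
    single_interval_params,
    wild_type_params,
)
from tetrakit.io import write_tetrad_table


class TestSimulateBivalent:
    def test_zero_length_no_crossovers(self):
        rng = np.random.default_rng(0)
        assert len(simulate_bivalent(0.0, 3, 0.2, rng)) == 0

    def test_poisson_moments_without_interference(self):
        rng = np.random.default_rng(1)
        counts = np.array(
            [len(simulate_bivalent(0.5, 0, 0.0, rng)) for _ in range(10_000)]
        )
        se = math.sqrt(1.0 / 10_000)
        assert abs(counts.mean() - 1.0) < 3 * se
        # Poisson: variance equals mean
        assert abs(counts.var() - counts.mean()) < 0.1

    def test_counting_model_underdispersed(self):
        rng = np.random.default_rng(2)
        counts = np.array(
            [len(simulate_bivalent(1.0, 3, 0.0, rng)) for _ in range(10_000)]
        )
        assert abs(counts.mean() - 2.0) < 0.05
        assert counts.var() < 0.8 * counts.mean()

    def test_mean_preserved_under_mixture(self):
        rng = np.random.default_rng(3)
        counts = [len(simulate_bivalent(1.0, 4, 0.3, rng)) for _ in range(10_000)]
        assert abs(np.mean(counts) - 2.0) < 3 * math.sqrt(2.0 / 10_000) + 0.02

    def test_interference_protects_obligate_crossover(self):
        """Zero-crossover bivalents are rarer under interference at equal length."""
        rng = np.random.default_rng(4)
        L = 1.0
        z0 = np.mean(
            [len(simulate_bivalent(L, 0, 0.0, rng)) == 0 for _ in range(10_000)]
        )
        z3 = np.mean(
            [len(simulate_bivalent(L, 3, 0.0, rng)) == 0 for _ in range(10_000)]
        )
        assert abs(z0 - math.exp(-2 * L)) < 3 * math.sqrt(math.exp(-2 * L) / 10_000) + 0.005
        assert z3 < z0


class TestSimulateDataset:
    def test_deterministic_for_fixed_seed(self, tmp_path):
        params = wild_type_params(n_tetrads=100, seed=77)
        d1, _ = simulate_dataset(params)
        d2, _ = simulate_dataset(params)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_tetrad_table(d1, p1)
        write_tetrad_table(d2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_length_all_parental_all_viable(self):
        params = SimParams(
            chromosomes=[
                ChromosomeSpec("c", 0.0, 0.0, ["A"], [0.0]),
            ],
            interference_m=0,
            conversion_prob=0.0,
            ndj_prob_e0=0.0,
            n_tetrads=50,
            seed=1,
        )
        ds, truths = simulate_dataset(params)
        for t in ds.tetrads:
            assert t.n_viable == 4
            calls = sorted(s.alleles["A"] for s in t.spores)
            assert calls == ["P1", "P1", "P2", "P2"]
        assert all(not tr.crossovers["c"] for tr in truths)

    def test_map_length_recovery(self):
        params = single_interval_params(20, 2000, seed=5, interference_m=0)
        ds, _ = simulate_dataset(params)
        est = perkins_distance(tally_interval(ds, ("A", "B")))
        assert abs(est.cM - 20.0) < 3 * est.se_cM

    def test_recombinant_spore_fraction_matches_length(self):
        """Short-interval limit: 1 cM = 1% recombinant spores.  At longer
        lengths double crossovers hide exchanges, so the recombinant
        fraction follows the Poisson-model expectation (1 - e^(-2d))/2
        rather than the map length itself."""
        from tetrakit.linkage import spore_rf, spore_tally

        for cm, seed in [(5, 11), (10, 12), (20, 13)]:
            params = single_interval_params(cm, 2000, seed=seed, interference_m=0)
            ds, _ = simulate_dataset(params)
            est = spore_rf(spore_tally(ds, ("A", "B")))
            p = (1 - math.exp(-2 * cm / 100)) / 2
            se = 100 * math.sqrt(p * (1 - p) / 8000)
            assert abs(est.cM - 100 * p) < 3 * se
            if cm == 5:
                assert abs(est.cM - cm) < 3 * se + 0.25  # 1 cM ~ 1% limit

    def test_tetratype_frequency_matches_closed_form(self):
        """20 cM, m=0: TT/n within 3 SEs of (2/3)(1-e^(-3x/2)), x=0.4."""
        params = single_interval_params(20, 2000, seed=6, interference_m=0)
        ds, _ = simulate_dataset(params)
        tally = tally_interval(ds, ("A", "B"))
        p_tt = (2 / 3) * (1 - math.exp(-1.5 * 0.4))
        se = math.sqrt(p_tt * (1 - p_tt) / tally.n)
        assert abs(tally.tt / tally.n - p_tt) < 3 * se

    def test_two_exchange_bivalents_give_1_2_1(self):
        """No chromatid interference: PD:TT:NPD = 1:2:1 given 2 exchanges."""
        params = single_interval_params(100, 20_000, seed=7, interference_m=0, flank_m=0.0)
        ds, truths = simulate_dataset(params)
        counts = {"PD": 0, "TT": 0, "NPD": 0}
        for t, tr in zip(ds.tetrads, truths):
            if len(tr.crossovers["chr1"]) == 2:
                counts[classify_interval(t, ds.marker_map, ("A", "B"))] += 1
        n = sum(counts.values())
        for cls, p in [("PD", 0.25), ("TT", 0.5), ("NPD", 0.25)]:
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[cls] / n - p) < 3.5 * se

    def test_conversion_rate_recovered(self):
        """g=0.02 yields ~2% aberrant segregation per marker."""
        params = single_interval_params(
            10, 5000, seed=8, interference_m=0, conversion_prob=0.02
        )
        ds, _ = simulate_dataset(params)
        se = 100 * math.sqrt(0.02 * 0.98 / 5000)
        for marker in ("A", "B"):
            assert abs(aberrant_rate(ds, marker) - 2.0) < 3 * se


class TestNondisjunction:
    def test_forced_ndj_yields_nonmater_sister_pairs(self):
        """A zero-length (always achiasmate) chromosome III with certain MI
        nondisjunction leaves two viable disomic spores that are sisters and
        carry both mating types."""
        chrom3 = ChromosomeSpec(
            "III",
            0.0,
            0.0,
            ["CEN3", "MAT"],
            [0.0, 1e-9],
            disome_viable=True,
            centromere_marker="CEN3",
            mating_type_marker="MAT",
        )
        params = SimParams(
            chromosomes=[chrom3],
            interference_m=0,
            conversion_prob=0.0,
            ndj_prob_e0=1.0,
            n_tetrads=100,
            seed=9,
        )
        ds, truths = simulate_dataset(params)
        from tetrakit.strain_stats import ndj_signature, viability_profile

        prof = viability_profile(ds)
        assert prof.counts_by_viable_spores == (0, 0, 100, 0, 0)
        sig = ndj_signature(ds)
        assert sig.two_spore_tetrads == 100
        assert sig.nonmater_two_spore_fraction == 100.0
        assert sig.sister_two_spore_fraction == 100.0
        assert all(tr.ndj_chromosomes == ["III"] for tr in truths)
        # disomic spores carry BOTH at every chromosome-III marker
        for t in ds.tetrads:
            for s in t.viable_spores:
                assert s.alleles["MAT"] == "BOTH"

    def test_lethal_disomes_kill_whole_tetrads(self):
        chrom = ChromosomeSpec("VII", 0.0, 0.0, ["A"], [0.0], disome_viable=False)
        params = SimParams(
            chromosomes=[chrom],
            ndj_prob_e0=1.0,
            conversion_prob=0.0,
            n_tetrads=20,
            seed=10,
        )
        ds, _ = simulate_dataset(params)
        assert all(t.n_viable == 0 for t in ds.tetrads)

    def test_excess_of_zero_and_two_viable_spores_under_strong_ndj(self):
        """Obligate-crossover failure produces the 0/2-viable excess, and the
        excess grows with the nondisjunction probability."""
        def profile(ndj_prob, seed):
            chroms = [
                ChromosomeSpec(
                    "III", 0.10, 0.05, ["CEN3", "MAT"], [0.05, 0.08],
                    disome_viable=True, centromere_marker="CEN3",
                    mating_type_marker="MAT",
                ),
                ChromosomeSpec("VII", 0.15, 0.05, ["A"], [0.05]),
            ]
            params = SimParams(
                chromosomes=chroms,
                interference_m=0,
                conversion_prob=0.0,
                ndj_prob_e0=ndj_prob,
                n_tetrads=2000,
                seed=seed,
            )
            ds, _ = simulate_dataset(params)
            from tetrakit.strain_stats import viability_profile

            return viability_profile(ds).counts_by_viable_spores

        # short map lengths -> many achiasmate bivalents, as in msh4/5 nulls
        c = profile(0.8, seed=11)
        assert c[0] + c[2] > c[1] + c[3]
        low = profile(0.2, seed=11)
        assert (c[0] + c[2]) > (low[0] + low[2])
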