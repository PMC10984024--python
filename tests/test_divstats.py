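import numpy as np
import pandas as pd
import pytest

from cryptaxon.core import AccessibilityMask, AlleleCounts, accessible_windows
from cryptaxon.divstats import (
    diversity_window,
    dxy,
    folded_sfs,
    hudson_fst,
    hudson_fst_sites,
    pi_window,
    rank_top_windows,
    site_pi,
)


def ac_from_alts(alts, n):
    alts = np.asarray(alts)
    return AlleleCounts(np.stack([n - alts, alts], axis=1))


def windows_1kb(n=1):
    mask = AccessibilityMask({"3R": np.ones(1000 * n, dtype=bool)})
    return accessible_windows(mask, "3R", 1000)


class TestPi:
    def test_per_site_combinatorial_value(self):
        # counts (2, 8), n = 10: 2*2*8 / (10*9) = 16/45
        assert site_pi(ac_from_alts([8], 10))[0] == pytest.approx(16 / 45)

    def test_monomorphic_window_zero(self):
        w = pi_window(ac_from_alts([0, 10], 10), np.array([100, 200]), windows_1kb())
        assert w.loc[0, "pi_per_base"] == 0.0

    def test_single_site_over_accessible_bases(self):
        w = pi_window(ac_from_alts([5], 10), np.array([100]), windows_1kb())
        assert w.loc[0, "pi_per_base"] == pytest.approx((25 / 45) / 1000)

    def test_equals_bruteforce_pairwise_differences(self):
        """pi from allele counts == explicit O(n^2 L) haplotype comparison."""
        rng = np.random.default_rng(8)
        haps = (rng.random((200, 20)) < rng.uniform(0.05, 0.95, 200)[:, None]).astype(int)
        n = 20
        alt = haps.sum(axis=1)
        ac = ac_from_alts(alt, n)
        brute = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                brute += (haps[:, i] != haps[:, j]).sum()
        brute /= n * (n - 1) / 2
        assert site_pi(ac).sum() == pytest.approx(brute, abs=1e-12)


class TestTajimaD:
    def test_no_segregating_sites_is_nan(self):
        w = diversity_window(ac_from_alts([0, 10], 10), np.array([100, 200]), windows_1kb())
        assert np.isnan(w.loc[0, "tajima_d"])

    def test_all_singletons_negative(self):
        ac = ac_from_alts([1] * 10, 20)
        w = diversity_window(ac, np.arange(1, 11) * 50, windows_1kb())
        assert w.loc[0, "tajima_d"] < 0

    def test_neutral_simulation_centered(self):
        """Under neutral constant-size coalescent replicates, mean D ~ 0."""
        import msprime

        ds = []
        reps = msprime.sim_ancestry(
            samples=10, ploidy=2, sequence_length=1, num_replicates=300,
            population_size=1000, random_seed=11,
        )
        for ts in reps:
            mts = msprime.sim_mutations(
                ts, rate=10 / (4 * 1000 * 4), random_seed=int(ts.num_edges) + 1,
                discrete_genome=False,
            )
            if mts.num_sites < 2:
                continue
            alt = np.array(
                [g.sum() for g in (v.genotypes for v in mts.variants())]
            )
            ac = ac_from_alts(alt, 20)
            w = diversity_window(ac, np.arange(1, len(alt) + 1), windows_1kb())
            if not np.isnan(w.loc[0, "tajima_d"]):
                ds.append(w.loc[0, "tajima_d"])
        assert len(ds) > 100
        assert -0.3 < np.mean(ds) < 0.3


class TestHudsonFst:
    def test_identical_cohort_samples_near_zero(self):
        """Two samples of one population: estimator unbiased near zero."""
        rng = np.random.default_rng(12)
        p = rng.uniform(0.05, 0.95, 10_000)
        a1 = ac_from_alts(rng.binomial(40, p), 40)
        a2 = ac_from_alts(rng.binomial(40, p), 40)
        assert abs(hudson_fst(a1, a2)) < 0.01

    def test_fixed_difference_is_one(self):
        assert hudson_fst(ac_from_alts([10], 10), ac_from_alts([0], 10)) == pytest.approx(1.0)

    def test_bhatia_hand_example(self):
        """pop1 8/10 alt, pop2 2/10 alt: N/D = 0.477124... (hand-checked)."""
        num, den = hudson_fst_sites(ac_from_alts([8], 10), ac_from_alts([2], 10))
        assert num[0] == pytest.approx(0.36 - 2 * (0.16 / 9), abs=1e-12)
        assert den[0] == pytest.approx(0.68, abs=1e-12)
        assert num[0] / den[0] == pytest.approx(0.477124, abs=1e-6)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        a = ac_from_alts([8, 10], 10)
        b = ac_from_alts([2, 0], 10)
        num, den = hudson_fst_sites(a, b)
        assert hudson_fst(a, b) == pytest.approx(num.sum() / den.sum())
        assert hudson_fst(a, b) != pytest.approx(np.mean(num / den))

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        a = ac_from_alts(rng.integers(0, 21, 500), 20)
        b = ac_from_alts(rng.integers(0, 21, 500), 20)
        assert hudson_fst(a, b) == pytest.approx(hudson_fst(b, a))

    def test_low_sample_sites_skipped(self):
        a = AlleleCounts(np.array([[1, 0]]))  # n1 = 1 < 2
        b = ac_from_alts([5], 10)
        num, _ = hudson_fst_sites(a, b)
        assert np.isnan(num[0])


class TestDxy:
    def test_identical_monomorphic_zero(self):
        w = dxy(ac_from_alts([0], 10), ac_from_alts([0], 10), np.array([100]), windows_1kb())
        assert w.loc[0, "dxy_per_base"] == 0.0

    def test_fixed_difference_over_100_bases(self):
        mask = AccessibilityMask({"3R": np.ones(100, dtype=bool)})
        win = accessible_windows(mask, "3R", 100)
        w = dxy(ac_from_alts([10], 10), ac_from_alts([0], 10), np.array([50]), win)
        assert w.loc[0, "dxy_per_base"] == pytest.approx(0.01)

    def test_per_site_formula(self):
        w = dxy(ac_from_alts([8], 10), ac_from_alts([2], 10), np.array([100]), windows_1kb())
        assert w.loc[0, "dxy_per_base"] * 1000 == pytest.approx(0.68)

    def test_symmetric(self, study_scenario, scenario_cohorts):
        from cryptaxon.core import allele_counts

        a = allele_counts(study_scenario.gm, scenario_cohorts["BIS"])
        b = allele_counts(study_scenario.gm, scenario_cohorts["GA"])
        pos = study_scenario.vt.pos
        win = accessible_windows(study_scenario.mask, "3R", 100_000)
        np.testing.assert_allclose(
            dxy(a, b, pos, win)["dxy_per_base"], dxy(b, a, pos, win)["dxy_per_base"]
        )


class TestFoldedSfs:
    def test_folding(self):
        # alt counts 1, 1, 9 of n=10 fold to minor count 1 three times
        sfs = folded_sfs(ac_from_alts([1, 1, 9], 10))
        assert sfs.tolist() == [0, 3, 0, 0, 0, 0]

    def test_monomorphic_excluded(self):
        sfs = folded_sfs(ac_from_alts([0, 10, 5], 10))
        assert sfs.sum() == 1 and sfs[5] == 1

    def test_expansion_excess_of_singletons(self):
        """Population growth leaves a singleton excess over constant size."""
        import msprime

        def singleton_fraction(demography, seed):
            counts = np.zeros(11, dtype=int)
            reps = msprime.sim_ancestry(
                samples=5, ploidy=2, sequence_length=1, num_replicates=400,
                demography=demography, random_seed=seed,
            )
            for ts in reps:
                mts = msprime.sim_mutations(ts, rate=2e-3, random_seed=seed + 1)
                for v in mts.variants():
                    alt = int(v.genotypes.sum())
                    if 0 < alt < 10:
                        counts[min(alt, 10 - alt)] += 1
            return counts[1] / counts.sum()

        const = msprime.Demography()
        const.add_population(initial_size=1000)
        grow = msprime.Demography()
        grow.add_population(initial_size=50_000)
        grow[0].growth_rate = 0  # expansion via a historical size change
        grow.add_population_parameters_change(time=100, initial_size=500)
        assert singleton_fraction(grow, 21) > singleton_fraction(const, 22)


class TestTopWindows:
    def _genes(self):
        return pd.DataFrame(
            {"contig": ["3R"], "start": [10_000], "end": [20_000],
             "strand": ["+"], "gene_id": ["AGAP000001"]}
        )

    def _win(self, values):
        n = len(values)
        df = pd.DataFrame(
            {"contig": "3R",
             "start": np.arange(n) * 100_000 + 1,
             "end": (np.arange(n) + 1) * 100_000,
             "n_accessible": 100_000, "fst": values}
        )
        return df

    def test_overlapping_gene_listed(self):
        top = rank_top_windows(self._win([0.5]), "fst", self._genes(), k=5)
        assert top.loc[0, "gene_ids"] == "AGAP000001"

    def test_touching_boundary_inclusive(self):
        genes = pd.DataFrame(
            {"contig": ["3R"], "start": [1], "end": [100_001],
             "strand": ["+"], "gene_id": ["G2"]}
        )
        win = self._win([0.1, 0.9])
        top = rank_top_windows(win, "fst", genes, k=1)
        assert top.loc[0, "start"] == 100_001  # highest-fst window
        assert top.loc[0, "gene_ids"] == "G2"  # gene ends exactly at its start

    def test_k_larger_than_window_count(self):
        top = rank_top_windows(self._win([0.1, 0.2]), "fst", self._genes(), k=10)
        assert len(top) == 2
        assert top["fst"].tolist() == [0.2, 0.1]
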