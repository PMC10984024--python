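import itertools

import numpy as np
import pandas as pd
import pytest

from cryptaxon.cnv import (
    CnState,
    CoverageMatrix,
    call_cnvs,
    cohort_cnv_frequency,
    filter_windows,
    fit_hmm,
    gc_normalize,
    sample_qc,
    viterbi_decode,
    _log_emissions,
)
from cryptaxon.synthetic import CnvTruth, default_gc_bias, simulate_coverage


def make_cov(counts, gc=None, contig="2R", mappability=None):
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    if gc is None:
        gc = np.full(n, 0.45)
    return CoverageMatrix(
        contig=np.full(n, contig, dtype=object),
        start=np.arange(n, dtype=np.int64) * 300 + 1,
        counts=counts,
        gc=gc,
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
        mappability=mappability,
    )


class TestFilterWindows:
    def test_gc_band(self):
        cov = make_cov(np.ones((3, 1)), gc=np.array([0.9, 0.5, 0.1]))
        keep = filter_windows(cov, gc_band=(0.2, 0.8))
        assert keep.tolist() == [False, True, False]

    def test_zero_mappability_removed(self):
        cov = make_cov(np.ones((2, 1)), mappability=np.array([0.0, 1.0]))
        assert filter_windows(cov).tolist() == [False, True]

    def test_all_pass(self):
        cov = make_cov(np.ones((5, 1)))
        assert filter_windows(cov).all()


class TestGcNormalize:
    def test_uniform_coverage_normalizes_to_two(self):
        cov = make_cov(np.full((500, 2), 60.0))
        norm = gc_normalize(cov)
        np.testing.assert_allclose(norm, 2.0)

    def test_removes_imposed_quadratic_bias(self):
        rng = np.random.default_rng(1)
        gc = rng.uniform(0.25, 0.65, 5000)
        counts = simulate_coverage(5000, ["s"], gc, [], seed=2)
        cov = make_cov(counts, gc=gc)
        norm = gc_normalize(cov)
        for lo in (0.25, 0.35, 0.45, 0.55):
            band = (gc >= lo) & (gc < lo + 0.1)
            assert abs(norm[band, 0].mean() - 2.0) < 0.05

    def test_implanted_cn4_segment_scales(self):
        counts = np.full((1000, 1), 60.0)
        counts[100:110] *= 2
        norm = gc_normalize(make_cov(counts))
        assert abs(norm[100:110, 0].mean() - 4.0) < 0.1

    def test_zero_coverage_sample_fails(self):
        with pytest.raises(ValueError):
            gc_normalize(make_cov(np.zeros((100, 1))))


class TestHmm:
    def test_flat_diploid_track(self):
        cn = fit_hmm(np.full(100, 2.0) + np.random.default_rng(1).normal(0, 0.05, 100))
        assert (cn.states == 2).all()

    def test_implanted_amplification_decoded(self):
        rng = np.random.default_rng(2)
        track = rng.normal(2.0, 0.25, 200)
        track[50:60] = rng.normal(4.0, 0.25, 10)
        cn = fit_hmm(track)
        assert (cn.states[50:60] == 4).all()
        assert (cn.states[:50] == 2).all() and (cn.states[60:] == 2).all()

    def test_male_x_flat_track(self):
        rng = np.random.default_rng(3)
        track = rng.normal(1.0, 0.1, 100)
        cn = fit_hmm(track, ploidy=1)
        assert (cn.states == 1).all()

    def test_viterbi_matches_bruteforce_enumeration(self):
        """Viterbi equals exhaustive max-product on short tracks, few states."""
        rng = np.random.default_rng(4)
        t, k = 10, 4
        stay = 0.9
        log_emit = rng.normal(0, 2, (t, k))
        path = viterbi_decode(log_emit, stay)
        log_trans = np.full((k, k), np.log((1 - stay) / (k - 1)))
        np.fill_diagonal(log_trans, np.log(stay))
        best_score, best_path = -np.inf, None
        for p in itertools.product(range(k), repeat=t):
            s = -np.log(k) + log_emit[0, p[0]]
            for i in range(1, t):
                s += log_trans[p[i - 1], p[i]] + log_emit[i, p[i]]
            if s > best_score:
                best_score, best_path = s, p
        assert tuple(path) == best_path

    def test_posteriors_sum_to_one(self):
        from cryptaxon.cnv import forward_backward

        rng = np.random.default_rng(5)
        post = forward_backward(rng.normal(0, 1, (50, 13)), 0.999)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)


class TestCallCnvs:
    def _state(self, states, post=None):
        states = np.asarray(states)
        if post is None:
            post = np.full(len(states), 0.99)
        return CnState(states, np.asarray(post), 2.0, 0.1)

    def test_four_window_run_not_called(self):
        states = [2] * 10 + [4] * 4 + [2] * 10
        calls = call_cnvs(self._state(states), "s", "2R")
        assert len(calls) == 0

    def test_five_window_run_called(self):
        states = [2] * 10 + [3] * 5 + [2] * 10
        calls = call_cnvs(self._state(states), "s", "2R")
        assert len(calls) == 1
        assert calls.loc[0, ["kind", "modal_state"]].tolist() == ["amp", 3]

    def test_male_x_threshold(self):
        states = [1] * 10 + [2] * 6 + [1] * 10
        calls = call_cnvs(self._state(states), "s", "X", ploidy=1)
        assert len(calls) == 1 and calls.loc[0, "kind"] == "amp"

    def test_deletions_called_symmetrically(self):
        states = [2] * 10 + [0] * 6 + [2] * 10
        calls = call_cnvs(self._state(states), "s", "2R")
        assert len(calls) == 1 and calls.loc[0, "kind"] == "del"

    def test_low_posterior_flagged(self):
        states = [2] * 10 + [3] * 5 + [2] * 10
        post = np.full(25, 0.99)
        post[10:15] = 0.5
        calls = call_cnvs(self._state(states, post), "s", "2R")
        assert not calls.loc[0, "qc_pass"]


class TestSampleQc:
    def test_low_variance_passes(self):
        norm = np.full((100, 1), 2.0) + np.random.default_rng(1).normal(0, 0.1, (100, 1))
        assert sample_qc(norm, np.ones(100, dtype=bool)).all()

    def test_high_variance_fails(self):
        norm = np.random.default_rng(2).normal(2.0, 0.8, (100, 1))
        assert not sample_qc(norm, np.ones(100, dtype=bool), variance_threshold=0.2)[0]


class TestCohortFrequency:
    def _calls(self, rows):
        return pd.DataFrame(
            rows,
            columns=["sample_id", "contig", "start_idx", "end_idx", "start", "end",
                     "kind", "modal_state", "mean_posterior", "qc_pass"],
        )

    def _samples(self, ids, cohort="BIS"):
        return pd.DataFrame(
            {"sample_id": ids, "cohort": cohort, "country": "c", "site": "s",
             "sex": "F", "year": 2020}
        )

    def _regions(self):
        return pd.DataFrame(
            [("cyp6", "2R", 1000, 2000)], columns=["name", "contig", "start", "end"]
        )

    def test_no_calls_zero_frequency(self):
        ids = [f"s{i}" for i in range(10)]
        qc = pd.DataFrame({"sample_id": ids, "qc_pass": True})
        freq = cohort_cnv_frequency(self._calls([]), self._regions(), self._samples(ids), qc)
        assert (freq["frequency"] == 0.0).all()

    def test_five_of_ten_carriers(self):
        ids = [f"s{i}" for i in range(10)]
        qc = pd.DataFrame({"sample_id": ids, "qc_pass": True})
        rows = [(f"s{i}", "2R", 0, 9, 1500, 1800, "amp", 4, 0.99, True) for i in range(5)]
        freq = cohort_cnv_frequency(self._calls(rows), self._regions(), self._samples(ids), qc)
        amp = freq[freq["kind"] == "amp"]
        assert amp["frequency"].iloc[0] == pytest.approx(0.5)

    def test_individual_with_two_calls_counts_once(self):
        ids = ["s0", "s1"]
        qc = pd.DataFrame({"sample_id": ids, "qc_pass": True})
        rows = [
            ("s0", "2R", 0, 9, 1100, 1200, "amp", 3, 0.99, True),
            ("s0", "2R", 20, 29, 1700, 1900, "amp", 5, 0.99, True),
        ]
        freq = cohort_cnv_frequency(self._calls(rows), self._regions(), self._samples(ids), qc)
        amp = freq[freq["kind"] == "amp"]
        assert amp["frequency"].iloc[0] == pytest.approx(0.5)

    def test_region_on_unknown_contig_errors(self):
        ids = ["s0"]
        qc = pd.DataFrame({"sample_id": ids, "qc_pass": True})
        with pytest.raises(ValueError):
            cohort_cnv_frequency(
                self._calls([]), self._regions(), self._samples(ids), qc,
                valid_contigs=["3L"],
            )
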