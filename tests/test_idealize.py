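"""HMM idealization: EM fitting, Viterbi decoding, exclusion, dwells."""

import itertools

import numpy as np
import pytest

from termfret import idealize as idz
from termfret._hmm import viterbi
from termfret.idealize import (
    IdealizedPath,
    decode,
    dwell_table,
    exclude_for_kinetics,
    extract_dwells,
    fit_hmm,
    merge_close_states,
    select_K,
)
from termfret.qc import compute_fret, correct_bleedthrough
from termfret.synthetic import get_fixture, render_trace, sample_state_path, simulate_scenario

from conftest import make_series, noiseless_emission, two_state_scheme

_LOG2PI = np.log(2 * np.pi)


def _brute_force_map(logb, logA, logpi):
    """Exhaustive maximum-a-posteriori path (oracle for Viterbi)."""
    T, K = logb.shape
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = logpi[path[0]] + logb[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logb[t, path[t]]
        if lp > best_lp + 1e-12:
            best_lp, best_path = lp, path
    return np.array(best_path), best_lp


class TestViterbi:
    @pytest.mark.parametrize("K,T", [(2, 6), (2, 10), (3, 7)])
    def test_matches_brute_force_enumeration(self, K, T, rng):
        for _ in range(20):
            logb = np.log(rng.random((T, K)) + 1e-3)
            A = rng.random((K, K)) + 0.1
            A /= A.sum(axis=1, keepdims=True)
            pi = rng.random(K) + 0.1
            pi /= pi.sum()
            path, lp = viterbi(logb, np.log(A), np.log(pi))
            ref_path, ref_lp = _brute_force_map(logb, np.log(A), np.log(pi))
            assert lp == pytest.approx(ref_lp, abs=1e-9)
            assert np.array_equal(path, ref_path)

    def test_tie_breaks_toward_lower_index_state(self):
        # a frame exactly midway between symmetric emissions
        logb = np.zeros((3, 2))  # all emissions equally likely
        logA = np.log(np.full((2, 2), 0.5))
        logpi = np.log(np.array([0.5, 0.5]))
        path, _ = viterbi(logb, logA, logpi)
        assert np.array_equal(path, [0, 0, 0])


class TestFitHmm:
    def test_noiseless_two_level_series_recovered_exactly(self):
        x = np.tile([0.5] * 10 + [0.7] * 10, 5)
        s = make_series(x)
        fit = fit_hmm(s, 2, rng_seed=0)
        assert fit.means == pytest.approx([0.5, 0.7], abs=1e-6)
        path = decode(fit, s)
        assert path.n_transitions == 9
        assert np.array_equal(np.flatnonzero(np.diff(path.states) != 0) + 1,
                              np.arange(10, 100, 10))

    def test_single_state_closed_form(self, rng):
        x = rng.normal(0.6, 0.05, 400)
        fit = fit_hmm(make_series(x), 1)
        assert fit.means[0] == pytest.approx(np.mean(x), abs=1e-12)
        assert fit.sds[0] == pytest.approx(np.std(x), abs=1e-12)

    def test_recovers_generator_state_means(self, rng):
        # fluctuating two-state traces at experimental noise: fitted means
        # within 0.02 of the generating values
        from termfret.synthetic import EmissionModel

        scheme = two_state_scheme(1.5, 1.0, e=(0.52, 0.73))
        em = EmissionModel(bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)
        hits = 0
        for i in range(6):
            path = sample_state_path(scheme, 20.0, 100 + i)
            trace = render_trace(path, scheme, em, 30.0, 200 + i)
            occupied = {s for s, dur in path.sojourns() if dur > 1.0}
            if len(occupied) < 2:
                continue
            series = compute_fret(correct_bleedthrough(trace, 0.13))
            fit = fit_hmm(series, 2, rng_seed=0)
            assert fit.means[0] == pytest.approx(0.52, abs=0.02)
            assert fit.means[1] == pytest.approx(0.73, abs=0.02)
            hits += 1
        assert hits >= 4

    def test_em_loglik_monotone_in_iterations(self, rng):
        x = np.concatenate([rng.normal(0.5, 0.05, 100), rng.normal(0.7, 0.05, 100)])
        s = make_series(x)
        lls = [fit_hmm(s, 2, n_restarts=0, max_iter=m, tol=0).log_likelihood
               for m in (1, 2, 5, 10, 40)]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm(make_series([0.5, 0.6, 0.7]), 2)

    def test_transition_rows_normalized(self, rng):
        x = rng.normal(0.5, 0.05, 60)
        x[::3] += 0.2
        fit = fit_hmm(make_series(x), 2, rng_seed=1)
        assert np.allclose(fit.transmat.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(fit.means) >= 0)

    def test_cross_check_against_reference_hmm(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        x = np.concatenate([rng.normal(0.45, 0.05, 150), rng.normal(0.75, 0.05, 150),
                            rng.normal(0.45, 0.05, 150)])
        fit = fit_hmm(make_series(x), 2, rng_seed=0)
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag",
                                   n_iter=500, tol=1e-8, random_state=0,
                                   min_covar=1e-6)
        ref.fit(x.reshape(-1, 1))
        ref_means = np.sort(ref.means_.ravel())
        assert fit.means == pytest.approx(ref_means, abs=0.01)
        ref_ll = ref.score(x.reshape(-1, 1))
        assert fit.log_likelihood >= ref_ll - 1.0


class TestSelectK:
    def test_single_state_data_selects_one(self, rng):
        x = rng.normal(0.7, 0.05, 400)
        assert select_K(make_series(x), K_max=3) == 1

    def test_clean_two_state_data_selects_two(self, rng):
        spans = rng.integers(5, 30, 30)
        parts, level = [], 0
        for n in spans:
            parts.append(rng.normal(0.5 + 0.2 * (level % 2), 0.05, n))
            level += 1
        x = np.concatenate(parts)
        assert select_K(make_series(x), K_max=4) == 2

    def test_constant_series_selects_one(self):
        assert select_K(make_series(np.full(100, 0.6)), K_max=3) == 1


class TestExclusionRules:
    def _path(self, states, means, ends_with_bleach=False):
        states = np.asarray(states)
        return IdealizedPath(frames=np.arange(states.size), states=states,
                             state_means=np.asarray(means, float), frame_rate=30.0,
                             trace_id=0, ends_with_bleach=ends_with_bleach)

    def test_close_states_are_merged(self):
        p = self._path([0, 1, 0, 1, 1], [0.65, 0.70])
        merged = merge_close_states(p, 0.1)
        assert merged.state_means.size == 1
        assert merged.n_transitions == 0

    def test_distant_states_kept(self):
        p = self._path([0, 1, 0, 1, 0, 1], [0.5, 0.7])
        merged = merge_close_states(p, 0.1)
        assert merged.state_means.size == 2
        assert merged.n_transitions == 5

    def test_merge_is_idempotent(self):
        p = self._path([0, 1, 2, 1, 0, 2], [0.40, 0.47, 0.80])
        once = merge_close_states(p, 0.1)
        twice = merge_close_states(once, 0.1)
        assert np.array_equal(once.states, twice.states)
        assert np.allclose(once.state_means, twice.state_means)

    def test_static_and_single_transition_traces_excluded_from_kinetics(self):
        static = self._path([0, 0, 0, 0], [0.7])
        single = self._path([0, 0, 1, 1], [0.5, 0.7])
        multi = self._path([0, 1, 0, 1], [0.5, 0.7])
        kinetic, all_merged = exclude_for_kinetics([static, single, multi])
        assert len(all_merged) == 3  # retained for histograms
        assert len(kinetic) == 1
        assert kinetic[0].n_transitions == 3


class TestExtractDwells:
    def test_example_sequence_at_30fps(self):
        p = IdealizedPath(frames=np.arange(6), states=np.array([1, 1, 1, 0, 0, 1]),
                          state_means=np.array([0.5, 0.7]), frame_rate=30.0,
                          trace_id=3)
        d = extract_dwells(p)
        assert list(d["n_frames"]) == [3, 2, 1]
        assert d.iloc[0]["censored_left"] and not d.iloc[0]["censored_right"]
        assert d.iloc[1]["duration_s"] == pytest.approx(2 / 30)
        assert not d.iloc[1]["censored_left"] and not d.iloc[1]["censored_right"]
        assert d.iloc[2]["censored_right"]
        assert d.iloc[2]["end_cause"] == "trace_end"

    def test_single_state_path_fully_censored(self):
        p = IdealizedPath(frames=np.arange(8), states=np.zeros(8, int),
                          state_means=np.array([0.7]), frame_rate=30.0,
                          ends_with_bleach=True)
        d = extract_dwells(p)
        assert len(d) == 1
        assert d.iloc[0]["censored_left"] and d.iloc[0]["censored_right"]
        assert d.iloc[0]["end_cause"] == "bleach"

    def test_dwell_frames_conserve_unmasked_frames(self, rng):
        # end-to-end: simulate, decode, dwell frames must sum to valid frames
        fx = get_fixture("posthc_s6l9")
        traces, _ = simulate_scenario(fx, 5, 3)
        for trace in traces:
            series = compute_fret(correct_bleedthrough(trace, 0.13))
            fit = fit_hmm(series, 2, rng_seed=0)
            path = decode(fit, series)
            d = extract_dwells(path)
            assert d["n_frames"].sum() == series.n_valid

    def test_decoded_path_matches_truth_on_noiseless_data(self, rng):
        scheme = two_state_scheme(1.5, 1.0, e=(0.4, 0.8))
        path_true = sample_state_path(scheme, 20.0, rng)
        trace = render_trace(path_true, scheme, noiseless_emission(), 30.0, rng)
        series = compute_fret(trace)
        fit = fit_hmm(series, 2, rng_seed=0)
        decoded = decode(fit, series)
        # majority-occupancy discretization of the true path
        e = {s: m for s, m in zip(scheme.state_ids, scheme.fret_mean)}
        true_frames = np.zeros(trace.n_frames, dtype=int)
        mid = (np.arange(trace.n_frames) + 0.5) / 30.0
        for st, a, b in zip(path_true.states, path_true.t_start, path_true.t_end):
            sel = (mid >= a) & (mid < b)
            true_frames[sel] = 0 if e[st] < 0.6 else 1
        agree = (decoded.states == true_frames[decoded.frames]).mean()
        assert agree > 0.97

    def test_dwell_table_concatenates_traces(self):
        p1 = IdealizedPath(frames=np.arange(4), states=np.array([0, 0, 1, 1]),
                           state_means=np.array([0.5, 0.7]), frame_rate=30.0, trace_id=0)
        p2 = IdealizedPath(frames=np.arange(3), states=np.array([1, 1, 1]),
                           state_means=np.array([0.5, 0.7]), frame_rate=30.0, trace_id=1)
        d = dwell_table([p1, p2])
        assert set(d["trace_id"]) == {0, 1}
        assert len(d) == 3
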