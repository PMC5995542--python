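"""Censored exponential dwell fits, photobleach handling, aggregation."""

import numpy as np
import pandas as pd
import pytest

from termfret.idealize import IdealizedPath
from termfret.kinetics import (
    RateEstimate,
    aggregate_replicates,
    classify_subpopulations,
    correct_koff,
    correct_missed_events,
    estimate_photobleach_rate,
    fit_dwell_exponential,
    select_exp_model,
)

FR = 30.0


def dwell_frame(n_frames, censored=None, trace_id=None, rank=1, mean=0.7):
    n_frames = np.asarray(n_frames, dtype=int)
    if censored is None:
        censored = np.zeros(n_frames.size, dtype=bool)
    if trace_id is None:
        trace_id = np.zeros(n_frames.size, dtype=int)
    return pd.DataFrame({
        "trace_id": trace_id,
        "state": rank,
        "state_mean": mean,
        "state_rank": rank,
        "start_frame": 0,
        "n_frames": n_frames,
        "duration_s": n_frames / FR,
        "censored_left": False,
        "censored_right": np.asarray(censored, dtype=bool),
        "end_cause": np.where(censored, "bleach", "transition"),
    })


def geometric_frames(rng, k, n, fr=FR):
    return rng.geometric(1.0 - np.exp(-k / fr), size=n)


class TestSingleExponential:
    def test_rate_recovery_from_geometric_draws(self, rng):
        d = dwell_frame(geometric_frames(rng, 2.0, 2000))
        fit = fit_dwell_exponential(d, None, 1, FR)
        assert fit.rates[0] == pytest.approx(2.0, rel=0.05)
        assert fit.amplitudes[0] == 1.0

    def test_censoring_aware_fit_is_unbiased_where_naive_is_not(self, rng):
        # 30% right-censoring: survival-aware MLE stays within 5% while
        # inverting the mean of uncensored dwells is biased upward
        k = 2.0
        n = geometric_frames(rng, k, 2000)
        cut = int(np.quantile(n, 0.7))
        censored = n > cut
        frames = np.minimum(n, cut)
        d = dwell_frame(frames, censored)
        fit = fit_dwell_exponential(d, None, 1, FR, n_min=1)
        assert abs(fit.rates[0] / k - 1) < 0.05
        naive = 1.0 / (frames[~censored] / FR).mean()
        assert naive / k > 1.15  # regression: the naive estimator is off

    def test_truncated_fit_consistent_by_memorylessness(self, rng):
        frames = geometric_frames(rng, 3.0, 4000)
        d = dwell_frame(frames)
        k1 = fit_dwell_exponential(d, None, 1, FR, n_min=1).rates[0]
        k2 = fit_dwell_exponential(d, None, 1, FR, n_min=2).rates[0]
        assert k1 == pytest.approx(3.0, rel=0.05)
        assert k2 == pytest.approx(3.0, rel=0.08)

    def test_rate_dwell_duality(self, rng):
        # 1/(mean dwell) ~ MLE rate for uncensored exponential data
        frames = geometric_frames(rng, 1.0, 3000)
        fit = fit_dwell_exponential(dwell_frame(frames), None, 1, FR, n_min=1)
        k_mean = -FR * np.log(1.0 - 1.0 / frames.mean())
        assert fit.rates[0] == pytest.approx(k_mean, rel=1e-9)

    def test_cross_check_against_survival_library(self, rng):
        lifelines = pytest.importorskip("lifelines")
        k = 0.8
        n = rng.exponential(1 / k, 3000)
        cut = 2.0
        censored = n > cut
        obs = np.minimum(n, cut)
        ef = lifelines.ExponentialFitter().fit(obs, ~censored)
        frames = np.maximum((obs * FR).round(), 1).astype(int)
        fit = fit_dwell_exponential(dwell_frame(frames, censored), None, 1, FR, n_min=1)
        assert fit.rates[0] == pytest.approx(1.0 / ef.lambda_, rel=0.03)

    def test_insufficient_dwells_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_dwell_exponential(dwell_frame([3]), None, 1, FR)

    def test_all_censored_rejected(self):
        d = dwell_frame([5] * 30, censored=[True] * 30)
        with pytest.raises(ValueError, match="censored"):
            fit_dwell_exponential(d, None, 1, FR)


class TestTwoExponential:
    def test_biphasic_mixture_recovered_and_preferred(self, rng):
        fast = geometric_frames(rng, 5.9, 2100)
        slow = geometric_frames(rng, 1.3, 900)
        d = dwell_frame(np.concatenate([fast, slow]))
        fit = fit_dwell_exponential(d, None, 2, FR)
        assert fit.n_components == 2
        assert fit.rates[0] == pytest.approx(5.9, rel=0.15)
        assert fit.rates[1] == pytest.approx(1.3, rel=0.15)
        assert fit.amplitudes[0] == pytest.approx(0.7, abs=0.05)
        assert select_exp_model(d, None, FR) == 2

    def test_pure_exponential_prefers_single(self, rng):
        d = dwell_frame(geometric_frames(rng, 2.0, 2000))
        assert select_exp_model(d, None, FR) == 1

    def test_small_sample_forced_single_with_flag(self, rng):
        d = dwell_frame(geometric_frames(rng, 2.0, 30))
        with pytest.warns(UserWarning, match="single"):
            fit = fit_dwell_exponential(d, None, 2, FR)
        assert fit.n_components == 1
        assert fit.forced_single


class TestMissedEventCorrection:
    def test_fixed_point_inverts_thinning(self):
        ka, kb, td = 4.4, 2.2, 1.5 / FR
        obs_a, obs_b = ka * np.exp(-kb * td), kb * np.exp(-ka * td)
        rec_a, rec_b = correct_missed_events(obs_a, obs_b, FR)
        assert rec_a == pytest.approx(ka, rel=1e-6)
        assert rec_b == pytest.approx(kb, rel=1e-6)

    def test_no_correction_for_slow_partner(self):
        rec_a, rec_b = correct_missed_events(1.0, 1e-9, FR)
        assert rec_a == pytest.approx(1.0, rel=1e-6)


class TestPhotobleach:
    def _static_path(self, n_frames, bleached):
        return IdealizedPath(frames=np.arange(n_frames),
                             states=np.zeros(n_frames, int),
                             state_means=np.array([0.7]), frame_rate=FR,
                             ends_with_bleach=bleached)

    def test_bleach_rate_recovery(self, rng):
        k = 0.1
        paths = []
        for _ in range(500):
            n = min(rng.geometric(1 - np.exp(-k / FR)), 600)
            paths.append(self._static_path(n, bleached=n < 600))
        est = estimate_photobleach_rate(paths)
        assert est.value == pytest.approx(0.1, rel=0.15)

    def test_fluctuating_input_rejected(self):
        fluct = IdealizedPath(frames=np.arange(4), states=np.array([0, 1, 0, 1]),
                              state_means=np.array([0.5, 0.7]), frame_rate=FR)
        with pytest.raises(ValueError, match="fluctuating"):
            estimate_photobleach_rate([fluct] * 30)

    def test_never_bleaching_traces_give_upper_bound(self):
        paths = [self._static_path(600, bleached=False) for _ in range(30)]
        est = estimate_photobleach_rate(paths)
        assert est.detection_limit
        assert est.value is None
        assert est.bound is not None and est.bound > 0


class TestCorrectKoff:
    def test_subtraction_with_propagated_sd(self):
        out = correct_koff(RateEstimate("k_off", 6.0, 0.3),
                           RateEstimate("k_bleach", 0.1, 0.05))
        assert out.value == pytest.approx(5.9)
        assert out.sd == pytest.approx(np.hypot(0.3, 0.05))
        assert out.photobleach_corrected

    def test_indistinguishable_rates_reported_as_bound(self):
        out = correct_koff(RateEstimate("k_off", 0.15, 0.02),
                           RateEstimate("k_bleach", 0.12, 0.02))
        assert out.detection_limit
        assert out.value is None
        assert out.bound == pytest.approx(0.2)

    def test_never_negative(self):
        out = correct_koff(RateEstimate("k_off", 0.05, 0.01),
                           RateEstimate("k_bleach", 0.12, 0.02))
        assert out.detection_limit and out.value is None


class TestAggregateReplicates:
    def test_mean_and_sample_sd(self):
        ests = [RateEstimate("k", v, 0.1) for v in (2.0, 2.2, 2.4)]
        out = aggregate_replicates(ests)
        assert out.value == pytest.approx(2.2)
        assert out.sd == pytest.approx(0.2)

    def test_single_replicate_flagged(self):
        out = aggregate_replicates([RateEstimate("k", 2.0, 0.1)])
        assert out.value == 2.0
        assert out.sd is None
        assert out.meta["single_replicate"]

    def test_mixed_quantities_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            aggregate_replicates([RateEstimate("a", 1.0, 0.1),
                                  RateEstimate("b", 1.0, 0.1)])

    def test_any_bound_makes_result_a_bound(self):
        ests = [RateEstimate("k", 2.0, 0.1),
                RateEstimate("k", None, None, detection_limit=True, bound=0.2)]
        out = aggregate_replicates(ests)
        assert out.detection_limit and out.bound == 0.2


class TestSubpopulations:
    def test_molecule_fraction_from_trace_classification(self, rng):
        # 70% fast molecules produce ~90% of dwells; the trace-level
        # classifier must still report the molecule fraction
        rows = []
        tid = 0
        true_fast = []
        for _ in range(400):
            fast = rng.random() < 0.7
            true_fast.append(fast)
            k_hi, k_lo = (5.9, 2.9) if fast else (1.3, 0.8)
            n_dwells = rng.poisson(16 if fast else 5) + 2
            for j in range(n_dwells):
                rank = j % 2
                k = (k_lo, k_hi)[rank]
                rows.append((tid, rank, rng.geometric(1 - np.exp(-k / FR))))
            tid += 1
        d = pd.DataFrame(rows, columns=["trace_id", "state_rank", "n_frames"])
        d["censored_left"] = False
        d["censored_right"] = False
        frac, resp = classify_subpopulations(
            d, {1: (5.9, 1.3), 0: (2.9, 0.8)}, FR)
        assert frac == pytest.approx(np.mean(true_fast), abs=0.04)
        # responsibilities separate the classes cleanly
        r = resp.to_numpy()
        assert r[np.asarray(true_fast)].mean() > 0.9
        assert r[~np.asarray(true_fast)].mean() < 0.2
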