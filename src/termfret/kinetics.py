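"""Dwell-time kinetics: censored exponential fits and rate estimates.

Dwell durations from idealized traces are discrete (whole frames) and
right-censored by photobleaching or the end of the movie, so rates are
estimated by maximum likelihood under a geometric dwell model with
per-frame survival q = exp(-k/frame_rate): uncensored dwells contribute
the mass function, censored dwells the survival function.  This keeps
the estimate unbiased at mean dwells of a few frames and under heavy
censoring, where inverting the mean of uncensored dwells is visibly
biased.  One- vs two-exponential models are compared by BIC; observed
dissociation rates can be corrected for the photobleach hazard that
competes with unbinding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .idealize import IdealizedPath


@dataclass
class ExpFit:
    """A 1- or 2-exponential dwell-time fit (rates in s^-1, descending)."""

    rates: np.ndarray
    amplitudes: np.ndarray  # dwell-count fractions, sum to 1
    rate_se: np.ndarray
    log_likelihood: float
    bic: float
    n_dwells: int
    n_censored: int
    forced_single: bool = False

    @property
    def n_components(self) -> int:
        return self.rates.size

    @property
    def rate(self) -> float:
        """Dominant (largest-amplitude) rate for single-rate reporting."""
        return float(self.rates[int(np.argmax(self.amplitudes))])


@dataclass
class RateEstimate:
    """A named rate with replicate statistics and reporting flags."""

    name: str
    value: float | None
    sd: float | None
    n: int = 0
    photobleach_corrected: bool = False
    detection_limit: bool = False
    bound: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.detection_limit and self.bound is None:
            raise ValueError("a detection-limit estimate needs a bound")


# ---------------------------------------------------------------------------
# dwell selection
# ---------------------------------------------------------------------------


def _select(dwells: pd.DataFrame, state, include_left_censored: bool) -> pd.DataFrame:
    d = dwells
    if state is not None:
        if isinstance(state, str):
            if state not in ("low", "high"):
                raise ValueError("state must be 'low', 'high', or a rank integer")
            rank = 0 if state == "low" else d["state_rank"].max()
            d = d[d["state_rank"] == rank]
        else:
            d = d[d["state_rank"] == int(state)]
    if not include_left_censored:
        d = d[~d["censored_left"]]
    return d


# ---------------------------------------------------------------------------
# censored geometric/exponential maximum likelihood
# ---------------------------------------------------------------------------


#: Effective detection dead time of frame-resolution idealization, in
#: frames: a sojourn is only decodable when it dominates at least one
#: full camera frame, and with random phase that threshold falls
#: uniformly between one and two frames.
DEAD_TIME_FRAMES = 1.5


def _mle_single(n_frames: np.ndarray, censored: np.ndarray, frame_rate: float):
    """Closed-form MLE of the per-frame survival q and rate k."""
    total = float(n_frames.sum())
    n_dwells = n_frames.size
    u = int((~censored).sum())
    if u == 0:
        return None  # all censored: no point estimate
    q = (total - n_dwells) / max(total - n_dwells + u, 1e-12)
    q = min(max(q, 1e-12), 1 - 1e-12)
    k = -np.log(q) * frame_rate
    info = (total - n_dwells) / q**2 + u / (1 - q) ** 2
    se_q = 1.0 / np.sqrt(max(info, 1e-12))
    se_k = se_q * frame_rate / q
    ll = (total - n_dwells) * np.log(q) + u * np.log(1 - q)
    return k, se_k, ll


def _mix_nll(theta, n_frames, censored, frame_rate, n_min=1):
    w = 1.0 / (1.0 + np.exp(-theta[0]))
    k1, k2 = np.exp(theta[1]), np.exp(theta[2])
    q1 = max(np.exp(-k1 / frame_rate), 1e-300)
    q2 = max(np.exp(-k2 / frame_rate), 1e-300)
    m = n_frames - 1
    s1 = np.exp(m * np.log(q1))
    s2 = np.exp(m * np.log(q2))
    lik = np.where(censored, w * s1 + (1 - w) * s2,
                   w * s1 * (1 - q1) + (1 - w) * s2 * (1 - q2))
    # condition on the dwell being at least n_min frames long
    norm = w * q1 ** (n_min - 1) + (1 - w) * q2 ** (n_min - 1)
    return -np.sum(np.log(np.maximum(lik, 1e-300)) - np.log(norm))


def fit_dwell_exponential(
    dwells: pd.DataFrame,
    state=None,
    n_components: int = 1,
    frame_rate: float = 30.0,
    min_dwells: int = 20,
    include_left_censored: bool = False,
    n_min: int = 2,
) -> ExpFit:
    """Maximum-likelihood (mixture-of-)exponential fit of dwell times.

    ``state`` selects dwells by rank ('low'/'high' FRET state or an
    integer rank); left-censored first dwells are excluded by default.
    Right-censored dwells (bleach/trace end) contribute survival terms.
    The likelihood is left-truncated at ``n_min`` frames (dwells shorter
    than the detection floor are dropped and the model is conditioned on
    survival past it — the ignore-the-first-bin rule of dwell-histogram
    fitting; harmless for exponential data by memorylessness).  With
    fewer than 50 dwells a requested two-component fit falls back to
    one component.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    d = _select(dwells, state, include_left_censored)
    d = d[d["n_frames"] >= n_min]
    n_frames = d["n_frames"].to_numpy(dtype=float)
    censored = d["censored_right"].to_numpy(dtype=bool)
    if n_frames.size < min_dwells:
        raise ValueError(f"need at least {min_dwells} dwells, got {n_frames.size}")
    single = _mle_single(n_frames - (n_min - 1), censored, frame_rate)
    if single is None:
        raise ValueError("all dwells are right-censored; no rate is identifiable")
    k1, se1, ll1 = single
    n = n_frames.size
    forced = False
    if n_components == 2 and n < 50:
        warnings.warn("fewer than 50 dwells: falling back to a single exponential")
        n_components, forced = 1, True
    if n_components == 1:
        return ExpFit(rates=np.array([k1]), amplitudes=np.array([1.0]),
                      rate_se=np.array([se1]), log_likelihood=float(ll1),
                      bic=float(-2 * ll1 + 1 * np.log(n)), n_dwells=n,
                      n_censored=int(censored.sum()), forced_single=forced)

    # two components: multi-start quasi-Newton on (logit w, log k1, log k2)
    starts = []
    med = np.median(n_frames)
    fast0 = max(k1 * 2.5, 1e-3)
    slow0 = max(k1 / 2.5, 1e-4)
    starts.append([0.0, np.log(fast0), np.log(slow0)])
    starts.append([1.0, np.log(k1 * 4), np.log(max(k1 / 4, 1e-4))])
    starts.append([-1.0, np.log(k1 * 1.5), np.log(max(k1 / 8, 1e-4))])
    # rates far beyond the frame rate are unresolvable; bound the search
    bounds = [(-8.0, 8.0),
              (np.log(1e-4), np.log(5.0 * frame_rate)),
              (np.log(1e-4), np.log(5.0 * frame_rate))]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(_mix_nll, x0, args=(n_frames, censored, frame_rate, n_min),
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    w = 1.0 / (1.0 + np.exp(-best.x[0]))
    ks = np.exp(best.x[1:3])
    order = np.argsort(ks)[::-1]
    rates = ks[order]
    amps = np.array([w, 1 - w])[order]
    ll = -float(best.fun)
    # crude curvature-based standard errors on log-rates
    se = np.full(2, np.nan)
    try:
        eps = 1e-4
        for i_out, i_in in enumerate(order + 1):
            xp, xm = best.x.copy(), best.x.copy()
            xp[i_in] += eps
            xm[i_in] -= eps
            h = (_mix_nll(xp, n_frames, censored, frame_rate, n_min) - 2 * best.fun
                 + _mix_nll(xm, n_frames, censored, frame_rate, n_min)) / eps**2
            if h > 0:
                se[i_out] = rates[i_out] / np.sqrt(h)
    except FloatingPointError:
        pass
    return ExpFit(rates=rates, amplitudes=amps, rate_se=se, log_likelihood=ll,
                  bic=float(-2 * ll + 3 * np.log(n)), n_dwells=n,
                  n_censored=int(censored.sum()), forced_single=False)


def select_exp_model(dwells: pd.DataFrame, state=None, frame_rate: float = 30.0,
                     min_dwells: int = 20) -> int:
    """1 vs 2 exponentials by BIC (forced to 1 below 50 dwells)."""
    fit1 = fit_dwell_exponential(dwells, state, 1, frame_rate, min_dwells)
    if fit1.n_dwells < 50:
        return 1
    fit2 = fit_dwell_exponential(dwells, state, 2, frame_rate, min_dwells)
    return 2 if fit2.bic < fit1.bic else 1


def correct_missed_events(
    k_a: float,
    k_b: float,
    frame_rate: float = 30.0,
    dead_frames: float = DEAD_TIME_FRAMES,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Dead-time correction for a pair of alternating dwell rates.

    A sojourn shorter than the detection dead time t_d is not decoded,
    which merges the flanking dwells of the opposite state: the observed
    exit rate of state a is thinned to k_a * P(dwell_b >= t_d).  Given
    the observed rates of both states, the true pair solves the fixed
    point k_a = k_a_obs / exp(-k_b * t_d) (and vice versa), the
    first-order missed-event correction familiar from single-channel
    kinetics.  Returns the corrected ``(k_a, k_b)``.
    """
    td = dead_frames / frame_rate
    ka, kb = float(k_a), float(k_b)
    # beyond ~the frame rate the dwells are unresolvable and the fixed
    # point may not exist; leave such rates uncorrected
    cap = 2.0 * frame_rate
    if ka >= cap or kb >= cap:
        return ka, kb
    for _ in range(max_iter):
        ka_new = k_a * np.exp(min(kb * td, 50.0))
        kb_new = k_b * np.exp(min(ka * td, 50.0))
        if ka_new >= cap or kb_new >= cap:
            return float(k_a), float(k_b)
        if abs(ka_new - ka) < tol and abs(kb_new - kb) < tol:
            ka, kb = ka_new, kb_new
            break
        ka, kb = ka_new, kb_new
    return ka, kb


# ---------------------------------------------------------------------------
# photobleaching
# ---------------------------------------------------------------------------


def estimate_photobleach_rate(
    static_paths: list[IdealizedPath],
    frame_rate: float = 30.0,
    min_traces: int = 20,
    name: str = "k_bleach",
) -> RateEstimate:
    """Photobleach rate from non-fluctuating traces.

    Input paths must show zero transitions; the duration of uninterrupted
    FRET signal is exponential in the total bleach hazard of the dye
    pair.  Traces that survive the whole movie enter as censored; if all
    are censored only an upper bound is reported.
    """
    static = [p for p in static_paths if p.n_transitions == 0 and p.frames.size > 0]
    if any(p.n_transitions > 0 for p in static_paths):
        raise ValueError("input contains fluctuating traces; supply static traces only")
    if len(static) < min_traces:
        raise ValueError(f"need at least {min_traces} static traces, got {len(static)}")
    n_frames = np.array([p.frames.size for p in static], dtype=float)
    censored = np.array([not p.ends_with_bleach for p in static])
    single = _mle_single(n_frames, censored, frame_rate)
    if single is None:
        # no bleach observed: bound at the rate that would have produced
        # at least one event with 95% probability
        bound = 3.0 / (n_frames.sum() / frame_rate)
        return RateEstimate(name=name, value=None, sd=None, n=len(static),
                            detection_limit=True, bound=float(bound))
    k, se, _ = single
    return RateEstimate(name=name, value=float(k), sd=float(se), n=len(static))


def correct_koff(
    k_obs: RateEstimate,
    k_bleach: RateEstimate,
    detection_limit: float = 0.2,
) -> RateEstimate:
    """Subtract the competing photobleach hazard from an observed k_off.

    If the corrected rate is indistinguishable from zero (k_obs within
    two combined standard deviations of k_bleach) only the detection
    limit is reported as an upper bound, never a negative rate.
    """
    if k_obs.value is None or k_bleach.value is None:
        raise ValueError("both rates need point estimates")
    sd_comb = float(np.hypot(k_obs.sd or 0.0, k_bleach.sd or 0.0))
    value = k_obs.value - k_bleach.value
    if k_obs.value <= k_bleach.value + 2 * sd_comb:
        return RateEstimate(name=k_obs.name, value=None, sd=None, n=k_obs.n,
                            photobleach_corrected=True, detection_limit=True,
                            bound=detection_limit,
                            meta={"k_obs": k_obs.value, "k_bleach": k_bleach.value})
    return RateEstimate(name=k_obs.name, value=float(value), sd=sd_comb, n=k_obs.n,
                        photobleach_corrected=True,
                        meta={"k_obs": k_obs.value, "k_bleach": k_bleach.value})


def aggregate_replicates(estimates: list[RateEstimate]) -> RateEstimate:
    """Unweighted mean +/- sample sd over replicate datasets."""
    if len(estimates) < 1:
        raise ValueError("no estimates to aggregate")
    names = {e.name for e in estimates}
    if len(names) > 1:
        raise ValueError(f"mixed quantities: {sorted(names)}")
    name = estimates[0].name
    if any(e.detection_limit for e in estimates):
        bounds = [e.bound for e in estimates if e.bound is not None]
        return RateEstimate(name=name, value=None, sd=None, n=len(estimates),
                            detection_limit=True, bound=max(bounds),
                            photobleach_corrected=any(e.photobleach_corrected for e in estimates))
    values = np.array([e.value for e in estimates], dtype=float)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else None
    return RateEstimate(name=name, value=float(values.mean()), sd=sd, n=len(estimates),
                        photobleach_corrected=any(e.photobleach_corrected for e in estimates),
                        meta={"replicates": values.tolist(), "single_replicate": values.size == 1})


# ---------------------------------------------------------------------------
# subpopulation (biphasic) analysis
# ---------------------------------------------------------------------------


def classify_subpopulations(
    dwells: pd.DataFrame,
    component_rates: dict[int, tuple[float, float]],
    frame_rate: float = 30.0,
    max_iter: int = 50,
) -> tuple[float, pd.Series]:
    """Molecule-level mixture fractions from a biphasic dwell fit.

    Pooled two-exponential amplitudes are dwell-count fractions and
    overweight fast molecules, which cycle more often per trace.  Here
    each trace is treated as one draw from a two-class mixture: class
    likelihoods multiply the geometric dwell densities of the fast (or
    slow) rate of each state (``component_rates`` maps state rank ->
    (k_fast, k_slow)), and the class prior is estimated by EM.  Returns
    ``(fast_fraction, per-trace posterior of the fast class)``.
    """
    d = dwells[~dwells["censored_left"]]
    logl = {}
    for cls in (0, 1):  # 0 = fast, 1 = slow
        ll = np.zeros(len(d))
        for rank, (k_fast, k_slow) in component_rates.items():
            k = (k_fast, k_slow)[cls]
            q = np.exp(-k / frame_rate)
            sel = d["state_rank"].to_numpy() == rank
            m = d["n_frames"].to_numpy(dtype=float) - 1
            cens = d["censored_right"].to_numpy(dtype=bool)
            contrib = m * np.log(q) + np.where(cens, 0.0, np.log(1 - q))
            ll = ll + np.where(sel, contrib, 0.0)
        logl[cls] = pd.Series(ll, index=d.index).groupby(d["trace_id"]).sum()
    lf, ls = logl[0], logl[1]
    pi = 0.5
    for _ in range(max_iter):
        num = np.log(pi) + lf
        den = np.logaddexp(num, np.log1p(-pi) + ls)
        resp = np.exp(num - den)
        pi_new = float(resp.mean())
        if abs(pi_new - pi) < 1e-8:
            pi = pi_new
            break
        pi = pi_new
    return pi, resp
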