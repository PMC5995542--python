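"""FRET trace idealization: HMM fitting, Viterbi decoding, dwell extraction.

Each FRET series is fit with a Gaussian-emission hidden Markov model by
maximum-likelihood EM with deterministic quantile initialization plus
seeded restarts; the number of states is chosen by BIC.  The decoded
(idealized) path is then filtered with the standard kinetic exclusion
rules — states closer than a minimum FRET separation are merged, traces
with at most one surviving transition are dropped from kinetics — and
converted into a dwell table with explicit censoring flags, the
substrate of all rate estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._hmm import forward_backward, viterbi
from .qc import FretSeries

_LOG2PI = float(np.log(2.0 * np.pi))
_MIN_SD = 1e-3


@dataclass
class HMMFit:
    """A fitted K-state Gaussian HMM, states ordered by ascending mean."""

    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    bic: float
    converged: bool
    n_obs: int

    @property
    def n_states(self) -> int:
        return self.means.size


@dataclass
class IdealizedPath:
    """Per-frame discrete state assignment for the unmasked frames."""

    frames: np.ndarray  # original frame indices
    states: np.ndarray  # integer labels into state_means
    state_means: np.ndarray
    frame_rate: float
    trace_id: int | None = None
    ends_with_bleach: bool = False

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.states = np.asarray(self.states, dtype=int)
        self.state_means = np.asarray(self.state_means, dtype=float)
        if self.frames.shape != self.states.shape:
            raise ValueError("frames and states must align")

    @property
    def n_transitions(self) -> int:
        return int(np.sum(np.diff(self.states) != 0))

    def transitions(self) -> list[tuple[int, int, int, float]]:
        """(frame, from_state, to_state, delta_E) at each state change."""
        out = []
        for i in np.flatnonzero(np.diff(self.states) != 0):
            a, b = int(self.states[i]), int(self.states[i + 1])
            out.append((int(self.frames[i + 1]), a, b,
                        float(self.state_means[b] - self.state_means[a])))
        return out


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


def _emission_lik(x: np.ndarray, means: np.ndarray, sds: np.ndarray):
    """Per-frame emission likelihoods, scaled per frame (and the log offset)."""
    z = (x[:, None] - means[None, :]) / sds[None, :]
    logb = -0.5 * z * z - np.log(sds)[None, :] - 0.5 * _LOG2PI
    off = logb.max(axis=1)
    return np.exp(logb - off[:, None]), off


def _em_run(x, means, sds, transmat, startprob, tol, max_iter):
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        b, off = _emission_lik(x, means, sds)
        gamma, xi_sum, ll = forward_backward(b, transmat, startprob)
        ll += off.sum()
        w = gamma.sum(axis=0)
        means = (gamma * x[:, None]).sum(axis=0) / np.maximum(w, 1e-12)
        var = (gamma * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / np.maximum(w, 1e-12)
        sds = np.maximum(np.sqrt(var), _MIN_SD)
        rows = xi_sum.sum(axis=1, keepdims=True)
        transmat = np.where(rows > 1e-12, xi_sum / np.maximum(rows, 1e-12),
                            1.0 / means.size)
        startprob = np.maximum(gamma[0], 1e-12)
        startprob = startprob / startprob.sum()
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            converged = True
            prev = ll
            break
        prev = ll
    return means, sds, transmat, startprob, prev, converged


def _n_params(k: int) -> int:
    return (k - 1) + k * (k - 1) + 2 * k


def fit_hmm(
    fret: FretSeries,
    n_states: int,
    n_restarts: int = 5,
    rng_seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HMMFit:
    """Fit a Gaussian HMM to the unmasked frames of a FRET series.

    One deterministic start places the state means at the emission
    quantiles; ``n_restarts`` additional seeded starts jitter them.  The
    best-likelihood solution is returned with states sorted by mean.
    """
    x = fret.valid_values()
    if x.size < 2 * n_states:
        raise ValueError(f"need at least {2 * n_states} unmasked frames, got {x.size}")
    k = int(n_states)
    if k == 1:
        mu, sd = float(np.mean(x)), max(float(np.std(x)), _MIN_SD)
        ll = float(np.sum(-0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI))
        return HMMFit(np.array([mu]), np.array([sd]), np.ones((1, 1)),
                      np.ones(1), ll, -2 * ll + _n_params(1) * np.log(x.size),
                      True, x.size)

    rng = np.random.default_rng(rng_seed)
    q = np.quantile(x, (np.arange(k) + 0.5) / k)
    spread = max(float(x.max() - x.min()), 0.05)
    sd0 = np.full(k, max(spread / (2.0 * k), 0.01))
    a0 = np.full((k, k), 0.05 / max(k - 1, 1))
    np.fill_diagonal(a0, 0.95)
    pi0 = np.full(k, 1.0 / k)

    best = None
    for r in range(n_restarts + 1):
        means0 = np.sort(q if r == 0 else q + rng.normal(0.0, 0.1 * spread, k))
        res = _em_run(x, means0.copy(), sd0.copy(), a0.copy(), pi0.copy(), tol, max_iter)
        if best is None or res[4] > best[4]:
            best = res
    means, sds, transmat, startprob, ll, converged = best
    order = np.argsort(means)
    means, sds = means[order], sds[order]
    transmat = transmat[np.ix_(order, order)]
    startprob = startprob[order]
    bic = -2.0 * ll + _n_params(k) * np.log(x.size)
    return HMMFit(means, sds, transmat, startprob, float(ll), float(bic),
                  bool(converged), x.size)


def select_K(fret: FretSeries, K_max: int = 4, rng_seed: int = 0, **kw) -> int:
    """State count minimizing BIC over K = 1..K_max."""
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    best_k, best_bic = 1, np.inf
    for k in range(1, K_max + 1):
        if fret.n_valid < 2 * k:
            break
        fit = fit_hmm(fret, k, rng_seed=rng_seed, **kw)
        if fit.bic < best_bic:
            best_k, best_bic = k, fit.bic
    return best_k


def decode(fit: HMMFit, fret: FretSeries) -> IdealizedPath:
    """Viterbi maximum-a-posteriori state sequence for the valid frames.

    Ties are broken toward the lower-mean state (states are
    mean-ordered, so the lower index is the lower mean).
    """
    frames = np.flatnonzero(fret.mask)
    x = fret.values[frames]
    ends_with_bleach = frames.size > 0 and frames[-1] < fret.values.size - 1
    if fit.n_states == 1:
        states = np.zeros(x.size, dtype=int)
    else:
        z = (x[:, None] - fit.means[None, :]) / fit.sds[None, :]
        logb = -0.5 * z * z - np.log(fit.sds)[None, :] - 0.5 * _LOG2PI
        with np.errstate(divide="ignore"):
            states, _ = viterbi(logb, np.log(np.maximum(fit.transmat, 1e-300)),
                                np.log(np.maximum(fit.startprob, 1e-300)))
    return IdealizedPath(frames=frames, states=states, state_means=fit.means.copy(),
                         frame_rate=fret.frame_rate, trace_id=fret.trace_id,
                         ends_with_bleach=ends_with_bleach)


# ---------------------------------------------------------------------------
# exclusion rules and dwell extraction
# ---------------------------------------------------------------------------


def merge_close_states(path: IdealizedPath, merge_de: float = 0.1) -> IdealizedPath:
    """Merge fitted states whose means differ by less than ``merge_de``.

    The closest pair is merged first (occupancy-weighted mean) and the
    rule is applied until all surviving means are separated by at least
    ``merge_de``; the operation is idempotent.
    """
    means = list(path.state_means)
    groups = [[i] for i in range(len(means))]
    weights = [float(np.sum(path.states == i)) or 1e-9 for i in range(len(means))]
    while len(means) > 1:
        order = np.argsort(means)
        sorted_means = np.asarray(means)[order]
        gaps = np.diff(sorted_means)
        j = int(np.argmin(gaps))
        if gaps[j] >= merge_de:
            break
        a, b = int(order[j]), int(order[j + 1])
        wa, wb = weights[a], weights[b]
        means[a] = (means[a] * wa + means[b] * wb) / (wa + wb)
        weights[a] = wa + wb
        groups[a].extend(groups[b])
        del means[b], weights[b], groups[b]
    relabel = np.empty(path.state_means.size, dtype=int)
    new_order = np.argsort(means)
    final_means = np.asarray(means)[new_order]
    for new_i, gi in enumerate(new_order):
        for old in groups[gi]:
            relabel[old] = new_i
    return IdealizedPath(frames=path.frames.copy(), states=relabel[path.states],
                         state_means=final_means, frame_rate=path.frame_rate,
                         trace_id=path.trace_id, ends_with_bleach=path.ends_with_bleach)


def exclude_for_kinetics(
    paths: list[IdealizedPath],
    merge_de: float = 0.1,
    min_transitions: int = 2,
) -> tuple[list[IdealizedPath], list[IdealizedPath]]:
    """Apply the kinetic exclusion rules.

    Returns ``(kinetic, all_merged)``: every path with sub-``merge_de``
    states merged, and the subset with at least ``min_transitions``
    surviving transitions that enters dwell-time analysis.  Static and
    single-transition traces stay in ``all_merged`` for population
    histograms.
    """
    merged = [merge_close_states(p, merge_de) for p in paths]
    kinetic = [p for p in merged if p.n_transitions >= min_transitions]
    return kinetic, merged


DWELL_COLUMNS = ["trace_id", "state", "state_mean", "state_rank", "start_frame",
                 "n_frames", "duration_s", "censored_left", "censored_right", "end_cause"]


def extract_dwells(path: IdealizedPath, frame_rate: float | None = None) -> pd.DataFrame:
    """One row per sojourn of the idealized path.

    The first sojourn is left-censored (its start is unobserved) and the
    last right-censored (ended by photobleach or the end of the movie);
    interior sojourns end in a genuine transition.  Dwell frames sum to
    the number of unmasked frames.
    """
    fr = path.frame_rate if frame_rate is None else frame_rate
    s = path.states
    if s.size == 0:
        return pd.DataFrame(columns=DWELL_COLUMNS)
    bounds = np.concatenate([[0], np.flatnonzero(np.diff(s) != 0) + 1, [s.size]])
    present = np.unique(s)
    rank_of = {int(lab): int(r) for r, lab in enumerate(present[np.argsort(path.state_means[present])])}
    rows = []
    n_dwells = bounds.size - 1
    for d in range(n_dwells):
        a, b = bounds[d], bounds[d + 1]
        lab = int(s[a])
        last = d == n_dwells - 1
        rows.append({
            "trace_id": path.trace_id,
            "state": lab,
            "state_mean": float(path.state_means[lab]),
            "state_rank": rank_of[lab],
            "start_frame": int(path.frames[a]),
            "n_frames": int(b - a),
            "duration_s": float((b - a) / fr),
            "censored_left": d == 0,
            "censored_right": last,
            "end_cause": ("bleach" if path.ends_with_bleach else "trace_end") if last else "transition",
        })
    return pd.DataFrame(rows, columns=DWELL_COLUMNS)


def dwell_table(paths: list[IdealizedPath], frame_rate: float | None = None) -> pd.DataFrame:
    """Concatenated dwell table over many idealized paths."""
    parts = [extract_dwells(p, frame_rate) for p in paths]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return pd.DataFrame(columns=DWELL_COLUMNS)
    return pd.concat(parts, ignore_index=True)
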