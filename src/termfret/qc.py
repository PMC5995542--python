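"""Trace selection and conversion of raw intensities to FRET series.

Implements the standard smFRET preprocessing chain: donor bleed-through
correction with a calibrated coefficient, 3-point smoothing, FRET
efficiency E = A/(D+A), photobleach step detection, and semi-automated
selection of single-molecule traces (anticorrelated channels, single
bleach steps, single-fluorophore intensity band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import Trace


@dataclass
class FretSeries:
    """Per-frame FRET efficiency with a validity mask.

    ``mask`` is True on analyzable frames; frames after the first
    photobleach and frames with near-zero total intensity are False and
    excluded from all downstream statistics.
    """

    values: np.ndarray
    mask: np.ndarray
    frame_rate: float
    trace_id: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have equal shape")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class Step:
    """A downward intensity step found by changepoint fitting."""

    frame: int
    pre_level: float
    post_level: float
    terminal: bool  # post level ~ background
    permanent: bool  # signal never recovers toward the pre level

    @property
    def drop(self) -> float:
        return self.pre_level - self.post_level


# ---------------------------------------------------------------------------
# elementary corrections
# ---------------------------------------------------------------------------


def correct_bleedthrough(trace: Trace, beta: float, background_donor: float = 0.0) -> Trace:
    """Remove donor leakage from the acceptor channel.

    acceptor' = acceptor - beta * (donor - bg_D); the donor is unchanged.
    """
    if not (0.0 <= beta < 1.0):
        raise ValueError("beta must be in [0, 1)")
    corrected = trace.acceptor - beta * (trace.donor - background_donor)
    return Trace(
        donor=trace.donor.copy(),
        acceptor=corrected,
        frame_rate=trace.frame_rate,
        metadata={**trace.metadata, "beta_corrected": beta},
        truth=trace.truth,
    )


def smooth3(series: np.ndarray) -> np.ndarray:
    """Centered 3-point moving average; edge windows shrink to 2 points."""
    x = np.asarray(series, dtype=float)
    if x.size <= 1:
        return x.copy()
    out = np.empty_like(x)
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return out


def compute_fret(
    trace: Trace,
    mask_after: int | None = None,
    total_floor: float | None = None,
) -> FretSeries:
    """FRET efficiency E_t = A_t / (D_t + A_t) on a bleed-through-corrected trace.

    Frames with total intensity at or below ``total_floor`` are masked
    (degenerate: both dyes dark, the ratio is pure noise); the default
    floor is a quarter of the trace's upper-decile total, which rejects
    post-bleach frames even when no explicit bleach mask is supplied.
    ``mask_after`` masks everything from that frame on (the first
    photobleach found by QC).
    """
    d, a = trace.donor, trace.acceptor
    total = d + a
    if total_floor is None:
        total_floor = max(0.25 * float(np.percentile(total, 90)), 1e-9)
    mask = total > total_floor
    values = np.zeros_like(total)
    np.divide(a, total, out=values, where=mask)
    if mask_after is not None:
        mask = mask & (np.arange(total.size) < mask_after)
    values[~mask] = np.nan
    return FretSeries(values=values, mask=mask, frame_rate=trace.frame_rate,
                      trace_id=trace.metadata.get("trace_id"))


# ---------------------------------------------------------------------------
# photobleach step detection
# ---------------------------------------------------------------------------


def _binary_segmentation(x: np.ndarray, penalty: float, min_size: int = 2) -> list[int]:
    """Changepoints of a piecewise-constant mean fit, SIC-type penalty."""
    n = x.size
    cum = np.concatenate([[0.0], np.cumsum(x)])
    cum2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(a: int, b: int) -> float:  # cost of segment x[a:b]
        s, s2, m = cum[b] - cum[a], cum2[b] - cum2[a], b - a
        return s2 - s * s / m if m > 0 else 0.0

    def best_split(a: int, b: int):
        if b - a < 2 * min_size:
            return None, 0.0
        base = sse(a, b)
        cuts = np.arange(a + min_size, b - min_size + 1)
        if cuts.size == 0:
            return None, 0.0
        gains = base - np.array([sse(a, c) + sse(c, b) for c in cuts])
        j = int(np.argmax(gains))
        return int(cuts[j]), float(gains[j])

    changepoints: list[int] = []
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        c, gain = best_split(a, b)
        if c is not None and gain > penalty:
            changepoints.append(c)
            stack.append((a, c))
            stack.append((c, b))
    return sorted(changepoints)


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise level from the median absolute successive difference."""
    d = np.diff(np.asarray(x, dtype=float))
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0))


def detect_bleach_steps(
    series: np.ndarray,
    background: float = 0.0,
    min_drop_frac: float = 0.5,
    noise_sd: float | None = None,
) -> list[Step]:
    """Find candidate photobleach steps in one intensity channel.

    The channel is fit with a penalized piecewise-constant model; a
    downward changepoint qualifies as a step when its drop is at least
    ``min_drop_frac`` of the pre-step level.  Steps are annotated as
    ``terminal`` when the post-step level sits at background and
    ``permanent`` when the signal never recovers toward the pre-step
    level — a true photobleach is both, a conformational transition is
    neither (sub-threshold drop or later recovery).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise ValueError("series must have at least 4 frames")
    sigma = robust_noise_sd(x) if noise_sd is None else float(noise_sd)
    penalty = max(2.0 * sigma * sigma * np.log(x.size), 1e-12)
    cps = _binary_segmentation(x, penalty)
    bounds = [0] + cps + [x.size]
    levels = [float(np.mean(x[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]
    steps: list[Step] = []
    for i, c in enumerate(cps):
        pre, post = levels[i], levels[i + 1]
        drop = pre - post
        if drop <= 0 or pre <= background:
            continue
        if drop < min_drop_frac * (pre - background):
            continue
        later = levels[i + 1:]
        permanent = max(later) < pre - 0.5 * drop
        terminal = post <= background + max(3.0 * sigma, 0.02 * abs(pre))
        steps.append(Step(frame=c, pre_level=pre, post_level=post,
                          terminal=terminal, permanent=permanent))
    return steps


def _first_terminal_frame(steps: list[Step]) -> int | None:
    for s in steps:
        if s.terminal and s.permanent:
            return s.frame
    return None


# ---------------------------------------------------------------------------
# bleed-through estimation
# ---------------------------------------------------------------------------


def estimate_bleedthrough(
    traces: list[Trace],
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
    guard_frames: int = 2,
) -> float:
    """Calibrate the bleed-through coefficient from donor-only segments.

    Uses frames after the acceptor has photobleached while the donor is
    still alive; there the acceptor channel contains only leaked donor
    signal, so beta = (A - bg_A) / (D - bg_D).  Returns the median over
    all qualifying frames of all traces.
    """
    ratios: list[np.ndarray] = []
    for trace in traces:
        donor_steps = detect_bleach_steps(trace.donor, background_donor)
        fr_d = _first_terminal_frame(donor_steps)
        # acceptor bleach = terminal step of the raw acceptor channel that
        # precedes the donor bleach (donor-only tail follows it)
        acc_steps = detect_bleach_steps(trace.acceptor, background_acceptor,
                                        min_drop_frac=0.3)
        end = fr_d if fr_d is not None else trace.n_frames
        fr_a = None
        for s in acc_steps:
            if s.permanent and s.frame < end - guard_frames:
                fr_a = s.frame
                break
        if fr_a is None:
            continue
        lo, hi = fr_a + guard_frames, end - guard_frames
        if hi - lo < 3:
            continue
        d = trace.donor[lo:hi] - background_donor
        a = trace.acceptor[lo:hi] - background_acceptor
        ok = d > 0.2 * np.median(d)
        if ok.any():
            ratios.append(a[ok] / d[ok])
    if not ratios:
        raise ValueError(
            "no traces with a post-acceptor-bleach donor-only segment; "
            "supply donor-only calibration traces"
        )
    return float(np.median(np.concatenate(ratios)))


# ---------------------------------------------------------------------------
# trace selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCThresholds:
    """Tunable trace-selection thresholds (defaults follow the protocol)."""

    corr_max: float = 0.1
    corr_min_frames: int = 40  # shorter windows carry no correlation evidence
    min_prebleach_frames: int = 10
    intensity_band: tuple[float, float] = (0.5, 1.5)
    min_drop_frac: float = 0.4
    allow_unbleached: bool = True


@dataclass
class QCReport:
    """Per-trace QC outcome plus set-level counts."""

    table: pd.DataFrame
    n_input: int = 0
    n_accepted: int = 0
    counts_by_reason: dict = field(default_factory=dict)


_OK = "ok"


def _total_drop_at(total: np.ndarray, frame: int, half: int = 5) -> float:
    lo = max(frame - half, 0)
    hi = min(frame + half, total.size)
    if frame - lo < 1 or hi - frame < 1:
        return 0.0
    return float(np.median(total[lo:frame]) - np.median(total[frame:hi]))


def _donor_step_counts(donor, total, min_drop_frac) -> tuple[int, int | None]:
    """Donor photobleach steps: permanent donor drops mirrored in the total.

    A FRET transition moves intensity between channels but conserves the
    corrected total, whereas a donor bleach removes it, so only donor
    steps accompanied by a comparable total-intensity drop count.
    """
    steps = [s for s in detect_bleach_steps(donor, min_drop_frac=min_drop_frac)
             if s.permanent and _total_drop_at(total, s.frame) >= 0.5 * s.drop]
    first = next((s.frame for s in steps if s.terminal), None)
    return len(steps), first


def _acceptor_step_counts(acceptor_corrected, min_drop_frac) -> tuple[int, int | None]:
    """Acceptor photobleach steps: terminal, permanent corrected-acceptor drops."""
    steps = [s for s in detect_bleach_steps(acceptor_corrected, min_drop_frac=min_drop_frac)
             if s.permanent and s.terminal]
    return len(steps), steps[0].frame if steps else None


def select_traces(
    traces: list[Trace],
    beta: float = 0.13,
    thresholds: QCThresholds = QCThresholds(),
    mode: str = "fret_pair",
) -> tuple[list[Trace], QCReport]:
    """Select analyzable single-molecule traces.

    A trace is accepted when (a) the Pearson correlation of the donor
    and corrected acceptor over the pre-bleach window is below
    ``corr_max`` (static traces sit near 0 and pass; windows shorter
    than ``corr_min_frames`` carry no evidence and are not held against
    the trace), (b) each
    channel shows a single photobleach step — or none, for traces that
    outlive the movie, and (c) the pre-bleach total intensity lies in the
    single-fluorophore band around the set median.  In ``binding`` mode
    the step rule applies to the donor only: the acceptor arrives and
    leaves with each factor-binding event, so its steps are signal.

    Returns the accepted traces (bleed-through corrected, with
    ``qc_first_bleach_frame`` recorded in metadata) and a QCReport in
    which every input trace appears exactly once.
    """
    if mode not in ("fret_pair", "binding"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    corrected_all: list[Trace] = []
    totals = []
    for i, trace in enumerate(traces):
        ct = correct_bleedthrough(trace, beta)
        corrected_all.append(ct)
        total_series = ct.donor + ct.acceptor
        n_d, fr_d = _donor_step_counts(trace.donor, total_series,
                                       thresholds.min_drop_frac)
        if mode == "fret_pair":
            n_a, fr_a = _acceptor_step_counts(ct.acceptor, thresholds.min_drop_frac)
        else:
            n_a, fr_a = 0, None  # acceptor steps are binding signal, not bleach
        first_bleach = min([f for f in (fr_d, fr_a) if f is not None], default=None)
        window = first_bleach if first_bleach is not None else trace.n_frames
        if window >= thresholds.corr_min_frames:
            d = trace.donor[:window]
            a = ct.acceptor[:window]
            with np.errstate(invalid="ignore"):
                corr = float(np.corrcoef(d, a)[0, 1])
            if not np.isfinite(corr):
                corr = 0.0  # constant channel: no anticorrelation evidence against it
        else:
            corr = np.nan
        total = float(np.median((trace.donor + ct.acceptor)[:max(window, 1)]))
        totals.append(total)
        rows.append({
            "trace_id": trace.metadata.get("trace_id", i),
            "corr": corr,
            "n_donor_steps": n_d,
            "n_acceptor_steps": n_a,
            "donor_bleach_frame": fr_d,
            "acceptor_bleach_frame": fr_a,
            "first_bleach_frame": first_bleach,
            "median_total": total,
        })

    med_total = float(np.median(totals)) if totals else 0.0
    lo, hi = thresholds.intensity_band
    accepted: list[Trace] = []
    reasons = []
    for i, row in enumerate(rows):
        reason = _OK
        if row["first_bleach_frame"] is not None and row["first_bleach_frame"] < thresholds.min_prebleach_frames:
            reason = "too_short"
        elif not np.isnan(row["corr"]) and row["corr"] >= thresholds.corr_max:
            reason = "correlation"
        elif row["n_donor_steps"] > 1 or row["n_acceptor_steps"] > 1:
            reason = "multistep"
        elif row["n_donor_steps"] == 0 and not thresholds.allow_unbleached and mode == "fret_pair":
            reason = "no_bleach"
        elif not (lo * med_total <= row["median_total"] <= hi * med_total):
            reason = "intensity"
        reasons.append(reason)
        if reason == _OK:
            ct = corrected_all[i]
            ct.metadata["qc_first_bleach_frame"] = row["first_bleach_frame"]
            accepted.append(ct)

    table = pd.DataFrame(rows)
    table["accepted"] = [r == _OK for r in reasons]
    table["reason"] = reasons
    counts = table["reason"].value_counts().to_dict()
    return accepted, QCReport(table=table, n_input=len(traces),
                              n_accepted=len(accepted), counts_by_reason=counts)


def fret_series_for(accepted: list[Trace], smooth: bool = False) -> list[FretSeries]:
    """Masked FRET series for QC-accepted corrected traces.

    ``smooth=True`` applies the 3-point running average to both channels
    first — useful for display and histograms, but it smears fast
    transitions over neighbouring frames, so dwell-time idealization
    runs on the unsmoothed series.
    """
    out = []
    for trace in accepted:
        if smooth:
            trace = Trace(
                donor=smooth3(trace.donor),
                acceptor=smooth3(trace.acceptor),
                frame_rate=trace.frame_rate,
                metadata=trace.metadata,
                truth=trace.truth,
            )
        out.append(compute_fret(trace, mask_after=trace.metadata.get("qc_first_bleach_frame")))
    return out
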