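"""Post-synchronized FRET probability density (contour) maps.

Traces are time-shifted so that a chosen kinetic feature — the start of
a FRET event, or the first transition into a given state — sits at
t = 0, then compiled into a 2-D (time since sync, FRET) histogram whose
columns are normalized over the traces still contributing, mirroring
the contour plots used to visualize factor residence and rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .idealize import IdealizedPath
from .qc import FretSeries

SYNC_MODES = ("fret_event_start", "first_transition_to_state", "first_n_to_r")


def synchronize(
    paths: list[IdealizedPath],
    mode: str = "fret_event_start",
    target_state: str = "high",
    dark_threshold: float = 0.25,
) -> tuple[list[int | None], int]:
    """Synchronization frame per trace (None when the feature is absent).

    Modes: ``fret_event_start`` — first frame decoded above the dark
    threshold (factor binding); ``first_transition_to_state`` — first
    transition into the 'high' or 'low' state; ``first_n_to_r`` — first
    high-to-low transition (N to R rotation).  Returns the per-trace sync
    frames and the count of traces lacking the feature.
    """
    if mode not in SYNC_MODES:
        raise ValueError(f"unknown sync mode {mode!r}; choose from {SYNC_MODES}")
    out: list[int | None] = []
    n_excluded = 0
    for p in paths:
        frame: int | None = None
        if p.frames.size:
            means = p.state_means[p.states]
            if mode == "fret_event_start":
                above = np.flatnonzero(means > dark_threshold)
                frame = int(p.frames[above[0]]) if above.size else None
            else:
                want_high = (mode == "first_transition_to_state" and target_state == "high")
                for f, a, b, _de in p.transitions():
                    into_high = p.state_means[b] > p.state_means[a]
                    if mode == "first_n_to_r" and not into_high:
                        frame = f
                        break
                    if mode == "first_transition_to_state" and into_high == want_high:
                        frame = f
                        break
        if frame is None:
            n_excluded += 1
        out.append(frame)
    return out, n_excluded


@dataclass
class DensityMap:
    """Column-normalized FRET density vs time since synchronization."""

    time_edges: np.ndarray  # seconds, len n_time+1
    fret_edges: np.ndarray  # len n_fret+1
    density: np.ndarray  # n_fret x n_time, each populated column sums to 1
    n_per_column: np.ndarray  # traces contributing per time column
    mode: str = ""

    def column_mean_fret(self) -> np.ndarray:
        centers = (self.fret_edges[:-1] + self.fret_edges[1:]) / 2
        with np.errstate(invalid="ignore"):
            return (self.density * centers[:, None]).sum(axis=0)


def density_map(
    series: list[FretSeries],
    sync_frames: list[int | None],
    n_time_frames: int = 150,
    time_bin_frames: int = 1,
    fret_bin: float = 0.02,
    fret_range: tuple[float, float] = (-0.1, 1.1),
    mode: str = "",
) -> DensityMap:
    """Compile aligned traces into a per-column-normalized 2-D histogram.

    Columns where traces have bleached are normalized over the
    survivors, so each populated column is a probability distribution
    over FRET.
    """
    contributing = [(s, f) for s, f in zip(series, sync_frames) if f is not None]
    if not contributing:
        raise ValueError("no synchronized traces to compile")
    frame_rate = contributing[0][0].frame_rate
    n_cols = int(np.ceil(n_time_frames / time_bin_frames))
    fret_edges = np.arange(fret_range[0], fret_range[1] + fret_bin / 2, fret_bin)
    counts = np.zeros((fret_edges.size - 1, n_cols))
    n_per_col = np.zeros(n_cols, dtype=int)
    for s, f0 in contributing:
        rel = np.arange(s.values.size) - f0
        sel = s.mask & (rel >= 0) & (rel < n_time_frames)
        if not sel.any():
            continue
        cols = rel[sel] // time_bin_frames
        vals = np.clip(s.values[sel], fret_range[0], fret_range[1] - 1e-9)
        idx = np.floor((vals - fret_range[0]) / fret_bin).astype(int)
        np.add.at(counts, (idx, cols), 1.0)
        n_per_col[np.unique(cols)] += 1
    col_sums = counts.sum(axis=0)
    density = np.divide(counts, col_sums, where=col_sums > 0,
                        out=np.zeros_like(counts))
    time_edges = np.arange(n_cols + 1) * time_bin_frames / frame_rate
    return DensityMap(time_edges=time_edges, fret_edges=fret_edges,
                      density=density, n_per_column=n_per_col, mode=mode)


def plot_density(dm: DensityMap, path=None, cmap: str = "viridis"):
    """Render a contour-style heatmap of a density map (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    mesh = ax.pcolormesh(dm.time_edges, dm.fret_edges, dm.density,
                         cmap=cmap, shading="auto")
    fig.colorbar(mesh, ax=ax, label="probability")
    ax.set_xlabel("time since synchronization (s)")
    ax.set_ylabel("FRET efficiency")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
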