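"""FRET population analysis: pooled samples, Gaussian mixtures, dynamics.

Reproduces the histogram-level quantities of the termination study:
Gaussian fits of FRET distributions with population fractions p (area
under each component), and the fraction of traces showing transitions.
The mixture is fit by EM on the raw pooled values (bin-width
independent); a least-squares fit to the binned histogram is provided as
a fidelity check and agrees on clean data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.mixture import GaussianMixture

from .idealize import IdealizedPath
from .qc import FretSeries


@dataclass
class GaussianMixtureFit:
    """Components sorted by ascending mean; weights sum to 1."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    bic: float
    n_samples: int

    @property
    def n_components(self) -> int:
        return self.means.size


def collect_fret_samples(
    series: list[FretSeries],
    policy: str = "steady_state",
    sync_frames: list[int | None] | None = None,
    n_post: int = 30,
) -> np.ndarray:
    """Pool per-frame FRET values across traces.

    ``steady_state`` pools every unmasked frame.  ``post_sync`` pools the
    first ``n_post`` unmasked frames at or after each trace's
    synchronization frame (``sync_frames``, one entry per series; None
    marks a trace without the sync feature, which contributes nothing).
    """
    if policy == "steady_state":
        parts = [s.valid_values() for s in series]
    elif policy == "post_sync":
        if sync_frames is None or len(sync_frames) != len(series):
            raise ValueError("post_sync needs one sync frame per series")
        if not 1 <= n_post:
            raise ValueError("n_post must be positive")
        parts = []
        for s, f0 in zip(series, sync_frames):
            if f0 is None:
                continue
            sel = s.mask & (np.arange(s.values.size) >= f0)
            parts.append(s.values[sel][:n_post])
    else:
        raise ValueError(f"unknown window policy {policy!r}")
    return np.concatenate(parts) if parts else np.array([])


def fit_gmm(values: np.ndarray, n_components: int, rng_seed: int = 0) -> GaussianMixtureFit:
    """EM Gaussian mixture on raw pooled FRET values.

    Initialized from the empirical quantiles with seeded restarts;
    components are reported sorted by mean.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.size < 10 * n_components:
        raise ValueError(f"need at least {10 * n_components} values, got {x.size}")
    if np.ptp(x) <= 0:
        raise ValueError("degenerate input: all values identical")
    q = np.quantile(x, (np.arange(n_components) + 0.5) / n_components).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        means_init=q,
        n_init=1,
        reg_covar=1e-6,
        random_state=rng_seed,
    ).fit(x)
    # seeded k-means restarts in case the quantile start is poor
    gm2 = GaussianMixture(n_components=n_components, covariance_type="full",
                          n_init=3, reg_covar=1e-6, random_state=rng_seed).fit(x)
    if gm2.score(x) > gm.score(x):
        gm = gm2
    order = np.argsort(gm.means_.ravel())
    ll = float(gm.score(x) * x.size)
    return GaussianMixtureFit(
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.reshape(-1)[order]),
        weights=gm.weights_[order],
        log_likelihood=ll,
        bic=float(gm.bic(x)),
        n_samples=x.size,
    )


def select_components(values: np.ndarray, max_components: int = 3, rng_seed: int = 0) -> int:
    """Component count minimizing BIC."""
    best_n, best_bic = 1, np.inf
    for n in range(1, max_components + 1):
        if np.asarray(values).size < 10 * n:
            break
        fit = fit_gmm(values, n, rng_seed)
        if fit.bic < best_bic:
            best_n, best_bic = n, fit.bic
    return best_n


def fit_gmm_binned(
    values: np.ndarray,
    n_components: int,
    bin_width: float = 0.02,
    domain: tuple[float, float] = (-0.1, 1.1),
) -> GaussianMixtureFit:
    """Least-squares Gaussian fit to the binned histogram (fidelity mode)."""
    x = np.asarray(values, dtype=float)
    if x.size < 10 * n_components:
        raise ValueError("too few values for a binned fit")
    edges = np.arange(domain[0], domain[1] + bin_width / 2, bin_width)
    hist, _ = np.histogram(x, bins=edges, density=True)
    centers = (edges[:-1] + edges[1:]) / 2

    def model(c, *theta):
        out = np.zeros_like(c)
        for i in range(n_components):
            w, m, s = theta[3 * i: 3 * i + 3]
            out = out + w / (np.sqrt(2 * np.pi) * s) * np.exp(-0.5 * ((c - m) / s) ** 2)
        return out

    q = np.quantile(x, (np.arange(n_components) + 0.5) / n_components)
    p0 = []
    for m in q:
        p0 += [1.0 / n_components, float(m), max(float(np.std(x)) / n_components, 0.01)]
    lb = [0.0, domain[0], 1e-3] * n_components
    ub = [1.5, domain[1], 1.0] * n_components
    popt, _ = optimize.curve_fit(model, centers, hist, p0=p0, bounds=(lb, ub), maxfev=20000)
    w = popt[0::3]
    order = np.argsort(popt[1::3])
    return GaussianMixtureFit(
        means=popt[1::3][order],
        sds=popt[2::3][order],
        weights=(w / w.sum())[order],
        log_likelihood=np.nan,
        bic=np.nan,
        n_samples=x.size,
    )


def dynamic_fraction(paths: list[IdealizedPath]) -> tuple[float, float]:
    """Fraction of traces with at least one surviving transition.

    Returns ``(fraction, binomial standard error)``; paths are expected
    to have passed the state-merging rule already.
    """
    if not paths:
        raise ValueError("no idealized paths supplied")
    n = len(paths)
    k = sum(1 for p in paths if p.n_transitions >= 1)
    frac = k / n
    se = float(np.sqrt(frac * (1 - frac) / n))
    return frac, se
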