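"""End-to-end orchestration: simulate -> QC -> idealize -> analyze.

`analyze_replicate` runs the full analysis chain on one trace set;
`run_scenario` repeats it over replicate seeds (three independent
datasets by default, matching how the experimental quantities are
reported as mean +/- sd) and aggregates; `run_pipeline` drives several
scenarios from one validated config and writes the result tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import idealize, kinetics, populations, qc, syncdensity
from .kinetics import ExpFit, RateEstimate
from .synthetic import FIXTURES, ScenarioFixture, get_fixture, simulate_scenario


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    scenarios: tuple[str, ...] = ()
    n_traces: int = 300
    seeds: tuple[int, ...] = (0, 1, 2)
    frame_rate: float = 30.0
    beta: float | str = 0.13  # or "auto" to calibrate from the data
    corr_max: float = 0.1
    merge_de: float = 0.1
    k_max: int = 4
    fix_K: bool = True  # use the scenario's known state count
    max_exp: int = 2
    bleach: float | str | None = "auto"  # binding photobleach calibration
    bleach_limit: float = 0.2  # detection limit for slow dissociation, s^-1
    n_post: int = 30  # frames pooled after synchronization
    dark_threshold: float = 0.25
    out_dir: str | None = None
    run_qc: bool = True
    run_kinetics: bool = True
    run_density: bool = False


def validate_config(raw: dict | PipelineConfig) -> PipelineConfig:
    """Fill defaults, check ranges, normalize units (s, s^-1, frames)."""
    if isinstance(raw, PipelineConfig):
        cfg = raw
    else:
        unknown = set(raw) - {f.name for f in dataclasses.fields(PipelineConfig)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = PipelineConfig(**raw)
    cfg = dataclasses.replace(cfg, scenarios=tuple(cfg.scenarios), seeds=tuple(cfg.seeds))
    for name in cfg.scenarios:
        if name not in FIXTURES:
            raise ValueError(f"unknown scenario {name!r}; available: {sorted(FIXTURES)}")
    if not (0.0 < cfg.corr_max <= 1.0):
        raise ValueError("corr_max must be in (0, 1]")
    if isinstance(cfg.beta, str):
        if cfg.beta != "auto":
            raise ValueError("beta must be a number in [0,1) or 'auto'")
    elif not (0.0 <= cfg.beta < 1.0):
        raise ValueError("beta must be in [0, 1)")
    if not (0.0 <= cfg.merge_de <= 0.5):
        raise ValueError("merge_de must be in [0, 0.5]")
    if cfg.k_max < 1:
        raise ValueError("k_max must be >= 1")
    if cfg.max_exp not in (1, 2):
        raise ValueError("max_exp must be 1 or 2")
    if cfg.frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if cfg.n_traces < 0:
        raise ValueError("n_traces must be nonnegative")
    if not cfg.seeds:
        raise ValueError("at least one replicate seed required")
    return cfg


# ---------------------------------------------------------------------------
# per-replicate analysis
# ---------------------------------------------------------------------------


def _rate_name(fixture: ScenarioFixture, rank: str) -> str:
    """Field name of the exit rate from the high/low FRET state."""
    if fixture.mode == "binding":
        return "k_off"
    scheme = fixture.schemes[0]
    e = scheme.emitted_fret()
    hi, lo = scheme.state_ids[int(np.argmax(e))], scheme.state_ids[int(np.argmin(e))]
    return f"k_{hi}_to_{lo}" if rank == "high" else f"k_{lo}_to_{hi}"


@dataclass
class ReplicateResult:
    scenario: str
    seed: int
    n_input: int
    n_accepted: int
    beta_hat: float
    qc_report: qc.QCReport | None
    series: list[qc.FretSeries]
    paths_all: list[idealize.IdealizedPath]
    paths_kinetic: list[idealize.IdealizedPath]
    dwells_all: pd.DataFrame
    dwells_kinetic: pd.DataFrame
    gmm: populations.GaussianMixtureFit | None = None
    dynamic: tuple[float, float] | None = None
    exp_fits: dict[str, ExpFit] = field(default_factory=dict)
    rates: dict[str, RateEstimate] = field(default_factory=dict)
    fast_fraction: float | None = None
    sync_frames: list | None = None
    density: syncdensity.DensityMap | None = None
    bound_fret: float | None = None


def analyze_replicate(
    fixture: ScenarioFixture,
    traces,
    cfg: PipelineConfig,
    k_bleach: RateEstimate | None = None,
    seed: int = 0,
) -> ReplicateResult:
    """Full analysis of one simulated (or loaded) trace set."""
    beta = cfg.beta
    if beta == "auto":
        beta = qc.estimate_bleedthrough(traces)
    if cfg.run_qc:
        accepted, report = qc.select_traces(
            traces, beta=beta,
            thresholds=qc.QCThresholds(corr_max=cfg.corr_max),
            mode=fixture.mode)
    else:
        accepted = [qc.correct_bleedthrough(t, beta) for t in traces]
        report = None
    # raw series for dwell-resolving idealization; 3-point-smoothed series
    # for histograms and density maps (as the traces are displayed)
    series = qc.fret_series_for(accepted)
    series_smooth = qc.fret_series_for(accepted, smooth=True)

    paths = []
    kept_series = []
    kept_smooth = []
    for s, ssm in zip(series, series_smooth):
        k = fixture.n_states if cfg.fix_K else idealize.select_K(s, cfg.k_max, rng_seed=seed)
        k = min(k, cfg.k_max)
        if s.n_valid < 2 * k:
            continue
        fit = idealize.fit_hmm(s, k, rng_seed=seed)
        paths.append(idealize.decode(fit, s))
        kept_series.append(s)
        kept_smooth.append(ssm)
    paths_kinetic, paths_all = idealize.exclude_for_kinetics(paths, cfg.merge_de)
    dwells_all = idealize.dwell_table(paths_all)
    dwells_kinetic = idealize.dwell_table(paths_kinetic)

    res = ReplicateResult(
        scenario=fixture.name, seed=seed, n_input=len(traces),
        n_accepted=len(accepted), beta_hat=float(beta), qc_report=report,
        series=kept_series, paths_all=paths_all, paths_kinetic=paths_kinetic,
        dwells_all=dwells_all, dwells_kinetic=dwells_kinetic,
    )

    if fixture.mode == "binding":
        res.sync_frames, _ = syncdensity.synchronize(
            paths_all, "fret_event_start", dark_threshold=cfg.dark_threshold)
        pool = populations.collect_fret_samples(
            kept_smooth, "post_sync", res.sync_frames, cfg.n_post)
        if pool.size >= 20:
            # short-lived events leave post-sync windows part dark, so the
            # pool is a dark/bound mixture; the bound peak is the highest-
            # mean Gaussian component
            n_comp = populations.select_components(pool, 2, rng_seed=seed)
            res.gmm = populations.fit_gmm(pool, n_comp, rng_seed=seed)
            res.bound_fret = float(res.gmm.means[-1])
        if cfg.run_density and any(f is not None for f in res.sync_frames):
            res.density = syncdensity.density_map(kept_smooth, res.sync_frames,
                                                  mode="fret_event_start")
        if cfg.run_kinetics:
            _binding_kinetics(res, fixture, cfg, k_bleach)
    else:
        pool = populations.collect_fret_samples(kept_smooth, "steady_state")
        n_comp = fixture.n_states if cfg.fix_K else populations.select_components(pool, 3, seed)
        if pool.size >= 10 * n_comp:
            res.gmm = populations.fit_gmm(pool, n_comp, rng_seed=seed)
        if paths_all:
            res.dynamic = populations.dynamic_fraction(paths_all)
        if cfg.run_kinetics:
            _rotation_kinetics(res, fixture, cfg)
    return res


def _rotation_kinetics(res: ReplicateResult, fixture: ScenarioFixture, cfg: PipelineConfig):
    d = res.dwells_kinetic
    if d.empty:
        return
    fr = fixture.frame_rate
    fits: dict[str, ExpFit] = {}
    for rank in ("high", "low"):
        try:
            n = kinetics.select_exp_model(d, rank, fr) if cfg.max_exp == 2 else 1
            fits[rank] = kinetics.fit_dwell_exponential(d, rank, n, fr)
        except ValueError:
            continue
    # joint dead-time correction of the dominant exit rates
    scale = {r: 1.0 for r in fits}
    if len(fits) == 2:
        kh, kl = fits["high"].rate, fits["low"].rate
        kh_c, kl_c = kinetics.correct_missed_events(kh, kl, fr)
        scale = {"high": kh_c / kh, "low": kl_c / kl}
    biphasic = {}
    for rank, fit in fits.items():
        name = _rate_name(fixture, rank)
        res.exp_fits[name] = fit
        sd = float(fit.rate_se[int(np.argmax(fit.amplitudes))])
        res.rates[name] = RateEstimate(
            name=name, value=fit.rate * scale[rank],
            sd=sd * scale[rank] if np.isfinite(sd) else None, n=fit.n_dwells,
            meta={"raw": fit.rate, "dead_time_scale": scale[rank]})
        if fit.n_components == 2:
            biphasic[rank] = fit
    if len(biphasic) == 2:
        # correct each molecular subpopulation's rate pair separately
        for label, i in (("fast", 0), ("slow", 1)):
            kh_c, kl_c = kinetics.correct_missed_events(
                float(biphasic["high"].rates[i]), float(biphasic["low"].rates[i]), fr)
            for rank, value in (("high", kh_c), ("low", kl_c)):
                fit = biphasic[rank]
                key = f"{_rate_name(fixture, rank)}_{label}"
                se = float(fit.rate_se[i])
                res.rates[key] = RateEstimate(
                    name=key, value=value,
                    sd=se * value / float(fit.rates[i]) if np.isfinite(se) else None,
                    n=fit.n_dwells,
                    meta={"amplitude": float(fit.amplitudes[i]), "raw": float(fit.rates[i])})
        rank_idx = {"low": 0, "high": 1}
        comp = {rank_idx[r]: (float(f.rates[0]), float(f.rates[1]))
                for r, f in biphasic.items()}
        res.fast_fraction, _ = kinetics.classify_subpopulations(d, comp, fr)


def _binding_kinetics(res: ReplicateResult, fixture: ScenarioFixture,
                      cfg: PipelineConfig, k_bleach: RateEstimate | None):
    d = res.dwells_all
    if d.empty:
        return
    bound = d[(d["state_mean"] > cfg.dark_threshold) & ~d["censored_left"]]
    dark = d[(d["state_mean"] <= cfg.dark_threshold) & ~d["censored_left"]]
    fr = fixture.frame_rate
    try:
        fit = kinetics.fit_dwell_exponential(bound, None, 1, fr)
    except ValueError:
        return
    res.exp_fits["k_off_obs"] = fit
    # merged events across undetected dark gaps are rare (slow rebinding)
    # but cheap to correct for
    k_off = fit.rate
    try:
        dark_fit = kinetics.fit_dwell_exponential(dark, None, 1, fr)
        k_off, _ = kinetics.correct_missed_events(fit.rate, dark_fit.rate, fr)
    except ValueError:
        pass
    obs = RateEstimate(name="k_off", value=k_off,
                       sd=float(fit.rate_se[0]) * k_off / fit.rate,
                       n=fit.n_dwells, meta={"raw": fit.rate})
    res.rates["k_off_obs"] = obs
    if k_bleach is not None and k_bleach.value is not None:
        res.rates["k_off"] = kinetics.correct_koff(obs, k_bleach, cfg.bleach_limit)


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSummary:
    scenario: str
    n_traces: int
    seeds: tuple[int, ...]
    replicates: list[ReplicateResult]
    gmm_means: np.ndarray | None = None
    gmm_means_sd: np.ndarray | None = None
    gmm_weights: np.ndarray | None = None
    gmm_weights_sd: np.ndarray | None = None
    rates: dict[str, RateEstimate] = field(default_factory=dict)
    dynamic: tuple[float, float] | None = None
    fast_fraction: tuple[float, float] | None = None
    bound_fret: tuple[float, float] | None = None


def run_scenario(
    name: str,
    cfg: PipelineConfig,
    n_traces: int | None = None,
    seeds: tuple[int, ...] | None = None,
    k_bleach: RateEstimate | None = None,
) -> ScenarioSummary:
    """Simulate and analyze one scenario over replicate seeds."""
    fixture = get_fixture(name)
    if cfg.frame_rate != fixture.frame_rate:
        fixture = dataclasses.replace(fixture, frame_rate=cfg.frame_rate)
    n = cfg.n_traces if n_traces is None else n_traces
    use_seeds = cfg.seeds if seeds is None else tuple(seeds)
    reps = []
    for seed in use_seeds:
        traces, _manifest = simulate_scenario(fixture, n, rng_seed=seed)
        reps.append(analyze_replicate(fixture, traces, cfg, k_bleach, seed))
    summary = ScenarioSummary(scenario=name, n_traces=n, seeds=use_seeds, replicates=reps)

    gmms = [r.gmm for r in reps if r.gmm is not None]
    if gmms and len({g.n_components for g in gmms}) == 1:
        means = np.array([g.means for g in gmms])
        weights = np.array([g.weights for g in gmms])
        summary.gmm_means = means.mean(axis=0)
        summary.gmm_means_sd = means.std(axis=0, ddof=1) if len(gmms) > 1 else np.full(means.shape[1], np.nan)
        summary.gmm_weights = weights.mean(axis=0)
        summary.gmm_weights_sd = weights.std(axis=0, ddof=1) if len(gmms) > 1 else np.full(weights.shape[1], np.nan)

    keys = sorted({k for r in reps for k in r.rates})
    for key in keys:
        ests = [r.rates[key] for r in reps if key in r.rates]
        if ests:
            summary.rates[key] = kinetics.aggregate_replicates(ests)

    dyn = [r.dynamic[0] for r in reps if r.dynamic is not None]
    if dyn:
        summary.dynamic = (float(np.mean(dyn)),
                           float(np.std(dyn, ddof=1)) if len(dyn) > 1 else np.nan)
    ff = [r.fast_fraction for r in reps if r.fast_fraction is not None]
    if ff:
        summary.fast_fraction = (float(np.mean(ff)),
                                 float(np.std(ff, ddof=1)) if len(ff) > 1 else np.nan)
    bf = [r.bound_fret for r in reps if r.bound_fret is not None]
    if bf:
        summary.bound_fret = (float(np.mean(bf)),
                              float(np.std(bf, ddof=1)) if len(bf) > 1 else np.nan)
    return summary


def calibrate_binding_bleach(cfg: PipelineConfig,
                             scenario: str = "l11_rf1",
                             n_traces: int | None = None) -> RateEstimate:
    """Photobleach hazard of binding events, from a stably bound factor.

    The disappearance rate of FRET events of an essentially non-
    dissociating factor is photobleach-limited, so its observed k_off
    serves as the bleach hazard subtracted from other scenarios (and as
    the detection limit for slow dissociation).
    """
    summary = run_scenario(scenario, cfg, n_traces=n_traces)
    est = summary.rates.get("k_off_obs")
    if est is None or est.value is None:
        raise RuntimeError("bleach calibration failed: no observed k_off")
    return RateEstimate(name="k_bleach", value=est.value, sd=est.sd, n=est.n,
                        meta={"calibration_scenario": scenario})


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: dict | PipelineConfig) -> dict[str, ScenarioSummary]:
    """Run every configured scenario and (optionally) write result tables."""
    cfg = validate_config(config)
    k_bleach = None
    needs_binding = any(get_fixture(s).mode == "binding" for s in cfg.scenarios)
    if needs_binding and cfg.bleach is not None:
        if cfg.bleach == "auto":
            k_bleach = calibrate_binding_bleach(cfg)
        else:
            k_bleach = RateEstimate(name="k_bleach", value=float(cfg.bleach), sd=0.0)
    summaries = {name: run_scenario(name, cfg, k_bleach=k_bleach)
                 for name in cfg.scenarios}
    if cfg.out_dir is not None:
        _write_outputs(cfg, summaries, k_bleach)
    return summaries


def _write_outputs(cfg: PipelineConfig, summaries: dict[str, ScenarioSummary],
                   k_bleach: RateEstimate | None) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pop_rows, rate_rows = [], []
    for name, s in summaries.items():
        if s.gmm_means is not None:
            for i, (m, msd, w, wsd) in enumerate(zip(
                    s.gmm_means, s.gmm_means_sd, s.gmm_weights, s.gmm_weights_sd)):
                pop_rows.append({"scenario": name, "component": i,
                                 "fret_mean": m, "fret_mean_sd": msd,
                                 "population": w, "population_sd": wsd,
                                 "n_traces": s.n_traces, "n_replicates": len(s.seeds)})
        for key, est in s.rates.items():
            rate_rows.append({"scenario": name, "quantity": key,
                              "mean": est.value, "sd": est.sd, "n": est.n,
                              "photobleach_corrected": est.photobleach_corrected,
                              "detection_limit": est.detection_limit,
                              "bound": est.bound})
        if s.dynamic is not None:
            rate_rows.append({"scenario": name, "quantity": "dynamic_fraction",
                              "mean": s.dynamic[0], "sd": s.dynamic[1], "n": s.n_traces,
                              "photobleach_corrected": False,
                              "detection_limit": False, "bound": None})
        if s.bound_fret is not None:
            pop_rows.append({"scenario": name, "component": "bound",
                             "fret_mean": s.bound_fret[0], "fret_mean_sd": s.bound_fret[1],
                             "population": None, "population_sd": None,
                             "n_traces": s.n_traces, "n_replicates": len(s.seeds)})
        if s.fast_fraction is not None:
            rate_rows.append({"scenario": name, "quantity": "fast_molecule_fraction",
                              "mean": s.fast_fraction[0], "sd": s.fast_fraction[1],
                              "n": s.n_traces, "photobleach_corrected": False,
                              "detection_limit": False, "bound": None})
    pd.DataFrame(pop_rows).to_csv(out / "populations.csv", index=False)
    pd.DataFrame(rate_rows).to_csv(out / "rates.csv", index=False)
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "k_bleach": None if k_bleach is None else
        {"value": k_bleach.value, "sd": k_bleach.sd, "n": k_bleach.n},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
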