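"""End-to-end AF episodes: induction, observation, analysis, ablation.

One episode reproduces the study design at a chosen conduction
velocity: calibrate the diffusion coefficient for the CV target, induce
AF by ramp pacing at the high-septum analogue site, observe AF for up
to 300 s, compute windowed DF and PS metrics (T1-T9: 6-s windows every
30 s of AF maintenance), branch the simulation at each window end for
virtual DF ablation, and classify outcomes.  Episode-level definitions:

* successful AF induction — AF maintained > 20 s after ramp pacing;
* AF maintenance duration — the pure sustained-AF period (ends at
  termination or at conversion to organised AT);
* AF/AT maintenance duration — sustained AF-or-AT period (<= cap).

Ensemble variability on homogeneous tissue comes from per-seed stimulus
timing jitter (+-1 ms) and initial-voltage micro-noise (sigma = 0.1 mV).
Desk-scale presets shrink the sheet and the observation cap while
keeping windows proportionally spaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cell_model import (
    IonicParameters,
    apply_af_remodeling,
    build_rate_tables,
    reaction_step,
    resting_state,
)
from .df_analysis import (
    RegionalProportionTable,
    compute_df_map,
    highest_df_area,
    regional_proportions,
    spatial_mean_variance,
    temporal_mean_variance,
)
from .pacing_protocols import ramp_pacing_protocol
from .ps_analysis import compute_phase, count_ps_per_ms, detect_ps_movie, link_trajectories
from .synthetic_geometry import make_sheet
from .tissue_solver import (
    MonodomainSolver,
    SolverSettings,
    TissueDomain,
    activation_times,
    calibrate_diffusion,
)
from .virtual_ablation import ablation_experiment, classify_outcome

__all__ = [
    "EpisodeConfig",
    "EpisodeResult",
    "define_windows",
    "run_episode",
    "aggregate_cv_statistics",
    "limit_cycle_states",
    "spiral_seed_states",
]


@dataclass(frozen=True)
class EpisodeConfig:
    """Study-design parameters for one AF episode.

    Defaults follow the full protocol (300-s cap, 6-s windows every
    30 s, 20-s induction threshold, 30-s post-ablation observation).
    ``sheet_n``/``sheet_spacing`` control the 2D geometry; the planar
    experiment configuration is 600 x 600 at 0.25 mm with conduction
    ratio 2 (use :meth:`full_scale`); :meth:`desk_scale` gives a
    reduced sheet and cap for workstation runs.
    """

    cv_target: float = 0.4              # m/s
    sheet_n: int = 600
    sheet_spacing: float = 0.025        # cm
    anisotropy_ratio: float = 2.0
    cap_s: float = 300.0
    induction_threshold_s: float = 20.0
    window_every_s: float = 30.0
    window_length_s: float = 6.0
    observe_ablation_s: float = 30.0
    ks: tuple = (10.0, 15.0, 20.0)
    seed: int = 0
    jitter_ms: float = 1.0
    noise_sigma_mv: float = 0.1
    quiescence_s: float = 1.0
    dt_min: float = 0.01
    dt_max: float = 0.1
    dvdt_threshold: float = np.inf      # fixed 0.1 ms step (planar runs)
    band_hz: tuple = (1.0, 20.0)
    stim_amplitude: float = -60.0
    stim_radius_cm: float = 0.15

    induction: str = "ramp"             # 'ramp' | 'spiral_seed'
    seed_cycle_length_ms: float = 300.0  # limit-cycle CL for spiral seeding

    @classmethod
    def full_scale(cls, cv_target: float, **kw) -> "EpisodeConfig":
        return cls(cv_target=cv_target, **kw)

    @classmethod
    def desk_scale(cls, cv_target: float, sheet_n: int = 120,
                   sheet_spacing: float = 0.05, cap_s: float = 24.0,
                   window_every_s: float = 6.0, window_length_s: float = 3.0,
                   observe_ablation_s: float = 6.0,
                   induction_threshold_s: float = 2.0,
                   quiescence_s: float = 0.5, **kw) -> "EpisodeConfig":
        """Reduced sheet and observation cap with proportional windows."""
        return cls(cv_target=cv_target, sheet_n=sheet_n,
                   sheet_spacing=sheet_spacing, cap_s=cap_s,
                   window_every_s=window_every_s,
                   window_length_s=window_length_s,
                   observe_ablation_s=observe_ablation_s,
                   induction_threshold_s=induction_threshold_s,
                   quiescence_s=quiescence_s, **kw)

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(dt_min=self.dt_min, dt_max=self.dt_max,
                              dvdt_threshold=self.dvdt_threshold,
                              record_dt=1.0, seed=self.seed)


def define_windows(af_end_s: float, pacing_end_s: float,
                   every_s: float = 30.0, length_s: float = 6.0,
                   cap_s: float = 300.0) -> list:
    """Analysis-window start times (s): every ``every_s`` of maintained AF.

    Windows start at pacing end + every_s, 2*every_s, ... and are kept
    only when fully inside the AF-maintained interval (and the cap).
    """
    starts = []
    k = 1
    while True:
        s = pacing_end_s + k * every_s
        if s + length_s > min(af_end_s, pacing_end_s + cap_s):
            break
        starts.append(s)
        k += 1
    return starts


@dataclass
class EpisodeResult:
    """Everything measured in one episode."""

    cv_target: float
    seed: int
    induced: bool
    af_duration_s: float                 # pure AF, from pacing end, capped
    afat_duration_s: float               # AF or AT, from pacing end, capped
    spontaneously_terminated: bool
    spontaneously_defragmented: bool
    window_metrics: pd.DataFrame = field(default_factory=pd.DataFrame)
    proportion_table: RegionalProportionTable | None = None
    spatial_mean_variance: float = np.nan
    temporal_mean_variance: float = np.nan
    ablation_outcomes: pd.DataFrame = field(default_factory=pd.DataFrame)
    diffusion_cm2_ms: float = np.nan
    achieved_cv: float = np.nan
    failed: bool = False
    failure_reason: str = ""


def limit_cycle_states(params: IonicParameters, cl_ms: float = 300.0,
                       n_beats: int = 6, dt: float = 0.02,
                       sample_ms: float = 1.0,
                       stim_amplitude: float = -40.0) -> np.ndarray:
    """Full membrane-state trajectory over one paced limit cycle.

    The single cell is paced to an approximate limit cycle and the last
    cycle is sampled every ``sample_ms``; the (n_samples, 21) array
    parameterises action-potential phase for spiral seeding.
    """
    S = resting_state()[None, :].copy()
    active = np.ones(1, bool)
    i_stim = np.zeros(1)
    nernst = np.zeros((1, 3))
    p = params.as_array()
    tabs = build_rate_tables(dt)
    n_steps = int(round(n_beats * cl_ms / dt))
    every = int(round(sample_ms / dt))
    snaps = []
    for k in range(n_steps):
        t = k * dt
        i_stim[0] = stim_amplitude if (t % cl_ms) < 2.0 else 0.0
        reaction_step(S, active, i_stim, dt, p, tabs.table, tabs.v_min,
                      tabs.inv_step, tabs.rl_f_ca, tabs.rl_u, nernst, True)
        if t >= (n_beats - 1) * cl_ms and (k + 1) % every == 0:
            snaps.append(S[0].copy())
    return np.array(snaps)


def spiral_seed_states(domain: TissueDomain, cycle: np.ndarray,
                       cores=((0.5, 0.5, 1),),
                       twist_rad_per_cm: float = 0.0) -> np.ndarray:
    """Phase-distributed (cross-field) initial condition for reentry.

    Each node is assigned the limit-cycle state at a phase given by the
    summed azimuths around one or more cores (``(fx, fy, chirality)``
    triples, positions as fractions of the domain extent), optionally
    with an Archimedean radial twist.  Evolving these states under the
    tissue model produces rotors that settle to their own rotation
    period — the standard desk-scale way to initiate reentry where the
    domain is smaller than the pacing-induced wavelength.  Several
    opposite-chirality cores give a multi-wavelet (fibrillation-like)
    state that is markedly more persistent than a single spiral on
    small sheets.
    """
    x, y = domain.coords[:, 0], domain.coords[:, 1]
    ex = x.max() - x.min()
    ey = y.max() - y.min()
    phi = np.zeros(domain.n_nodes)
    for fx, fy, q in cores:
        xc = x.min() + fx * ex
        yc = y.min() + fy * ey
        phi += q * np.arctan2(y - yc, x - xc)
        if twist_rad_per_cm:
            phi += twist_rad_per_cm * np.hypot(x - xc, y - yc)
    frac = ((phi + np.pi) / (2 * np.pi)) % 1.0
    idx = (frac * (len(cycle) - 1)).astype(int)
    return cycle[idx]


def _stim_site(domain: TissueDomain, radius_cm: float) -> np.ndarray:
    centre = domain.landmarks.get("pacing_site", 0)
    d = np.linalg.norm(domain.coords - domain.coords[centre], axis=1)
    site = np.nonzero(d <= radius_cm)[0]
    return site if site.size else np.array([centre])


def _last_activation(movie, probes, threshold=-40.0) -> float:
    last = -np.inf
    for p in probes:
        acts = activation_times(movie, int(p), threshold)
        if acts.size:
            last = max(last, acts[-1])
    return last


def run_episode(config: EpisodeConfig, params: IonicParameters | None = None,
                domain: TissueDomain | None = None,
                diffusion: float | None = None,
                run_ablation: bool = True) -> EpisodeResult:
    """Simulate one full episode at the configured CV.

    ``diffusion`` (cm^2/ms) skips calibration when the coefficient for
    the CV target is already known.  Returns an :class:`EpisodeResult`;
    numerical blow-up marks the episode failed instead of raising.
    """
    if params is None:
        params = apply_af_remodeling(IonicParameters())
    if diffusion is None:
        diffusion, achieved = calibrate_diffusion(
            config.cv_target, spacing=config.sheet_spacing, params=params)
    else:
        achieved = np.nan
    if domain is None:
        domain = make_sheet(n=config.sheet_n, spacing=config.sheet_spacing,
                            D=diffusion, anisotropy_ratio=config.anisotropy_ratio)
    else:
        domain = domain.copy()
        domain.D[:] = diffusion

    rng = np.random.default_rng(config.seed)
    from .tissue_solver import stable_settings
    settings = stable_settings(domain, config.solver_settings())

    probes = np.unique(np.concatenate([
        _probe_grid(domain, 49), [domain.landmarks.get("probe", 0)]]))

    result = EpisodeResult(cv_target=config.cv_target, seed=config.seed,
                           induced=False, af_duration_s=0.0,
                           afat_duration_s=0.0,
                           spontaneously_terminated=False,
                           spontaneously_defragmented=False,
                           diffusion_cm2_ms=diffusion, achieved_cv=achieved)

    try:
        if config.induction == "spiral_seed":
            cycle = limit_cycle_states(params, config.seed_cycle_length_ms)
            # four alternating-chirality rotors, positions jittered per seed
            cores = []
            for fx, fy, q in ((0.3, 0.35, 1), (0.7, 0.35, -1),
                              (0.3, 0.75, -1), (0.7, 0.75, 1)):
                cores.append((fx + rng.uniform(-0.05, 0.05),
                              fy + rng.uniform(-0.05, 0.05), q))
            states0 = spiral_seed_states(domain, cycle, cores=cores)
            states0[:, 0] += rng.normal(0.0, config.noise_sigma_mv,
                                        domain.n_nodes)
            solver = MonodomainSolver(domain, params, settings, states=states0)
            pacing_end_ms = 0.0
            last_act0 = 0.0             # seeded activity is present at t = 0
        elif config.induction == "ramp":
            site = _stim_site(domain, config.stim_radius_cm)
            ramp = ramp_pacing_protocol(site, amplitude=config.stim_amplitude)
            if config.jitter_ms > 0:
                ramp = ramp.jittered(config.jitter_ms, rng)
            pacing_end_ms = float(ramp.onsets_ms[-1] + 180.0)
            solver = MonodomainSolver(domain, params, settings)
            pace_movie = solver.run(pacing_end_ms, [ramp],
                                    noise_sigma=config.noise_sigma_mv, rng=rng)
            last_act0 = _last_activation(pace_movie, probes)
        else:
            raise ValueError(f"unknown induction mode {config.induction!r}")
    except FloatingPointError as err:
        result.failed = True
        result.failure_reason = str(err)
        return result

    every_ms = config.window_every_s * 1000.0
    wlen_ms = config.window_length_s * 1000.0
    cap_ms = config.cap_s * 1000.0
    quiesce_ms = config.quiescence_s * 1000.0

    af_end_ms = None            # absolute time AF stopped (term or AT)
    afat_end_ms = None          # absolute time all activity stopped
    window_rows = []
    prop_cols = []
    window_labels = []
    checkpoints = []

    t_next_window = pacing_end_ms + every_ms     # window STARTS at k*every
    t = pacing_end_ms
    last_act_global = last_act0
    widx = 0
    try:
        while t < pacing_end_ms + cap_ms and afat_end_ms is None:
            run_af_window = abs(t - t_next_window) < 1e-6
            chunk_ms = wlen_ms if run_af_window else min(
                t_next_window - t, pacing_end_ms + cap_ms - t)
            if chunk_ms <= 0:
                chunk_ms = wlen_ms
            movie = solver.run(chunk_ms)
            la = _last_activation(movie, probes)
            if np.isfinite(la):
                last_act_global = la
            t = solver.time_ms
            # termination: terminal quiescence at all probes
            if t - last_act_global >= quiesce_ms:
                afat_end_ms = last_act_global
                if af_end_ms is None:
                    af_end_ms = last_act_global
                result.spontaneously_terminated = True
                break
            if run_af_window:
                widx += 1
                label = f"T{widx}"
                dfmap = compute_df_map(movie, movie.t0_ms, wlen_ms,
                                       band_hz=config.band_hz)
                outcome = classify_outcome(
                    movie, domain, probes=probes,
                    quiescence_ms=min(quiesce_ms, wlen_ms / 2),
                    ps_window_ms=min(2000.0, wlen_ms))
                phase = compute_phase(movie)
                rec = link_trajectories(detect_ps_movie(phase))
                ls = rec.life_spans_ms()
                sel = highest_df_area(dfmap, 10.0)
                prop = regional_proportions(sel, domain)
                window_rows.append({
                    "window": label,
                    "start_ms": movie.t0_ms,
                    "mean_df_hz": float(np.nanmean(dfmap.df_hz)),
                    "ps_per_ms": float(np.mean(rec.counts)),
                    "longest_ps_life_ms": float(ls.max()) if ls.size else 0.0,
                    "label": outcome.label,
                })
                prop_cols.append(prop)
                window_labels.append(label)
                checkpoints.append((label, solver.states.copy(), dfmap))
                if outcome.label == "AT" and af_end_ms is None:
                    af_end_ms = movie.t0_ms
                t_next_window += every_ms
    except FloatingPointError as err:
        result.failed = True
        result.failure_reason = str(err)
        return result

    cap_end = pacing_end_ms + cap_ms
    if afat_end_ms is None:
        afat_end_ms = cap_end
    if af_end_ms is None:
        af_end_ms = afat_end_ms
    result.af_duration_s = max(0.0, (af_end_ms - pacing_end_ms) / 1000.0)
    result.afat_duration_s = max(0.0, (afat_end_ms - pacing_end_ms) / 1000.0)
    result.induced = result.af_duration_s > config.induction_threshold_s
    result.spontaneously_defragmented = (
        result.spontaneously_terminated or af_end_ms < afat_end_ms)
    # keep only windows fully inside the AF-maintained interval
    keep = [i for i, row in enumerate(window_rows)
            if row["start_ms"] + wlen_ms <= af_end_ms + 1e-6]
    window_rows = [window_rows[i] for i in keep]
    prop_cols = [prop_cols[i] for i in keep]
    window_labels = [window_labels[i] for i in keep]
    checkpoints = [checkpoints[i] for i in keep]
    result.window_metrics = pd.DataFrame(window_rows)
    if prop_cols:
        table = RegionalProportionTable(
            np.column_stack(prop_cols), 10.0, tuple(window_labels),
            domain.region_names)
        result.proportion_table = table
        if len(prop_cols) >= 2:
            result.spatial_mean_variance = spatial_mean_variance(table)
            result.temporal_mean_variance = temporal_mean_variance(table)

    if run_ablation and checkpoints and result.induced:
        result.ablation_outcomes = ablation_experiment(
            domain, params, checkpoints, ks=config.ks,
            observe_ms=config.observe_ablation_s * 1000.0,
            settings=settings,
            classify_kwargs={"quiescence_ms": quiesce_ms,
                             "ps_window_ms": min(2000.0,
                                                 config.observe_ablation_s * 500.0)})
    return result


def _probe_grid(domain: TissueDomain, n: int) -> np.ndarray:
    if domain.grid_shape is not None:
        ny, nx = domain.grid_shape
        side = int(round(np.sqrt(n)))
        ys = np.linspace(ny * 0.1, ny * 0.9, side).astype(int)
        xs = np.linspace(nx * 0.1, nx * 0.9, side).astype(int)
        return (ys[:, None] * nx + xs[None, :]).ravel()
    active = np.nonzero(~domain.ablation_mask)[0]
    step = max(1, active.size // n)
    return active[::step][:n]


def _nanmean(values) -> float:
    values = [v for v in values if np.isfinite(v)]
    return float(np.mean(values)) if values else np.nan


def aggregate_cv_statistics(episodes, reference_cv: float = 0.4) -> pd.DataFrame:
    """CV-stratified summary with paired comparisons to the reference.

    One row per CV: induction rate, mean +- SD AF and AF/AT durations,
    spontaneous termination/defragmentation rates among induced
    episodes, DF mean-variance statistics, PS counts, and per-k ablation
    defragmentation rates.  Paired t-tests against the ``reference_cv``
    stratum use episodes matched by seed; degenerate (zero-variance)
    comparisons report nan with a flag.
    """
    if not episodes:
        raise ValueError("no episodes to aggregate")
    by_cv: dict[float, list] = {}
    for ep in episodes:
        if ep.failed:
            continue
        by_cv.setdefault(ep.cv_target, []).append(ep)

    ref = {ep.seed: ep for ep in by_cv.get(reference_cv, [])}
    rows = []
    for cv in sorted(by_cv):
        eps = by_cv[cv]
        ind = [ep for ep in eps if ep.induced]
        af = np.array([ep.af_duration_s for ep in eps])
        afat = np.array([ep.afat_duration_s for ep in eps])
        row = {
            "cv_m_s": cv,
            "n_episodes": len(eps),
            "induction_rate": float(np.mean([ep.induced for ep in eps])),
            "af_duration_mean_s": float(af.mean()),
            "af_duration_sd_s": float(af.std(ddof=1)) if len(eps) > 1 else np.nan,
            "afat_duration_mean_s": float(afat.mean()),
            "spont_termination_rate": (float(np.mean([ep.spontaneously_terminated for ep in ind]))
                                       if ind else np.nan),
            "spont_defrag_rate": (float(np.mean([ep.spontaneously_defragmented for ep in ind]))
                                  if ind else np.nan),
            "spatial_mean_variance": _nanmean([ep.spatial_mean_variance for ep in eps]),
            "temporal_mean_variance": _nanmean([ep.temporal_mean_variance for ep in eps]),
            "ps_per_ms_mean": _nanmean([
                ep.window_metrics["ps_per_ms"].mean()
                for ep in eps if len(ep.window_metrics)]),
            "mean_df_hz": _nanmean([
                ep.window_metrics["mean_df_hz"].mean()
                for ep in eps if len(ep.window_metrics)]),
        }
        for k in (10.0, 15.0, 20.0):
            rates = []
            for ep in ind:
                tab = ep.ablation_outcomes
                if len(tab):
                    sub = tab[tab["k_percent"] == k]
                    if len(sub):
                        rates.append(float(sub["defragmented"].mean()))
            row[f"ablation_defrag_rate_k{int(k)}"] = float(np.mean(rates)) if rates else np.nan
        # paired test vs the reference stratum (matched seeds)
        if cv != reference_cv and ref:
            paired = [(ep.af_duration_s, ref[ep.seed].af_duration_s)
                      for ep in eps if ep.seed in ref]
            if len(paired) >= 2:
                a, b = map(np.asarray, zip(*paired))
                if np.allclose(a - b, (a - b)[0]):
                    row["p_vs_ref"] = np.nan
                    row["p_flag"] = "degenerate"
                else:
                    row["p_vs_ref"] = float(stats.ttest_rel(a, b).pvalue)
                    row["p_flag"] = ""
            else:
                row["p_vs_ref"] = np.nan
                row["p_flag"] = "unmatched"
        else:
            row["p_vs_ref"] = np.nan
            row["p_flag"] = "reference" if cv == reference_cv else "no_reference"
        rows.append(row)
    return pd.DataFrame(rows)
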