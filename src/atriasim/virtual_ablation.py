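"""Virtual ablation of highest-DF areas and outcome classification.

Lesions are the nodes carrying the top-k% dominant frequencies of an
analysis window; ablation renders them non-conducting (D = 0, no flux
into the lesion) with membrane states frozen at their ablation-time
values.  The post-ablation episode is observed for 30 s and labelled:

* ``terminated`` — no propagated activation over a terminal quiescent
  interval (>= 1 s);
* ``AT`` (defragmented) — sustained activation that is organised:
  probe-node cycle-length coefficient of variation < 10% and mean PS
  count per ms <= 1;
* ``AF_maintained`` — otherwise.

"Defragmentation" counts terminated plus AT outcomes.  The numeric
thresholds are declared defaults (configurable and recorded in the
evidence of every label), since the clinical definitions are
qualitative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .df_analysis import DFMap, highest_df_area
from .ps_analysis import compute_phase, count_ps_per_ms, detect_ps_movie
from .tissue_solver import (
    MonodomainSolver,
    SolverSettings,
    TissueDomain,
    VoltageMovie,
    activation_times,
)

__all__ = [
    "AblationPlan",
    "OutcomeLabel",
    "plan_from_dfmap",
    "apply_ablation",
    "classify_outcome",
    "ablation_experiment",
]


@dataclass
class AblationPlan:
    """Lesion node set targeting the highest-k% DF area."""

    target_nodes: np.ndarray
    k_percent: float
    time_applied_ms: float
    source: DFMap | None = None

    def __post_init__(self):
        self.target_nodes = np.unique(np.asarray(self.target_nodes, np.int64))


def plan_from_dfmap(dfmap: DFMap, k_percent: float,
                    time_applied_ms: float | None = None) -> AblationPlan:
    """Lesion plan for the highest-k% DF area of one analysis window."""
    nodes = highest_df_area(dfmap, k_percent)
    if time_applied_ms is None:
        time_applied_ms = dfmap.window_start_ms + dfmap.window_length_ms
    return AblationPlan(target_nodes=nodes, k_percent=float(k_percent),
                        time_applied_ms=float(time_applied_ms), source=dfmap)


def apply_ablation(domain: TissueDomain, plan: AblationPlan) -> TissueDomain:
    """Non-conducting copy of the domain: D = 0 on the lesion set.

    The diffusion operator drops every element touching a lesion node,
    so no flux enters or leaves the lesion (symmetric removal).  The
    membrane states of lesioned nodes are frozen by the solver.
    """
    if plan.target_nodes.size and (plan.target_nodes.min() < 0 or
                                   plan.target_nodes.max() >= domain.n_nodes):
        raise ValueError("ablation plan targets nodes outside the domain")
    out = domain.copy()
    out.ablation_mask[plan.target_nodes] = True
    out.D[out.ablation_mask] = 0.0
    return out


@dataclass
class OutcomeLabel:
    """Post-intervention rhythm classification with its evidence."""

    label: str                          # 'terminated' | 'AT' | 'AF_maintained'
    evidence: dict = field(default_factory=dict)
    evaluation_window_ms: float = 30000.0

    @property
    def defragmented(self) -> bool:
        return self.label in ("terminated", "AT")


def _probe_nodes(domain: TissueDomain, n_probes: int) -> np.ndarray:
    active = np.nonzero(~domain.ablation_mask)[0]
    if active.size == 0:
        return active
    step = max(1, active.size // n_probes)
    return active[::step][:n_probes]


def classify_outcome(movie: VoltageMovie, domain: TissueDomain | None = None,
                     probes: np.ndarray | None = None,
                     quiescence_ms: float = 1000.0,
                     cl_cov_threshold: float = 0.10,
                     ps_per_ms_threshold: float = 1.0,
                     activation_threshold: float = -40.0,
                     n_probes: int = 64,
                     ps_window_ms: float = 2000.0) -> OutcomeLabel:
    """Label a post-ablation recording as terminated / AT / AF.

    Cycle lengths are measured at probe nodes over the final portion of
    the window; PS counting runs on the last ``ps_window_ms`` of the
    movie.  Identical movies always produce identical labels.
    """
    domain = domain or movie.domain
    if domain is None:
        raise ValueError("classification needs the tissue geometry")
    if movie.duration_ms < max(quiescence_ms, ps_window_ms):
        raise ValueError("movie shorter than the classification windows")
    if probes is None:
        probes = _probe_nodes(domain, n_probes)

    t_end = movie.t0_ms + movie.duration_ms
    last_act = -np.inf
    cycle_lengths = []
    for p in probes:
        acts = activation_times(movie, int(p), activation_threshold)
        if acts.size:
            last_act = max(last_act, acts[-1])
            if acts.size >= 3:
                cycle_lengths.append(np.diff(acts))
    evidence = {
        "last_activation_ms": float(last_act),
        "quiescence_ms": float(quiescence_ms),
        "cl_cov_threshold": cl_cov_threshold,
        "ps_per_ms_threshold": ps_per_ms_threshold,
        "n_probes": int(len(probes)),
    }

    if not np.isfinite(last_act) or (t_end - last_act) >= quiescence_ms:
        evidence["terminal_quiescence_ms"] = float(t_end - last_act) if np.isfinite(last_act) else movie.duration_ms
        return OutcomeLabel("terminated", evidence, movie.duration_ms)

    if cycle_lengths:
        cls = np.concatenate(cycle_lengths)
        cl_cov = float(np.std(cls) / np.mean(cls)) if np.mean(cls) > 0 else np.inf
    else:
        cl_cov = np.inf
    evidence["cl_mean_ms"] = float(np.mean(np.concatenate(cycle_lengths))) if cycle_lengths else np.nan
    evidence["cl_cov"] = cl_cov

    ps_start = t_end - ps_window_ms
    try:
        phase = compute_phase(movie, window_start_ms=ps_start,
                              window_length_ms=ps_window_ms)
        record = detect_ps_movie(phase)
        ps_rate = count_ps_per_ms(record)
    except ValueError:
        ps_rate = 0.0
    evidence["ps_per_ms"] = float(ps_rate)

    if cl_cov < cl_cov_threshold and ps_rate <= ps_per_ms_threshold:
        return OutcomeLabel("AT", evidence, movie.duration_ms)
    return OutcomeLabel("AF_maintained", evidence, movie.duration_ms)


def ablation_experiment(domain: TissueDomain, params, checkpoints,
                        ks=(10.0, 15.0, 20.0), observe_ms: float = 30000.0,
                        settings: SolverSettings | None = None,
                        classify_kwargs: dict | None = None) -> pd.DataFrame:
    """Branch-and-ablate over analysis-window checkpoints.

    ``checkpoints`` is a list of ``(window_label, states, dfmap)``
    tuples: the saved membrane state at the end of each analysis window
    together with that window's DF map.  For every checkpoint and every
    k the simulation is branched, the top-k% DF lesion applied, the
    episode observed for ``observe_ms`` and classified.  Returns one row
    per (window, k) with the label and evidence metrics.
    """
    if settings is None:
        settings = SolverSettings()
    classify_kwargs = classify_kwargs or {}
    rows = []
    for label, states, dfmap in checkpoints:
        if states is None:
            raise ValueError(f"missing checkpoint states for window {label!r}")
        for k in ks:
            plan = plan_from_dfmap(dfmap, k)
            branch_domain = apply_ablation(domain, plan)
            solver = MonodomainSolver(branch_domain, params, settings,
                                      states=np.array(states, float))
            movie = solver.run(observe_ms)
            outcome = classify_outcome(movie, branch_domain, **classify_kwargs)
            row = {
                "window": label,
                "k_percent": float(k),
                "n_lesion_nodes": int(plan.target_nodes.size),
                "label": outcome.label,
                "defragmented": outcome.defragmented,
            }
            row.update({f"ev_{k_}": v for k_, v in outcome.evidence.items()})
            rows.append(row)
    return pd.DataFrame(rows)
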