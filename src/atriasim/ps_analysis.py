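"""Phase mapping and phase-singularity (PS) detection and tracking.

Phase is computed by time-delay embedding: at each node,

    theta(t) = atan2(V(t + tau) - V_mean, V(t) - V_mean)

with ``V_mean`` the per-node time average over the analysis window, the
embedding origin.  A phase singularity — the pivot of a reentrant rotor,
where phase is undefined — is detected by topological charge: the sum
of wrapped phase differences around an elementary closed loop (grid
plaquette or mesh triangle) equals +-2*pi exactly when the loop encloses
a singularity, zero otherwise.  Detections are counted per millisecond
frame and linked into trajectories (greedy nearest-neighbour,
same-charge, bounded step) whose durations are the PS life-spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .df_analysis import compute_df_map
from .tissue_solver import TissueDomain, VoltageMovie

__all__ = [
    "PhaseMovie",
    "PSRecord",
    "compute_phase",
    "detect_ps",
    "detect_ps_movie",
    "count_ps_per_ms",
    "link_trajectories",
    "PSTrajectory",
]

TWO_PI = 2.0 * np.pi


def _wrap(d: np.ndarray) -> np.ndarray:
    """Wrap phase differences to (-pi, pi]."""
    return d - TWO_PI * np.floor(d / TWO_PI + 0.5)


@dataclass
class PhaseMovie:
    """Node x frame phase in (-pi, pi] from delay embedding."""

    theta: np.ndarray          # (N, F)
    dt_ms: float
    t0_ms: float
    tau_ms: float
    v_mean: np.ndarray         # (N,)
    undefined: np.ndarray      # (N,) nodes with degenerate embedding
    domain: TissueDomain | None = None

    @property
    def n_frames(self) -> int:
        return self.theta.shape[1]


def default_tau(movie: VoltageMovie, window_start_ms: float | None = None,
                window_length_ms: float | None = None) -> float:
    """Quarter of the dominant period (1 / (4 median DF)), on the sample grid."""
    if window_length_ms is None:
        window_length_ms = movie.duration_ms
    dfmap = compute_df_map(movie, window_start_ms, window_length_ms)
    med = np.nanmedian(dfmap.df_hz)
    if not np.isfinite(med) or med <= 0:
        raise ValueError("median DF undefined; specify tau explicitly")
    tau = 250.0 / med                   # ms; quarter period
    return max(movie.dt_ms, round(tau / movie.dt_ms) * movie.dt_ms)


def compute_phase(movie: VoltageMovie, tau_ms: float | None = None,
                  window_start_ms: float | None = None,
                  window_length_ms: float | None = None) -> PhaseMovie:
    """Delay-embedding phase of a voltage movie.

    ``tau_ms`` must be a positive multiple of the sampling interval
    (default: quarter of the dominant period).  ``V_mean`` is averaged
    over the analysis window itself.  Frames are produced for
    t in [start, start + length - tau].
    """
    if window_start_ms is None:
        window_start_ms = movie.t0_ms
    if window_length_ms is None:
        window_length_ms = movie.duration_ms - (window_start_ms - movie.t0_ms)
    if tau_ms is None:
        tau_ms = default_tau(movie, window_start_ms, window_length_ms)
    n_tau = tau_ms / movie.dt_ms
    if abs(n_tau - round(n_tau)) > 1e-9 or round(n_tau) < 1:
        raise ValueError("tau must be a positive multiple of the sampling interval")
    n_tau = int(round(n_tau))

    sub = movie.window(window_start_ms, window_length_ms)
    sig = sub.data.astype(np.float64)
    if sig.shape[1] <= n_tau:
        raise ValueError("window too short for the requested tau")
    v_mean = sig.mean(axis=1)
    a = sig[:, n_tau:] - v_mean[:, None]   # V(t + tau) - V_mean
    b = sig[:, :-n_tau] - v_mean[:, None]  # V(t) - V_mean
    undefined = (np.abs(a).max(axis=1) < 1e-9) & (np.abs(b).max(axis=1) < 1e-9)
    theta = np.arctan2(a, b)
    return PhaseMovie(theta=theta, dt_ms=movie.dt_ms, t0_ms=sub.t0_ms,
                      tau_ms=float(tau_ms), v_mean=v_mean, undefined=undefined,
                      domain=sub.domain or movie.domain)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _grid_loops(domain: TissueDomain):
    ny, nx = domain.grid_shape
    iy, ix = np.meshgrid(np.arange(ny - 1), np.arange(nx - 1), indexing="ij")
    a = (iy * nx + ix).ravel()          # counterclockwise plaquette loop
    return np.column_stack([a, a + 1, a + nx + 1, a + nx])


def _loops_for(domain: TissueDomain) -> np.ndarray:
    if domain.grid_shape is not None:
        return _grid_loops(domain)
    return domain.triangles


def _detect_frame(theta_f: np.ndarray, loops: np.ndarray, coords: np.ndarray,
                  good_loop: np.ndarray):
    th = theta_f[loops]                                  # (n_loops, k)
    w = _wrap(np.diff(np.column_stack([th, th[:, 0]]), axis=1)).sum(axis=1)
    hit = good_loop & (np.abs(w) > np.pi)
    idx = np.nonzero(hit)[0]
    charge = np.sign(w[idx]).astype(np.int8)
    centers = coords[loops[idx]].mean(axis=1)
    return idx, centers, charge


@dataclass
class PSRecord:
    """Per-frame PS detections plus (optionally) linked trajectories."""

    frame_times_ms: np.ndarray
    detections: list                   # per frame: (k, 4) array [x, y, z, charge]
    loop_ids: list                     # per frame: (k,) loop indices
    dt_ms: float
    domain: TissueDomain | None = None
    trajectories: list = field(default_factory=list)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(d) for d in self.detections])

    @property
    def net_charge(self) -> np.ndarray:
        return np.array([int(d[:, 3].sum()) if len(d) else 0 for d in self.detections])

    def life_spans_ms(self) -> np.ndarray:
        return np.array([tr.life_span_ms for tr in self.trajectories])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, det in enumerate(self.detections):
            for x, y, z, q in det:
                rows.append((f, self.frame_times_ms[f], x, y, z, int(q)))
        return pd.DataFrame(rows, columns=["frame", "time_ms", "x", "y", "z", "charge"])


def detect_ps(phase: PhaseMovie, frame: int):
    """Detections for one frame: (k, 4) array of [x, y, z, charge]."""
    domain = phase.domain
    if domain is None:
        raise ValueError("phase movie lacks geometry")
    loops = _loops_for(domain)
    bad_node = phase.undefined | domain.ablation_mask
    good_loop = ~np.any(bad_node[loops], axis=1)
    idx, centers, charge = _detect_frame(phase.theta[:, frame], loops,
                                         domain.coords, good_loop)
    return np.column_stack([centers, charge.astype(float)]), idx


def detect_ps_movie(phase: PhaseMovie) -> PSRecord:
    """Run PS detection on every frame of a phase movie."""
    domain = phase.domain
    if domain is None:
        raise ValueError("phase movie lacks geometry")
    loops = _loops_for(domain)
    bad_node = phase.undefined | domain.ablation_mask
    good_loop = ~np.any(bad_node[loops], axis=1)
    dets, ids = [], []
    for f in range(phase.n_frames):
        idx, centers, charge = _detect_frame(phase.theta[:, f], loops,
                                             domain.coords, good_loop)
        dets.append(np.column_stack([centers, charge.astype(float)]))
        ids.append(idx)
    times = phase.t0_ms + np.arange(phase.n_frames) * phase.dt_ms
    return PSRecord(frame_times_ms=times, detections=dets, loop_ids=ids,
                    dt_ms=phase.dt_ms, domain=domain)


def count_ps_per_ms(record: PSRecord, start_ms: float | None = None,
                    end_ms: float | None = None) -> float:
    """Mean number of simultaneous PS detections per 1-ms frame."""
    t = record.frame_times_ms
    sel = np.ones(t.size, bool)
    if start_ms is not None:
        sel &= t >= start_ms
    if end_ms is not None:
        sel &= t < end_ms
    if not np.any(sel):
        raise ValueError("empty window: no frames to count")
    counts = record.counts[sel]
    return float(counts.mean())


# ---------------------------------------------------------------------------
# trajectory linking
# ---------------------------------------------------------------------------

@dataclass
class PSTrajectory:
    frames: list                       # strictly increasing frame indices
    points: list                       # (x, y, z) per frame
    charge: int
    dt_ms: float

    @property
    def life_span_ms(self) -> float:
        return (self.frames[-1] - self.frames[0]) * self.dt_ms


def link_trajectories(record: PSRecord, max_step_cm: float = 0.2,
                      gap_frames: int = 0) -> PSRecord:
    """Greedy frame-to-frame linking of same-charge detections.

    Candidate links between the latest point of each open trajectory and
    the detections of the next frame are taken in order of increasing
    distance, subject to the ``max_step_cm`` bound; unmatched detections
    open new trajectories, trajectories unmatched for more than
    ``gap_frames`` frames close.  Fills ``record.trajectories`` (also
    returned) with life-spans (last minus first frame time).
    """
    open_tracks: list[PSTrajectory] = []
    done: list[PSTrajectory] = []
    for f, det in enumerate(record.detections):
        candidates = []
        for ti, tr in enumerate(open_tracks):
            if f - tr.frames[-1] > gap_frames + 1:
                continue
            p_last = np.asarray(tr.points[-1])
            for di in range(len(det)):
                if int(det[di, 3]) != tr.charge:
                    continue
                dist = float(np.linalg.norm(det[di, :3] - p_last))
                if dist <= max_step_cm * (f - tr.frames[-1]):
                    candidates.append((dist, ti, di))
        candidates.sort()
        used_t, used_d = set(), set()
        for dist, ti, di in candidates:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = open_tracks[ti]
            tr.frames.append(f)
            tr.points.append(tuple(det[di, :3]))
        for di in range(len(det)):
            if di not in used_d:
                open_tracks.append(PSTrajectory(
                    frames=[f], points=[tuple(det[di, :3])],
                    charge=int(det[di, 3]), dt_ms=record.dt_ms))
        still_open = []
        for tr in open_tracks:
            if f - tr.frames[-1] > gap_frames:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
    done.extend(open_tracks)
    done.sort(key=lambda tr: (tr.frames[0], tr.points[0]))
    record.trajectories = done
    return record
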