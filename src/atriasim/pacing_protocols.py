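"""Stimulation protocols and restitution analysis.

Two protocols are provided: the AF-induction ramp (24 stimuli, eight
each at cycle lengths 200, 190, 180 ms — 4,560 ms in total) delivered at
the high-septum pacing site, and a dynamic restitution ramp (cycle
length descending 500 -> 196 ms) from which APD- and CV-restitution
curves are built with 1:1 capture-failure detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_model import apd90_from_trace
from .tissue_solver import TissueDomain, VoltageMovie, activation_times, measure_cv

__all__ = [
    "StimulusProtocol",
    "RestitutionCurve",
    "ramp_pacing_protocol",
    "dynamic_restitution_protocol",
    "detect_capture_failure",
    "build_restitution_curves",
]


@dataclass
class StimulusProtocol:
    """A train of rectangular current pulses at a fixed node set.

    ``cycle_lengths_ms[i]`` is the interval following stimulus ``i``
    (the last entry closes the protocol); onsets are therefore the
    cumulative sums of the preceding cycle lengths.
    """

    site: np.ndarray
    onsets_ms: np.ndarray
    pulse_ms: float = 2.0
    amplitude: float = -40.0            # pA/pF, negative = depolarising
    cycle_lengths_ms: np.ndarray | None = None
    cl_markers: list = field(default_factory=list)   # (cycle_length, first_onset_index)

    def __post_init__(self):
        self.site = np.atleast_1d(np.asarray(self.site, np.int64))
        if self.site.size == 0:
            raise ValueError("stimulus site must be non-empty")
        self.onsets_ms = np.atleast_1d(np.asarray(self.onsets_ms, float))
        if np.any(np.diff(self.onsets_ms) <= 0):
            raise ValueError("onset times must be strictly increasing")
        if self.cycle_lengths_ms is not None:
            self.cycle_lengths_ms = np.asarray(self.cycle_lengths_ms, float)
            if self.cycle_lengths_ms.size != self.onsets_ms.size:
                raise ValueError("need one cycle length per stimulus")
            d = np.diff(self.onsets_ms)
            if not np.allclose(d, self.cycle_lengths_ms[:-1]):
                raise ValueError("onset differences must equal the declared cycle lengths")

    @property
    def n_stimuli(self) -> int:
        return self.onsets_ms.size

    @property
    def total_duration_ms(self) -> float:
        """Sum of all cycle lengths (protocol footprint)."""
        if self.cycle_lengths_ms is not None:
            return float(self.cycle_lengths_ms.sum())
        return float(self.onsets_ms[-1] - self.onsets_ms[0])

    def shifted(self, offset_ms: float) -> "StimulusProtocol":
        return StimulusProtocol(
            site=self.site, onsets_ms=self.onsets_ms + offset_ms,
            pulse_ms=self.pulse_ms, amplitude=self.amplitude,
            cycle_lengths_ms=self.cycle_lengths_ms, cl_markers=list(self.cl_markers))

    def jittered(self, sigma_ms: float, rng: np.random.Generator) -> "StimulusProtocol":
        """Onset jitter for ensemble variability (cycle-length record dropped)."""
        jit = rng.uniform(-sigma_ms, sigma_ms, self.n_stimuli)
        onsets = np.sort(self.onsets_ms + jit)
        return StimulusProtocol(site=self.site, onsets_ms=onsets,
                                pulse_ms=self.pulse_ms, amplitude=self.amplitude,
                                cl_markers=list(self.cl_markers))


@dataclass
class RestitutionCurve:
    """(cycle length, diastolic interval, value) samples from captured beats."""

    cycle_lengths_ms: np.ndarray
    diastolic_intervals_ms: np.ndarray
    values: np.ndarray                  # APD90 (ms) or CV (m/s)
    kind: str = "apd90"
    capture_failure_cl_ms: float | None = None

    def to_text(self, path) -> None:
        arr = np.column_stack([self.cycle_lengths_ms, self.diastolic_intervals_ms,
                               self.values])
        np.savetxt(path, arr, header=f"CL_ms DI_ms {self.kind}", fmt="%.4f")


def ramp_pacing_protocol(site, beats_per_cl: int = 8,
                         cycle_lengths=(200.0, 190.0, 180.0),
                         start_ms: float = 0.0, pulse_ms: float = 2.0,
                         amplitude: float = -40.0) -> StimulusProtocol:
    """AF-induction ramp: ``beats_per_cl`` stimuli at each cycle length.

    Defaults give the standard induction ramp: 24 stimuli at cycle
    lengths 200, 190 and 180 ms (eight each), total footprint 4,560 ms.
    """
    cls = np.repeat(np.asarray(cycle_lengths, float), beats_per_cl)
    onsets = start_ms + np.concatenate([[0.0], np.cumsum(cls[:-1])])
    markers = [(float(cl), int(i * beats_per_cl)) for i, cl in enumerate(cycle_lengths)]
    return StimulusProtocol(site=site, onsets_ms=onsets, pulse_ms=pulse_ms,
                            amplitude=amplitude, cycle_lengths_ms=cls,
                            cl_markers=markers)


def dynamic_restitution_protocol(site, cl_start: float = 500.0, cl_end: float = 196.0,
                                 decrement: float = 2.0, beats_per_cl: int = 10,
                                 start_ms: float = 0.0, pulse_ms: float = 2.0,
                                 amplitude: float = -40.0) -> StimulusProtocol:
    """Dynamic restitution ramp: descending cycle-length train.

    Cycle length steps from ``cl_start`` down to ``cl_end`` (inclusive
    when the decrement divides the range) by ``decrement``, with
    ``beats_per_cl`` beats at each level; per-level markers are recorded
    for curve building.
    """
    if cl_start <= cl_end:
        raise ValueError("cl_start must exceed cl_end")
    levels = np.arange(cl_start, cl_end - 1e-9, -decrement)
    levels = levels[levels >= cl_end - 1e-9]
    if levels.size == 0:
        levels = np.array([cl_start])
    cls = np.repeat(levels, beats_per_cl)
    onsets = start_ms + np.concatenate([[0.0], np.cumsum(cls[:-1])])
    markers = [(float(cl), int(i * beats_per_cl)) for i, cl in enumerate(levels)]
    return StimulusProtocol(site=site, onsets_ms=onsets, pulse_ms=pulse_ms,
                            amplitude=amplitude, cycle_lengths_ms=cls,
                            cl_markers=markers)


def _propagated_activations(movie: VoltageMovie, probe: int,
                            protocol: StimulusProtocol,
                            latency_ms: float, threshold: float):
    """Per-stimulus capture flags at a distant probe node."""
    acts = activation_times(movie, probe, threshold)
    onsets = protocol.onsets_ms
    bounds = np.append(onsets, onsets[-1] + 2 * latency_ms)
    captured = np.zeros(onsets.size, bool)
    for b in range(onsets.size):
        lo = onsets[b]
        hi = min(lo + latency_ms, bounds[b + 1] + latency_ms)
        captured[b] = np.any((acts > lo) & (acts <= hi))
    return captured


def detect_capture_failure(movie: VoltageMovie, protocol: StimulusProtocol,
                           probe: int | None = None, threshold: float = -40.0,
                           latency_ms: float = 150.0):
    """Largest cycle length at which 1:1 capture is lost (None if never).

    Capture of a stimulus means a propagated activation at ``probe``
    within ``latency_ms`` of the stimulus onset.  The probe should lie
    well away from the pacing site so local (non-propagated) capture is
    not counted; it defaults to the domain's ``probe`` landmark.
    """
    if probe is None:
        dom = movie.domain
        if dom is None or "probe" not in dom.landmarks:
            raise ValueError("no probe node given and the geometry declares none")
        probe = dom.landmarks["probe"]
    if protocol.cycle_lengths_ms is None:
        raise ValueError("protocol lacks cycle-length bookkeeping")
    captured = _propagated_activations(movie, probe, protocol, latency_ms, threshold)
    failed = ~captured
    if not np.any(failed):
        return None
    return float(np.max(protocol.cycle_lengths_ms[failed]))


def build_restitution_curves(movie: VoltageMovie, protocol: StimulusProtocol,
                             probe: int | None = None, cv_path=None,
                             threshold: float = -40.0, latency_ms: float = 150.0,
                             exclude_after_failure: bool = True):
    """APD90- and CV-restitution curves from a dynamic-ramp recording.

    One point per fully captured cycle-length level, taken from the last
    beat of the level; levels at or below the detected capture-failure
    cycle length are excluded (the post-failure response is no longer
    1:1 paced).  Returns ``(apd_curve, cv_curve)``; the CV curve is
    ``None`` when no ``cv_path`` is given.
    """
    if not protocol.cl_markers:
        raise ValueError("protocol lacks per-cycle-length markers")
    if probe is None:
        dom = movie.domain
        if dom is None or "probe" not in dom.landmarks:
            raise ValueError("no probe node given and the geometry declares none")
        probe = dom.landmarks["probe"]

    fail_cl = detect_capture_failure(movie, protocol, probe, threshold, latency_ms)
    v = movie.data[probe].astype(float)
    t = movie.times
    onsets = protocol.onsets_ms

    captured, apd, t_act, t_rec = apd90_from_trace(t, v, onsets, threshold=threshold)

    cls, dis, apds, cvs = [], [], [], []
    levels = protocol.cl_markers
    n = onsets.size
    for li, (cl, first) in enumerate(levels):
        last = (levels[li + 1][1] if li + 1 < len(levels) else n) - 1
        if exclude_after_failure and fail_cl is not None and cl <= fail_cl:
            continue
        if not captured[last] or not np.isfinite(apd[last]):
            continue
        cls.append(cl)
        di = t_act[last] - t_rec[last - 1] if last > 0 and np.isfinite(t_rec[last - 1]) else np.nan
        dis.append(di)
        apds.append(apd[last])
        if cv_path is not None:
            w0 = onsets[last]
            w1 = w0 + cl
            try:
                sub = movie.window(max(w0 - 5.0, t[0]), min(w1, t[-1]) - max(w0 - 5.0, t[0]))
                cvs.append(measure_cv(sub, cv_path, movie.domain, threshold))
            except ValueError:
                cvs.append(np.nan)

    if len(cls) < 2:
        raise ValueError("insufficient data: fewer than 2 captured cycle lengths")
    order = np.argsort(cls)[::-1]
    cls = np.asarray(cls)[order]
    dis = np.asarray(dis)[order]
    apd_curve = RestitutionCurve(cls, dis, np.asarray(apds)[order], "apd90", fail_cl)
    cv_curve = None
    if cv_path is not None:
        cv_curve = RestitutionCurve(cls, dis, np.asarray(cvs)[order], "cv", fail_cl)
    return apd_curve, cv_curve
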