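"""Phase computation, singularity detection and trajectory tracking."""

import numpy as np
import pytest

from atriasim import ps_analysis as psa
from atriasim import synthetic_geometry as sg
from atriasim.tissue_solver import VoltageMovie


def brute_force_windings(theta, ny, nx):
    """Winding number of every plaquette by explicit loop summation."""
    th = theta.reshape(ny, nx)

    def wrap(d):
        while d > np.pi:
            d -= 2 * np.pi
        while d <= -np.pi:
            d += 2 * np.pi
        return d

    out = np.zeros((ny - 1, nx - 1), int)
    for i in range(ny - 1):
        for j in range(nx - 1):
            loop = [th[i, j], th[i, j + 1], th[i + 1, j + 1], th[i + 1, j]]
            w = sum(wrap(b - a) for a, b in zip(loop, loop[1:] + loop[:1]))
            out[i, j] = int(round(w / (2 * np.pi)))
    return out


class TestComputePhase:
    def test_sinusoid_advances_through_2pi(self, small_sheet):
        f = 5.0
        t = np.arange(1000) * 1e-3
        v = np.sin(2 * np.pi * f * t)
        movie = VoltageMovie(np.tile(v, (small_sheet.n_nodes, 1)).astype(np.float32),
                             1.0, domain=small_sheet)
        tau = 1000.0 / f / 4.0   # quarter period
        ph = psa.compute_phase(movie, tau_ms=tau)
        th = np.unwrap(ph.theta[0])
        slope = np.polyfit(np.arange(th.size), th, 1)[0]
        # phase winds through 2 pi once per period (sign is the
        # embedding handedness convention)
        assert abs(slope) * 1000 == pytest.approx(2 * np.pi * f, rel=0.02)

    def test_constant_node_flagged_undefined(self, small_sheet):
        data = np.random.default_rng(0).normal(-80, 5, (small_sheet.n_nodes, 500))
        data[7] = -80.0
        movie = VoltageMovie(data.astype(np.float32), 1.0, domain=small_sheet)
        ph = psa.compute_phase(movie, tau_ms=10.0)
        assert ph.undefined[7]
        assert not ph.undefined[8]

    def test_non_multiple_tau_rejected(self, small_sheet):
        movie = VoltageMovie(np.zeros((small_sheet.n_nodes, 100), np.float32),
                             1.0, domain=small_sheet)
        with pytest.raises(ValueError):
            psa.compute_phase(movie, tau_ms=0.5)
        with pytest.raises(ValueError):
            psa.compute_phase(movie, tau_ms=0.0)


class TestDetection:
    def test_single_spiral_one_positive_ps(self, spiral_movie):
        movie, gt = spiral_movie
        ph = psa.compute_phase(movie, tau_ms=42.0)
        rec = psa.detect_ps_movie(ph)
        assert np.all(rec.counts == 1)
        for det in rec.detections:
            assert det[0, 3] == 1.0
        # detected location stays near the known core
        xc, yc = gt.ps_tracks[0][1], gt.ps_tracks[0][2]
        for det in rec.detections[:50]:
            assert abs(det[0, 0] - xc) < 0.08 and abs(det[0, 1] - yc) < 0.08

    def test_planar_ramp_no_detection(self, planar_movie):
        movie, _ = planar_movie
        ph = psa.compute_phase(movie, tau_ms=42.0, window_length_ms=500.0)
        rec = psa.detect_ps_movie(ph)
        assert rec.counts.max() == 0

    def test_dual_spiral_net_zero(self, dual_spiral_movie):
        movie, gt = dual_spiral_movie
        ph = psa.compute_phase(movie, tau_ms=42.0)
        rec = psa.detect_ps_movie(ph)
        assert np.all(rec.counts == 2)
        assert np.all(rec.net_charge == 0)

    def test_matches_brute_force_windings(self, small_sheet, rng):
        """Detector equals explicit winding sums on smooth random fields."""
        ny, nx = small_sheet.grid_shape
        x = small_sheet.coords[:, 0]
        y = small_sheet.coords[:, 1]
        for trial in range(3):
            xc, yc = rng.uniform(0.2, 0.8, 2) * x.max()
            sgn = rng.choice([-1, 1])
            theta = sgn * np.arctan2(y - yc, x - xc) + 0.3 * np.sin(
                2 * np.pi * x / x.max())
            theta = np.angle(np.exp(1j * theta))
            ph = psa.PhaseMovie(theta=theta[:, None], dt_ms=1.0, t0_ms=0.0,
                                tau_ms=1.0, v_mean=np.zeros(theta.size),
                                undefined=np.zeros(theta.size, bool),
                                domain=small_sheet)
            det, _ = psa.detect_ps(ph, 0)
            bf = brute_force_windings(theta, ny, nx)
            assert len(det) == np.count_nonzero(bf)
            assert int(det[:, 3].sum()) == bf.sum()

    def test_charge_conservation_per_frame(self, dual_spiral_movie):
        movie, _ = dual_spiral_movie
        ph = psa.compute_phase(movie, tau_ms=42.0)
        rec = psa.detect_ps_movie(ph)
        assert np.all(np.abs(np.diff(rec.net_charge)) <= 2)


class TestWrapProperty:
    from hypothesis import given, settings as hsettings
    from hypothesis import strategies as st_

    @given(d=st_.floats(-50.0, 50.0))
    @hsettings(max_examples=100, deadline=None, derandomize=True)
    def test_wrap_range_and_congruence(self, d):
        w = float(psa._wrap(np.array(d)))
        assert -np.pi < w <= np.pi + 1e-12
        # wrapped value differs from the input by a multiple of 2 pi
        k = (d - w) / (2 * np.pi)
        assert abs(k - round(k)) < 1e-9


class TestCounting:
    def _record(self, counts):
        dets = [np.zeros((c, 4)) for c in counts]
        return psa.PSRecord(frame_times_ms=np.arange(len(counts), dtype=float),
                            detections=dets, loop_ids=[None] * len(counts),
                            dt_ms=1.0)

    def test_mean_count(self):
        rec = self._record([2] * 50 + [0] * 50)
        assert psa.count_ps_per_ms(rec) == 1.0

    def test_stationary_spiral_unity(self, spiral_movie):
        movie, _ = spiral_movie
        ph = psa.compute_phase(movie, tau_ms=42.0)
        assert psa.count_ps_per_ms(psa.detect_ps_movie(ph)) == 1.0

    def test_empty_window_rejected(self):
        rec = self._record([1, 1])
        with pytest.raises(ValueError):
            psa.count_ps_per_ms(rec, start_ms=100.0)


def _det(x, y, q):
    return np.array([[x, y, 0.0, q]])


class TestLinking:
    def test_single_stationary_track(self):
        dets = [_det(0.5, 0.5, 1) for _ in range(100)]
        rec = psa.PSRecord(np.arange(100.0), dets, [None] * 100, 1.0)
        psa.link_trajectories(rec)
        assert len(rec.trajectories) == 1
        assert rec.trajectories[0].life_span_ms == 99.0

    def test_two_distant_ps_never_merge(self):
        dets = [np.vstack([_det(0.1, 0.1, 1), _det(0.9, 0.9, 1)]) for _ in range(20)]
        rec = psa.PSRecord(np.arange(20.0), dets, [None] * 20, 1.0)
        psa.link_trajectories(rec, max_step_cm=0.2)
        assert len(rec.trajectories) == 2
        for tr in rec.trajectories:
            assert len(tr.frames) == 20

    def test_jump_beyond_bound_splits(self):
        dets = [_det(0.1, 0.1, 1)] * 10 + [_det(0.9, 0.9, 1)] * 10
        rec = psa.PSRecord(np.arange(20.0), dets, [None] * 20, 1.0)
        psa.link_trajectories(rec, max_step_cm=0.2)
        assert len(rec.trajectories) == 2
        assert sorted(tr.life_span_ms for tr in rec.trajectories) == [9.0, 9.0]

    def test_opposite_charges_not_linked(self):
        dets = [_det(0.5, 0.5, 1), _det(0.5, 0.5, -1)] * 5
        rec = psa.PSRecord(np.arange(10.0), dets, [None] * 10, 1.0)
        psa.link_trajectories(rec, max_step_cm=0.2)
        # alternating charges can never chain into one trajectory
        assert all(len(tr.frames) == 1 for tr in rec.trajectories)

    def test_greedy_matches_exhaustive_on_jump_sequence(self):
        """Greedy assignment equals the optimal one for well-separated tracks."""
        rng = np.random.default_rng(7)
        base = np.array([[0.2, 0.2], [0.8, 0.8]])
        dets, truth = [], {0: [], 1: []}
        for f in range(30):
            base += rng.normal(0, 0.01, base.shape)
            dets.append(np.column_stack([base, np.zeros(2), np.ones(2)]))
            truth[0].append(tuple(base[0]))
            truth[1].append(tuple(base[1]))
        rec = psa.PSRecord(np.arange(30.0), dets, [None] * 30, 1.0)
        psa.link_trajectories(rec, max_step_cm=0.1)
        assert len(rec.trajectories) == 2
        assert all(len(tr.frames) == 30 for tr in rec.trajectories)
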