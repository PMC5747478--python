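"""Diffusion operator, monodomain stepping, CV measurement/calibration."""

import numpy as np
import pytest

from atriasim import cell_model as cm
from atriasim import synthetic_geometry as sg
from atriasim import tissue_solver as ts
from atriasim.pacing_protocols import StimulusProtocol


@pytest.fixture(scope="module")
def remodeled():
    return cm.apply_af_remodeling(cm.IonicParameters())


def _edge_protocol(domain, n_beats=1, cl=500.0, amplitude=-40.0):
    ny, nx = domain.grid_shape
    idx = np.arange(domain.n_nodes).reshape(ny, nx)
    ncol = max(2, int(round(0.06 / domain.spacing)))
    return StimulusProtocol(site=idx[:, :ncol].ravel(),
                            onsets_ms=np.arange(n_beats) * cl,
                            pulse_ms=2.0, amplitude=amplitude)


class TestDiffusionOperator:
    def test_constant_field_maps_to_zero(self):
        dom = sg.make_strip(length_cm=1.0, spacing=0.05, D=0.001)
        L, _, _ = ts.assemble_diffusion_operator(dom)
        assert np.abs(L @ np.ones(dom.n_nodes)).max() < 1e-12

    def test_quadratic_field_interior_laplacian(self):
        dom = sg.make_strip(length_cm=1.0, spacing=0.05, D=0.001)
        L, _, _ = ts.assemble_diffusion_operator(dom)
        x = dom.coords[:, 0]
        lap = (L @ x ** 2) / 0.001
        ny, nx = dom.grid_shape
        inner = (np.arange(dom.n_nodes).reshape(ny, nx))[1:-1, 1:-1].ravel()
        assert np.allclose(lap[inner], 2.0, atol=1e-8)

    def test_all_ablated_zero_operator(self):
        dom = sg.make_strip(length_cm=0.5, spacing=0.05, D=0.001)
        dom.ablation_mask[:] = True
        L, _, _ = ts.assemble_diffusion_operator(dom)
        assert L.nnz == 0

    def test_ablated_rows_symmetrically_removed(self):
        dom = sg.make_strip(length_cm=1.0, spacing=0.05, D=0.001)
        lesion = np.arange(40, 50)
        dom.ablation_mask[lesion] = True
        L, _, _ = ts.assemble_diffusion_operator(dom)
        dense = np.abs(L.toarray())
        assert dense[lesion].max() == 0.0          # no flux out of lesion
        assert dense[:, lesion].max() == 0.0       # no flux into lesion
        assert np.abs(L @ np.ones(dom.n_nodes)).max() < 1e-12

    def test_degenerate_triangle_reported(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]], float)
        tri = np.array([[0, 1, 2], [0, 1, 3]])
        dom = ts.TissueDomain(coords=coords, triangles=tri, D=np.full(4, 1e-3))
        with pytest.raises(ValueError, match="degenerate"):
            ts.assemble_diffusion_operator(dom)

    def test_mass_weighted_conservation_diffusion_only(self, rng):
        """With the reaction zeroed, total (mass-weighted) V is conserved."""
        dom = sg.make_sheet(n=24, spacing=0.05, D=0.002, anisotropy_ratio=2.0)
        L, mass, dt_stable = ts.assemble_diffusion_operator(dom)
        V = rng.normal(-60, 20, dom.n_nodes)
        total0 = float(mass @ V)
        dt = 0.5 * dt_stable
        for _ in range(500):
            V = V + dt * (L @ V)
        assert float(mass @ V) == pytest.approx(total0, rel=1e-9)
        # and diffusion flattens the field toward its mean
        assert V.std() < 0.5 * rng.normal(-60, 20, dom.n_nodes).std()


class TestStepping:
    def test_quiescent_tissue_stays_at_rest(self):
        # non-remodeled cells start at their published steady state
        dom = sg.make_sheet(n=24, spacing=0.05, D=0.002)
        movie, _ = ts.simulate(dom, cm.IonicParameters(), 100.0)
        drift = np.abs(movie.data[:, -1] - movie.data[:, 0]).max()
        assert drift < 0.01

    def test_subthreshold_point_source_no_far_field(self, remodeled):
        dom = sg.make_sheet(n=30, spacing=0.05, D=0.002)
        centre = dom.n_nodes // 2
        proto = StimulusProtocol(site=[centre], onsets_ms=[0.0], pulse_ms=2.0,
                                 amplitude=-40.0)
        movie, _ = ts.simulate(dom, remodeled, 80.0, [proto])
        assert movie.data[5, :].max() < -70.0      # far corner silent

    def test_activation_times_increase_with_distance(self, remodeled):
        dom = sg.make_strip(length_cm=2.0, spacing=0.03, D=0.00154)
        movie, _ = ts.simulate(dom, remodeled, 120.0, [_edge_protocol(dom)])
        ny, nx = dom.grid_shape
        mid = ny // 2
        t_act = []
        for frac in (0.3, 0.5, 0.7, 0.9):
            node = mid * nx + int(frac * (nx - 1))
            acts = ts.activation_times(movie, node)
            assert acts.size == 1
            t_act.append(acts[0])
        assert np.all(np.diff(t_act) > 0)

    def test_blowup_detection(self, remodeled):
        dom = sg.make_sheet(n=20, spacing=0.05, D=0.002)
        solver = ts.MonodomainSolver(dom, remodeled)
        solver.states[10, 0] = np.nan
        with pytest.raises(FloatingPointError, match="node"):
            solver.run(5.0)

    def test_reproducibility_same_seed(self, remodeled):
        def run(seed):
            dom = sg.make_sheet(n=20, spacing=0.05, D=0.002)
            proto = StimulusProtocol(site=np.arange(40), onsets_ms=[1.0],
                                     pulse_ms=2.0, amplitude=-40.0)
            movie, _ = ts.simulate(dom, remodeled, 50.0, [proto],
                                   noise_sigma=0.1, seed=seed)
            return movie.data
        a, b, c = run(3), run(3), run(4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestMeasureCV:
    def _constructed_movie(self, domain, speed_m_s):
        x = domain.coords[:, 0]
        t_act = np.round(x / (speed_m_s * 0.1), 6)  # ms (cm / (cm/ms))
        frames = np.arange(0, t_act.max() + 100.0, 1.0)
        data = np.where(frames[None, :] >= t_act[:, None] + 1.0, 0.0, -80.0)
        return ts.VoltageMovie(data.astype(np.float32), 1.0, domain=domain)

    def test_constructed_movie_half_meter_per_second(self):
        dom = sg.make_strip(length_cm=2.0, spacing=0.05, D=0.001)
        movie = self._constructed_movie(dom, 0.5)
        ny, nx = dom.grid_shape
        path = np.arange(nx // 4, 3 * nx // 4)
        assert ts.measure_cv(movie, path, dom) == pytest.approx(0.5, rel=0.02)

    def test_zero_length_path_rejected(self):
        dom = sg.make_strip(length_cm=1.0, spacing=0.05, D=0.001)
        movie = self._constructed_movie(dom, 0.5)
        with pytest.raises(ValueError, match="path"):
            ts.measure_cv(movie, [3, 3], dom)
        with pytest.raises(ValueError, match="zero-length"):
            ts.measure_cv(movie, [3, 3, 3], dom)

    def test_never_activating_endpoint(self):
        dom = sg.make_strip(length_cm=1.0, spacing=0.05, D=0.001)
        data = np.full((dom.n_nodes, 200), -80.0, np.float32)
        movie = ts.VoltageMovie(data, 1.0, domain=dom)
        with pytest.raises(ValueError, match="no capture"):
            ts.measure_cv(movie, np.arange(5), dom)

    def test_anisotropy_ratio_two(self, remodeled):
        """Fiber-parallel vs fiber-transverse planar CV = 2 +- 5%.

        Two thin strips with identical tensors (conduction ratio 1:2,
        eigenvalue ratio 1:4): fibers along the strip vs across it.
        Fine spacing so the transverse wave is spatially resolved.
        """
        h, d_long = 0.0075, 0.00154
        st = ts.SolverSettings(dt_min=0.005, dt_max=0.005,
                               dvdt_threshold=np.inf)
        cvs = {}
        for name, angle in (("long", 0.0), ("trans", np.pi / 2)):
            dom = sg.make_strip(length_cm=1.6, spacing=h, D=d_long,
                                fiber_angle=angle, anisotropy_ratio=2.0)
            movie, _ = ts.simulate(dom, remodeled, 180.0,
                                   [_edge_protocol(dom)], settings=st)
            ny, nx = dom.grid_shape
            mid = ny // 2
            path = mid * nx + np.arange(int(0.3 / h), int(1.3 / h))
            cvs[name] = ts.measure_cv(movie, path, dom)
        assert cvs["long"] / cvs["trans"] == pytest.approx(2.0, rel=0.05)


class TestCalibration:
    def test_round_trip_identity(self, remodeled):
        """Calibrating to a measured CV returns the originating D."""
        d0 = 0.0008
        # measure CV at d0 using the calibration's own forward model
        d1, cv1 = ts.calibrate_diffusion(0.4, spacing=0.05, tol=0.02)
        d2, cv2 = ts.calibrate_diffusion(cv1, spacing=0.05, tol=0.02)
        assert d2 == pytest.approx(d1, rel=0.1)
        assert cv2 == pytest.approx(cv1, rel=0.02)

    def test_monotone_in_target(self):
        d_low, _ = ts.calibrate_diffusion(0.3, spacing=0.05)
        d_high, _ = ts.calibrate_diffusion(0.6, spacing=0.05)
        assert d_high > d_low

    def test_sqrt_d_scaling(self, sqrt_d_cvs):
        """CV(alpha D)/CV(D) = sqrt(alpha) within 5% at fine resolution."""
        base = sqrt_d_cvs[1.0]
        assert sqrt_d_cvs[0.25] / base == pytest.approx(0.5, rel=0.05)
        assert sqrt_d_cvs[4.0] / base == pytest.approx(2.0, rel=0.05)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            ts.calibrate_diffusion(2.5)


class TestEmbeddingInvariance:
    def test_rotated_strip_same_cv(self, remodeled):
        """A strip rotated out of plane conducts identically (FEM is
        coordinate-free), standing in for grid-vs-mesh consistency."""
        def cv_for(rotate):
            dom = sg.make_strip(length_cm=2.5, spacing=0.03, D=0.00154)
            if rotate:
                ang = np.deg2rad(35.0)
                R = np.array([[np.cos(ang), 0, np.sin(ang)],
                              [0, 1, 0],
                              [-np.sin(ang), 0, np.cos(ang)]])
                dom.coords = dom.coords @ R.T
            movie, _ = ts.simulate(dom, remodeled, 150.0, [_edge_protocol(dom)])
            ny, nx = dom.grid_shape
            mid = ny // 2
            path = mid * nx + np.arange(int(0.5 / 0.03), int(2.0 / 0.03))
            return ts.measure_cv(movie, path, dom)
        assert cv_for(True) == pytest.approx(cv_for(False), rel=1e-6)
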