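import numpy as np
import pytest

from atriasim import synthetic_geometry as sg


@pytest.fixture(scope="session")
def small_sheet():
    """Isotropic 40x40 sheet used by the analytic-movie fixtures."""
    return sg.make_sheet(n=40, spacing=0.025, D=0.001, anisotropy_ratio=1.0)


@pytest.fixture(scope="session")
def spiral_movie(small_sheet):
    return sg.make_analytic_movie("spiral", small_sheet, duration_ms=600.0,
                                  freq_hz=6.0)


@pytest.fixture(scope="session")
def dual_spiral_movie(small_sheet):
    return sg.make_analytic_movie("dual-spiral", small_sheet, duration_ms=400.0,
                                  freq_hz=6.0)


@pytest.fixture(scope="session")
def planar_movie(small_sheet):
    return sg.make_analytic_movie("planar", small_sheet, duration_ms=6000.0,
                                  freq_hz=6.0, cv_m_s=0.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def sqrt_d_cvs():
    """Planar CV at D, D/4 and 4D on a finely resolved strip (computed once).

    75 um spacing so the continuum sqrt(D) scaling law is spatially
    resolved at the smallest diffusivity.
    """
    import atriasim.cell_model as cm
    import atriasim.tissue_solver as ts
    from atriasim.pacing_protocols import StimulusProtocol

    remodeled = cm.apply_af_remodeling(cm.IonicParameters())
    h, d0 = 0.0075, 0.00154

    def cv_of(d, dt):
        dom = sg.make_strip(length_cm=1.6, spacing=h, D=d)
        ny, nx = dom.grid_shape
        idx = np.arange(dom.n_nodes).reshape(ny, nx)
        proto = StimulusProtocol(site=idx[:, :8].ravel(), onsets_ms=[0.0],
                                 pulse_ms=2.0, amplitude=-40.0)
        st = ts.SolverSettings(dt_min=dt, dt_max=dt, dvdt_threshold=np.inf)
        movie, _ = ts.simulate(dom, remodeled, 150.0, [proto], settings=st)
        mid = ny // 2
        path = mid * nx + np.arange(int(0.3 / h), int(1.3 / h))
        return ts.measure_cv(movie, path, dom)

    return {1.0: cv_of(d0, 0.005),
            0.25: cv_of(0.25 * d0, 0.005),
            4.0: cv_of(4.0 * d0, 0.002)}
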