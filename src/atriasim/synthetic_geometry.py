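"""Generators for test geometries and analytic voltage movies.

Three families of inputs:

* 2D anisotropic sheets (triangulated structured grids) matching the
  planar experiment configuration: 0.25 mm spacing, fiber anisotropy
  with a longitudinal:transverse conduction ratio of 2, ten labelled
  segments, and landmark nodes for pacing and CV measurement;
* a closed left-atrium surrogate surface (sphere-like triangle mesh
  with four pulmonary-vein ostia and a mitral-annulus hole, ~300 um
  edges, ten labelled regions) standing in for patient CT anatomy;
* analytic voltage movies (planar waves, pulse trains, spirals) whose
  dominant frequency and phase-singularity content are known exactly,
  used as ground truth for the analysis modules.

All generators are deterministic given their arguments (and seed where
one applies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tissue_solver import TissueDomain, VoltageMovie

__all__ = [
    "LA_SEGMENT_NAMES",
    "make_sheet",
    "make_strip",
    "make_la_surrogate",
    "make_analytic_movie",
    "AnalyticGroundTruth",
    "save_ply",
]

# the ten left-atrial segments used for regional DF statistics
LA_SEGMENT_NAMES = (
    "septum",
    "anterior_wall",
    "la_appendage",
    "peri_mitral",
    "posterior_inferior_wall",
    "posterior_wall",
    "left_upper_pv",
    "left_lower_pv",
    "right_upper_pv",
    "right_lower_pv",
)


# ---------------------------------------------------------------------------
# structured sheets
# ---------------------------------------------------------------------------

def _triangulate_grid(ny: int, nx: int) -> np.ndarray:
    """Triangulate an ny x nx node grid (uniform diagonal split).

    A uniform split keeps the lumped mass constant at h^2 on interior
    nodes and reproduces the exact 5-point stencil for axis-aligned
    diffusion tensors (diagonal edges carry zero cotangent weight).
    """
    iy, ix = np.meshgrid(np.arange(ny - 1), np.arange(nx - 1), indexing="ij")
    a = (iy * nx + ix).ravel()
    b = a + 1
    c = a + nx
    d = c + 1
    return np.concatenate([np.column_stack([a, b, d]), np.column_stack([a, d, c])])


def _sheet_regions(ny: int, nx: int) -> np.ndarray:
    """Ten segments: 3x3 blocks with the centre block split in two."""
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    by = np.minimum(iy * 3 // ny, 2)
    bx = np.minimum(ix * 3 // nx, 2)
    lab = (by * 3 + bx + 1).astype(np.int32)       # 1..9
    centre = lab == 5
    right_half = ix >= nx // 2
    lab[centre & right_half] = 10
    return lab.ravel()


def make_sheet(n: int = 200, spacing: float = 0.025, D: float = 0.001,
               fiber_angle: float = 0.0, anisotropy_ratio: float = 2.0) -> TissueDomain:
    """Square n x n sheet (spacing in cm) with uniform fiber direction.

    The fast (longitudinal) axis makes ``fiber_angle`` radians with x;
    ``anisotropy_ratio`` is the longitudinal:transverse CV ratio.
    Landmarks: ``pacing_site`` near the top edge centre (high-septum
    analogue), ``cv_path_start``/``cv_path_end`` on the horizontal
    midline, and ``probe`` at three quarters of the diagonal.
    """
    if n < 20:
        raise ValueError("sheet must be at least 20 x 20 nodes")
    ny = nx = int(n)
    y, x = np.meshgrid(np.arange(ny) * spacing, np.arange(nx) * spacing, indexing="ij")
    coords = np.column_stack([x.ravel(), y.ravel(), np.zeros(nx * ny)])
    tri = _triangulate_grid(ny, nx)
    labels = _sheet_regions(ny, nx)
    landmarks = {
        "pacing_site": (ny - 3) * nx + nx // 2,
        "cv_path_start": (ny // 2) * nx + nx // 8,
        "cv_path_end": (ny // 2) * nx + (7 * nx) // 8,
        "probe": (3 * ny // 4) * nx + 3 * nx // 4,
    }
    return TissueDomain(
        coords=coords, triangles=tri, D=np.full(nx * ny, float(D)),
        anisotropy_ratio=float(anisotropy_ratio),
        fiber_angle=np.full(nx * ny, float(fiber_angle)),
        region_labels=labels, region_names=LA_SEGMENT_NAMES,
        landmarks=landmarks, grid_shape=(ny, nx), spacing=float(spacing))


def make_strip(length_cm: float = 4.0, spacing: float = 0.03, D: float = 0.00154,
               width_nodes: int = 5, fiber_angle: float | None = None,
               anisotropy_ratio: float = 1.0) -> TissueDomain:
    """Thin homogeneous strip for planar-wave CV measurement.

    Isotropic by default; a ``fiber_angle`` (radians from +x) with an
    ``anisotropy_ratio`` > 1 yields an anisotropic tensor, e.g. angle
    pi/2 makes propagation along the strip transverse to the fibers.
    """
    nx = int(round(length_cm / spacing)) + 1
    ny = int(width_nodes)
    y, x = np.meshgrid(np.arange(ny) * spacing, np.arange(nx) * spacing, indexing="ij")
    coords = np.column_stack([x.ravel(), y.ravel(), np.zeros(nx * ny)])
    tri = _triangulate_grid(ny, nx)
    mid = ny // 2
    landmarks = {
        "pace_edge": 0,
        "cv_path_start": mid * nx + int(round(1.0 / spacing)),
        "cv_path_end": mid * nx + min(nx - 1, int(round(3.0 / spacing))),
    }
    return TissueDomain(
        coords=coords, triangles=tri, D=np.full(nx * ny, float(D)),
        anisotropy_ratio=float(anisotropy_ratio),
        fiber_angle=(None if fiber_angle is None
                     else np.full(nx * ny, float(fiber_angle))),
        region_labels=np.ones(nx * ny, np.int32),
        landmarks=landmarks, grid_shape=(ny, nx), spacing=float(spacing))


# ---------------------------------------------------------------------------
# left-atrium surrogate surface
# ---------------------------------------------------------------------------

# hole directions (unit vectors) and angular radii (radians): four PV
# ostia on the posterior-superior aspect, mitral annulus inferior
_DEFAULT_HOLES = (
    ("left_upper_pv_ostium", (-0.55, 0.55, 0.63), 0.16),
    ("left_lower_pv_ostium", (-0.62, 0.60, -0.05), 0.16),
    ("right_upper_pv_ostium", (0.55, 0.55, 0.63), 0.16),
    ("right_lower_pv_ostium", (0.62, 0.60, -0.05), 0.16),
    ("mitral_annulus", (0.0, -1.0, 0.0), 0.42),
)

_REGION_SEEDS = {
    "septum": (0.9, 0.1, 0.4),
    "anterior_wall": (0.0, -0.3, 0.95),
    "la_appendage": (-0.95, -0.2, 0.25),
    "peri_mitral": (0.0, -0.85, -0.5),
    "posterior_inferior_wall": (0.0, 0.35, -0.94),
    "posterior_wall": (0.0, 0.95, 0.2),
    "left_upper_pv": (-0.55, 0.45, 0.7),
    "left_lower_pv": (-0.7, 0.6, -0.2),
    "right_upper_pv": (0.55, 0.45, 0.7),
    "right_lower_pv": (0.7, 0.6, -0.2),
}


def make_la_surrogate(radius: float = 1.65, target_edge: float = 0.03,
                      D: float = 0.00154, holes=_DEFAULT_HOLES) -> TissueDomain:
    """Closed sphere-like LA surrogate with PV/mitral holes (cm units).

    The icosphere subdivision level is chosen so the mean edge length is
    as close as possible to ``target_edge`` (the default radius puts the
    level-6 mean edge at ~300 um).  Region labels assign each node to
    the nearest of ten segment seed directions; landmarks mark the
    high-septum pacing analogue and the appendage tip (the CV path of
    the atrial model).
    """
    import trimesh

    subdiv, best = 4, np.inf
    for s in range(3, 8):
        # mean edge of a subdivided icosphere from its triangle budget:
        # 20 * 4^s near-equilateral triangles tiling the sphere
        e = np.sqrt(16.0 * np.pi * radius ** 2 / (np.sqrt(3.0) * 20 * 4 ** s))
        if abs(e - target_edge) < best:
            best, subdiv = abs(e - target_edge), s
    mesh = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
    verts = np.asarray(mesh.vertices)
    faces = np.asarray(mesh.faces)

    unit = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    drop = np.zeros(len(verts), bool)
    for _name, direction, ang in holes:
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        drop |= unit @ d > np.cos(ang)
    keep_face = ~np.any(drop[faces], axis=1)
    faces = faces[keep_face]
    used = np.unique(faces)
    remap = -np.ones(len(verts), np.int64)
    remap[used] = np.arange(used.size)
    verts = verts[used]
    faces = remap[faces]
    unit = unit[used]

    seeds = np.array([_REGION_SEEDS[name] for name in LA_SEGMENT_NAMES])
    seeds = seeds / np.linalg.norm(seeds, axis=1, keepdims=True)
    labels = (np.argmax(unit @ seeds.T, axis=1) + 1).astype(np.int32)

    septum_dir = np.array(_REGION_SEEDS["septum"], float)
    laa_dir = np.array(_REGION_SEEDS["la_appendage"], float)
    high_septum = int(np.argmax(unit @ (septum_dir / np.linalg.norm(septum_dir))))
    laa_tip = int(np.argmax(unit @ (laa_dir / np.linalg.norm(laa_dir))))

    return TissueDomain(
        coords=verts, triangles=faces, D=np.full(len(verts), float(D)),
        anisotropy_ratio=1.0, region_labels=labels,
        region_names=LA_SEGMENT_NAMES,
        landmarks={"high_septum": high_septum, "laa_tip": laa_tip})


def boundary_loop_count(domain: TissueDomain) -> int:
    """Number of closed boundary loops (edges on exactly one triangle)."""
    tri = domain.triangles
    edges = np.sort(np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    bedges = uniq[counts == 1]
    if len(bedges) == 0:
        return 0
    # walk loops through the boundary adjacency
    nbr: dict[int, list[int]] = {}
    for a, b in bedges:
        nbr.setdefault(int(a), []).append(int(b))
        nbr.setdefault(int(b), []).append(int(a))
    seen = set()
    loops = 0
    for start in nbr:
        if start in seen:
            continue
        loops += 1
        stack = [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(nbr[v])
    return loops


def save_ply(domain: TissueDomain, path) -> None:
    """Write the surface as ASCII PLY."""
    import trimesh

    mesh = trimesh.Trimesh(vertices=domain.coords, faces=domain.triangles,
                           process=False)
    mesh.export(path, file_type="ply", encoding="ascii")


# ---------------------------------------------------------------------------
# analytic movies with ground truth
# ---------------------------------------------------------------------------

@dataclass
class AnalyticGroundTruth:
    """Known content of an analytic movie.

    ``df_hz``: true per-node dominant frequency; ``ps_tracks``: list of
    (frame_index, x, y, charge) tuples, one entry per frame per true
    phase singularity.
    """

    df_hz: np.ndarray
    ps_tracks: list = field(default_factory=list)

    @property
    def net_charge_per_frame(self) -> dict:
        net: dict[int, int] = {}
        for fr, _x, _y, q in self.ps_tracks:
            net[fr] = net.get(fr, 0) + q
        return net


def make_analytic_movie(kind: str, domain: TissueDomain | None = None,
                        duration_ms: float = 2000.0, dt_ms: float = 1.0,
                        freq_hz: float = 6.0, period_ms: float | None = None,
                        apd_ms: float = 100.0, cv_m_s: float = 0.5,
                        core=(0.5, 0.5), core2=(0.25, 0.5),
                        drift_cm_per_s: float = 0.0,
                        amplitude: float = 50.0, v_rest: float = -80.0):
    """Build an analytic :class:`VoltageMovie` plus its ground truth.

    ``kind``:
      * ``"pulse-train"`` — every node repeats a rectangular action
        potential of duration ``apd_ms`` with period ``period_ms``
        (or 1000/freq_hz); no propagation delay.
      * ``"planar"`` — sinusoidal plane wave travelling along +x at
        ``cv_m_s``; smooth phase ramp, no singularity.
      * ``"spiral"`` — single rotor: V = A cos(atan2(y-yc, x-xc) - w t),
        one +1 phase singularity at the (optionally drifting) core.
      * ``"dual-spiral"`` — two opposite-chirality rotors (net charge 0)
        at ``core`` and ``core2``.

    ``core``/``core2`` are fractions of the domain extent.  Returns
    ``(movie, AnalyticGroundTruth)``.
    """
    if domain is None:
        from . import synthetic_geometry as _self  # noqa: F401
        domain = make_sheet(n=40, spacing=0.025, anisotropy_ratio=1.0)
    x = domain.coords[:, 0]
    y = domain.coords[:, 1]
    n_frames = int(round(duration_ms / dt_ms))
    t = np.arange(n_frames) * dt_ms
    if period_ms is None:
        period_ms = 1000.0 / freq_hz
    f_true = 1000.0 / period_ms
    omega = 2.0 * np.pi * f_true / 1000.0          # rad/ms

    extent_x = x.max() - x.min()
    extent_y = y.max() - y.min()

    if kind == "pulse-train":
        phase = np.mod(t, period_ms)
        v_t = np.where(phase < apd_ms, v_rest + amplitude + 0.0, v_rest)
        data = np.broadcast_to(v_t, (domain.n_nodes, n_frames)).astype(np.float32)
        gt = AnalyticGroundTruth(df_hz=np.full(domain.n_nodes, f_true))
        return VoltageMovie(data.copy(), dt_ms, domain=domain), gt

    if kind == "planar":
        k_rad = omega / (cv_m_s * 0.1)             # rad/cm; cv in cm/ms = m/s * 0.1
        theta = omega * t[None, :] - k_rad * (x - x.min())[:, None]
        data = (v_rest + amplitude * (1.0 + np.cos(theta)) / 1.0).astype(np.float32)
        gt = AnalyticGroundTruth(df_hz=np.full(domain.n_nodes, f_true))
        return VoltageMovie(data, dt_ms, domain=domain), gt

    if kind in ("spiral", "dual-spiral"):
        xc = x.min() + core[0] * extent_x
        yc = y.min() + core[1] * extent_y
        tracks = []
        if kind == "spiral":
            drift = drift_cm_per_s / 1000.0        # cm per ms
            xcs = xc + drift * t
            ycs = np.full_like(t, yc)
            ang = np.arctan2(y[:, None] - ycs[None, :], x[:, None] - xcs[None, :])
            theta = ang - omega * t[None, :]
            for fr in range(n_frames):
                tracks.append((fr, float(xcs[fr]), float(ycs[fr]), 1))
        else:
            xc2 = x.min() + core2[0] * extent_x
            yc2 = y.min() + core2[1] * extent_y
            ang1 = np.arctan2(y - yc, x - xc)
            ang2 = np.arctan2(y - yc2, x - xc2)
            theta = (ang1 - ang2)[:, None] - omega * t[None, :]
            for fr in range(n_frames):
                tracks.append((fr, float(xc), float(yc), 1))
                tracks.append((fr, float(xc2), float(yc2), -1))
        data = (v_rest + amplitude * (1.0 + np.cos(theta))).astype(np.float32)
        gt = AnalyticGroundTruth(df_hz=np.full(domain.n_nodes, f_true), ps_tracks=tracks)
        return VoltageMovie(data, dt_ms, domain=domain), gt

    raise ValueError(f"unknown analytic movie kind: {kind!r}")
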