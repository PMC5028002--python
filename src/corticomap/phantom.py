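"""Synthetic cortical phantom with known ground truth.

The phantom is a single folded cortical sheet: a generalized cylinder
``z = A * sin(2*pi*x / wavelength)`` extruded along ``y``, thickened into
a ribbon of constant (vertical) cortical thickness.  Because the sheet is
developable, geodesic distance on it is exact and cheap:
``sqrt((s(x1) - s(x2))**2 + (y1 - y2)**2)`` with ``s`` the arc length of
the fold profile.  All ground truth (patch membership, areas, section
chord lengths) is therefore analytic, never estimated from the renders.

A high-myelin patch (the V5/MT+MST analogue) sits on the sheet; the
myelin density through the ribbon follows a depth profile concentrated
around a configurable cortical-depth fraction.  Renderers derive from
this single scalar field:

* T1w and T2w structural volumes (opposite myelin contrast, independent
  smooth bias fields, additive Gaussian noise),
* a z-statistic volume with a functional activation cluster at a
  configurable offset from the patch (plus an ipsilateral-motion
  subcluster, the MST analogue),
* phase-encoded retinotopy time series (cosine responses at the stimulus
  frequency inside the cluster, pure noise outside),
* silver-stain-like parasagittal section series (darker = more myelin).

All randomness flows from ``spec.seed`` through per-renderer child
streams, so a fixed seed gives byte-identical outputs while different
renders stay statistically independent.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import (
    CorticalSurface,
    TimeSeriesVolume,
    VertexMask,
    Volume,
    VoxelMask,
    write_surface,
    write_volume,
)
from .errors import ConfigError
from .histology import SectionSeries

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "render_structural",
    "render_functional",
    "render_retinotopy",
    "render_histology",
    "write_fixture_set",
]

# background tissue analogues (arbitrary units around 1 inside the ribbon)
_WM_T1, _WM_T2 = 1.4, 0.55
_CSF_T1, _CSF_T2 = 0.35, 1.5
_TRUTH_Z_THRESHOLD = 2.3  # default truth definition of cluster extent


@dataclass
class PhantomSpec:
    """Parameters of one phantom dataset.  Distances in mm, times in s."""

    # sheet geometry
    nx: int = 120
    ny: int = 120
    extent: tuple[float, float] = (30.0, 30.0)
    thickness: float = 2.5
    fold_amplitude: float = 1.5
    fold_wavelength: float = 15.0
    # myelin depth profile (depth fraction: 0 = white, 1 = pial)
    peak_depth: float = 0.6
    profile_width: float = 0.2
    # high-myelin patch
    patch_center: tuple[float, float] | None = None  # (x, y); None = centre
    patch_radius: float = 5.0
    patch_contrast: float = 2.0
    # structural rendering
    voxel_size: float = 0.5
    t1_gain: float = 0.4
    t2_drop: float = 0.3
    noise_sd: float = 0.03
    bias_amplitude: float = 0.1
    # functional cluster
    cluster_offset: tuple[float, float, float] = (2.5, 0.0, 0.0)
    cluster_radius: float = 5.0
    peak_z: float = 6.0
    mst_offset: float = 3.0
    mst_radius_factor: float = 0.6
    # retinotopy
    stimulus_period: float = 20.0
    frame_interval: float = 1.0
    n_frames: int = 200
    retino_amplitude: float = 1.0
    retino_noise_sd: float = 0.5
    # histology
    hist_spacing: float = 0.5
    hist_thickness_um: float = 50.0
    hist_pixel_size: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ConfigError("cortical thickness must be > 0")
        if self.patch_radius <= 0 or self.cluster_radius <= 0:
            raise ConfigError("radii must be > 0")
        if not (0.0 <= self.peak_depth <= 1.0):
            raise ConfigError("peak_depth must lie in [0, 1]")

    @property
    def surface_ref(self) -> str:
        return f"phantom-{self.seed}-surface"

    @property
    def volume_ref(self) -> str:
        return f"phantom-{self.seed}-volume"


@dataclass
class PhantomTruth:
    """Ground truth of one phantom; derived from geometry only."""

    spec: PhantomSpec
    patch_vertices: VertexMask
    patch_area_mm2: float
    peak_depth_fraction: float
    patch_center_world: np.ndarray
    cluster_center_world: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    cluster_voxels: VoxelMask | None = None
    mst_voxels: VoxelMask | None = None
    mst_protrusion_voxels: VoxelMask | None = None
    phase_map: np.ndarray | None = None
    section_positions: np.ndarray | None = None
    section_lengths_mm: np.ndarray | None = None


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _arc_length_table(spec: PhantomSpec, n: int = 4096):
    """Cumulative fold arc length s(x) on a fine grid, for interpolation."""
    x = np.linspace(0.0, spec.extent[0], n)
    if spec.fold_amplitude == 0:
        return x, x.copy()
    k = 2 * np.pi / spec.fold_wavelength
    dz = spec.fold_amplitude * k * np.cos(k * x)
    ds = np.sqrt(1.0 + dz ** 2)
    s = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2 * np.diff(x))])
    return x, s


def _s_of_x(spec: PhantomSpec, x: np.ndarray) -> np.ndarray:
    xt, st = _arc_length_table(spec)
    return np.interp(x, xt, st)


def _mid_z(spec: PhantomSpec, x: np.ndarray) -> np.ndarray:
    if spec.fold_amplitude == 0:
        return np.zeros_like(np.asarray(x, dtype=float))
    return spec.fold_amplitude * np.sin(2 * np.pi * x / spec.fold_wavelength)


def _depth_profile(spec: PhantomSpec, d: np.ndarray) -> np.ndarray:
    """Unit-peak myelin density as a function of depth fraction d in [0,1]."""
    return np.exp(-((d - spec.peak_depth) ** 2) / (2 * spec.profile_width ** 2))


def _patch_center_xy(spec: PhantomSpec) -> tuple[float, float]:
    if spec.patch_center is not None:
        return tuple(float(c) for c in spec.patch_center)
    return (spec.extent[0] / 2.0, spec.extent[1] / 2.0)


def _grid(spec: PhantomSpec):
    """Voxel-centre world coordinates and the grid-to-world affine."""
    vs = spec.voxel_size
    margin = 1.5
    zmax = spec.fold_amplitude + spec.thickness / 2 + margin
    x0, y0, z0 = -margin, -margin, -zmax
    nx = int(np.ceil((spec.extent[0] + 2 * margin) / vs))
    ny = int(np.ceil((spec.extent[1] + 2 * margin) / vs))
    nz = int(np.ceil(2 * zmax / vs))
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = (x0, y0, z0)
    xs = x0 + (np.arange(nx)) * vs
    ys = y0 + (np.arange(ny)) * vs
    zs = z0 + (np.arange(nz)) * vs
    return (nx, ny, nz), affine, xs, ys, zs


def _myelin_field(spec: PhantomSpec):
    """Voxelwise myelin density, ribbon mask, and depth-fraction array."""
    shape, affine, xs, ys, zs = _grid(spec)
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    white_z = _mid_z(spec, xs)[:, None, None] - spec.thickness / 2
    d = (Z - white_z) / spec.thickness
    in_sheet = (
        (X >= 0) & (X <= spec.extent[0]) & (Y >= 0) & (Y <= spec.extent[1])
    )
    ribbon = (d >= 0) & (d <= 1) & in_sheet
    xc, yc = _patch_center_xy(spec)
    ds_lat = _s_of_x(spec, xs) - float(_s_of_x(spec, np.array([xc]))[0])
    in_patch = (ds_lat[:, None, None] ** 2 + (Y - yc) ** 2
                <= spec.patch_radius ** 2)
    m = _depth_profile(spec, d) * np.where(in_patch, spec.patch_contrast, 1.0)
    m = np.where(ribbon, m, 0.0)
    below = (d < 0) & in_sheet
    return shape, affine, m, ribbon, below, d


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec) -> tuple[CorticalSurface, PhantomTruth]:
    """Build the phantom surface and its ground-truth record.

    The truth (patch vertex set, patch area, cluster centre) depends on
    geometry only — rendering settings (noise, bias) never touch it.
    """
    xs = np.linspace(0.0, spec.extent[0], spec.nx)
    ys = np.linspace(0.0, spec.extent[1], spec.ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    mid = _mid_z(spec, X)
    white = np.column_stack(
        [X.ravel(), Y.ravel(), (mid - spec.thickness / 2).ravel()])
    pial = np.column_stack(
        [X.ravel(), Y.ravel(), (mid + spec.thickness / 2).ravel()])
    # two triangles per quad
    idx = np.arange(spec.nx * spec.ny).reshape(spec.nx, spec.ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[:-1, 1:].ravel()
    dq = idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([a, b, dq]), np.column_stack([a, dq, c])])
    surface = CorticalSurface(white, pial, faces)

    xc, yc = _patch_center_xy(spec)
    s_all = _s_of_x(spec, X.ravel())
    s_c = float(_s_of_x(spec, np.array([xc]))[0])
    geodesic = np.sqrt((s_all - s_c) ** 2 + (Y.ravel() - yc) ** 2)
    # the patch must fit on the sheet
    s_max = float(_s_of_x(spec, np.array([spec.extent[0]]))[0])
    if (
        s_c - spec.patch_radius < 0 or s_c + spec.patch_radius > s_max
        or yc - spec.patch_radius < 0 or yc + spec.patch_radius > spec.extent[1]
    ):
        raise ConfigError("patch radius exceeds the sheet extent")
    patch_idx = np.flatnonzero(geodesic <= spec.patch_radius)
    patch = VertexMask(patch_idx, spec.surface_ref, surface.n_vertices)
    area = float(surface.vertex_areas()[patch_idx].sum())

    shape, affine, *_ = _grid(spec)
    patch_center_world = np.array([xc, yc, float(_mid_z(spec, np.array([xc]))[0])])
    cluster_center = patch_center_world + np.asarray(spec.cluster_offset)
    truth = PhantomTruth(
        spec=spec,
        patch_vertices=patch,
        patch_area_mm2=area,
        peak_depth_fraction=spec.peak_depth,
        patch_center_world=patch_center_world,
        cluster_center_world=cluster_center,
        grid_shape=shape,
        affine=affine,
    )
    return surface, truth


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------

def _bias_field(spec: PhantomSpec, shape, rng) -> np.ndarray:
    """Smooth low-order polynomial bias, exactly ±bias_amplitude in range."""
    if spec.bias_amplitude == 0:
        return np.ones(shape)
    u = np.linspace(-1, 1, shape[0])[:, None, None]
    v = np.linspace(-1, 1, shape[1])[None, :, None]
    w = np.linspace(-1, 1, shape[2])[None, None, :]
    c = rng.uniform(-1, 1, size=9)
    poly = (c[0] * u + c[1] * v + c[2] * w + c[3] * u * v + c[4] * u * w
            + c[5] * v * w + c[6] * (u ** 2 - 1 / 3)
            + c[7] * (v ** 2 - 1 / 3) + c[8] * (w ** 2 - 1 / 3))
    peak = np.abs(poly).max()
    if peak > 0:
        poly = poly / peak
    return 1.0 + spec.bias_amplitude * poly


def render_structural(surface: CorticalSurface, truth: PhantomTruth,
                      spec: PhantomSpec) -> tuple[Volume, Volume]:
    """Render T1w and T2w volumes from the myelin field.

    Inside the ribbon T1w increases and T2w decreases with myelin, so the
    T1w/T2w ratio is strictly increasing in the true myelin density when
    noise and bias are off.  Voxels below the white surface take
    white-matter analogue levels, voxels above the pial surface CSF
    levels.  Each modality gets an independent smooth bias field and
    additive Gaussian noise.
    """
    shape, affine, m, ribbon, below, _ = _myelin_field(spec)
    t1 = np.where(ribbon, 1.0 + spec.t1_gain * m,
                  np.where(below, _WM_T1, _CSF_T1))
    t2 = np.where(ribbon, 1.0 - spec.t2_drop * m,
                  np.where(below, _WM_T2, _CSF_T2))
    rng1 = np.random.default_rng([spec.seed, 1])
    rng2 = np.random.default_rng([spec.seed, 2])
    t1 = t1 * _bias_field(spec, shape, rng1)
    t2 = t2 * _bias_field(spec, shape, rng2)
    if spec.noise_sd > 0:
        t1 = t1 + rng1.normal(0.0, spec.noise_sd, shape)
        t2 = t2 + rng2.normal(0.0, spec.noise_sd, shape)
    vs = (spec.voxel_size,) * 3
    return (
        Volume(t1, vs, affine, space_tag=spec.volume_ref),
        Volume(t2, vs, affine, space_tag=spec.volume_ref),
    )


def render_functional(surface: CorticalSurface, truth: PhantomTruth,
                      spec: PhantomSpec,
                      contrast: str = "full_field") -> Volume:
    """Render a z-statistic volume for one stimulus contrast.

    ``full_field`` places a Gaussian activation cluster (peak ``peak_z``,
    scale ``cluster_radius / 2``) at the configured offset from the patch
    centre, restricted to the cortical ribbon; ``ipsilateral`` renders a
    smaller cluster displaced anteriorly (the MST analogue).  Background
    is N(0, 1) everywhere.  Truth voxel sets (noiseless z above 2.3) are
    recorded on the truth object.
    """
    if contrast not in ("full_field", "ipsilateral"):
        raise ConfigError(f"unknown contrast {contrast!r}")
    shape, affine, m, ribbon, below, _ = _myelin_field(spec)
    _, _, xs, ys, zs = _grid(spec)
    center = truth.cluster_center_world.copy()
    sigma = spec.cluster_radius / 2.0
    if contrast == "ipsilateral":
        center = center + np.array([0.0, spec.mst_offset, 0.0])
        sigma = sigma * spec.mst_radius_factor
    d2 = ((xs[:, None, None] - center[0]) ** 2
          + (ys[None, :, None] - center[1]) ** 2
          + (zs[None, None, :] - center[2]) ** 2)
    signal = spec.peak_z * np.exp(-d2 / (2 * sigma ** 2))
    signal = np.where(ribbon, signal, 0.0)
    cluster = VoxelMask.from_dense(signal > _TRUTH_Z_THRESHOLD,
                                   spec.volume_ref)
    if contrast == "full_field":
        truth.cluster_voxels = cluster
    else:
        truth.mst_voxels = cluster
        if truth.cluster_voxels is not None:
            protr = np.setdiff1d(cluster.indices,
                                 truth.cluster_voxels.indices)
            truth.mst_protrusion_voxels = VoxelMask(
                protr, spec.volume_ref, shape)
    rng = np.random.default_rng(
        [spec.seed, 3 if contrast == "full_field" else 4])
    z = signal + rng.standard_normal(shape)
    return Volume(z, (spec.voxel_size,) * 3, affine,
                  space_tag=spec.volume_ref)


def render_retinotopy(surface: CorticalSurface, truth: PhantomTruth,
                      spec: PhantomSpec) -> TimeSeriesVolume:
    """Render phase-encoded retinotopy time series.

    Every voxel of the (full-field) truth cluster responds with
    ``amplitude * cos(2*pi*f*t - phase)`` at the stimulus frequency; the
    true phase varies linearly with the ``y`` coordinate across the
    cluster (a polar-angle map analogue).  All other voxels are pure
    Gaussian noise.  Requires at least two stimulus cycles per run.
    """
    n_cycles = spec.n_frames * spec.frame_interval / spec.stimulus_period
    if n_cycles < 2:
        raise ConfigError(
            f"run covers {n_cycles:.2f} stimulus cycles; need >= 2")
    if truth.cluster_voxels is None:
        render_functional(surface, truth, spec, "full_field")
    shape, affine, xs, ys, zs = _grid(spec)
    cluster = truth.cluster_voxels
    ijk = cluster.to_ijk()
    yy = ys[ijk[:, 1]]
    y0, y1 = yy.min(), yy.max()
    span = max(y1 - y0, 1e-9)
    phases = 0.25 * np.pi + 1.5 * np.pi * (yy - y0) / span
    phase_map = np.full(shape, np.nan)
    phase_map[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = phases
    truth.phase_map = phase_map

    rng = np.random.default_rng([spec.seed, 5])
    t = np.arange(spec.n_frames) * spec.frame_interval
    f = 1.0 / spec.stimulus_period
    data = rng.normal(0.0, spec.retino_noise_sd,
                      size=shape + (spec.n_frames,))
    signal = spec.retino_amplitude * np.cos(
        2 * np.pi * f * t[None, :] - phases[:, None])
    data[ijk[:, 0], ijk[:, 1], ijk[:, 2], :] += signal
    return TimeSeriesVolume(data, (spec.voxel_size,) * 3, affine,
                            frame_interval=spec.frame_interval,
                            space_tag=spec.volume_ref)


def render_histology(surface: CorticalSurface, truth: PhantomTruth,
                     spec: PhantomSpec,
                     spacing_mm: float | None = None,
                     thickness_um: float | None = None) -> SectionSeries:
    """Render a parasagittal Gallyas-like section series through the patch.

    Sections are planes of constant ``x``, rasterized in (z, y) with
    ``hist_pixel_size`` mm pixels; stain darkness increases with myelin
    (patch pixels are darker than surrounding cortex).  The true
    myelinated length of each section — the chord of the patch disc at
    that arc-length position — is recorded in the truth object.
    """
    spacing = spec.hist_spacing if spacing_mm is None else spacing_mm
    thickness = spec.hist_thickness_um if thickness_um is None else thickness_um
    xc, yc = _patch_center_xy(spec)
    r = spec.patch_radius
    # sections covering the patch plus one empty section on each side
    n_half = int(np.ceil(r / spacing)) + 1
    positions = xc + np.arange(-n_half, n_half + 1) * spacing
    positions = positions[(positions >= 0) & (positions <= spec.extent[0])]
    if positions.size == 0:
        raise ConfigError("section series does not intersect the sheet")

    px = spec.hist_pixel_size
    zmax = spec.fold_amplitude + spec.thickness / 2 + 0.5
    z_grid = np.arange(zmax, -zmax, -px)  # top row = max z
    y_grid = np.arange(0.0, spec.extent[1] + px / 2, px)
    s_c = float(_s_of_x(spec, np.array([xc]))[0])
    m_max = spec.patch_contrast  # unit-peak profile times patch contrast

    images, lengths = [], []
    for x_sec in positions:
        midz = float(_mid_z(spec, np.array([x_sec]))[0])
        d = (z_grid[:, None] - (midz - spec.thickness / 2)) / spec.thickness
        ribbon = (d >= 0) & (d <= 1)
        ds = float(_s_of_x(spec, np.array([x_sec]))[0]) - s_c
        in_patch = (ds ** 2 + (y_grid[None, :] - yc) ** 2) <= r ** 2
        m = _depth_profile(spec, d) * np.where(in_patch, spec.patch_contrast,
                                               1.0)
        m = np.where(ribbon, m, 0.0)
        img = 240.0 - 200.0 * (m / m_max)
        img = np.where(ribbon, img, 250.0)
        images.append(img.astype(np.float64))
        if abs(ds) < r and spec.patch_contrast > 1.0:
            lengths.append(2.0 * np.sqrt(r ** 2 - ds ** 2))
        else:
            lengths.append(0.0)
    truth.section_positions = positions
    truth.section_lengths_mm = np.asarray(lengths)
    return SectionSeries(images=images, pixel_size=px, spacing=spacing,
                         thickness_um=thickness,
                         positions=positions - positions[0],
                         orientation="parasagittal")


def histology_pial_trace(spec: PhantomSpec, series: SectionSeries,
                         section_index: int) -> np.ndarray:
    """Pial-surface polyline (row, col in pixels) for one rendered section."""
    xc, yc = _patch_center_xy(spec)
    n_half = int(np.ceil(spec.patch_radius / spec.hist_spacing)) + 1
    positions = xc + np.arange(-n_half, n_half + 1) * spec.hist_spacing
    positions = positions[(positions >= 0) & (positions <= spec.extent[0])]
    x_sec = positions[section_index]
    px = series.pixel_size
    zmax = spec.fold_amplitude + spec.thickness / 2 + 0.5
    pial_z = float(_mid_z(spec, np.array([x_sec]))[0]) + spec.thickness / 2
    row = (zmax - pial_z) / px
    n_cols = series.images[section_index].shape[1]
    return np.array([[row, 0.0], [row, n_cols - 1.0]])


# ---------------------------------------------------------------------------
# fixture materialization
# ---------------------------------------------------------------------------

def write_fixture_set(spec: PhantomSpec, out_dir: str | os.PathLike) -> dict:
    """Materialize a named phantom fixture set on disk.

    Writes NIfTI volumes (T1w, T2w, full-field and ipsilateral z-maps,
    retinotopy series), the GIFTI surface, and a JSON truth/metadata
    sidecar.  Returns the manifest dictionary.
    """
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    surface, truth = make_phantom(spec)
    t1, t2 = render_structural(surface, truth, spec)
    z_full = render_functional(surface, truth, spec, "full_field")
    z_ipsi = render_functional(surface, truth, spec, "ipsilateral")
    retino = render_retinotopy(surface, truth, spec)
    write_volume(t1, os.path.join(out, "t1w.nii.gz"))
    write_volume(t2, os.path.join(out, "t2w.nii.gz"))
    write_volume(z_full, os.path.join(out, "zstat_full_field.nii.gz"))
    write_volume(z_ipsi, os.path.join(out, "zstat_ipsilateral.nii.gz"))
    write_volume(retino, os.path.join(out, "retinotopy.nii.gz"))
    write_surface(surface, os.path.join(out, "surface.gii"))
    truth.patch_vertices.to_text(os.path.join(out, "patch_vertices.txt"))
    manifest = {
        "spec": asdict(spec),
        "patch_area_mm2": truth.patch_area_mm2,
        "peak_depth_fraction": truth.peak_depth_fraction,
        "patch_center_world": truth.patch_center_world.tolist(),
        "cluster_center_world": truth.cluster_center_world.tolist(),
        "n_cluster_voxels": len(truth.cluster_voxels),
        "n_mst_voxels": len(truth.mst_voxels),
        "files": [
            "t1w.nii.gz", "t2w.nii.gz", "zstat_full_field.nii.gz",
            "zstat_ipsilateral.nii.gz", "retinotopy.nii.gz", "surface.gii",
            "patch_vertices.txt",
        ],
    }
    with open(os.path.join(out, "truth.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
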