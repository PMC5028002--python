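"""Functional definition of the motion complex: hMT+, MST and V5/MT.

The full-field motion contrast defines the hMT+ complex as the
suprathreshold cluster nearest a putative anatomical anchor; ipsilateral
motion clusters intersecting hMT+ define MST (included in full, even
where they protrude beyond hMT+); phase-encoded retinotopy analyzed by
Fourier decomposition, with a coherence criterion, assigns the
retinotopically organized remainder of hMT+ to V5/MT.

Cluster inference uses an explicit extent rule: either a fixed voxel
count or a sign-flip permutation null of the largest suprathreshold
cluster (no Gaussian-random-field assumptions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import TimeSeriesVolume, VertexMask, Volume, VoxelMask, mask_algebra
from .errors import (
    ConfigError,
    FrequencyBinError,
    GridMismatchError,
    NoClusterError,
    ParentMismatchError,
)

__all__ = [
    "ClusterConfig",
    "RetinotopyResult",
    "extract_clusters",
    "define_hmt",
    "define_mst",
    "fourier_retinotopy",
    "define_v5mt",
    "group_mask",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterConfig:
    """Cluster-forming threshold and extent criterion.

    ``min_extent`` is a voxel count (clusters must exceed it) or
    ``"permutation"``: the extent criterion is the (1 - cluster_alpha)
    quantile of the largest-cluster null distribution obtained from
    ``n_perm`` voxelwise sign-flip surrogates of the z-map.
    """

    z_threshold: float = 2.3
    cluster_alpha: float = 0.05
    min_extent: int | str = "permutation"
    connectivity: int = 18
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cluster_alpha < 1.0):
            raise ConfigError("cluster_alpha must lie in (0, 1)")
        if self.connectivity not in _STRUCTURES:
            raise ConfigError("connectivity must be 6, 18 or 26")


@dataclass
class RetinotopyResult:
    """Per-voxel phase, amplitude and coherence at the stimulus frequency.

    Coherence is the spectral amplitude at the stimulus frequency divided
    by the root-sum-square amplitude over the non-DC, non-drift
    frequencies of the time course; it lies in [0, 1], and phase is
    meaningful only where coherence is appreciable.
    """

    phase: np.ndarray
    amplitude: np.ndarray
    coherence: np.ndarray
    stimulus_bin: int
    parent_ref: str
    grid_shape: tuple[int, int, int]


def _label_sizes(binary: np.ndarray, structure) -> tuple[np.ndarray, int, np.ndarray]:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return labels, 0, np.zeros(0, dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, n, sizes


def _permutation_extent(zmap: Volume, cfg: ClusterConfig) -> int:
    """Extent criterion from sign-flip surrogates of the z-map."""
    rng = np.random.default_rng(cfg.seed)
    structure = _STRUCTURES[cfg.connectivity]
    data = np.where(zmap.valid, zmap.data, 0.0)
    maxima = np.empty(cfg.n_perm)
    for i in range(cfg.n_perm):
        flips = rng.integers(0, 2, size=data.shape) * 2 - 1
        surrogate = data * flips
        _, n, sizes = _label_sizes(surrogate > cfg.z_threshold, structure)
        maxima[i] = sizes.max() if n else 0
    return int(np.quantile(maxima, 1.0 - cfg.cluster_alpha))


def extract_clusters(zmap: Volume, cfg: ClusterConfig) -> list[VoxelMask]:
    """Suprathreshold clusters surviving the extent criterion.

    Connected components of ``{z > z_threshold}`` under the configured
    connectivity; components whose voxel count exceeds the extent
    criterion are returned sorted by descending peak z.
    """
    structure = _STRUCTURES[cfg.connectivity]
    binary = (zmap.data > cfg.z_threshold) & zmap.valid
    labels, n, sizes = _label_sizes(binary, structure)
    if n == 0:
        return []
    if cfg.min_extent == "permutation":
        extent = _permutation_extent(zmap, cfg)
    else:
        extent = int(cfg.min_extent)
    keep = np.flatnonzero(sizes > extent) + 1
    peaks = ndimage.maximum(zmap.data, labels=labels, index=keep) if len(keep) \
        else np.zeros(0)
    order = np.argsort(-np.asarray(peaks, dtype=float), kind="stable")
    out = []
    for lab in np.asarray(keep)[order]:
        out.append(VoxelMask(np.flatnonzero(labels.ravel() == lab),
                             zmap.space_tag, zmap.shape))
    return out


def define_hmt(full_field_zmap: Volume, cfg: ClusterConfig,
               anchor) -> VoxelMask:
    """The hMT+ complex: the surviving cluster nearest an anatomical anchor.

    ``anchor`` is a world coordinate (mm) marking the putative anatomical
    location of the complex; the cluster whose peak voxel lies nearest
    wins.  Exact ties keep the earlier cluster in the deterministic
    (peak-z-sorted) order.
    """
    clusters = extract_clusters(full_field_zmap, cfg)
    if not clusters:
        raise NoClusterError("no cluster survived thresholding")
    anchor = np.asarray(anchor, dtype=float)
    dists = []
    for cl in clusters:
        ijk = cl.to_ijk()
        zvals = full_field_zmap.data.flat[cl.indices]
        peak_ijk = ijk[np.argmax(zvals)]
        peak_world = full_field_zmap.voxel_to_world(peak_ijk)[0]
        dists.append(np.linalg.norm(peak_world - anchor))
    return clusters[int(np.argmin(dists))]


def define_mst(hmt: VoxelMask, ipsi_zmap: Volume,
               cfg: ClusterConfig) -> VoxelMask:
    """MST: ipsilateral-motion clusters that intersect hMT+, kept in full.

    Clusters of the ipsilateral contrast that share at least one voxel
    with hMT+ are included whole — including any voxels extending beyond
    hMT+.  An empty result is legitimate (no ipsilateral response).
    """
    if hmt.parent_ref != ipsi_zmap.space_tag:
        raise ParentMismatchError("hMT+ mask and ipsilateral map differ in grid")
    selected = np.zeros(0, dtype=np.int64)
    for cl in extract_clusters(ipsi_zmap, cfg):
        if np.intersect1d(cl.indices, hmt.indices).size:
            selected = np.union1d(selected, cl.indices)
    return VoxelMask(selected, hmt.parent_ref, hmt.parent_shape)


def fourier_retinotopy(ts: TimeSeriesVolume, stimulus_period: float,
                       repeats=None, detrend: bool = True) -> RetinotopyResult:
    """Fourier analysis of phase-encoded retinotopy runs.

    Each voxel's time course is Fourier transformed; phase and amplitude
    are read at the stimulus-frequency bin.  Drift handling is spectral:
    the DC component and the lowest frequency bins (1 and 2, where slow
    scanner drift concentrates) are excluded from the coherence
    denominator rather than removed by time-domain detrending, which
    would bias the stimulus-bin phase of a finite run.  Repeat runs are
    combined by complex (vector) averaging of their spectra before phase
    extraction, so runs with consistent phase reinforce and noise
    cancels.  Phase follows the ``cos(2*pi*f*t - phase)`` convention.

    Raises
    ------
    FrequencyBinError
        If the run length is not an integer number of stimulus periods
        (the stimulus frequency must fall exactly on a DFT bin — choose
        n_frames * frame_interval as a multiple of the period).
    ConfigError
        If a run covers fewer than two stimulus cycles.
    """
    runs = [ts] + list(repeats or [])
    n = ts.n_frames
    dt = ts.frame_interval
    cycles = n * dt / stimulus_period
    if cycles < 2:
        raise ConfigError(f"run covers {cycles:.2f} cycles; need >= 2")
    if abs(cycles - round(cycles)) > 1e-6:
        raise FrequencyBinError(
            f"{n} frames x {dt} s = {n * dt} s is not a multiple of the "
            f"{stimulus_period} s stimulus period; the stimulus frequency "
            "must land on a DFT bin"
        )
    stim_bin = int(round(cycles))
    spectra = None
    for run in runs:
        if run.n_frames != n or run.data.shape[:3] != ts.data.shape[:3]:
            raise GridMismatchError("repeat runs must share grid and length")
        spec = np.fft.rfft(run.data, axis=-1)
        spectra = spec if spectra is None else spectra + spec
    spectra /= len(runs)
    comp = spectra[..., stim_bin]
    first_bin = 3 if (detrend and stim_bin > 2) else 1  # drop drift bins
    amp_all = np.abs(spectra[..., first_bin:])
    denom = np.sqrt(np.sum(amp_all ** 2, axis=-1))
    coherence = np.where(denom > 0, np.abs(comp) / np.where(denom > 0, denom, 1),
                         0.0)
    phase = np.mod(-np.angle(comp), 2 * np.pi)
    amplitude = 2.0 * np.abs(comp) / n
    return RetinotopyResult(
        phase=phase, amplitude=amplitude, coherence=coherence,
        stimulus_bin=stim_bin, parent_ref=ts.space_tag,
        grid_shape=ts.data.shape[:3],
    )


def define_v5mt(retino: RetinotopyResult, coherence_threshold: float,
                hmt: VoxelMask, mst: VoxelMask) -> VoxelMask:
    """V5/MT: retinotopically organized hMT+ voxels, minus MST.

    Voxels of hMT+ whose response coherence exceeds the threshold are
    retinotopic; any of them already assigned to MST are excluded here
    (ipsilateral activity inside the retinotopic zone belongs to MST).
    """
    if retino.parent_ref != hmt.parent_ref:
        raise GridMismatchError("retinotopy and hMT+ are on different grids")
    coh = retino.coherence.ravel()
    retinotopic = hmt.indices[coh[hmt.indices] > coherence_threshold]
    v5 = VoxelMask(retinotopic, hmt.parent_ref, hmt.parent_shape)
    return mask_algebra(v5, mst, "difference")


def project_voxel_mask(mask: VoxelMask, vol: Volume, surface,
                       depth_fraction: float = 0.5,
                       surface_ref: str | None = None) -> VertexMask:
    """Project a voxel mask onto a surface as a vertex mask.

    A vertex joins the projected mask when its cortical-depth sampling
    point (``white + depth_fraction * (pial - white)``) falls in a member
    voxel (nearest-voxel assignment).  This is how volume-space
    functional ROIs are carried to the surface for comparison with
    surface-based myelin masks.
    """
    if mask.parent_ref != vol.space_tag:
        raise ParentMismatchError("mask and volume differ in grid")
    dense = mask.to_dense()
    pts = (surface.vertices_white
           + depth_fraction * (surface.vertices_pial - surface.vertices_white))
    ijk = np.round(vol.world_to_voxel(pts)).astype(int)
    shape = np.asarray(vol.shape)
    inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
    member = np.zeros(surface.n_vertices, dtype=bool)
    ii = ijk[inside]
    member[np.flatnonzero(inside)] = dense[ii[:, 0], ii[:, 1], ii[:, 2]]
    return VertexMask(np.flatnonzero(member),
                      surface_ref or vol.space_tag + "-surface",
                      surface.n_vertices)


def group_mask(masks, min_fraction: float) -> VertexMask:
    """Vertices present in at least ``min_fraction`` of individual masks.

    Each mask is binarized, the indicators summed, and vertices kept
    where ``count / n_masks >= min_fraction`` (so 4 of 8 masks pass a
    0.5 criterion).  ``min_fraction = 1.0`` is the intersection.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    ref = masks[0].parent_ref
    size = masks[0].parent_size
    counts = {}
    for m in masks:
        if m.parent_ref != ref:
            raise ParentMismatchError("group masks must share a common space")
        for i in m.indices:
            counts[int(i)] = counts.get(int(i), 0) + 1
    need = min_fraction * len(masks)
    keep = sorted(i for i, c in counts.items() if c >= need - 1e-12)
    return VertexMask(keep, ref, size)
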