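"""Myelin-weighted cortical maps and dense-myelin masks.

Implements the structural arm: the voxelwise T1w/T2w ratio image,
cortical-depth sampling onto a surface, the search for the depth
fraction with the strongest myelin-weighted signal, thresholding into a
"heavily myelinated" mask (top-fraction quantile rule or mean + k SEM
rule, with optional exclusion regions), contiguous-region surface area,
and the display-range clipping used for visualization only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.sparse.csgraph import connected_components

from .core import CorticalSurface, VertexMap, VertexMask, Volume
from .errors import (
    AllInvalidError,
    EmptyMaskError,
    GridMismatchError,
    SamplingBoundsError,
    SeedNotInMaskError,
)

__all__ = [
    "MyelinMapConfig",
    "ratio_map",
    "sample_to_surface",
    "optimal_depth_fraction",
    "threshold_map",
    "contiguous_region_area",
    "display_clip",
]

DEFAULT_DEPTH_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


@dataclass
class MyelinMapConfig:
    """Protocol parameters for myelin-weighted map construction.

    ``threshold_rule`` is ``("top_fraction", f)`` (keep the top fraction
    ``f`` of vertex values — the macaque protocol uses f = 1/3) or
    ``("mean_plus_k_sem", k)`` (keep vertices above mean + k standard
    errors of the mean — the human protocol uses k = 1).
    ``depth_fraction`` may be a number in [0, 1] or ``"auto"`` to search
    the 0..1 grid in steps of 0.1 for the strongest mean signal.
    """

    depth_fraction: float | str = "auto"
    threshold_rule: tuple[str, float] = ("mean_plus_k_sem", 1.0)
    exclusion_mask: VertexMask | None = None
    display_clip: tuple[float, float] = (4.0, 96.0)
    top_fraction_mode: str = "quantile"  # or "intensity_range"


def ratio_map(t1w_repeats, t2w_repeats, eps: float = 1e-9) -> Volume:
    """Voxelwise mean(T1w) / mean(T2w) ratio image.

    Repeats of each modality are averaged before division, enhancing
    myelin contrast and cancelling shared receive-field bias.  Voxels
    whose mean T2w value is ~0 are flagged invalid, never infinite.
    """
    t1w_repeats = list(t1w_repeats)
    t2w_repeats = list(t2w_repeats)
    if not t1w_repeats or not t2w_repeats:
        raise ValueError("need at least one volume per modality")
    ref = t1w_repeats[0]
    for v in t1w_repeats[1:] + t2w_repeats:
        ref.require_same_grid(v)
    t1 = np.mean([v.data for v in t1w_repeats], axis=0)
    t2 = np.mean([v.data for v in t2w_repeats], axis=0)
    valid = np.logical_and.reduce(
        [v.valid for v in t1w_repeats + t2w_repeats])
    ok = np.abs(t2) > eps
    ratio = np.where(ok, t1 / np.where(ok, t2, 1.0), 0.0)
    return Volume(ratio, ref.voxel_size, ref.transform,
                  space_tag=ref.space_tag, valid=valid & ok)


def sample_to_surface(vol: Volume, surface: CorticalSurface,
                      depth_fraction: float,
                      surface_ref: str | None = None) -> VertexMap:
    """Sample a volume onto a surface at one cortical-depth fraction.

    Sampling points are ``white + depth_fraction * (pial - white)``;
    values are trilinearly interpolated.  Vertices that touch invalid
    voxels (or fall outside the grid) are flagged invalid on the map.
    """
    if not (0.0 <= depth_fraction <= 1.0):
        raise ValueError("depth_fraction must lie in [0, 1]")
    pts = (surface.vertices_white
           + depth_fraction * (surface.vertices_pial - surface.vertices_white))
    ijk = vol.world_to_voxel(pts)
    shape = np.asarray(vol.shape)
    outside = np.any((ijk < -0.5) | (ijk > shape - 0.5), axis=1)
    if outside.all():
        raise SamplingBoundsError("every vertex samples outside the volume")
    vals = map_coordinates(vol.data, ijk.T, order=1, mode="nearest")
    # a vertex is valid only if no invalid voxel bleeds into its interpolant
    validity = map_coordinates(vol.valid.astype(float), ijk.T, order=1,
                               mode="constant", cval=0.0)
    valid = (validity > 1.0 - 1e-6) & ~outside
    return VertexMap(vals, surface_ref or vol.space_tag,
                     depth_fraction=depth_fraction, valid=valid,
                     n_vertices=surface.n_vertices)


def optimal_depth_fraction(vol: Volume, surface: CorticalSurface,
                           fractions=DEFAULT_DEPTH_GRID) -> float:
    """Depth fraction with the greatest mean sampled intensity.

    Candidates are evaluated by the mean over valid vertices; ties break
    toward the smaller fraction.  This reproduces the protocol of
    generating surface maps at thickness fractions 0 to 1 in steps of
    0.1 and keeping the strongest one.
    """
    fractions = sorted(float(f) for f in fractions)
    if len(fractions) < 2:
        raise ValueError("need at least 2 candidate fractions")
    best_f, best_mean = None, -np.inf
    for f in fractions:
        vmap = sample_to_surface(vol, surface, f)
        vals = vmap.valid_values()
        if vals.size == 0:
            continue
        mean = float(vals.mean())
        if mean > best_mean + 1e-12:  # strict: ties keep the smaller fraction
            best_f, best_mean = f, mean
    if best_f is None:
        raise AllInvalidError("no depth fraction had any valid vertex")
    return best_f


def _reference_values(vmap: VertexMap, exclusion_mask: VertexMask | None):
    """Valid, non-excluded values and their vertex indices."""
    keep = vmap.valid.copy()
    if exclusion_mask is not None:
        keep[exclusion_mask.indices] = False
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        raise AllInvalidError("fewer than 2 usable vertices after exclusion")
    return vmap.values[idx], idx


def threshold_map(vmap: VertexMap, rule: tuple[str, float],
                  exclusion_mask: VertexMask | None = None,
                  top_fraction_mode: str = "quantile") -> VertexMask:
    """Threshold a myelin-weighted map into a dense-myelin vertex mask.

    Rules
    -----
    ``("top_fraction", f)``
        Keep vertices with value >= the (1 - f) quantile of the valid,
        non-excluded values (ties at the boundary are included).  With
        ``top_fraction_mode="intensity_range"`` the cut is placed on the
        intensity axis instead: value >= min + (1 - f) * (max - min).
    ``("mean_plus_k_sem", k)``
        Keep vertices with value strictly above mean + k * sd / sqrt(n),
        computed over the valid, non-excluded values.

    Excluded vertices never enter the output mask nor the reference
    statistics.
    """
    name, param = rule
    vals, idx = _reference_values(vmap, exclusion_mask)
    if name == "top_fraction":
        f = float(param)
        if not (0.0 < f < 1.0):
            raise ValueError("top_fraction f must lie in (0, 1)")
        if top_fraction_mode == "quantile":
            cut = np.quantile(vals, 1.0 - f)
        elif top_fraction_mode == "intensity_range":
            rng_span = vals.max() - vals.min()
            # boundary ties are included; guard the cut against fp error
            cut = vals.min() + (1.0 - f) * rng_span - 1e-12 * max(rng_span, 1.0)
        else:
            raise ValueError(f"unknown top_fraction_mode {top_fraction_mode!r}")
        chosen = idx[vals >= cut]
    elif name == "mean_plus_k_sem":
        k = float(param)
        if k < 0:
            raise ValueError("k must be >= 0")
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        cut = vals.mean() + k * sem
        chosen = idx[vals > cut]
    else:
        raise ValueError(f"unknown threshold rule {name!r}")
    if chosen.size == 0 and name == "top_fraction":
        raise EmptyMaskError("threshold produced an empty mask")
    return VertexMask(chosen, vmap.surface_ref, vmap.n_vertices)


def contiguous_region_area(mask: VertexMask, surface: CorticalSurface,
                           seed_vertex: int) -> float:
    """Surface area (mm²) of the connected mask component holding a seed.

    Connectivity follows mesh edges; the area is the sum of per-vertex
    midthickness areas over the component, i.e. the extent of
    above-threshold vertices in native anatomical space.
    """
    if seed_vertex not in mask:
        raise SeedNotInMaskError(f"seed vertex {seed_vertex} not in mask")
    sub = surface.adjacency()[mask.indices][:, mask.indices]
    _, labels = connected_components(sub, directed=False)
    seed_pos = int(np.searchsorted(mask.indices, seed_vertex))
    comp = mask.indices[labels == labels[seed_pos]]
    return float(surface.vertex_areas()[comp].sum())


def display_clip(vmap: VertexMap, low_pct: float = 4.0,
                 high_pct: float = 96.0) -> VertexMap:
    """Clamp a map to a percent window of its full intensity range.

    Values outside ``min + low_pct% * range`` .. ``min + high_pct% *
    range`` are set to plateau.  This is a visualization aid only; no
    statistic in the package consumes clipped maps.
    """
    if not low_pct < high_pct:
        raise ValueError("low_pct must be < high_pct")
    vals = vmap.valid_values()
    if vals.size == 0 or vals.max() == vals.min():
        return VertexMap(vmap.values.copy(), vmap.surface_ref,
                         vmap.depth_fraction, valid=vmap.valid.copy(),
                         n_vertices=vmap.n_vertices)
    lo = vals.min() + low_pct / 100.0 * (vals.max() - vals.min())
    hi = vals.min() + high_pct / 100.0 * (vals.max() - vals.min())
    clipped = np.clip(vmap.values, lo, hi)
    return VertexMap(clipped, vmap.surface_ref, vmap.depth_fraction,
                     valid=vmap.valid.copy(), n_vertices=vmap.n_vertices)
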