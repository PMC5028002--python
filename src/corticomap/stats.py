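"""Overlap and correspondence statistics with permutation nulls.

Implements the quantitative comparisons between thresholded maps:
whole-cortex correspondence (intersection over union, in percent),
within-ROI correspondence, percent-of-ROI-myelinated, pairwise overlap
across subjects, the intensity-shuffling permutation null, and the
structural x functional threshold-sensitivity sweep.

All percentages are exact ratios of recorded integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import VertexMap, mask_algebra
from .errors import EmptyMaskError, ParentMismatchError
from .myelin import threshold_map

__all__ = [
    "CorrespondenceResult",
    "PermutationNull",
    "whole_cortex_correspondence",
    "roi_correspondence",
    "percent_roi_myelinated",
    "shuffle_null",
    "pairwise_overlap_matrix",
    "threshold_sweep",
]


@dataclass
class CorrespondenceResult:
    """An overlap percentage together with its exact integer counts."""

    percent: float
    n_overlap: int
    n_denominator: int
    context: str = "whole_cortex"

    def __post_init__(self) -> None:
        assert 0.0 <= self.percent <= 100.0


@dataclass
class PermutationNull:
    """Null distribution of a correspondence statistic under shuffling."""

    n_perm: int
    null_percents: np.ndarray
    observed: float

    @property
    def p_value(self) -> float:
        """Add-one permutation p-value: (1 + #{null >= observed}) / (n + 1)."""
        return (1 + int(np.sum(self.null_percents >= self.observed))) / (
            self.n_perm + 1
        )


def _check_parents(*masks) -> None:
    refs = {m.parent_ref for m in masks}
    if len(refs) > 1:
        raise ParentMismatchError(f"masks live in different spaces: {refs}")


def whole_cortex_correspondence(mask_a, mask_b) -> CorrespondenceResult:
    """Percent correspondence of two masks over their union.

    ``100 * |A ∩ B| / |A ∪ B|``: the overlapping elements divided by the
    combination of both masks, counting overlapping elements once.
    """
    _check_parents(mask_a, mask_b)
    inter = np.intersect1d(mask_a.indices, mask_b.indices)
    union = np.union1d(mask_a.indices, mask_b.indices)
    if union.size == 0:
        raise EmptyMaskError("both masks are empty")
    return CorrespondenceResult(
        percent=100.0 * inter.size / union.size,
        n_overlap=int(inter.size),
        n_denominator=int(union.size),
        context="whole_cortex",
    )


def roi_correspondence(mask_a, mask_b, roi,
                       denominator: str = "union") -> CorrespondenceResult:
    """Correspondence of two masks restricted to a region of interest.

    Default: ``100 * |A ∩ B ∩ R| / |(A ∪ B) ∩ R|`` — the thresholded
    elements within the ROI counted once.  ``denominator="sum"`` uses the
    double-counting (Dice-like) variant ``|A∩R| + |B∩R|`` instead.
    """
    _check_parents(mask_a, mask_b, roi)
    a_r = np.intersect1d(mask_a.indices, roi.indices)
    b_r = np.intersect1d(mask_b.indices, roi.indices)
    inter = np.intersect1d(a_r, b_r)
    if denominator == "union":
        denom = np.union1d(a_r, b_r).size
        scale = 100.0
    elif denominator == "sum":
        denom = a_r.size + b_r.size
        scale = 200.0  # Dice: 2|A∩B| / (|A|+|B|), as a percent
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise EmptyMaskError("no thresholded elements within the ROI")
    return CorrespondenceResult(
        percent=scale * inter.size / denom,
        n_overlap=int(inter.size),
        n_denominator=int(denom),
        context="roi",
    )


def percent_roi_myelinated(roi, myelin_mask) -> CorrespondenceResult:
    """Percent of ROI elements that also carry above-threshold myelin signal."""
    _check_parents(roi, myelin_mask)
    if len(roi) == 0:
        raise EmptyMaskError("empty ROI")
    inter = np.intersect1d(roi.indices, myelin_mask.indices)
    return CorrespondenceResult(
        percent=100.0 * inter.size / len(roi),
        n_overlap=int(inter.size),
        n_denominator=len(roi),
        context="roi",
    )


def shuffle_null(map_a: VertexMap, map_b: VertexMap, rule,
                 statistic: str = "whole_cortex", roi=None,
                 n_perm: int = 1000, seed: int = 0,
                 exclusion_mask=None) -> PermutationNull:
    """Permutation null by intensity shuffling.

    Each permutation independently shuffles each map's valid values
    across its vertices (producing images of randomly placed
    intensities), re-thresholds both with the same rule, and recomputes
    the chosen statistic.  Shuffling values preserves the intensity
    distribution — and hence the mask size under quantile rules —
    isolating spatial correspondence as the quantity under test.
    """
    if map_a.n_vertices != map_b.n_vertices:
        raise ParentMismatchError("maps differ in vertex count")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    def compute(a_map, b_map):
        ma = threshold_map(a_map, rule, exclusion_mask)
        mb = threshold_map(b_map, rule, exclusion_mask)
        if statistic == "whole_cortex":
            return whole_cortex_correspondence(ma, mb).percent
        if statistic == "roi":
            return roi_correspondence(ma, mb, roi).percent
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = compute(map_a, map_b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    ia = np.flatnonzero(map_a.valid)
    ib = np.flatnonzero(map_b.valid)
    for i in range(n_perm):
        va = map_a.values.copy()
        vb = map_b.values.copy()
        va[ia] = map_a.values[rng.permutation(ia)]
        vb[ib] = map_b.values[rng.permutation(ib)]
        pa = VertexMap(va, map_a.surface_ref, map_a.depth_fraction,
                       valid=map_a.valid.copy())
        pb = VertexMap(vb, map_b.surface_ref, map_b.depth_fraction,
                       valid=map_b.valid.copy())
        null[i] = compute(pa, pb)
    return PermutationNull(n_perm=n_perm, null_percents=null,
                           observed=observed)


def pairwise_overlap_matrix(masks, statistic: str = "whole_cortex",
                            roi=None):
    """Symmetric matrix of pairwise overlap percents across subjects.

    Returns ``(matrix, mean, sd)`` where mean and sd summarize the
    off-diagonal (unordered-pair) entries; the diagonal is 100.
    """
    masks = list(masks)
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    n = len(masks)
    mat = np.full((n, n), 100.0)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            if statistic == "whole_cortex":
                p = whole_cortex_correspondence(masks[i], masks[j]).percent
            elif statistic == "roi":
                p = roi_correspondence(masks[i], masks[j], roi).percent
            else:
                raise ValueError(f"unknown statistic {statistic!r}")
            mat[i, j] = mat[j, i] = p
            vals.append(p)
    vals = np.asarray(vals)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
    return mat, float(vals.mean()), sd


def threshold_sweep(
    struct_map: VertexMap,
    func_zmap,
    surface,
    anchor,
    cluster_cfg,
    sem_ks=(0.0, 0.5, 1.0, 1.5),
    z_thresholds=(1.3, 1.8, 2.3, 2.8),
    depth_fraction: float = 0.5,
    exclusion_mask=None,
    surface_ref: str | None = None,
) -> pd.DataFrame:
    """Sensitivity of the structural-functional overlap to both thresholds.

    Crosses structural rules (mean + k SEM over ``sem_ks``; the standard
    threshold is k = 1, flanked by a very low / low / high threshold)
    with functional cluster-forming thresholds (``z_thresholds``; the
    standard is z > 2.3).  For every cell the myelin mask and the hMT+
    ROI are re-derived from scratch, the ROI projected to the surface,
    and the percent of the ROI carrying myelin signal plus both mask
    sizes tabulated — so the (k = 1, z = 2.3) cell equals the standalone
    pipeline value exactly.

    Returns a tidy DataFrame with columns ``sem_k``, ``z_threshold``,
    ``myelin_vertices``, ``roi_vertices``, ``percent_roi_myelinated``,
    ``correspondence_percent``.
    """
    from dataclasses import replace

    from .rois import define_hmt, project_voxel_mask

    rows = []
    rois = {}
    for z in z_thresholds:
        cfg_z = replace(cluster_cfg, z_threshold=float(z))
        roi_vox = define_hmt(func_zmap, cfg_z, anchor)
        rois[z] = project_voxel_mask(
            roi_vox, func_zmap, surface, depth_fraction,
            surface_ref=surface_ref or struct_map.surface_ref)
    for k in sem_ks:
        mask = threshold_map(struct_map, ("mean_plus_k_sem", float(k)),
                             exclusion_mask)
        for z in z_thresholds:
            roi = rois[z]
            pct = percent_roi_myelinated(roi, mask)
            corr = whole_cortex_correspondence(mask, roi)
            rows.append({
                "sem_k": float(k),
                "z_threshold": float(z),
                "myelin_vertices": len(mask),
                "roi_vertices": len(roi),
                "percent_roi_myelinated": pct.percent,
                "correspondence_percent": corr.percent,
            })
    return pd.DataFrame(rows)
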