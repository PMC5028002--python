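"""Histological myeloarchitecture analysis.

Covers the stained-section arm of the workflow: cortical intensity
profiles orthogonal to the layers, robust local-quadratic smoothing,
profile comparison (two-sample Kolmogorov–Smirnov), measurement of the
densely myelinated length along the pial surface of each section, and
aggregation of per-section lengths into a surface area across a section
series with known spacing.

Sections follow the silver-stain convention: *darker* pixels mean more
myelin.  Lengths are in mm, depth positions in μm, areas in mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates

from .errors import DegenerateInputError, ProfileError

__all__ = [
    "SectionSeries",
    "IntensityProfile",
    "extract_profile",
    "smooth_profile",
    "compare_profiles",
    "section_myelin_length",
    "aggregate_area",
    "summarize_areas",
    "method_agreement",
]


@dataclass
class SectionSeries:
    """Ordered grayscale histology sections with physical metadata.

    Parameters
    ----------
    images:
        List of 2D arrays (row, column); darker = more myelin.
    pixel_size:
        mm per pixel (isotropic within a section).
    spacing:
        mm between consecutive *retained* sections of the series
        (e.g. 0.5 mm for a 1-in-10 series of 50 μm sections).
    thickness_um:
        Physical thickness of each cut section, μm.
    positions:
        Position of each section along the cutting axis, mm;
        strictly increasing.
    orientation:
        Free-text tag (e.g. ``"parasagittal"``).
    """

    images: list[np.ndarray]
    pixel_size: float
    spacing: float
    thickness_um: float
    positions: np.ndarray = None
    orientation: str = "parasagittal"

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("section spacing must be > 0")
        if self.thickness_um <= 0:
            raise ValueError("section thickness must be > 0")
        if self.positions is None:
            self.positions = np.arange(len(self.images)) * self.spacing
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.positions) != len(self.images):
            raise ValueError("one position per section required")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("section positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class IntensityProfile:
    """Mean stain intensity vs. cortical depth (μm from the pial surface)."""

    positions_um: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if len(self.positions_um) > 1 and not np.all(
            np.diff(self.positions_um) > 0
        ):
            raise ValueError("profile positions must be strictly increasing")
        if np.any(self.n < 1):
            raise ValueError("each profile point needs n >= 1 measurements")

    def __len__(self) -> int:
        return len(self.positions_um)


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length steps (same units)."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(seg)]
    total = arc[-1]
    if total <= 0:
        raise ProfileError("degenerate (zero-length) polyline")
    targets = np.arange(0.0, total + 0.5 * step, step)
    targets = targets[targets <= total]
    out = np.column_stack([
        np.interp(targets, arc, points[:, 0]),
        np.interp(targets, arc, points[:, 1]),
    ])
    return out


def extract_profile(
    image: np.ndarray,
    path: np.ndarray,
    pixel_size_mm: float,
    step_um: float = 15.0,
    n_lateral: int = 6,
    lateral_spacing_um: float | None = None,
) -> IntensityProfile:
    """Sample an intensity profile along a pial-to-white path.

    At every ``step_um`` along the path, ``n_lateral`` bilinear samples
    are taken on a short segment perpendicular to the path; their mean
    and standard deviation form one profile point.

    Parameters
    ----------
    image:
        2D grayscale section (row, column).
    path:
        K x 2 polyline in pixel coordinates (row, col), ordered from the
        pial surface toward the white matter.
    pixel_size_mm:
        mm per pixel.
    step_um:
        Spacing of profile points along the path (default 15 μm).
    n_lateral:
        Number of perpendicular measurements per point (default 6).
    lateral_spacing_um:
        Spacing between the perpendicular samples; defaults to ``step_um``.
    """
    if step_um <= 0:
        raise ValueError("step_um must be > 0")
    image = np.asarray(image, dtype=float)
    px_um = pixel_size_mm * 1000.0
    step_px = step_um / px_um
    pts = _resample_polyline(path, step_px)
    # unit tangents by central differences, then perpendicular
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normal = np.column_stack([tang[:, 1], -tang[:, 0]])
    lat_um = step_um if lateral_spacing_um is None else lateral_spacing_um
    lat_px = lat_um / px_um
    offsets = (np.arange(n_lateral) - (n_lateral - 1) / 2.0) * lat_px
    # sample grid: (n_points, n_lateral, 2)
    sample = pts[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    if (
        sample[..., 0].min() < 0 or sample[..., 1].min() < 0
        or sample[..., 0].max() > image.shape[0] - 1
        or sample[..., 1].max() > image.shape[1] - 1
    ):
        raise ProfileError("profile path (or its lateral samples) exits image")
    vals = map_coordinates(
        image, sample.reshape(-1, 2).T, order=1
    ).reshape(sample.shape[:2])
    return IntensityProfile(
        positions_um=np.arange(len(pts)) * step_um,
        mean=vals.mean(axis=1),
        sd=vals.std(axis=1, ddof=0),
        n=np.full(len(pts), n_lateral),
    )


def _rloess(x: np.ndarray, y: np.ndarray, span: float,
            robust_iters: int = 4) -> np.ndarray:
    """Robust locally weighted quadratic regression (rloess).

    Tricube distance weights within a window of ``ceil(span * n)`` nearest
    neighbours, a local second-degree polynomial model, and bisquare
    robustness reweighting of residuals.
    """
    n = len(x)
    window = max(int(np.ceil(span * n)), 3)
    robust_w = np.ones(n)
    fitted = y.astype(float).copy()
    for iteration in range(robust_iters + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            idx = np.argsort(d)[:window]
            dmax = d[idx].max()
            if dmax <= 0:
                fitted[i] = np.average(y[idx], weights=robust_w[idx])
                continue
            w = (1 - (d[idx] / dmax) ** 3) ** 3
            w = np.clip(w, 0, None) * robust_w[idx]
            if w.sum() <= 0:
                w = np.ones(len(idx))
            # local quadratic, centred for conditioning
            xi = x[idx] - x[i]
            X = np.column_stack([np.ones(len(xi)), xi, xi ** 2])
            W = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(X * W[:, None], y[idx] * W, rcond=None)
            fitted[i] = coef[0]
        if iteration == robust_iters:
            break
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = resid / (6.0 * s)
        robust_w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
    return fitted


def smooth_profile(profile: IntensityProfile, span: float = 0.25,
                   robust_iters: int = 4) -> IntensityProfile:
    """Smooth a profile with robust local quadratic regression.

    ``span`` is the fraction of points in each local window.  The method
    reproduces exactly quadratic data and downweights gross outliers via
    bisquare reweighting.
    """
    if len(profile) < 5:
        raise ProfileError("need at least 5 points to smooth")
    window = max(int(np.ceil(span * len(profile))), 3)
    if window < 3:
        raise ProfileError("span too small: local windows have < 3 points")
    sm = _rloess(profile.positions_um, profile.mean, span, robust_iters)
    return IntensityProfile(profile.positions_um, sm, profile.sd, profile.n)


def compare_profiles(a: IntensityProfile, b: IntensityProfile):
    """Two-sample Kolmogorov–Smirnov test on the raw per-position means.

    Returns ``(D, p)`` with the asymptotic p-value.  The comparison uses
    the unsmoothed per-position mean intensities of each profile.
    """
    if len(a) < 2 or len(b) < 2:
        raise ProfileError("need at least 2 points per profile for the KS test")
    res = stats.ks_2samp(a.mean, b.mean, method="asymp")
    return float(res.statistic), float(res.pvalue)


def section_myelin_length(
    image: np.ndarray,
    stain_threshold: float,
    pial_trace: np.ndarray,
    pixel_size_mm: float,
    probe_depth_mm: float,
    flip_normal: bool = False,
):
    """Length of densely myelinated cortex along a section's pial surface.

    Walks the pial trace at half-pixel arc steps; at each step the stain
    intensity is probed ``probe_depth_mm`` below the surface (along the
    inward normal, which for a left-to-right trace with cortex below is
    the default orientation; pass ``flip_normal=True`` otherwise).  Arc
    length is accumulated over the contiguous runs where the probed
    intensity is darker (smaller) than ``stain_threshold``.

    Returns
    -------
    total_mm : float
        Total myelinated arc length.
    runs : list of (start_mm, end_mm)
        Arc-length interval of each contiguous run along the trace.
    """
    image = np.asarray(image, dtype=float)
    step_px = 0.5
    pts = _resample_polyline(np.asarray(pial_trace, float), step_px)
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normal = np.column_stack([tang[:, 1], -tang[:, 0]])
    if flip_normal:
        normal = -normal
    probe = pts + normal * (probe_depth_mm / pixel_size_mm)
    if (
        probe.min() < 0
        or probe[:, 0].max() > image.shape[0] - 1
        or probe[:, 1].max() > image.shape[1] - 1
    ):
        raise ProfileError("probe points exit the image; check trace/depth")
    vals = map_coordinates(image, probe.T, order=1)
    dark = vals < stain_threshold
    step_mm = step_px * pixel_size_mm
    runs = []
    in_run = False
    for i, d in enumerate(dark):
        if d and not in_run:
            start = i
            in_run = True
        elif not d and in_run:
            runs.append((start * step_mm, i * step_mm))
            in_run = False
    if in_run:
        runs.append((start * step_mm, len(dark) * step_mm))
    total = float(sum(e - s for s, e in runs))
    return total, runs


def aggregate_area(
    lengths_mm,
    spacing_mm: float,
    thickness_end_caps_um: float | None = None,
) -> float:
    """Aggregate per-section myelinated lengths into a surface area (mm²).

    Trapezoidal rule between successive sections of one series:
    ``sum over pairs of (l_i + l_{i+1}) / 2 * spacing``.  Zero-length
    sections participate, tapering the ends of the area.  Section
    thickness is metadata: the spacing between retained sections already
    spans the cut tissue.  The optional end-caps mode adds
    ``thickness * (l_first + l_last)`` for the outermost cut sections.
    """
    lengths = np.asarray(lengths_mm, dtype=float)
    if len(lengths) < 2:
        raise DegenerateInputError("need >= 2 sections to aggregate an area")
    if spacing_mm <= 0:
        raise ValueError("spacing must be > 0")
    area = float(np.sum((lengths[:-1] + lengths[1:]) / 2.0) * spacing_mm)
    if thickness_end_caps_um is not None:
        area += thickness_end_caps_um / 1000.0 * (lengths[0] + lengths[-1])
    return area


def summarize_areas(table, pooled: dict[str, list[str]] | None = None):
    """Mean and sample SD (n-1) per column of an area table, plus pooled groups.

    Missing entries (NaN) are ignored; a column with a single value
    reports its mean but a missing SD (never zero).

    Parameters
    ----------
    table:
        DataFrame of areas (rows = subjects/hemispheres, columns = methods).
    pooled:
        Optional mapping from a pooled-summary name to the list of columns
        whose non-missing values are pooled before summarizing.

    Returns
    -------
    DataFrame with rows ``mean``, ``sd``, ``n`` and one column per input
    column plus each pooled group.
    """
    import pandas as pd

    table = pd.DataFrame(table)
    out = {}
    for col in table.columns:
        vals = table[col].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            raise DegenerateInputError(f"column {col!r} has no values")
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        out[col] = {"mean": float(np.mean(vals)), "sd": sd, "n": len(vals)}
    if pooled:
        for name, cols in pooled.items():
            vals = np.concatenate(
                [table[c].dropna().to_numpy(dtype=float) for c in cols]
            )
            if len(vals) == 0:
                raise DegenerateInputError(f"pooled group {name!r} is empty")
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
            out[name] = {"mean": float(np.mean(vals)), "sd": sd,
                         "n": len(vals)}
    return pd.DataFrame(out).reindex(["mean", "sd", "n"])


def method_agreement(pairs):
    """Pearson correlation between paired area measurements of two methods.

    ``pairs`` is an iterable of ``(area_method1, area_method2)``;
    incomplete pairs (either entry missing) are dropped.  Returns
    ``(r, p, n)`` with the two-sided p-value.
    """
    arr = np.asarray(
        [(a, b) for a, b in pairs
         if a is not None and b is not None
         and np.isfinite(a) and np.isfinite(b)],
        dtype=float,
    )
    if len(arr) < 3:
        raise DegenerateInputError(
            f"need >= 3 complete pairs, got {len(arr)}"
        )
    if np.std(arr[:, 0]) == 0 or np.std(arr[:, 1]) == 0:
        raise DegenerateInputError("zero variance in one method's areas")
    r, p = stats.pearsonr(arr[:, 0], arr[:, 1])
    return float(r), float(p), len(arr)
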