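"""End-to-end workflows composing the analysis stages.

Two study arms are orchestrated here:

* the macaque arm: T1w/T2w ratio map -> depth sampling -> top-third
  threshold -> contiguous dense-myelin surface area, with an optional
  histology series measured and aggregated alongside for method
  agreement;
* the human arm: myelin-weighted map (mean + 1 SEM threshold, exclusion
  honored) -> functional hMT+/MST/V5-MT definition -> overlap tables,
  intensity-shuffling permutation null, and the threshold sweep.

Every report embeds the resolved configuration and seed, and reruns with
identical inputs are deterministic.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, replace

import numpy as np

from .core import CorticalSurface, VertexMask, Volume
from .errors import ConfigError
from .histology import (
    SectionSeries,
    aggregate_area,
    section_myelin_length,
)
from .myelin import (
    contiguous_region_area,
    optimal_depth_fraction,
    ratio_map,
    sample_to_surface,
    threshold_map,
)
from .rois import (
    ClusterConfig,
    define_hmt,
    define_mst,
    define_v5mt,
    fourier_retinotopy,
    project_voxel_mask,
)
from .stats import (
    percent_roi_myelinated,
    shuffle_null,
    threshold_sweep,
    whole_cortex_correspondence,
)

__all__ = ["run_macaque", "run_human", "write_report"]


def _resolve_depth(vol, surface, depth_fraction):
    if depth_fraction == "auto":
        return optimal_depth_fraction(vol, surface)
    return float(depth_fraction)


def run_macaque(
    t1w_repeats,
    t2w_repeats,
    surface: CorticalSurface,
    seed_vertex: int | None = None,
    depth_fraction="auto",
    top_fraction: float = 1.0 / 3.0,
    top_fraction_mode: str = "quantile",
    histology: SectionSeries | None = None,
    histology_traces=None,
    histology_probe_depth_mm: float | None = None,
    histology_stain_threshold: float | None = None,
    surface_ref: str | None = None,
) -> dict:
    """Macaque workflow: structural myelin area, optional histology area.

    The ratio image is sampled onto the surface (depth chosen
    automatically unless given), thresholded with the top-fraction rule,
    and the contiguous dense-myelin region around ``seed_vertex``
    (default: the map's peak vertex) is measured in mm².  If a histology
    series is supplied with per-section pial traces, the densely
    myelinated length of each section is measured and aggregated into an
    area for comparison.
    """
    ratio = ratio_map(t1w_repeats, t2w_repeats)
    depth = _resolve_depth(ratio, surface, depth_fraction)
    vmap = sample_to_surface(ratio, surface, depth, surface_ref=surface_ref)
    mask = threshold_map(vmap, ("top_fraction", top_fraction),
                         top_fraction_mode=top_fraction_mode)
    if seed_vertex is None:
        vals = np.where(vmap.valid, vmap.values, -np.inf)
        seed_vertex = int(np.argmax(vals))
        if seed_vertex not in mask:
            # peak of the map is by construction above the threshold, but
            # guard against an invalid-peak edge case
            seed_vertex = int(mask.indices[0])
    area = contiguous_region_area(mask, surface, seed_vertex)
    report = {
        "mode": "macaque",
        "depth_fraction": depth,
        "top_fraction": top_fraction,
        "top_fraction_mode": top_fraction_mode,
        "seed_vertex": int(seed_vertex),
        "n_mask_vertices": len(mask),
        "smri_area_mm2": area,
    }
    if histology is not None:
        if histology_traces is None or histology_stain_threshold is None:
            raise ConfigError(
                "histology requires per-section pial traces and a stain "
                "threshold")
        lengths = []
        for img, trace in zip(histology.images, histology_traces):
            total, _ = section_myelin_length(
                img, histology_stain_threshold, trace,
                histology.pixel_size, histology_probe_depth_mm)
            lengths.append(total)
        hist_area = aggregate_area(lengths, histology.spacing)
        report["histology_lengths_mm"] = lengths
        report["histology_area_mm2"] = hist_area
    return report


def run_human(
    struct_vol: Volume,
    surface: CorticalSurface,
    zmap_full: Volume,
    anchor,
    zmap_ipsi: Volume | None = None,
    retino_ts=None,
    stimulus_period: float | None = None,
    retino_repeats=None,
    coherence_threshold: float = 0.25,
    depth_fraction="auto",
    sem_k: float = 1.0,
    exclusion_mask: VertexMask | None = None,
    cluster_cfg: ClusterConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    sweep: bool = True,
    surface_ref: str | None = None,
) -> dict:
    """Human workflow: myelin mask vs. functional hMT+/MST/V5-MT.

    The structural volume (an MP2RAGE-like or precomputed T1w/T2w ratio
    image) is sampled at the optimal depth and thresholded at
    mean + ``sem_k`` SEM with the exclusion mask honored.  Functional
    ROIs are defined from the z-maps and, when retinotopy is supplied,
    Fourier analysis with the coherence criterion splits hMT+ into
    V5/MT and MST.  Overlap statistics are computed on the surface, with
    an intensity-shuffling permutation null and (optionally) the full
    threshold sweep.
    """
    cfg = cluster_cfg or ClusterConfig()
    depth = _resolve_depth(struct_vol, surface, depth_fraction)
    vmap = sample_to_surface(struct_vol, surface, depth,
                             surface_ref=surface_ref)
    myelin_mask = threshold_map(vmap, ("mean_plus_k_sem", sem_k),
                                exclusion_mask)
    hmt = define_hmt(zmap_full, cfg, anchor)
    report = {
        "mode": "human",
        "depth_fraction": depth,
        "sem_k": sem_k,
        "seed": seed,
        "cluster_config": asdict(cfg),
        "n_myelin_vertices": len(myelin_mask),
        "n_hmt_voxels": len(hmt),
    }
    mst = None
    if zmap_ipsi is not None:
        mst = define_mst(hmt, zmap_ipsi, cfg)
        report["n_mst_voxels"] = len(mst)
    if retino_ts is not None:
        if stimulus_period is None:
            raise ConfigError("retinotopy requires the stimulus period")
        retino = fourier_retinotopy(retino_ts, stimulus_period,
                                    repeats=retino_repeats)
        from .core import VoxelMask

        empty_mst = mst if mst is not None else VoxelMask(
            [], hmt.parent_ref, hmt.parent_shape)
        v5mt = define_v5mt(retino, coherence_threshold, hmt, empty_mst)
        report["n_v5mt_voxels"] = len(v5mt)

    ref = surface_ref or vmap.surface_ref
    hmt_surface = project_voxel_mask(hmt, zmap_full, surface, depth,
                                     surface_ref=ref)
    report["n_hmt_vertices"] = len(hmt_surface)
    pct = percent_roi_myelinated(hmt_surface, myelin_mask)
    corr = whole_cortex_correspondence(myelin_mask, hmt_surface)
    report["percent_hmt_myelinated"] = pct.percent
    report["hmt_myelin_correspondence"] = corr.percent

    if n_perm > 0:
        # null for percent-of-ROI-myelinated: shuffle the structural
        # intensities, re-threshold, recompute against the fixed ROI
        rng = np.random.default_rng(seed)
        valid_idx = np.flatnonzero(vmap.valid)
        null = np.empty(n_perm)
        from .core import VertexMap

        for i in range(n_perm):
            vals = vmap.values.copy()
            vals[valid_idx] = vmap.values[rng.permutation(valid_idx)]
            pmap = VertexMap(vals, vmap.surface_ref, vmap.depth_fraction,
                             valid=vmap.valid.copy())
            pmask = threshold_map(pmap, ("mean_plus_k_sem", sem_k),
                                  exclusion_mask)
            null[i] = percent_roi_myelinated(hmt_surface, pmask).percent
        p_value = (1 + int(np.sum(null >= pct.percent))) / (n_perm + 1)
        report["null_mean_percent"] = float(null.mean())
        report["null_q95_percent"] = float(np.quantile(null, 0.95))
        report["p_value"] = p_value
        report["n_perm"] = n_perm
    if sweep:
        sweep_df = threshold_sweep(
            vmap, zmap_full, surface, anchor, cfg,
            depth_fraction=depth, exclusion_mask=exclusion_mask,
            surface_ref=ref)
        report["sweep"] = sweep_df.to_dict(orient="records")
    return report


def write_report(report: dict, out_dir: str | os.PathLike,
                 stem: str = "report") -> str:
    """Write a pipeline report as JSON (and its sweep table as TSV)."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, f"{stem}.json")
    serializable = {}
    for key, val in report.items():
        if isinstance(val, np.ndarray):
            serializable[key] = val.tolist()
        elif isinstance(val, (np.floating, np.integer)):
            serializable[key] = val.item()
        else:
            serializable[key] = val
    with open(path, "w") as fh:
        json.dump(serializable, fh, indent=2, default=str)
    if "sweep" in report:
        import pandas as pd

        pd.DataFrame(report["sweep"]).to_csv(
            os.path.join(out_dir, f"{stem}_sweep.tsv"), sep="\t", index=False)
    return path
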