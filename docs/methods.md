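# Methods

## The problem

Extrastriate visual area V5/MT (with its neighbour MST) can be located
three independent ways: histologically, by the dense band of myelin
across its lower cortical layers; structurally in vivo, by
myelin-weighted MRI contrast (the T1w/T2w ratio or an MP2RAGE-like
image); and functionally, by fMRI responses to moving stimuli.  This
package implements the quantitative machinery for asking how well these
definitions coincide: constructing myelin-weighted surface maps,
thresholding them into "heavily myelinated" masks, defining the
functional hMT+/MST/V5-MT complex, measuring overlap with permutation
nulls, and validating areal measurements against stained section
series.  Because the underlying imaging data are not redistributable,
every stage is exercised on a synthetic cortical phantom whose ground
truth is analytic.

## Structural arm

**Ratio map.** Repeats of each modality are averaged voxelwise before
division (`ratio_map`), which cancels the shared receive-field bias;
voxels with near-zero T2w are flagged invalid rather than made
infinite.  Non-finite voxels anywhere are tracked in a validity mask
and excluded from all statistics, never zeroed.

**Depth sampling.** A map value at cortical-depth fraction *f* is the
trilinear interpolation of the volume at `white + f*(pial - white)`
(*f* = 0 white surface, *f* = 1 pial).  The working depth is chosen by
evaluating the grid *f* = 0, 0.1, …, 1 and keeping the fraction with
the greatest mean intensity over valid vertices (ties break toward the
smaller fraction, recorded deterministically).

**Thresholding.** Two protocol rules produce the dense-myelin mask:

* `top_fraction(f)` — keep vertices at or above the (1−f) quantile of
  the valid, non-excluded values (the macaque protocol, f = 1/3).  An
  alternative reading — a cut on the intensity *axis* at
  `min + (1-f)·range` — is available via `top_fraction_mode=
  "intensity_range"`; the quantile reading is the default.
* `mean_plus_k_sem(k)` — keep vertices strictly above
  `mean + k·sd/sqrt(n)` (the human protocol, k = 1; the sweep uses
  k ∈ {0, 0.5, 1, 1.5}).  *n* is the count of valid, non-excluded
  vertices of that hemisphere's map; excluded regions (e.g. a
  temporal-lobe artifact mask) are removed from both the reference
  statistics and the output.

Both rules are quantile/affine in the data, hence invariant to positive
rescaling.  Thresholds are computed per hemisphere.

**Areal measurement.** The contiguous dense-myelin region is the
edge-connected component of the mask containing a seed vertex; its area
is the sum of per-vertex areas (one third of incident triangle areas)
computed on the midthickness surface — the least biased single layer
when the protocol does not name one.

**Display clipping** (4%/96% of the intensity range) affects
visualization output only; no statistic consumes clipped maps.

## Functional arm

**Clusters.** Suprathreshold (`z > 2.3` by default) connected
components under configurable connectivity (6/18/26; default 18).  The
cluster-extent criterion is explicit rather than field-theoretic:
either a fixed voxel count, or the (1−α) quantile of the
largest-cluster null obtained from voxelwise sign-flip surrogates of
the z-map (default 1000, α = 0.05).

**Assignment rules.** hMT+ is the surviving full-field cluster whose
peak lies nearest a user-supplied anatomical anchor coordinate (the
"putative anatomical location" is observer knowledge the software
cannot infer).  MST is the union of ipsilateral-motion clusters that
intersect hMT+, each included in full even where it protrudes beyond
hMT+.  V5/MT is the retinotopically organized remainder: hMT+ voxels
whose response coherence exceeds 0.25, minus MST.  V5/MT ∩ MST = ∅ by
construction.

**Phase-encoded retinotopy.** Each voxel's time course is Fourier
transformed; amplitude and phase (convention `cos(2πft − φ)`) are read
at the stimulus-frequency bin, which must lie exactly on a DFT bin
(the run must span an integer number ≥ 2 of stimulus periods; anything
else raises a named error rather than smearing the estimate).
Coherence is the stimulus-bin amplitude divided by the root-sum-square
amplitude over non-DC bins.  Drift handling is spectral: bins 1–2,
where slow drift concentrates, are excluded from the denominator.  We
deliberately do **not** detrend in the time domain: removing a fitted
line from a finite cosine record perturbs the stimulus-bin phase
(the ramp has spectral content at every bin), whereas the spectral
exclusion leaves a pure tone's phase exact to machine precision.
Repeat runs are combined by complex (vector) averaging of spectra
before phase extraction, so consistent phases reinforce while noise
cancels; whether the original workflow averaged complex components or
phases is not documented — vector averaging is the standard choice and
is recorded here, not guessed as intent.

**Group maps.** Individual masks in a common space are binarized and
summed; vertices where the count reaches `min_fraction` of subjects
(≥ 50% by default, boundary inclusive) form the group mask.

## Correspondence statistics

* Whole-cortex correspondence: `100·|A∩B| / |A∪B|` (overlap counted
  once).
* ROI correspondence: same ratio restricted to the ROI.  The protocol
  phrase "total number of thresholded voxels present within the ROI" is
  read as the union-within-ROI; a Dice-like double-counting denominator
  is available via `denominator="sum"`.
* Percent-of-ROI-myelinated: `100·|ROI ∩ myelin| / |ROI|`.
* Permutation null: each iteration shuffles each map's valid values
  across vertices (shuffling intensities preserves the value
  distribution, hence mask sizes under quantile rules), re-thresholds
  with the same rule, and recomputes the statistic.  The p-value uses
  the add-one convention `(1 + #{null ≥ obs}) / (n_perm + 1)`, so p is
  never zero.  For two independent masks of densities p and q the
  expected null correspondence is `100·pq/(p+q−pq)`; the calibration
  test checks the simulated mean against this closed form.
* Threshold sweep: structural (mean + {0, 0.5, 1, 1.5} SEM) ×
  functional (z > {1.3, 1.8, 2.3, 2.8}) grid; every cell re-derives
  both masks from scratch, so the standard cell (1 SEM, z > 2.3)
  equals the standalone pipeline value exactly, and both margins are
  monotone by construction.

Functional ROIs live on the volume grid and myelin masks on the
surface; before any overlap statistic the ROI is projected to the
surface by nearest-voxel lookup at each vertex's sampling depth
(`project_voxel_mask`).  Inter-volume operations require identical
grids — registration is upstream — and refuse otherwise; a
nearest-neighbour resampler is an explicit opt-in.

## Histology arm

Intensity profiles are sampled along a pial-to-white path every 15 μm
with 6 perpendicular measurements per point (mean ± SD).  Smoothing is
robust locally weighted quadratic regression (rloess: tricube distance
weights, local second-degree polynomial, bisquare robustness
reweighting) — written in-house because available lowess
implementations are locally linear, and the local-quadratic model class
is what makes an exactly quadratic profile reproduce to 1e-6.
Profiles are compared with the two-sample Kolmogorov–Smirnov test on
the raw per-position means (smoothing is for display), asymptotic
p-value.

Per section, the densely myelinated length is the arc length along the
pial trace over which the stain probed `probe_depth_mm` below the
surface (default: the depth of the dense band, 0.7 of local thickness
configurable) is darker than the threshold.  Areas aggregate by the
trapezoidal rule between successive retained sections,
`Σ (l_i + l_{i+1})/2 · spacing`; zero-length end sections taper the
series.  Section thickness is carried as metadata but not added to the
trapezoid — the spacing between retained sections already spans the cut
tissue; an optional end-caps mode adds `thickness·(l_first + l_last)`.
Missing table cells stay missing (never zero); a single-value group
reports its SD as missing.

## The phantom

The synthetic cortex is a single folded sheet: a generalized cylinder
`z = A·sin(2πx/λ)` extruded along y, thickened vertically into a ribbon
of constant thickness (defaults: 30×30 mm sheet, 120×120 vertices,
2.5 mm thick, fold amplitude 1.5 mm, wavelength 15 mm, 0.5 mm voxels).
Two properties motivate this geometry: the white/pial displacement is
vertical, so the voxel-level depth fraction and surface-based sampling
agree exactly; and the sheet is developable, so geodesic distance is
`sqrt(Δs² + Δy²)` with `s(x)` the fold arc length — patch membership,
patch area and section chord lengths are therefore analytic, and
ground truth never depends on rendering settings.

The myelin field is a unit-peak Gaussian profile in depth (peak at
fraction 0.6, width 0.2) times a ×2 contrast inside a 5 mm-radius
patch — the V5/MT+MST analogue, whose default disc area (~79 mm²)
matches the scale of the measured complex.  Structural renders map
myelin to T1w (increasing) and T2w (decreasing) contrast with
independent smooth polynomial bias fields (≤ ±20%, default 10%) and
additive Gaussian noise (default sd 0.03 on unit-scale intensities);
the noiseless ratio is strictly increasing in true myelin.  Functional
renders place a Gaussian activation cluster (peak z = 6, scale
radius/2) at a configurable offset from the patch (default 2.5 mm —
"next to and partly overlapping"), restricted to the ribbon, over
N(0,1) background; the ipsilateral (MST) cluster is smaller and
displaced anteriorly.  Retinotopy renders give every truth-cluster
voxel a cosine response whose phase varies linearly across the cluster
(200 frames, 20 s period → 10 cycles; at this run length the
coherence-0.25 criterion excludes > 99% of pure-noise voxels).
Histology renders are parasagittal (constant-x) sections rasterized at
50 μm pixels with darkness increasing in myelin (silver-stain
convention), a 0.5 mm series spacing and 50 μm nominal thickness.

All randomness flows from one integer seed through per-renderer child
streams: a fixed seed gives byte-identical outputs, different renders
stay independent, and truth is geometry-only.

What the phantom does *not* emulate: MR physics (no Bloch simulation,
distortion, motion), physiological noise, multi-subject anatomical
variability, cortex-wide myeloarchitectonic structure (V1, somatomotor
strip), or stain variability across sections.  Passing recovery tests
therefore demonstrates the correctness of the measurement chain — not
robustness to the full variability of real data.

## Numerical choices and degenerate inputs

* Quantile-rule boundary ties are included; the SEM rule is strictly
  `>`; the intensity-range cut carries a 1e-12·range guard against
  floating-point ties.
* Depth-search ties break toward the smaller fraction (strict
  improvement required, 1e-12 margin).
* hMT+ anchor ties keep the earlier cluster in peak-z order (logged
  behaviourally as deterministic order).
* Empty results are legitimate where the protocol allows them (MST,
  cluster lists); operations that need non-empty input raise named
  errors (`EmptyMaskError`, `NoClusterError`, `AllInvalidError`, …).
* The permutation-extent criterion rounds down (int of the quantile),
  i.e. is slightly liberal at the margin; clusters must strictly
  exceed it.

## Problem sizes

Test and acceptance runs use reduced but structurally identical
conditions chosen to keep ground truth analytic and runs desk-scale:
80×80-vertex slab phantoms (4 mm patch) for recovery (20 seeded
replicates in tests, 10 in the acceptance script), 10⁴ vertices and
1000 permutations for null calibration, 200-frame runs for retinotopy,
and 100-voxel ensembles for phase-error statistics.
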