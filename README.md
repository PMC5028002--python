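# corticomap

Quantifying the correspondence between structural (myelin-weighted MRI)
and functional (motion-localizer fMRI) definitions of the V5/MT + MST
cortical complex, with a histological validation arm.

Area V5/MT is marked histologically by a dense band of myelin across
its lower cortical layers.  That band raises the T1w/T2w ratio and
MP2RAGE-like intensities enough to be seen in vivo, which suggests a
structural shortcut to localizing the complex without a functional
scan.  `corticomap` implements the measurement chain needed to test
that idea quantitatively, for researchers working on cortical
parcellation, myelin mapping, or structure-function alignment:

* **Myelin-weighted maps** — voxelwise `mean(T1w)/mean(T2w)` ratio
  images, sampled onto a cortical surface at the depth fraction with
  the strongest signal (searched over 0, 0.1, …, 1), and thresholded
  into "heavily myelinated" masks by either the top-third quantile rule
  or the mean + k·SEM rule with exclusion masking; contiguous-region
  surface area in native space.
* **Functional ROIs** — z-map cluster extraction with an explicit
  extent criterion (fixed or sign-flip permutation), hMT+ as the
  cluster nearest an anatomical anchor, MST from ipsilateral-motion
  clusters intersecting hMT+, and V5/MT from phase-encoded retinotopy
  by Fourier analysis with a coherence > 0.25 criterion.
* **Correspondence statistics** — whole-cortex and within-ROI overlap
  (`100·|A∩B|/|A∪B|`), percent-of-ROI-myelinated, pairwise overlap
  matrices, intensity-shuffling permutation nulls with add-one
  p-values, and a structural × functional threshold sweep.
* **Histology** — cortical intensity profiles (15 μm steps, n = 6
  lateral measurements), robust local-quadratic (rloess) smoothing,
  two-sample Kolmogorov–Smirnov profile comparison, densely myelinated
  length per stained section, and trapezoidal aggregation of lengths
  into areas across a section series.
* **A synthetic cortical phantom** — a folded cortical ribbon with a
  depth-dependent myelin field, an embedded high-myelin patch, offset
  functional clusters, periodic retinotopy responses, and
  silver-stain-like sections, all with analytic ground truth for
  parameter-recovery testing.

See `docs/methods.md` for the model, conventions, and limitations.

## Worked example

```python
import numpy as np
from corticomap import (
    PhantomSpec, make_phantom, render_structural, render_functional,
    ratio_map, optimal_depth_fraction, run_human, ClusterConfig,
)

spec = PhantomSpec(seed=1)                     # 30x30 mm folded sheet
surface, truth = make_phantom(spec)            # patch ~ pi * 5^2 mm^2
t1w, t2w = render_structural(surface, truth, spec)
zmap_full = render_functional(surface, truth, spec, "full_field")
zmap_ipsi = render_functional(surface, truth, spec, "ipsilateral")

struct = ratio_map([t1w], [t2w])
report = run_human(
    struct, surface, zmap_full, anchor=truth.cluster_center_world,
    zmap_ipsi=zmap_ipsi, depth_fraction="auto",
    cluster_cfg=ClusterConfig(min_extent=10), n_perm=999, sweep=False,
)
print(report["depth_fraction"], report["percent_hmt_myelinated"],
      report["p_value"])
```

prints

```
0.6 87.5 0.001
```

The depth search recovers 0.6 — the fraction where the phantom's myelin
profile peaks.  87.5% of the functionally defined hMT+ ROI carries
above-threshold myelin signal (the phantom renders the activation
cluster 2.5 mm from the myelin patch, so the markers overlap only
partly, as in real cortex), and that overlap beats all 999
intensity-shuffled nulls (p = 1/1000): the structural and functional
definitions coincide far above chance.

The same machinery reproduces published summary statistics: running
`summarize_areas` on the shipped macaque area table
(`corticomap.datasets.macaque_area_table()`) gives a pooled in vivo
area of 82.4 ± 8.9 mm² over 10 hemispheres, and `method_agreement` on
the four hemispheres measured with both methods gives r ≈ 0.996.

A command-line interface wraps the common stages:

```bash
corticomap make-fixtures --out fixtures/ --seed 3
corticomap myelin --t1w fixtures/t1w.nii.gz --t2w fixtures/t2w.nii.gz \
    --surface fixtures/surface.gii --rule top_fraction:0.333 --depth auto
corticomap compare --mask-a a.txt --mask-b b.txt --parent-size 14400
```

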