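# octsp — variable-size superpixel analysis of OCT RNFL maps

Glaucoma thins the retinal nerve fiber layer (RNFL). Spectral-domain OCT
devices image the full 6 × 6 mm region around the optic nerve head (ONH) —
a 200 × 200 grid of A-scans — yet the standard clinical measurement reduces
all of it to a few hundred samples on a single 3.4 mm circle (the
circumpapillary RNFL, cpRNFL). A focal wedge defect that lies mostly off
that circle can be missed entirely.

`octsp` implements a full-map analysis pipeline for researchers working on
structural glaucoma screening:

1. **Normative atlas** — per-pixel mean/SD of healthy RNFL thickness after
   *bundle-path normalization*: each eye's superior and inferior arcuate
   bundle peaks are detected on concentric circles and warped (a monotone,
   piecewise-linear angular stretch anchored at the temporal and nasal
   horizontals) onto the population-average bundle angles, removing the
   main source of healthy inter-eye variability.
2. **Deviation map** — per-pixel deficit below the atlas cutoff
   `mean − 1·SD` (bottom 15.9 % of the normative distribution), deliberately
   more sensitive than the conventional `mean − 2·SD` (2.3 %) rule.
3. **Feature map** — vessel shadows inpainted by bilinear interpolation,
   RNFL internal reflectivity (saturation-normalized per A-scan), and a
   combined scalar intensity `(T/T_max)·(w_r + (1−w_r)·R)`.
4. **Variable-size superpixels** — normalized-cuts spectral partition into
   100 initial segments, then recursive re-partition: a segment of size
   `S` with mean thickness `mT`, SD `sT` and mean deviation `D` is split
   into `N + 1` parts where

   ```
   S < 2·S_min             →  N = 0
   mT ≥ μ   (thick branch) →  N = round(0.2 · S/S_min · sT/σ)   if sT > σ else 0
   mT < μ   (thin branch)  →  N = round(1.2 · S/S_min · ((1 − mT/T_max) + D))
   ```

   capped at `⌊S/(2·S_min)⌋`, so damaged (thin, deviant) tissue is covered
   by many small superpixels and healthy tissue by few large ones.
5. **68 features + LogitBoost** — superpixel counts, moments, normalized
   histograms and global thickness averages feed a from-scratch LogitBoost
   (decision-stump) classifier, evaluated by 10-fold cross-validated ROC
   AUC and sensitivity at 85 % specificity, with DeLong tests against the
   cpRNFL baseline.

No public dataset exists for this protocol, so the package ships a
first-class synthetic generator (`octsp.synthetic`): double-hump angular
thickness profiles with radial decay, per-eye bundle jitter, an ONH disc,
random-walk vessel shadows, and configurable focal wedge defects and
diffuse thinning per clinical group (healthy / glaucoma suspect /
glaucoma).

## Worked example

```python
import numpy as np, octsp
import octsp.pipeline as pl, octsp.superpixel as spx, octsp.features as feat
from octsp.synthetic import sample_phenotype

grid = octsp.GridSpec.for_size(64)          # 6x6 mm field at 93.75 um/px
rng = np.random.default_rng(0)
normative = [octsp.generate_eye(sample_phenotype("healthy", rng), grid,
                                rng_seed=int(rng.integers(2**31)))
             for _ in range(46)]
atlas = pl.build_normative_atlas_from_eyes(normative)

eye = octsp.generate_eye(                    # superior-temporal wedge defect
    octsp.EyePhenotype(group="glaucoma",
                       defects=(octsp.Defect(65.0, 45.0, 0.8, 2.8),)),
    grid, rng_seed=42)
params = spx.SegmentationParams.for_grid(grid.n, seed=0)
th = feat.SizeThresholds.for_grid(grid.n)
res = pl.process_eye(eye, atlas, params, th)
```

prints (via the feature vector and cpRNFL baseline in `res`):

```
superpixels:            421
mean SP thickness (um): 59.5
mean SP size (px):      9.1
cpRNFL mean (um):       88.3
quadrants T/S/N/I (um): 96.7/74.6/61.9/119.8
mean thickness, scan excl. disc (um): 74.0
```

The deep superior wedge pulls the superior quadrant down to 74.6 µm while
the intact inferior bundle stays at 119.8 µm; the damaged sector is tiled
by many small superpixels, which is what the count/size/histogram features
hand to the classifier. `run_pipeline(PipelineConfig(...))` runs the whole
study — cohort generation, atlas, per-eye features, cross-validated
LogitBoost and the cpRNFL comparison — and returns the evaluation report.

A CLI mirrors the stages: `octsp synth-cohort`, `octsp atlas-build`,
`octsp superpixel`, `octsp pipeline` (see `octsp --help`).

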