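# Methods

This note records the models, conventions and numerical choices behind
`erbody`, in the order the pipeline runs.

## Image model and conventions

An `ImageVolume` is a `(C, Z, Y, X)` (optionally `(T, C, Z, Y, X)`) float
array in [0, 1]. Intensities are always divided by the dtype maximum (255
or 65535), never the observed maximum, so normalisation is monotone and
identical across images of one experiment. Pixel coordinates are 0-based
with x = column; centroids stay in pixel units and are converted to µm
only in displacement reports. Channel roles (`wall`, `erbody`, `t0`)
default to red/green/blue and come from the config, because TIFF metadata
for channel semantics is unreliable in practice. The default pixel size
(0.65 µm/px ≈ 0.42 µm²/px) matches a typical 20× confocal setting for
epidermal imaging; it is config-supplied metadata, not inferred.

## Maximum-contrast projection

Per pixel and slice we compute the sample variance (ddof = 1) in a
(2r+1)×(2r+1) reflect-padded window (default r = 3) and copy the
intensity from the slice with the largest variance; ties break toward the
smaller z, deterministically. Local variance rather than local range is
used because it is the criterion family of contrast-driven projection
methods and varies smoothly with noise. With `smooth_radius > 0`
(default 2) the argmax index map is median-filtered before sampling,
which removes salt-and-pepper slice switching in flat background; with
smoothing disabled every output pixel is exactly a copied input pixel
(tested). Mean- and max-intensity projections exist as comparison modes
only.

## Segmentation

**Cells.** The projected wall image is Gaussian-smoothed (σ = 1 px, to
keep shot noise out of the mask), adaptively thresholded
(pixel > local mean + offset; window 31 px, offset 0.02), closed and
hole-filled. Connected components of the complement (≥ 200 px, 4-connected)
seed a Voronoi propagation with per-pixel path cost
`1 + λ·|∇wall|` (λ = 10), computed as a Dijkstra-style minimum-cost flood
(`skimage.graph.MCP_Geometric`). At λ = 0 the implementation switches to
the exact Euclidean nearest-seed partition (distance transform), which is
the geometric oracle the tests pin. The outermost 4 px cannot seed a cell
(a bright frame at the field edge otherwise leaves a ring-shaped seed).
Cells under `min_cell_area_px` (default 5000) are dropped and the rest
relabelled 1..N; border-touching cells are kept but flagged.

**ER bodies.** Per cell, reporter pixels above the cell's
`erbody_quantile` (default 0.97, type-7 quantile) AND a global Otsu
threshold (256-bin, maximising between-class variance; ties resolved by
the scan order of bin edges) form the candidate mask. 8-connected
components are kept if their area lies in `[10, 2000]` px — a 5–10 µm
spindle at ~0.42 µm²/px spans tens to hundreds of pixels — and their mean
intensity exceeds `min_erbody_intensity` (default 0.15): ER bodies are a
dense, bright signal, and without an absolute floor the dim ER-network
web of body-free genotypes is called as spurious objects. Objects are
assigned to the cell containing their centroid (falling back to the
smallest adjacent cell id on a boundary pixel).

## Features

Forty features per object: 6 spatial, 8 intensity, 26 Haralick.

* Spatial: area (pixel count), perimeter (4-connected exposed edges),
  and mean/sd/min/max of boundary-pixel distances to the **binary**
  centroid. The reported location `m.cx`/`m.cy` is the
  intensity-weighted centroid — shape statistics should not shift with
  brightness, but a tracking location should.
* Intensity: mean, population sd, median absolute deviation, and the
  0.01/0.05/0.5/0.95/0.99 quantiles (type 7) under the mask.
* Haralick: grey levels are equal-width bins of [0, 1] (32 bins), so the
  grey map — and hence all 26 values — is invariant to any intensity
  change that does not cross bin edges. One symmetric GLCM per scale
  (offsets 1 and 2 px → suffixes `.s1`/`.s2`) pools the four directions
  0°/45°/90°/135° before statistics are taken (a single documented
  convention rather than averaging per-direction statistics; the
  brute-force oracle in the tests pins it). Entropies use log₂ with
  0·log 0 := 0. The sum-variance statistic is centred on the sum
  average. Degenerate matrices (zero marginal variance) return 0 for the
  correlation-type features. An object too thin to have any valid pixel
  pair at an offset gets 0 for that scale's block.
* Zernike moment magnitudes (orders ≤ 12, over the circumscribing disk,
  intensity-weighted) are computed on demand but excluded from the
  40-feature statistical block by default. On rasterised images the
  m ≡ 0 (mod 4) magnitudes of rotationally symmetric objects do not
  vanish exactly — square-lattice sampling is 4-fold anisotropic.

Objects touching the image border are excluded from the matrix: their
shapes are truncated. Cells are not excluded for touching the border —
their interior objects are intact.

**Aggregation.** `object` rows carry one object; `cell` rows the mean
over the cell's objects; the `image` row the mean over cell rows. A
retained cell with no detected objects still gets a cell row, profiled
over its reporter candidate mask (the above-quantile signal): body-free
cells then carry a low-intensity, low-texture profile that separates them
from body-bearing cells in the ordination, which is what makes
presence/absence the leading axis in mixed experiments.

## Multivariate analysis

Features are z-scored per stratum (sample sd; constant columns set to 0
and flagged). Dissimilarity is `d = 1 − r` (Pearson, range [0, 2]);
zero-variance profiles get distance 1 to everything, flagged. Classical
MDS double-centres −½D² and eigendecomposes; axis fractions are shares of
the positive spectrum, negative eigenvalues are reported but carry no
coordinates.

**k-means / AIC.** Best-of-restarts k-means (k-means++ seeding) over a k
interval. The selection criterion is the AIC of the spherical-Gaussian
*classification* likelihood (the X-means formulation),
`n·d·ln(WCSS/(n·d)) − 2·Σ n_k ln(n_k/n) + 2·k·(d+1)`: the
assignment-entropy term is what penalises splitting a coherent cluster.
A pure profile-likelihood AIC (`n·d·ln(WCSS/(n·d)) + 2·k·d`) was tried
first and rejected — its WCSS term falls faster than the penalty grows
essentially without bound, so it always selects the top of the k range.
Ties break toward smaller k.

**Constrained ordination.** What field pipelines run under the label
"CCA" on correlation distances is implemented as distance-based RDA:
principal coordinates of the Pearson dissimilarity, residualised
(together with the fixed-factor dummies) on the condition dummies;
constrained axes are the principal axes of the fitted values of the
multivariate regression of coordinates on the fixed factor. The
constrained fraction is constrained over total (conditioned) inertia; on
label-permuted data its expectation is (g−1)/(n−1), which the tests
check. Chi-square canonical correspondence analysis is not applicable to
a correlation dissimilarity. MDS axis percentages are reported under the
standard normalisation (share of the positive spectrum); conventions
that can exceed 100 % in total are not reproduced.

**PERMANOVA.** Pseudo-F from the Gower-centred distance matrix; because
centred rows sum to zero the intercept terms vanish and the between-group
sum of squares reduces to within-group block sums (verified against an
independent implementation to 1e-13). `p = (1 + #{F* ≥ F}) / (1 + m)`;
permutations are restricted within condition strata when conditions are
given (the conservative default when nuisance factors exist).

**FDA / MDA.** FDA is fitted by optimal scoring (indicator regression
with a 1e-8 ridge, eigen-decomposition of the scoring operator);
classification uses Mahalanobis distance to class centroids with
log-prior correction in the discriminant subspace, which makes the linear
case exactly LDA (pinned against scikit-learn on random data). MDA fits
per-class Gaussian mixtures (default 3 subclasses) with one shared pooled
covariance by EM from k-means initialisation; the log-likelihood trace is
recorded and must be non-decreasing; with one subclass it reduces to LDA.
Confusion matrices are row-normalised over true classes.

Per-feature one-way F tests use Benjamini–Hochberg step-up adjustment;
the default FDR cut-off is 0.05.

## Dynamics

The frame-0 reporter channel is copied into every frame's blue channel,
so each frame shows current (green) versus initial (blue) positions.
Tracks are anchored at frame 0 — no new tracks start mid-series — and
linked frame-to-frame by greedy mutual-nearest centroids within
`max_link_um` (default 3 µm); unmatched frames carry `matched = False`
and the last seen position.

Displacement is computed two ways: Euclidean `|p_t − p_0|` in µm (the
headline metric) and the cosine distance `1 − cos(p_0, p_t)` with
positions referenced to the enclosing cell's frame-0 centroid — an
image-origin cosine would depend on where the cell happens to sit in the
field, the cell-referenced form is translation-invariant. Zero-norm
reference vectors make the cosine undefined; such rows are flagged and
excluded from cosine summaries. Both series get a centred moving average
(default window 3, truncated at the ends).

Trends are LOESS curves (tricube-weighted local linear fit, span 0.75;
bandwidth = distance to the ⌈span·n⌉-th neighbour, so the infinite-span
limit is the OLS line) of mean displacement versus time per genotype. The
GLM `displacement ~ genotype + time` (Gaussian, identity link) is fitted
on all rows; genotype contrasts use Tukey's HSD with BH adjustment across
pairs. Crucially, the HSD standard error is computed over **per-track**
time-adjusted mean displacements: frames of one track share its frame-0
reference and are strongly dependent, and per-frame testing is
pseudoreplicated (measured null flag rate 0.16 at α = 0.05 versus ≤ 0.05
with track-level replicates). Genotypes with a single track are dropped
with a warning. Default contrast FDR cut-off: 0.01.

## Synthetic data

The generator emulates what the segmentation and statistics need to be
tested against, not optics:

* **Mosaic**: jittered-grid seeds, nearest-seed assignment under a smooth
  random warp (the jigsaw-puzzle wall pattern), walls dilated to ~3 px at
  intensity 0.8 over a noisy 0.02–0.06 background.
* **ER bodies**: per-cell counts and sizes by genotype preset — wild type
  5–15 spindles, major axis 5–10 µm, axis ratio 3–5; `long_few` ≤ 5
  spindles 1.5–2× longer; `small` axes ×0.6; `round_aggregate` ratio
  ≤ 1.5 with centroids clustered (σ = 3 px) around a per-cell centre;
  `none` empty; `slow` wild-type shapes with speeds ×0.2. Body centroids
  keep ≥ 4 µm separation (discrete organelles; `round_aggregate` exempt).
  The wild-type count range and speeds (0.3–0.5 µm/s) are package
  choices of realistic magnitude; no published per-cell census exists.
* **Rendering**: each body is a rotated anisotropic Gaussian whose FWHM
  equals its axis lengths, in focus at its own slice; defocus follows
  σ(z) = σ₀ + 1.2·|z − z_f| px with amplitude scaled to conserve
  integrated intensity, so local contrast peaks at the focal slice. A dim
  band-passed-noise web (amplitude 0.06) mimics the ER network; bodies
  integrate ≥ 5× brighter than equal-area web (tested). Noise is
  Poisson-like with variance ∝ intensity at `noise_level` (default 0.01).
* **Time-lapse**: constant per-object velocity plus Brownian jitter,
  reflecting at cell boundaries; the blue channel of every frame holds
  frame-0 green; ground-truth tracks are returned.

What the generator does **not** emulate: real PSFs, spectral
bleed-through, stage drift, photobleaching, 3-D ER topology, or stomata
and autofluorescence artefacts. Passing tests therefore demonstrate
algorithmic correctness against the stated model, not robustness to
every real-microscope artefact.

## Problem sizes and determinism

The validation suite and `scripts/acceptance.py` use a 25-cell 1024²
mosaic for segmentation recovery, 512² fields for projection and
tracking, 320² fields (4 presets × 8–10 images) for the end-to-end
phenotype ordering, 1000 null simulations (99 permutations each, n = 16)
for PERMANOVA calibration, and 100 replicates for dynamics power and
null rates — sizes chosen so ground truth is unambiguous and the whole
validation runs on a laptop. All randomness flows from explicit seeds;
the CLI derives per-stage seeds by stable hashing of stage names, so
adding a stage never perturbs another stage's stream, and identical
reruns are byte-identical.

## Known limitations

* The pipeline is 2-D after projection by design; volumetric shape and
  z-motion are not measured.
* Quantile-based ER-body candidate masks always select ~3 % of cell
  pixels; the absolute intensity floor is what prevents false objects in
  body-free cells, and its default (0.15) assumes reporter-dominant
  images normalised by bit depth.
* FDA's training confusion matrix on separable data is exactly diagonal;
  like any resubstitution estimate it is optimistic — use held-out data
  for honest error rates.
* The cosine displacement metric saturates for motion through the cell
  centroid and is reported alongside, not instead of, the Euclidean
  metric.
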