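# Methods

## The problem

Flow cytometry reads a fluorescence intensity for tens of thousands of
individual cells, but destroys the sample's spatial context and requires
detaching adherent cells. A standard fluorescence microscope can deliver a
comparable *per-cell* intensity readout if images are segmented into
single cells and each cell's mean intensity is treated as one "event".
`imflow` implements that image-based cytometry pipeline — segmentation,
whole-cell quantification, flow-style histogram analytics, and group
statistics — together with a matched synthetic-data generator, so that
every stage can be validated by parameter recovery against a known ground
truth. The motivating application is metabolic imaging of tumour cells
with a glucose-uptake probe (2-NBDG-like, green) and a mitochondrial
membrane-potential probe (TMRE-like, red).

## Pipeline model

1. **Normalization.** Integer images are divided by their dtype's full
   scale (255 or 65535), never by the per-image maximum: acquisition gain
   and illumination are fixed across an experiment, and per-image scaling
   would destroy cross-image comparability. Float images are clipped to
   [0, 1].
2. **Cropping.** A uniformly random, fully interior 1000×750 px window is
   cut from each frame (seeded; disabled automatically impossible — the
   caller turns it off for frames smaller than the window).
3. **Binarization** by global minimum cross-entropy (Li) thresholding.
   Intensities are quantized to `n_bins` (default 256) bin centers `g`
   with histogram `h(g)`; for every boundary `t` with non-empty sides the
   cost
   `−Σ_{g<t} g·h·ln μ_low(t) − Σ_{g≥t} g·h·ln μ_high(t)`
   is evaluated with cumulative sums and the minimizing boundary returned
   (ties break toward the smaller boundary; across a run of empty bins
   the cost is bitwise constant, so the tie-break pins the threshold to
   the left edge of the inter-mode gap). A constant image raises a
   degenerate-histogram error.
4. **Labeling and declumping.** 8-connected components; when declumping
   is on (default), seeds are local maxima of the Gaussian-smoothed
   (σ = 2 px) Euclidean distance transform separated by at least 9 µm
   (half the lower gate bound), and a watershed on the negated distance
   transform splits touching cells. Components that receive no seed keep
   a fallback marker so no object is silently dropped.
5. **Gating.** Objects touching the frame border are removed (partially
   imaged cells), then the equivalent-diameter gate
   `2·√(area/π)·pitch ∈ [18, 38] µm` is applied with inclusive bounds.
   The gate is expressed in micrometres; at the default pitch of
   1/2.7 µm/px this corresponds to roughly 49–103 px. Kept + removed
   always equals the input count and the gate is idempotent.
6. **Measurement.** Each cell's value is the arithmetic mean of *all* its
   pixels — the whole cell region, no nucleus/cytoplasm split, no
   background subtraction — reported both normalized and ×255 on the
   continuous 8-bit scale (no integer rounding, to avoid quantization
   bias in the density estimates).
7. **Histogram characteristics.** Per group × modality, a Gaussian-kernel
   density estimate with the normal-reference (Silverman) bandwidth
   `h = 1.06·s·n^(−1/5)` on a 512-point grid spanning
   [min − 3h, max + 3h]. Four characteristics: **peak** (grid argmax,
   ties to the smaller grid value), **FWHM** (distance between the
   outermost half-maximum crossings bracketing the global peak, linearly
   interpolated; a multimodal curve therefore gets one width — a
   documented limitation), **mean** and **median** (computed from the raw
   sample, since they describe the cell population rather than the
   smoothed curve). Group effects are expressed as
   `100·(group − control)/control` per characteristic.
8. **Inference.** Classical equal-variance two-sided Student's t between
   two groups, one-way ANOVA among three or more, at α = 0.05, with no
   multiple-testing correction by default (Bonferroni is exposed as an
   option). The statistical unit is the **per-image mean** for imaging
   (sample size = number of images, 10–20 per group) and the **per-tube
   mean** for flow (3–6 tubes per group). Pooling per-cell values would
   treat thousands of correlated cells as independent replicates and
   inflate significance; a pooled mode exists for sensitivity analysis
   only. Degenerate inputs follow fixed conventions: zero pooled variance
   with equal means gives t = 0, p = 1; with unequal means it is an
   error.
9. **Concordance.** For every (metric, group) key the imaging and flow
   relative changes are joined with a sign-agreement flag (zero agrees
   with anything) and the magnitude ratio |flow|/|imaging|, alongside the
   two modalities' p-values.

## Synthetic-data generator

The generator emulates the study conditions end to end: two or more
treatment groups per channel, ~1 µm optical resolution (pitch
1/2.7 µm/px), 15 images per group of 1200×900 px (so the 1000×750 crop
window fits inside), 65 cells per frame (~1000 cells per condition), and
20,000 flow events per group split across 4 tubes.

* **Cell intensities** are lognormal with log-scale σ = 0.22 (CV ≈ 22%,
  a typical unimodal right-skewed fluorescence histogram); group means
  are the channel's base mean times a per-group fold change (default
  control 1.0, treated 1.3). Draws at or above 0.95 are redrawn
  (saturation guard; <0.2% of the mass at the default CV). A Gaussian
  family is available to stress the KDE metrics.
* **Geometry.** Cells are non-overlapping disks placed by seeded dart
  throwing, largest-first, with a 6 px rim clearance so PSF blur cannot
  merge neighbours. Default diameters are uniform on 19–37 µm — strictly
  inside the 18–38 µm analysis gate, because rasterization and blur
  perturb the measured equivalent diameter by up to ~1 px and the
  noise-free recovery contract is *exact* count equality. Disk shape is a
  deliberate simplification: the analytics under test consume only areas
  and mean intensities.
* **Channels.** Presets give the glucose-like channel a mean cell
  intensity of 0.25 with microscopy SBR 20 and flow SBR 10, and the
  MMP-like channel 0.30 with microscopy SBR 80 and flow SBR 1000
  (SBR = mean in-cell intensity / mean background intensity).
* **Background calibration.** A flat background of `mean/SBR` would be
  biased once the PSF bleeds cell flux outward — at SBR 80 the
  mask-measured ratio would fall >20% short. The generator therefore
  renders a fixed noiseless probe layout (internal constant seed, so the
  calibration depends only on the parameters) and secant-adjusts the
  background until the measured ratio is within 0.5% of target, in at
  most 6 steps.
* **Optics and noise.** Gaussian PSF with σ = 0.5 px (mild blur,
  consistent with ~1 µm resolution at this sampling) and a Gaussian
  approximation to Poisson shot noise, variance = signal/5000 full-scale
  photons, plus additive read noise σ = 0.002; values are clipped to
  [0, 1]. Exact Poisson sampling is deliberately not used: at these
  photon counts the Gaussian approximation is indistinguishable and
  keeps rendering fast and exactly reproducible across platforms.
* **Flow events** are drawn from the *same* per-group distribution, with
  multiplicative lognormal measurement noise (σ = 0.05, mean-preserving)
  plus the SBR-derived baseline `control_mean/SBR_flow`, clipped at full
  scale. Because the baseline is additive, a +30% fold change appears in
  flow as ≈ +30%·m/(m + baseline) ≈ +27% for the glucose channel — the
  small attenuation both modalities' tests tolerate.

**What the generator does not emulate:** real cell morphology (elliptical
or touching-in-3D cells), uneven illumination and vignetting, focus
drift, autofluorescence structure in the background, dead-cell
subpopulations, and instrument-specific flow artefacts (spillover,
doublets). Passing recovery tests therefore demonstrates correctness of
the *analysis* under the stated model, not robustness to every real-world
imaging pathology.

## Reproducibility and numerics

One master seed fans out to per-stage and per-image child streams through
`numpy.random.SeedSequence`, so stages re-run individually are
bit-identical to the end-to-end run. CSV output uses a frozen dialect
(comma, '.' decimal, `\n`). The KDE is evaluated by direct chunked
summation (no FFT binning), so densities are deterministic to float64
round-off. Threshold ties, KDE peak ties and FWHM edge cases (density
still above half-maximum at the grid edge) all have fixed, documented
resolutions.

Problem sizes in the test suite are the default study conditions above;
unit tests use smaller frames and cell counts where they exercise a
single operation rather than the study design.

## Known limitations

* FWHM is single-peak by construction; bimodal populations get one width
  spanning all lobes above half the global maximum.
* The FCS reader covers list-mode `$DATATYPE F/I` single-segment files
  only — no compensation, analysis segments, or FlowJo workspaces.
* Diameter gating replaces the original workflow's manual rescue of
  out-of-range objects with exclusion plus a reported removed-count; a
  fully automated pipeline cannot reproduce a human-in-the-loop step.
* The declumping watershed uses shape (distance-transform) seeds; an
  intensity-seeded variant is not implemented.
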