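# Methods

## Synthetic field generator

`eduscan.simulate` emulates scanned chamber-slide fields of roundish
adherent-cell nuclei as they appear in DAPI/Flag/EdU three-channel
epifluorescence:

- **Geometry.** Nuclei are discs with a flat top and a Gaussian edge
  falloff (`edge_sigma`, default 1 px), truncated at 3 `edge_sigma` so each
  nucleus has compact support and per-nucleus intensities are analytic.
  Centers sit on a jittered grid (spacing `spacing_factor × radius_mean`,
  default 2.7 × 8 px; jitter ±15% of spacing), which makes placement
  feasible by construction at realistic densities while looking irregular.
  A `touching_fraction` (default 0.1) of cells is planted as fused pairs:
  equal-radius sisters at 0.7 × (r₁+r₂) = 1.4 radii center separation, a
  two-lobe geometry whose ground-truth split is well defined and which the
  watershed stage must resolve.  Overlapping contributions combine by
  maximum, as saturating stains do.
- **Intensities.** Per-cell channel amplitudes are Gaussian draws:
  DAPI ~ N(8000, 800); Flag bimodal over cells — N(6000, 600) if
  transfected (probability `transfected_fraction`, default 0.4) else
  N(500, 600); EdU N(7000, 500) if proliferating else N(400, 500), with
  per-class EdU probabilities (default 0.2 for transfected, 0.5 for
  control-like cells — an effect size typical of a strong proliferation
  suppressor).  A smooth background (random-orientation ramp plus a
  half-period sinusoid, peak 300) and additive Gaussian noise (sd 100, so
  foreground SNR ≈ 80 at the defaults; SNR can be degraded arbitrarily via
  `noise_sd`) are added to every channel.  All values are float in memory
  and quantized to 16 bit only on TIFF export, matching camera bit depth.
- **Determinism.** One `numpy` Generator seeded from the single config
  seed drives placement, class draws, amplitudes, background and noise, so
  identical configs give bit-identical fields on any platform.
- **Scale.** The default pixel size of 0.65 µm/px corresponds to a 10×
  slide-scanner objective; it affects only reported physical areas.  No
  acquisition optics (PSF, vignetting, photobleaching) are modeled, and
  fields are 2-D: passing tests show recovery of the assumed statistical
  structure, not robustness to optical artifacts, debris, or irregular
  nuclear shapes in real scans.

## Nucleus detection

- **DoG filter.** `blur(σ_low) − blur(σ_high)` with defaults σ_low = 1 px
  (noise suppression) and σ_high = 15 px (background estimation, roughly
  two nucleus radii).  Standard band-pass semantics are implemented; both
  sigmas are exposed.  Reflections at borders use nearest-edge padding.
- **Thresholding.** 1-D k-means on pixel intensities.  For k = 2 the
  optimum is found exactly by exhaustive search over all ordered splits of
  the sorted unique values using prefix sums (identical objective to
  Lloyd's algorithm at convergence, but deterministic and exact).  For
  k > 2 an exact dynamic program runs on the unique values, quantized to a
  1024-bin histogram when there are more than 1024 of them.  The brightest
  cluster alone is foreground; the returned threshold is the midpoint
  between the clusters' adjacent boundary values.  A constant image has no
  threshold and raises `DegenerateImageError`.
- **Hybrid watershed.** Euclidean distance transform of the foreground
  mask, Gaussian-smoothed (σ = 0.5 px), h-maxima with h = 0.5 px as
  markers, marker-controlled watershed on the inverted distance map
  restricted to the mask.  The h and smoothing defaults were calibrated on
  the synthetic generator: they split planted fused pairs (saddle depth
  ≈ 2 px at the default geometry) without fragmenting single nuclei.  If
  the mask is too thin to produce any marker, connected components are
  returned.  Flooding ties are resolved by scikit-image's deterministic
  raster-order processing.
- **Region filter.** Candidates need mean source-image intensity ≥
  `min_mean_intensity` (default 1000, calibrated between the synthetic
  background ceiling and the nuclear signal) and area ≥ `min_region_area`
  (default 40 px; the size floor suppresses single-pixel noise regions).
  Survivors are relabeled contiguously in ascending original-label order.
  Border-touching regions are kept by default (`clear_border=False`).

## Cell classification

- Flag is measured on the Flag channel band-passed with the same DoG
  parameters as segmentation, averaged over each nucleus's pixels
  (optionally dilated by `flag_dilation_px` via nearest-label assignment,
  default 0); EdU is averaged on the raw channel over nucleus pixels.
- The transfection threshold is an automatic two-component split
  minimizing within-class variance, computed on log intensities when all
  values are positive and on raw values otherwise (band-passed means can
  be negative).  If the two components' means are separated by fewer than
  3.0 pooled within-class standard deviations the distribution is treated
  as unimodal — a two-means split of a single Gaussian produces ≈ 2.7 by
  construction, so the criterion only fires on genuine bimodality — and a
  configurable percentile fallback (default 75th) is used with a warning.
  A manual threshold always overrides.
- Decision rules: transfected ⇔ `mean_flag > flag_threshold` (strict) and
  `mean_flag ≥ flag_min_intensity`; proliferating ⇔
  `mean_edu ≥ edu_min_intensity` (inclusive, default 2000 — calibrated
  between the synthetic EdU-negative ceiling and positive mode).  EdU
  positivity deliberately uses a fixed minimum rather than a distribution
  split, mirroring the minimum-intensity post-processing used for nuclei.
- In multi-condition runs the pipeline pools Flag means within each
  condition and selects one threshold per condition, matching how a
  threshold is chosen once per experiment.

## Statistics

- Proliferation rate: double-positive / transfected; control conditions
  use EdU-positive / total.  Zero denominators raise with the condition
  named.
- Group comparison: Levene's test (center = mean) first; if P > 0.05,
  one-way ANOVA then Tukey HSD (scipy's studentized-range implementation,
  which matches statsmodels on balanced designs — cross-checked in the
  test suite).  If Levene fails, the report records the violation and
  returns descriptive statistics; no silent switch to a different test.
  When every group has zero variance Levene's statistic is 0/0; variances
  are then trivially equal and P is reported as 1.
- Two-group comparisons use the unpaired two-tailed t-test, pooled
  variance by default (consistent with the Levene prescreen), Welch by
  flag.  Two degenerate groups with equal means return P = 1 by
  convention.
- Stars: `*` P < 0.05, `**` P < 0.01, `***` P < 0.001.

## Auxiliary quantifications

- **ΔΔCt.** Ct replicates aggregate by arithmetic mean.  ΔCt = mean
  Ct(target) − mean Ct(reference, default RPL37A) per condition;
  ΔΔCt = ΔCt(control) − ΔCt(condition); fold change = 2^(−ΔΔCt).  The
  subtraction order is the reverse of the common Livak convention and is
  implemented exactly as stated; the module documents the consequence
  (fold > 1 when the condition's ΔCt is higher).
- **Co-IP densitometry.** raw = tead / (flag / igg); values normalize to
  the positive control.  Non-positive flag or IgG signals are rejected.
- **Spreading.** Fractions of cells with area ≤ / > the 120 µm² cutoff;
  ties count as "below" (the boundary is otherwise undefined).
- **Alanine cassettes.** A region tiled by consecutive length-L all-alanine
  cassettes; the region length must divide evenly (the canonical α9 scan:
  49 residues, 7 cassettes of 7, the first covering residues 376–382).
- **Docking contacts.** Minimum atomic distance between a model and the
  receptor's reference residue stretch (default 376–382), all atoms by
  default with a Cα-only option; a model is in contact when the distance
  is strictly below the cutoff (default 10 Å).  PDB parsing (Biopython)
  drops HETATM and non-primary altlocs by default.

## Problem sizes and verification

Tests and the acceptance script run on synthetic fields of 512 × 512 px
with 300–500 nuclei and on 3-replicate, 2-condition designs (sizes chosen
to match the statistical structure of a typical chamber-slide experiment
at tractable cost).  At these conditions the detector recovers nucleus
counts within ±5% (exactly, in noise-free fields), splits ≥ 70% of planted
fused pairs, recovers the transfected fraction and per-class proliferation
rates within ±0.05, and the Levene→ANOVA→Tukey chain detects a 0.5-vs-0.2
rate difference in ≥ 95% of seeded runs.  Independent oracles used in the
tests: dense direct convolution (DoG), exhaustive split-point search
(k-means masks), per-label brute-force aggregation (region filters and
distances), nearest-maximum flooding (watershed), permutation resampling
(t-test), closed-form F and statsmodels Tukey (ANOVA chain).

## Known limitations

- Nuclei are convex discs; crescent or lobed nuclei, apoptotic debris and
  mitotic figures are not simulated, and the watershed's behavior on them
  is untested.
- Fused clusters of three or more nuclei occur only incidentally; the
  split-rate guarantees cover pairs.
- The transfection threshold assumes a (log-)bimodal marker distribution;
  very low transfection efficiencies (< ~5%) will often take the
  percentile fallback.
- Physical areas assume square pixels and a single magnification per run.
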