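# Methods

## Scope and model

The package quantifies three linked quantities for yeast strains displaying
a GFP-tagged enzyme on the cell wall:

1. **Displayed fraction** — per-cell ratio of bleed-corrected integrated
   GFP in the wall region to total corrected cell GFP, from two-channel
   micrographs (GFP + concanavalin-A wall stain).
2. **Abundance** — molecules/cell from bulk GFP/OD600 readings via a
   log-log standard curve against reference strains of known abundance,
   converted to molarity at a stated cell density
   (nM = molecules/cell × cells/mL × 10³ / N_A × 10⁹).
3. **Whole-cell catalytic constants** — V_max and K_m from endpoint
   chromogenic assays, with k_cat = V_max/[E] taking [E] from the displayed
   abundance chain, so k_cat has an explicit provenance (displayed / total /
   purified).

### Ring geometry

Each segmented cell is partitioned by erosion depth: ring −k (k = 0…9) is
the set of pixels removed by the (k+1)-th one-pixel erosion and not the
k-th; whatever survives ten erosions is the CORE; rings +1…+4 are successive
dilation shells outside the mask, contested pixels going to the nearest
cell. With the default 3×3 cross structuring element the erosion depth of a
pixel equals its city-block distance to the background minus one, so the
implementation uses a chamfer distance transform; the test suite proves
equivalence against brute-force iterated erosion on a battery of masks
(disks, ellipses, rectangles, diamonds, random blobs) up to 41×41 px and on
hypothesis-generated random masks. A 3×3 square element (chessboard metric)
is available via config. Cells whose outward rings would leave the frame are
excluded so outside rings are always complete.

Wall signal is integrated over rings 0…−9 by default (the wall-stain profile
spans that band); a 9-ring variant (0…−8) is available via `wall_span` for
sensitivity analysis, since the innermost one-pixel ring can also be read as
part of the core.

### Bleed-through correction

Intracellular GFP leaks into the wall rings through the PSF. The correction
is ring-level, not a deconvolution: per-ring bleed factors FB_i are the mean
over intracellular-control cells of the background-corrected ring median
normalized by the background-corrected CORE median (per-cell-then-mean;
median aggregation is available). Fitting requires ≥ 40 valid control cells
by default. Per-cell correction subtracts GFPmed_inner · FB_i · P_i from the
background-corrected ring integral. Negative corrected ring values are kept
in the numerator sum — flooring them would bias the intracellular null
upward — and only the final reported fraction is clamped to [0, 1]; the raw
value is preserved alongside.

Cell validity differs by stage: profile normalization requires a CORE median
above ε_floor = 10⁻⁶ × image dynamic range (guards division without
discarding dim cells), while display quantification only requires a positive
total corrected intensity — a pure-surface cell legitimately has a CORE
median at background and its near-zero bleed term is subtracted as-is.
Invalid cells are excluded, not zero-filled.

### Calibration, growth, kinetics

The GFP standard curve is ordinary least squares of log10(GFP_norm) on
log10(molecules/cell); a single line across 2.3 × 10³–7.5 × 10⁵
molecules/cell is only plausible on log axes, though a linear-space fit is
offered for sensitivity analysis. Fitting requires ≥ 3 distinct abundances;
predictions outside the fitted GFP_norm range carry an extrapolation flag.
Negative-control handling is by ratio (GFP_norm), not subtraction.

Growth rate is the maximum 5-point sliding-window slope of ln(OD600)
(75 min at 15-min sampling — spans the exponential phase without smoothing
it away); fitness is the ratio of a strain's rate to the parental strain's.

pNP quantification uses Beer–Lambert with ε(pH) from a Henderson–Hasselbalch
model ε_max/(1+10^(pKa−pH)) fitted to a packaged reference table
(`data/pnp_extinction_synthetic.csv`, a synthetic stand-in generated from
the model at literature pKa 7.15 and ε_max 18 000 M⁻¹cm⁻¹; users with
measured coefficients should fit their own table). The measurement
wavelength is carried as a tag (default 405 nm). The paired
substrate-autohydrolysis control is subtracted before conversion; negative
net absorbance floors at zero with a warning. Michaelis–Menten fitting is
unweighted nonlinear least squares on individual replicate points (no
averaging), initial guesses V_max = max(v) and K_m = S nearest half-max,
parameters bounded positive. Path length has no default and must be given
for real plate geometries; synthetic assays use 1 cm.

## The synthetic-data generator

The generator's role is ground truth, not photorealism. Cells are
non-overlapping disks (ring peeling is shape-agnostic, so circles suffice);
the wall stain is a Gaussian shell in distance-to-boundary space centred
4 px inside the border (σ 1.5 px, truncated at 3σ and at the border), and
the reporter channel mixes a cytoplasmic fill and a surface shell weighted
(1−f) : f by the cell's true displayed fraction. Distance-to-boundary is
measured in the same city-block metric as the analysis peel, which makes the
shell's peak ring and the core's emptiness exact by construction.

Two choices matter for realism of the bleed:

- The cytoplasmic fill edge sits `fill_margin` = 4.4 px inside the
  segmented border (with a one-pixel partial-volume edge). Physically the
  plasma membrane lies inside the cell wall, so intracellular protein never
  reaches the outermost rings — the same offset that separates a
  membrane-protein peak (−5) from the wall-stain peak (−4).
- Bleed is produced mechanistically by Gaussian PSF blur (σ 0.8 px) of that
  fill, never imposed; `fb_true` is measured from a noiseless
  intracellular-only render of the same scene, so FB estimation is
  validated against truth rather than against its own assumptions.

This geometry puts roughly half of the inner signal in ring −4 and ~90% in
ring −5 of intracellular controls, the regime the method operates in.
Remaining defaults: 512×512 scenes (700×700 in the recovery suites), 30–50
cells of radius 14–20 px (chosen to make a 10-ring peel meaningful; pixel
size is not modelled), background 100 ADU, Gaussian read noise σ 10 ADU
(Poisson optional), per-cell total GFP 2 × 10⁵ ADU, wall-stain total
3 × 10⁵ ADU. A single RNG stream per dataset; identical seeds give
bit-identical output.

Plate-reader tables place reference strains log-uniformly over
2.3 × 10³–7.5 × 10⁵ molecules/cell with log-normal noise (σ 0.05 dex) around
a unit-slope line, plus autofluorescent negative-control rows. Kinetic
assays span 0.07–134.1 µM substrate (12 log-spaced points, triplicate,
10 min endpoint) with a 0.005 µM/min autohydrolysis background, absorbance
read noise σ 0.003, and paired buffer-only control rows. Growth curves are
logistic (default µ ≈ 0.4 h⁻¹, OD₀ 0.02, capacity 1.5, 15-min sampling) with
multiplicative noise.

What the generator does **not** emulate: ovoid or budding cells, focal
drift, spatially varying background and illumination, wall-thickness
heterogeneity, camera gain nonlinearity, pipetting errors correlated across
a plate, or substrate depletion during the endpoint assay. Passing recovery
tests therefore shows the *estimators* are unbiased under the stated imaging
model, not that segmentation or FB transfer is robust to all real-data
pathologies; on real images the segmentation thresholds and size filters
must be set per dataset.

## Numerical and design notes

- Segmentation recipe: Gaussian smooth (σ 1) → global threshold → closing →
  hole filling → 1-px shrink (compensates the systematic outward bias of
  thresholding a blurred shell) → distance-transform watershed →
  size filter (defaults 200–5000 px², bracketing the synthetic radii; must
  be user-set for real data) → border exclusion. The default threshold is
  the triangle method: with a background-dominated histogram Otsu cuts
  through the upper shell and shrinks masks by ~2 px; Otsu and fixed values
  remain available.
- Peak localization ties break toward the outermost ring; a peak at the
  innermost rings is read as "no surface peak" (intracellular pattern).
- The +1 outside ring is computed and reported in profiles but never enters
  FB or display-fraction arithmetic.
- Background is the median over pixels outside all masks and outward rings.
- Calibration problem sizes in tests and the acceptance script (200-cell FB
  sets, 200-cell recovery sets per strain, 100 Michaelis–Menten replicates,
  30 reference strains) were chosen to match the scale at which the method
  is typically operated while keeping the suites quick to run.
- The unit audit for molarity uses Avogadro cancellation
  (6.022 × 10⁵ molecules/cell at 10⁸ cells/mL = 100 nM exactly).

## Known limitations

- The FB model assumes control strains share the imaging geometry (radius
  distribution, PSF) of the assay strains; a mismatched PSF biases the null.
- Ring peeling in the city-block metric is slightly anisotropic (diagonal
  shells sit ~√2 closer in Euclidean terms); profile peaks are reported in
  peel coordinates, consistent between generator and analysis but not
  identical to Euclidean depth.
- Single-endpoint rates assume linearity over the incubation; no
  progress-curve or inhibition models are provided.
- The growth-rate estimator's max-window design is upward-biased under heavy
  multiplicative noise; replicate averaging is the recommended mitigation.
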