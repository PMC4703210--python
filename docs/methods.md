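# Methods

This note documents the models, parameters and numerical choices behind
`sicklestain`, and what the synthetic-data tests do and do not establish
about real scans.

## The rendering model behind the synthetic stains

The generator emulates what the scorer sees, not the fluid mechanics of
wicking (no Lucas–Washburn transport, buffer chemistry or stain aging).
One stain is a two-compartment radial field:

- The droplet deposits hemoglobin mass proportional to
  `hb_conc · droplet_volume / (1 + dilution_ratio)` — only the blood
  fraction of the mixture carries Hb. `hb_conc` is in g/dL,
  `droplet_volume` in μL, `dilution_ratio` is buffer volumes per blood
  volume (default 1:10, 20 μL).
- A fraction `p = percent_hbs/100` of that mass is HbS. Mass partitions
  between the center disk (radius `r_center_mm`, default 2.5 mm) and the
  ring (out to `r_outer_mm`, default 7.5 mm) with two leak terms:
  center share `(1−δ)p + ε(1−p)`, ring share `(1−ε)(1−p) + δp`, with
  `ε = leak_center = 0.15` (soluble Hb retained among the fibers of the
  center spot) and `δ = leak_ring = 0.05` (HbS escaping outward). The
  shares sum to one, so total deposited signal is exactly conserved and
  independent of `p`.
- Each compartment renders as a uniform intensity = share × mass / area,
  with areas measured on the pixel grid (so conservation is exact in the
  continuous field), times a gain of 150 intensity units per
  (g/dL·μL/mm²) chosen to keep the full clinical range (6.2–16.5 g/dL,
  0–100 %HbS) below 8-bit saturation. Renderings that would clip more
  than 1% of stain pixels are refused (`SaturationError`), because
  clipping breaks the linearity both indices rely on.
- The field is smoothed with a Gaussian of σ = 0.2 mm, background (default
  10) and i.i.d. Gaussian pixel noise (default SD 3) are added, and the
  result is clipped to [0, 255] and quantized to 8 bits. Only the Blue
  channel carries signal (`B = 255 − intensity`); Red is constant 255 and
  Green tracks half the intensity, giving plausible-looking red stains.
- The outer radius scales with `sqrt(droplet_volume · dilution_ratio)`
  relative to the 20 μL / 1:10 reference (two-dimensional spreading), so
  metering-jitter experiments (ratios 1:8–1:12, droplets 16–24 μL) perturb
  geometry as well as amplitude.

Default cohort draws mirror a three-genotype validation study
(18 AA / 17 AS / 20 SS), with %HbS uniform in the genotype bands
(AA = 0, AS 38–42%, SC 41–50%, SS 74–93%, Sβ⁺ > 60%) and total Hb uniform
in genotype-appropriate ranges (SS and Sβ⁺ anemic at 6.2–11 g/dL, AA/AS in
the normal range, union spanning 6.2–16.5 g/dL). Sβ⁺-thalassemia is
intentionally indistinguishable from SS in the S-index domain (high %HbS),
so no Sβ⁺-specific call is attempted.

**What passing tests on this generator do not show:** real stains have
illumination gradients, scanner color profiles, paper texture, irregular
stain outlines and temporal drift, none of which are modeled. Perfect
separation (AUC 1.00 everywhere at noise 0) is a property of these clean
conditions; a real study observed AUC 1.00 only for AA-vs-carriers, with
slightly imperfect SS separation. Published per-sample results (confusion
matrix cells, per-rater mean ± SD tables, an inter-rater kappa of 0.91)
depend on that study's samples and raters and are not reproducible from
synthetic data; the package reproduces the *machinery*, and its printed-CI
checks, exactly.

## Detection and geometry

Sheets are thresholded at `median + 5·MAD` (robust to background texture),
closed morphologically over 0.3 mm, and connected components with
equivalent diameter in 8–25 mm that do not touch the border become stains;
components wider than 1.5× the maximum diameter raise a merged-stain
warning. Centers are intensity-weighted centroids (sub-pixel).

Region radii can be assigned two ways:

- **fixed** (default): every stain gets the nominal radii (2.5 / 7.5 mm),
  the way a readout overlays constant dashed circles on each stain.
- **profile**: per-stain estimation from the radial intensity profile
  (0.25 mm bins): `r_outer` is the last radius whose bin mean stays above
  `background + 0.1·(peak − background)`; `r_center` is where the profile
  falls below `background + 0.5·(plateau − background)` (plateau = inner
  1 mm mean), clamped to `[0.5 mm, r_outer − 0.5 mm]`.

Fixed is the default because the profile rules have a limited validity
range under this rendering model: the ring of a high-%HbS stain sits at
~1.5% of the center peak (below the 10% rule, collapsing `r_outer`), and an
HbS-free stain's ring exceeds half its center contrast (so the 50% rule
never fires at the spot boundary). Within 20–60 %HbS the estimator recovers
both radii to within one bin and is exercised in tests.

## Index computation

Indices use raw intensities with no background subtraction (the definitions
name raw means; an optional subtraction argument exists but defaults off).
Region membership uses pixel-center distance with a half-open ring
`(r_center, r_outer]` so every pixel belongs to exactly one region. The
"5 mm from the center" circle of the C-index is realized as an annulus of
half-width 0.25 mm, since a zero-width circle contains no pixel centers.
A zero ring mean is reported as an undefined-index error, distinct from
domain errors. DPI converts px ↔ mm (1 mm = dpi/25.4 px).

Note that with a nonzero paper background the measured S-index is only
approximately Hb-concentration-invariant: the background enters both means
additively. The exact scale-invariance property holds for the intensity
field above background and is asserted in tests by scaling intensity maps
directly.

## Classification and calibration

S-index cutoffs are fitted, not hard-coded, because the assay has no
universal numeric cutoffs (they depend on paper, buffer, scanner): each
binary split (AA vs rest, SS vs rest) maximizes Youden's J over midpoints
between adjacent distinct scores, breaking ties toward higher specificity
and then toward the higher cutoff. Boundary S-index values classify to the
less severe genotype — deterministic and conservative for trait-vs-disease.
On two-class AA/SS data both splits coincide and the AS band collapses to
zero width. Fitted cutoffs can be pinned in a config file for reproducible
deployments.

The C-index decision direction (low = SC) encodes the lower total Hb of
HbSC disease. The cutoff helper targets 100% SC sensitivity (screening
regime: never miss SC, accept false positives); with overlapping Hb ranges
this reproduces the high-sensitivity / low-specificity behaviour expected
of the metric. Whether one global or per-panel C-cutoff is appropriate is
left to configuration.

Calibration is OLS of %HbS on S-index; `residual_sd` is the ddof=1 SD of
fit residuals. Predictions clamp to [0, 100]. Recovery is validated over
100 simulated dilution series (4 SS donors at 74.9–90.0 %HbS × 11 volume
fractions, n = 44 per series, y-noise SD 6 %HbS, true slope 12): the mean
fitted slope lands within 2% of truth.

## Evaluation statistics

- Sensitivity = TP/(TP+FN), specificity = TN/(FP+TN), PPV = TP/(TP+FP),
  NPV = TN/(TN+FN), accuracy = (TP+TN)/total. Zero-denominator metrics are
  flagged undefined, never silently 0.
- Wilson score intervals use z = 1.96 exactly (the conventional printed
  value, not the full-precision 0.975 quantile; configurable). Two
  effective-n conventions are provided: **standard** (n = the metric's own
  denominator) and **total_n** (n = all samples in the comparison, every
  metric). Published validation reports in this assay family print
  intervals reproducible only under total_n — verified against eleven
  independent printed endpoints — so both modes exist rather than guessing
  intent; the default for reports is total_n. Percents format with half-up
  rounding to one decimal.
- ROC curves sweep all distinct score values (positive = score above
  threshold); the trapezoidal AUC equals the Mann–Whitney statistic with
  ties counted ½, which is property-tested exactly.
- Fleiss' kappa requires a complete rectangular subjects × raters table
  (no generalized weighting for ragged data); the tally is done in-package
  and the statistic is computed through statsmodels, cross-checked against
  a hand-worked table in tests.

## Problem sizes and determinism

The default validation-scale problems are deliberately small: 55-stain
cohorts rendered at 300 dpi on 7×8-stain sheets (~2 s end to end), 100
dilution series for calibration, 200 random instances for the AUC oracle
check, and a 2000-subject table for the kappa null. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; identical
inputs and seeds give bit-identical images and byte-identical CSVs.

## Known limitations

- No scanner color-profile or illumination-gradient correction; only the
  Blue channel is used.
- Per-stain geometry estimation is unreliable outside moderate %HbS (see
  above); use fixed radii unless stain sizes genuinely vary.
- 8-bit quantization biases low-amplitude compartments by up to ~1% of
  total signal at noise 0 (constant fractional intensities round one way);
  with default noise the rounding dithers away.
- The newborn/high-HbF regime (HbS below ~10% of total Hb) is out of scope;
  the indices as defined do not resolve it.
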