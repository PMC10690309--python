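# Methods

## Signal model

A B-scan is a 650 (lateral) × 1050 (depth) grid of nonnegative intensities
covering 1.30 mm × 2.10 mm, i.e. 2 µm per pixel in both directions. Depth
`z` increases downward from image row 0. Rows 0–2 carry a saturated bright
band representing the distal surface of the GRIN relay lens; the tissue
surface sits at a configurable row below it (default row 5).

Below the tissue surface the ensemble-mean intensity follows the
Beer-Lambert law `I(z) = I0·exp(−2µz) + noise_floor`, with `µ` in mm⁻¹ and
`z` the physical depth below the tissue surface. Individual pixels are
fully developed speckle: independent exponential draws with that local
mean. This is the standard first-order statistic of coherent imaging, and
it has a property the estimator relies on: `E[log Exp(m)] = log m − γ`
(Euler–Mascheroni γ), so speckle shifts the expected log-intensity by a
depth-independent constant and leaves the log-slope — hence the estimated
µ — asymptotically unbiased. A gamma speckle option (`speckle_looks > 1`)
models incoherent averaging of several looks; it only tightens the
distribution and is off by default.

Phenotype texture is layered on top of the decay:

- **calyx** — µ is modulated sinusoidally in depth
  (`stripe_period_px`, `stripe_contrast`), and the mean image uses the
  cumulative optical path `∫µ dz` (left-Riemann sum, exact for constant µ),
  producing the alternating bright/dark strata of transitional epithelium
  and fibrous tissue;
- **fat** — sparse bright circular inclusions (Poisson count from
  `dot_density` per mm², radius 3 px, multiplicative `dot_intensity_gain`)
  emulate adipocytes on a dark background;
- **pelvis** — `has_tissue_signal = false`: nothing but the surface band
  and the noise floor. With the default `noise_floor = 0` every pixel below
  the band is exactly zero, reproducing the observed failure of the
  attenuation method for this fluid-filled space.

### Default phenotype parameters

| class   | µ (mm⁻¹) | i0 (a.u.) | texture |
|---------|----------|-----------|---------|
| cortex  | 2.5      | 800       | homogeneous |
| medulla | 1.5      | 700       | homogeneous, deepest penetration |
| calyx   | 3.0      | 750       | stripes: period 40 px, contrast 0.35 |
| fat     | 2.0      | 300       | dots: 8 /mm², gain 4 |
| pelvis  | —        | —         | no tissue signal |
| tumor   | 8.0      | 1200      | brightest, fastest decay |

No quantitative µ or intensity scale is available for this probe and
tissue set, so these defaults are free simulator parameters chosen to
respect the qualitative ordering (tumor brightest and most attenuating,
medulla imaging deepest, fat darkest). Nothing downstream depends on the
absolute values: correctness is established by parameter *recovery*, not by
matching any published distribution plot. Per-subject variation multiplies
µ and i0 by independent U(1±0.15) draws, so cross-testing folds face real
between-subject variance.

Intensities are stored as floats; quantization to 16-bit happens only in
the TIFF writer at a fixed scale of 1.0 intensity unit per count, clipped
at 65535.

## Attenuation estimation

Each A-scan's µ is the OLS slope of natural-log intensity versus physical
depth (mm) over a 250-pixel window, divided by −2. The per-image µ is the
arithmetic mean over a 200-column ROI. Placement: the surface band is
located as the argmax of the laterally averaged profile within the top 10%
of rows; the ROI is laterally centered (columns 225–424 of 650) and the
depth window starts 10 px below the detected surface. The published
analysis specifies the 200×250 window and "top middle" placement but no
exact coordinates, so both offsets are configuration, not claims.

Validity rules (artifact decisions, configurable):

- nonpositive pixels are dropped from the fit, not floored — flooring
  would fabricate a finite µ for signal-free regions;
- a column keeps its fit only if ≥ 50% of its window pixels are positive
  (and ≥ 2 remain), otherwise it is *not computable* (NaN);
- an image is valid only if ≥ 50% of ROI columns are computable; otherwise
  `mu_image` is NaN and the image abstains downstream. Abstentions are
  counted and reported, never silently dropped.

A Theil–Sen slope is available as a robustness option; OLS is the contract.
The estimator is scale-invariant (the log-slope ignores the intercept), so
detector gain and TIFF quantization scale do not affect µ.

## Gaussian threshold classification

Class-conditional normals are fitted by moments (sample mean, SD with n−1
denominator; maximum likelihood differs only in the variance denominator,
and n−1 is preferred for unbiasedness). The two-class decision threshold is
the crossing point of the fitted density curves: with equal SDs, the
midpoint of the means; otherwise the root of the log-density-equality
quadratic that lies between the means (if both real roots qualify
numerically, the one nearer the midpoint; if neither lies between —
possible for nearly concentric fits of very different widths — the root
nearest the midpoint is used and a warning is issued). For equal priors
this crossing minimizes the error rate, and the test suite checks it
maximizes balanced accuracy against a dense cutoff sweep. Values exactly at
the threshold go to the higher-mean class (documented tie-break); NaN µ
abstains.

For k-class confusion matrices the pairwise crossings do not compose into
one rule, so the multi-class decision assigns each image to the fitted
class of highest Gaussian likelihood (equal priors). This rule is this
package's choice; its phantom-data outputs are not claimed to match the
published 5-class confusion matrix, which was produced by an unstated rule
on real data.

ROC curves sweep the pooled sample values (scikit-learn's `roc_curve`);
the AUC is the rank statistic — the probability a random positive scores
above a random negative, ties counting one half — which the tests verify
against the closed binormal form `Φ(Δµ/√(σ₁²+σ₂²))`.

## Evaluation

Per-class metrics are one-vs-rest on the pooled confusion matrix:
`accuracy = (TP+TN)/N`, `precision = TP/(TP+FP)`, `recall = TP/(TP+FN)`,
`F1 = 2TP/(2TP+FP+FN)`, computed in exact integer/rational arithmetic.
Zero-denominator ratios are reported as undefined, never as 0. Display
formatting rounds half-up to two decimals; numeric comparisons against
printed values use half a unit in the last printed place, since printed
two-decimal figures can sit exactly on a rounding boundary.

Cross-testing rotates whole subjects: every subject is the held-out test
set exactly once, and within each test fold the validation subject rotates
over the remainder (n test folds × (n−1) rotations). The Gaussian threshold
method has no hyperparameters to tune, so validation rotations are
enumerated for harness parity but the models are fitted on all non-test
subjects. Classes with no computable µ anywhere (pelvis) are excluded from
the rotation up front, mirroring the published removal of that category;
their images are tallied as abstentions.

## What the phantom does and does not show

The generator reproduces exactly the statistical structure the estimator
assumes: exponential depth decay, multiplicative speckle, class-specific µ,
subject-level parameter variation, and the pelvis zero-signal mode. Passing
tests therefore demonstrate the *correctness of the analysis chain* —
unbiased slope recovery, threshold placement, split hygiene, abstention
routing — under its own model.

Real B-scans violate that model in ways the phantom does not emulate:
confocal and sensitivity roll-off multiply the decay by a depth-dependent
envelope, speckle is laterally correlated at the resolution scale, tissue
is heterogeneous within the ROI, surfaces tilt and deform under probe
contact, and refraction at the GRIN lens distorts geometry. Phantom
results consequently say nothing about the real-data separability of the
tissue classes (the normal-tissue overlap pattern here is an artifact of
the chosen default µ values), and the published real-data AUCs are not
reproducible from synthetic data — only the printed confusion matrices,
which ship as fixtures, anchor those numbers.

## Problem sizes and numerical choices

- Noiseless recovery is checked on µ ∈ {0, 0.5, …, 10} mm⁻¹ at ≤ 10⁻⁹
  relative error (observed ≈ 10⁻¹³, limited by cumulative-sum rounding).
- Speckle-bias checks use 1,000 rendered images per signal-bearing class
  in the test suite and 400 per class in the acceptance script, against
  the bound |mean(µ̂) − µ| < 0.05µ + 0.02 mm⁻¹; observed biases are an
  order of magnitude below the bound.
- The cross-testing demonstration uses 5 subjects × 6 classes × 20 images;
  the tumor/normal separation at the default parameters makes the expected
  held-out tumor error rate ≪ 10⁻³.
- Density-equality at the returned threshold holds to ≤ 10⁻¹⁰; the
  single-image µ̂ check uses a 99% interval frozen from a 1,000-replicate
  Monte-Carlo run of the generator.
- Root seeds fan out to stage seeds via `numpy.random.SeedSequence.spawn`,
  so every stage is independently reproducible and reruns are
  byte-identical.

## Known limitations

One µ per image discards spatial information (no depth-resolved attenuation
maps, no multi-layer fits). The surface detector assumes the lens band is
the brightest structure in the top rows. The multi-class likelihood rule
assumes equal priors and normal class-conditionals, which the heavy-tailed
fat/calyx µ̂ distributions only approximate. CNN baselines appear solely
through their published confusion matrices; no networks are trained here.
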