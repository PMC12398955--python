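# Methods

This note documents the models implemented in `srsmargins`, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the package's known limitations.

## Coordinate and unit conventions

Patient axes are x = left-right, y = anteroposterior, z = craniocaudal;
3-D arrays are stored z-slowest so the CT slice thickness maps to the leading
axis. Distances and margins are in mm, GTV equivalent diameter ("size") in cm,
volumes in cm³, dose in Gy. Lesions are treated as sphere-equivalent for all
rule-based geometry (`d = (6V/π)^{1/3}`); voxelized masks appear only in the
dosimetry layer.

## Maximum setup displacement (margin seed)

For a lesion centroid **p** (relative to the isocenter) and symmetric per-axis
tolerances (rotation ±θ̄ deg, translation ±t̄ mm), the seed is

    max ‖R(θ)·p + t − p‖₂  over  θ ∈ [−θ̄, θ̄]³, t ∈ [−t̄, t̄]³

with R an intrinsic rotation about the three patient axes. Defaults:
θ̄ = 0.2°, t̄ = 0.2 mm. Because rotation ordering is a convention (and its
effect at 0.2° is ~10⁻³ mm — the same order as the GA/oracle agreement
contract), the objective is defined as the maximum over all six axis
orderings; a fixed ordering can be requested.

Two maximizers:

* **Corner oracle** — exhaustive evaluation of the 8 rotation-sign × 8
  translation-sign corners × 6 orderings. For fixed rotation the optimal
  box translation is `tᵢ = t̄·sign((Rp−p)ᵢ)`, a sign corner, and at these
  angle scales the norm is monotone in each angle magnitude, so the optimum
  sits at a corner; a dense 21³ grid reference (`max_displacement_grid`)
  confirms this to ~10⁻¹⁵ relative.
* **Genetic algorithm** — population 50, 100 generations, tournament
  selection (size 3), uniform crossover (rate 0.9), per-gene Gaussian
  mutation (rate 0.1, σ = 0.1 × box span) clipped to the box, elitism 1,
  fixed seed required. Two extra mutation moves address the box-corner
  landscape: clipped genes settle on box faces, and a sign-flip move jumps
  between symmetric corners (the landscape is multi-modal in the sign
  pattern; without it the population can converge to a wrong corner).
  Agreement with the oracle on 200 random points within a 10 cm ball:
  worst ratio 0.9996.

Displacement is evaluated at the centroid only; lesion extent adds at most
r·θ ≈ 0.01 mm at these tolerances.

## Margin pipeline

Margins live on a 0.1 mm grid (round half up, with a 10⁻⁹ epsilon so that
binary-float representations of grid midpoints round upward as intended).

* **Geometric criterion (GMC)**: 0.5 mm isotropic if distance < 50 mm and
  volume ≥ 0.1 cm³, else 1.0 mm. Boundaries (exactly 50 mm, exactly
  0.1 cm³) resolve to the conservative 1 mm / 0.5 mm branch respectively
  per the rule's strict inequalities.
* **MLC correction**: the PTV sphere-equivalent diameter
  (10·d_GTV + 2·margin, mm) must reach two leaf widths (default leaf
  2.5 mm). This is an absolute machine constraint and may exceed the 1.0 mm
  regressor cap (a 2 mm lesion requires 1.5 mm; a 1 mm lesion 2.0 mm).
* **Minimum-volume correction**: the PTV equivalent diameter must reach
  3.0 mm. The threshold is expressed as a diameter rather than a volume
  because only that reading reproduces the rule's canonical example
  (1 mm lesion → 1 mm margin); it is configurable.
* **Training label**: `clamp(min_vol(mlc(setup_seed)), 0.1, 1.0)` — the
  corrected displacement margin clamped to the regressor's discrete output
  space.
* **Deployment (OMC)**: prediction → quantize/clamp to [0.1, 1.0] → MLC →
  minimum-volume → anisotropic finalization (ap/lr = corrected prediction,
  cc = max(corrected prediction, slice thickness)). Corrections are
  re-applied after prediction so the two safety constraints always hold,
  which means small lesions can exceed the clamp range by design.
* **Dose-cluster rule**: lesions i, j cluster when
  ‖cᵢ−cⱼ‖ < rᵢ + rⱼ + 6 mm (sphere-equivalent radii); the 6 mm buffer
  corresponds to twice the ~3 mm prescription-to-half-prescription fall-off
  distance at 16.6 %/mm. The flag is per-lesion (participation in any
  clustered pair).

## Regression

Six features per lesion, in fixed order: metastasis count, lobe code,
volume (cm³), size (cm), distance (mm), cluster flag. Four families:
linear, MLP (ReLU, Adam — a stochastic gradient-based solver — behind a
standard scaler), random forest, XGBoost (gbtree, uniform row sampling).
Hyperparameters are grid-searched (exhaustive) with shuffled 5-fold CV
scored by mean R² (the "cross-validation score" reported as CVS); the best
configuration is refit on all data. Default grids are deliberately small
(2–3 values per searched parameter) and live in `DEFAULT_GRIDS`.

**Noise-injection augmentation** draws `x_new = x + μ + σ√2·erf⁻¹(2p−1)`
with `p ~ U(0,1)` — the inverse-CDF form of a zero-mean Gaussian — applied
only to the continuous features (volume, size, distance; noise on counts,
lobe codes or flags would be meaningless), σ defaulting to 2 % of each
value, μ = 0, and 2160 new rows for cohort-scale runs. Perturbed values are
floored at 10⁻⁶ to preserve positivity.

**Metrics**: accuracy is the fraction of exact matches after quantizing both
arguments to the 0.1 mm grid (only well-defined there); MAE is the plain
mean absolute error; feature importance uses mutual information with
discrete-feature handling, normalized to sum to 1. Confidence intervals for
MAE and R² come from a percentile bootstrap (default 5000 resamples,
2.5th/97.5th percentiles) of a *fixed* model's predictions.

## Dosimetry

Voxelization uses the voxel-center inclusion rule with no partial-volume
weighting — the simplest reproducible surrogate for contouring on CT slices;
the slice-thickness study samples random sub-voxel offsets to exercise
partial-volume variability. Isodose volumes use an inclusive threshold
(dose ≥ level) by voxel counting. The cumulative DVH uses 0.05 Gy bins with
linear interpolation for Dxx, giving sub-percent accuracy at these volumes.
Plan-level Paddick CI treats the union of targets against the prescription;
per-lesion CI is also reported. V12 is computed on the healthy brain: whole
brain minus GTVs and brainstem.

## Radionecrosis models

Both are logistic in the irradiated volume: the NTCP model
`logistic(4γ₅₀(V/V₅₀−1))` with V₅₀ = 63.2 cm³, γ₅₀ = 0.87 (exactly 0.5 at
V₅₀, symmetric about it), and the permanent-injury model
`logistic(−7.8713 + 0.7506·SPIE + 0.0734·V12)`. The SPIE location score is
deliberately user-supplied: its per-location score table belongs to the
cited clinical literature and is not re-derived here. The injury model was
fitted on an arteriovenous-malformation population; applying it to
metastases is an extrapolation. Probabilities are fractions internally;
percent only at presentation.

## Synthetic data

The cohort generator emulates the reported multi-institutional statistics:
metastases per patient from a rounded lognormal truncated to [2, 40]
(mean ≈ 6); volumes from a lognormal truncated to [0.01, 18.80] cm³ whose
underlying σ is moment-matched to mean 1.33 / sd 4.31 cm³ and whose location
is then recalibrated so the *truncated* mean equals 1.33 cm³ (the upper
truncation would otherwise bias the realized mean ≈ 0.2 cm³ low; the
realized sd is necessarily below 4.31 under truncation); distances from a
normal(46, 16) mm truncated to [9, 101]. Centroids get uniformly random
directions, rejected when the GTV would leave an ellipsoidal brain
(semi-axes 85 × 110 × 80 mm) or overlap a sibling GTV. Lobe labels are
sampled uniformly over the common metastasis sites (the source lobe mix is
unreported) and are configurable. The default CT slice thickness is 0.6 mm,
the modal value across the emulated institutions; the default prescription
is 21 Gy.

The dose model assigns each lesion its prescription inside the ellipsoidal
PTV and a linear fall-off of 16.6 % of the prescription per mm outside
(distance to the ellipsoid approximated by the radial gap ‖d‖(1−1/ρ),
exact for spheres), combined by voxelwise maximum — so dose bridging
between clustered lesions emerges without explicit modelling. This is an
idealized fall-off: it reproduces the geometry-driven behaviour of plan
indices (GI = (13/10)³ for a 10 mm radius target, V12 monotone in margin,
bridging) but not TPS-specific effects (beam arrangement, modulation,
inhomogeneity control, monitor units). Passing tests on synthetic plans
therefore demonstrate the pipeline's internal consistency and direction of
effect, not clinical magnitudes; absolute V12 and index values depend on
the idealized dose and the ellipsoidal brain.

Problem sizes used in the shipped experiments: the parameter-recovery run
trains on ~2000 synthetic lesions (340 patients, 80/20 split); the
criterion comparison evaluates 50 plans at 1 mm dose-grid spacing; the
fall-off/GI checks use 0.5 mm grids. These sizes give stable statistics
while keeping the full suite in the minutes range.

## Numerical choices and degenerate inputs

* Margin grid rounding: round half up, ε = 10⁻⁹; grid-ceiling for the
  corrections uses a matching ε so exact boundary cases stay put.
* Quantized-accuracy comparison is done on integer-scaled grid values to
  avoid float equality.
* Empty masks are legal (a sub-voxel sphere may voxelize to nothing and is
  reported as volume 0); an empty DVH cannot yield a Dxx.
* PIV = 0 makes the Paddick index 0 by convention but is an error for the
  gradient and efficiency indices (their denominators vanish).
* Identical paired metric lists in the comparison report return t = 0,
  p = 1, correlation 1 (documented degenerate case); fewer than 3 pairs
  suppress inferential statistics.
* The logistic is evaluated in its symmetric numerically stable form.

## Known limitations

* No TPS dose calculation, DICOM-RT I/O, or MRI/CT fusion; grids move via
  NRRD/NIfTI (SimpleITK).
* Margins are sphere-equivalent per direction; no MLC-leaf-resolved or
  couch-angle-dependent margins.
* The brain is an ellipsoid; no anatomical atlas, and the brainstem mask is
  optional external input rather than modeled anatomy.
* Residual post-image-guidance motion and fractionation effects are out of
  scope; tolerances model intra-fraction setup only.
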