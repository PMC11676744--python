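# Methods

This note records the models implemented by `cyclopure`, the defaults and
their rationale, the numerical choices, and what the synthetic data do and
do not establish about real measurements.

## The measurement problem

A linear peptide cyclised by intramolecular azide–alkyne cycloaddition is
isomeric with its precursor, and both isomers' dominant CID fragments are
the same N₂ loss, so fragment-specific quantification is impossible. The
package quantifies the molar ratio x = n_lin/n_total from two signals that
*do* differ between the isomers: the collision energy needed to fragment
them (ER-MS branch) and the alkyne/azide IR stretch present only in the
linear form (IR branch).

## ER-MS branch

**Survival yield.** Each MS/MS peak list is reduced to
SY = I_precursor / TIC, where the precursor intensity is the sum of peaks
within ±0.5 m/z of the precursor (the isolation window is 1 m/z wide and
centroiding may split the peak; summing a window instead of matching one
centroid is robust to that). Centroid heights are used as intensities. A
spectrum with zero TIC has no defined SY and raises; a spectrum whose
window is empty yields SY = 0 with a warning, since an absent precursor is
the physically meaningful limit of complete fragmentation.

**Boltzmann fits.** SY(V) = A₂ + (A₁ − A₂)/(1 + exp((V − V₀)/dV)),
A₁ > A₂, dV > 0, fitted by trust-region least squares. Initialisation:
A₁ = max(SY), A₂ = min(SY), V₀ = voltage nearest the half-height crossing,
dV = span/10; evaluation cap 200, RSS tolerance 1e-10. A flat curve has no
identifiable V₀ and raises a degenerate-fit error rather than returning an
arbitrary width.

**Calibration models.**

* Univariate: response ΔSY(2.2 V) = SY_cyc − SY_mix, ordinary least squares
  against x. 2.2 V sits where the pure curves separate most on the default
  generator parameters.
* CLS: the full-curve coefficient a from
  min_a ‖m − a·l − (1 − a)·c‖², solved in closed form
  a = ⟨m − c, l − c⟩/⟨l − c, l − c⟩ over the entire common voltage grid
  (an optional sub-range is a sensitivity tool, not the default). The
  coefficient is deliberately **not clipped** to [0, 1]: out-of-range values
  are diagnostic of noise or model failure and must reach the report.
* Pure-component reference curves come from the x = 0 and x = 1 standards
  of the same simulated batch, replicate curves averaged pointwise — the
  references carry measurement noise exactly as real pure standards would.
* Segmented: two independent OLS lines on [0, 0.3] and [0.3, 1], the
  breakpoint fixed at 0.3 (not estimated); standards at the breakpoint
  belong to both segments.
* Quadratic: a single degree-2 polynomial over the full range, provided for
  comparison with the segmented model; on suppression-shaped data its
  low-range prediction error is worse than the dedicated low-range line,
  which the tests assert.

**Inverse prediction.** Linear models invert directly (slope magnitudes
below 1e-12 raise). A segmented model uses the segment whose inverse lands
in its own ratio range and treats disagreement between both segments as
ambiguity; a quadratic model takes the real root inside [−0.1, 1.1]. In
the calibration context, where the reference ratio of a standard is known,
per-standard fit errors resolve segment/root choice by the reference —
otherwise standards near the breakpoint would raise spurious ambiguity
errors for purely numerical reasons.

**Residual sd conventions.** The univariate residual sd uses n − 2 degrees
of freedom (n − 3 for the quadratic) — the conventional OLS standard error.

## Ion-suppression model in the generator

The least-constrained choice in any simulation of electrospray mixtures is the
suppression law. Two are implemented:

* `saturation` (default): a_eff(x) = r·x / (r·x + (1 − x)), a relative
  response-factor model. Its derivative r/(1 + (r − 1)x)² equals r at x = 0
  and 1/r at x = 1, so sensitivity is depressed exactly where trace
  contamination must be detected. Default r = 0.483.
* `piecewise`: slope r up to a breakpoint (0.3), then linear to (1, 1).
  The low-range calibration is then an *exact* line with slope r, which
  makes slope-recovery tests sharp; the high/low slope ratio is
  (1 − 0.3r)/(0.7r) ≈ 2.53 at r = 0.483.

Both laws satisfy a_eff(0) = 0, a_eff(1) = 1, monotonicity, and
a_eff(x) ≤ x for r < 1 (suppression can only depress the linear signal).
The mixture SY curve is a_eff·SY_lin + (1 − a_eff)·SY_cyc.

**Noise.** Multiplicative Gaussian noise (relative sd 0.01 by default) on
every peak intensity, truncated at zero — MS counting noise is
heteroscedastic and this is the simplest stand-in. Fragment current is
split over 5 channels by a symmetric Dirichlet draw; SY depends only on the
precursor/TIC split, so the partition is immaterial. No reported noise
magnitudes exist for either platform; the defaults were chosen once for
qualitative resemblance to published breakdown curves and kept.

**Boltzmann defaults.** Linear V₀ = 2.05 V, cyclic V₀ = 2.55 V, widths
0.10 V, asymptotes 1 and 0, on a 1.7–2.9 V grid in 0.1 V steps. At 2.5 V
this leaves the linear peptide almost fully fragmented and the cyclic one
only slightly, matching the qualitative picture the method relies on.

**Seeding.** One integer seed; per-(ratio, replicate) substreams derive
deterministically from `SeedSequence([seed, level_index, replicate])`, so
equal seeds give bit-identical datasets and adding a level does not shift
other levels' draws.

## IR branch

**Generator.** Grid 675–4000 cm⁻¹ with 1725 points. Shared Gaussian bands
at 1655, 1545, 1240, 2930 and 3290 cm⁻¹ (amide I/II/III, CH stretch,
amide A); a linear-specific band at 2105 cm⁻¹ (sd 18 cm⁻¹, amplitude
0.25·x AU) standing for the unresolved alkyne + azide stretches. Each raw
spectrum adds a random cubic polynomial baseline (scale 0.05 AU, emulating
smooth scattering drift) and white noise (sd 0.01 AU); 100 raw spectra per
replicate are averaged into one dataset row, mirroring a microscope grid
scan. The averaged spectrum is exactly the arithmetic mean of its raws.

**Preprocessing order** is normalise-to-mean first, then AsLS, and is
configurable; the two operations nearly commute (AsLS is shift- and
scale-equivariant at fixed weights) and the chosen order keeps all spectra
on one scale before the baseline estimate.

**AsLS.** Baseline z minimises Σ wᵢ(yᵢ − zᵢ)² + λ‖Δ²z‖² with weights
iterated as wᵢ = p if yᵢ > zᵢ else 1 − p (max 50 iterations, stop when the
weight vector changes by < 1e-6). Second-order differences are the standard
smoothness penalty for this method. The pentadiagonal SPD system is solved
by banded Cholesky each iteration. Parameter tuning scans a (p, λ) grid,
discards candidates whose corrected spectra dip below −2% of the maximum
corrected height (the no-negative-parts screen made quantitative), and
picks the survivor with the lowest PLS RMSECV.

**Band area** integrates the corrected absorbance over 2040–2170 cm⁻¹ by
the trapezoidal rule with interpolated window edges (plain window
integration; no local peak-bounded baseline anchoring). The integrated area
is the default univariate response; an absorbance-maximum response
(`band_maximum`) is available as the simpler alternative, at the cost of
using a single channel's noise instead of averaging over the band.

**PLS.** Mean-centred PLS1 (NIPALS, via scikit-learn) with contiguous-block
cross-validation: one block per concentration level (11 blocks of 3 on the
default design), so replicates of the held-out level never appear in
training. The latent-variable count minimises RMSECV, ties resolved toward
fewer LVs; requests beyond the rank of centred X are capped with a warning.
Reported: RMSEC, RMSECV, bias (mean CV residual), R² for calibration and CV.

## Figures of merit

* fit errorᵢ = predictedᵢ − referenceᵢ; percentage errors are undefined at
  reference 0 and reported as NaN with the absolute error standing alone.
* RMSEC = √(Σ e²/n), divisor exactly n (not n − p).
* LOD: 3.3·s_e/|b₁| for line calibrations; 3.3·RMSEC for multivariate
  models; 3.3 corresponds to α = β = 0.05. For the ER-MS CLS model both
  routes are computed and labelled distinctly (`lod` and `lod_alt`),
  because the two definitions need not agree and the choice is a reporting
  convention, not mathematics.
* Intermediate precision: dof-weighted pooled replicate sd,
  √(Σ (n_g − 1)s_g² / Σ (n_g − 1)); singleton groups raise.

## Problem sizes and determinism

The default simulated designs are the study's own: ER-MS mixtures at
x ∈ {0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 1} × 3 replicates with
calibration restricted to x ≤ 0.3 (6 levels × 3 = 18 standards), and IR
mixtures at 11 levels × 3 replicates = 33 averaged spectra over 1725
channels. Statistical tests in the suite use 200 seeds (slope recovery) and
500 seeds (model-comparison direction), sizes at which the Monte-Carlo
error is far below the asserted tolerances. Pipeline runs write no
timestamps into artefacts, so a fixed seed reproduces the output tree
byte for byte.

## What the synthetic data do not show

The generator reproduces the *structure* the analysis assumes — sigmoidal
breakdown curves, convex-combination mixing distorted by a smooth
suppression law, shared-plus-specific IR bands under polynomial drift. It
does not emulate space-charge effects, isotope envelopes, detector
saturation, water-vapour/CO₂ IR interference, specular-reflectance
distortions, or replicate-to-replicate concentration errors. Passing tests
therefore demonstrate correctness of the estimators and their documented
behaviour under the stated noise models, not instrument-level validity;
figures of merit computed on synthetic data characterise the generator's
noise settings, not any particular spectrometer.

## Known limitations

* The Boltzmann fit assumes a single fragmentation transition; multi-step
  breakdown curves would need a sum of sigmoids.
* The segmented model's breakpoint is fixed, not estimated; estimating it
  is out of scope.
* No internal-standard correction is implemented, so the restricted ER-MS
  linearity range is inherent to the calibration as modelled.
* No scatter-correction alternatives (MSC/SNV), variable selection, or
  hyperspectral/spatial logic; a grid scan is represented only by its
  averaged spectrum.
* Peak-list inputs are assumed already combined over acquisition time and
  centroided; vendor formats and mzML are not read.
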