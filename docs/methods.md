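# Methods

`fluorbind` analyses steady-state fluorescence titrations of a protein with a
small-molecule quencher (the motivating system is hen-egg lysozyme titrated
with an anticancer drug, alone or with cyclodextrin co-solutes), together
with the companion scattering, red-edge and circular-dichroism measurements
that probe the accompanying conformational change.

## Quenching models

For reference intensity F₀ (no quencher) and intensity F at quencher
concentration [Q]:

* **Stern-Volmer** — F₀/F = 1 + Ksv[Q]. The slope is estimated by least
  squares with the intercept pinned to 1, because the equation forces the
  intercept; the correlation coefficient reported next to it comes from the
  unconstrained regression and is a linearity diagnostic only. The apparent
  bimolecular rate constant k_q = Ksv/τ₀ uses τ₀ = 10⁻⁸ s (typical intrinsic
  lifetime of protein fluorophores; configurable). A k_q above the
  diffusion-collision ceiling of 2×10¹⁰ M⁻¹s⁻¹ cannot be collisional, so the
  mechanism is called *static*; the comparison is strict, and a boundary
  value is conservatively reported as *dynamic_possible*. The classifier
  refuses a k_q that is not on the reciprocal-molar scale — fits carry the
  unit of their concentration grid and conversion is explicit
  (`per_concentration_to_per_molar`).
* **Two-regime Stern-Volmer** — proteins with two binding-site classes show
  two slopes. No published rule exists for where the regimes divide, so the
  split is found by exhaustive search over contiguous partitions with at
  least three points per side, scoring each by the total squared residual of
  two lines (first segment pinned to intercept 1, second free, since the
  regimes join away from [Q] = 0) and keeping the minimiser.
* **Modified Stern-Volmer** — F₀/(F₀−F) = 1/f_a + 1/(f_a·k_a[Q]): intercept
  1/f_a (accessible fraction), slope 1/(f_a·k_a). Raw parameters are never
  clamped; when the intercept is nonpositive, f_a exceeds 1 (beyond 10⁻⁹
  round-off headroom) or k_a is nonpositive the fit is flagged `unphysical`
  and a warning is issued, because literature tables do report f_a > 1 and
  silently "repairing" such values would hide a real inconsistency. The
  same exhaustive contiguous-split search is available here.
* **Double-log (Hill-type)** — log₁₀((F₀−F)/F) = log₁₀K_A + n·log₁₀[Q];
  slope n is the number of binding sites, intercept log₁₀K_A. Points with
  F = F₀ carry no signal (log of zero) and are dropped with a warning.

Shared guards: nonpositive intensities are refused outright; points with
F > F₀ (enhancement, not quenching) are excluded with a warning.

### Intensity readout

Fits accept `readout="peak"` (parabolically interpolated peak intensity,
the default) or a fixed wavelength in nm. For noisy spectra the peak readout
carries a small upward selection bias — it picks the maximum over ~10² noisy
samples, a max-statistic — which propagates into the fitted constants; the
fixed-wavelength readout is unbiased and preferred when noise matters. The
replicate-bias test in the suite quantifies the envelope with the
fixed-wavelength readout for exactly this reason.

## Peak location

Emission maxima are located by a three-point parabola through the maximal
sample and its neighbours, giving sub-grid resolution (≈0.01 nm error for a
smooth band with σ = 15 nm on a 1-nm grid) so that ≤3-nm red shifts can be
tracked point by point. Exact ties resolve to the lower wavelength with no
interpolation; a maximum on the grid boundary is returned uninterpolated
with a warning, since the band is then truncated.

## Corrections

Inner-filter: F_corr = F·10^((A_ex+A_em)/2), the standard re-absorption
correction. Dilution: F_corr = F·(V₀+V_added)/V₀. Both are multiplicative,
hence commute; the pipeline applies dilution from manifest volume metadata
and records corrected values.

## REES and synchronous fluorescence

REES is λ_max(λ_ex = 305 nm) − λ_max(λ_ex = 295 nm); a positive value of a
few nm indicates slow solvent relaxation around tryptophan. In table mode
each maximum is rounded to integer nm before differencing, matching how
REES is conventionally tabulated; raw mode differences the interpolated
maxima. Synchronous series (Δλ = 15 nm for tyrosine, 60 nm for tryptophan)
are reduced to the least-squares slope of F/F₀ against [Q]; any curvature
appears as the reported residual RMS rather than being modelled, and the
λ_max shift over the series is reported alongside.

## RLS aggregation onset

The RLS intensity curve is modelled as a continuous hinge — flat baseline b
up to the critical induced aggregation concentration (C_CIAC), then
b + m·([Q]−C_CIAC). The knot is found by least squares over candidate knots
at the observed concentrations and their midpoints, followed by iterative
local subdivision of the best bracket, so clean data resolve the knot far
below the grid spacing. The hinge is accepted only when the rise slope is
positive and it beats the flat-only model by an F-ratio (default threshold
4.0, roughly the 5% point for the relevant degrees of freedom at these
series lengths); otherwise "no onset" is reported. The estimate is invariant
under positive affine transforms of the intensity and under adding flat
points below the onset.

## FRET

J = ∫F(λ)ε(λ)λ⁴dλ / ∫F(λ)dλ by trapezoidal quadrature on the donor grid
restricted to the overlap interval, acceptor extinction linearly
interpolated, wavelengths in cm so J emerges in cm³·M⁻¹ (normalisation makes
J independent of the donor intensity scale). The Förster radius is computed
as R₀⁶ = 8.8×10⁻²⁵·K²·n⁻⁴·φ·J in cm⁶ — the prefactor form common in the
binding literature prints this expression as R₀, but dimensional analysis
requires the sixth power, and the implementation follows the dimensionally
consistent reading. Defaults: K² = 2/3 (isotropic dipole averaging),
n = 1.336 (aqueous buffer). The donor quantum yield φ has no defensible
universal default (hen lysozyme literature values cluster near 0.05–0.14
depending on conditions) and must be supplied. E = 1 − F/F₀ and
r = R₀·((1−E)/E)^(1/6); stored results enforce E = R₀⁶/(R₀⁶+r⁶) to 10⁻⁹.

## CD bookkeeping

[θ] = 100·θ_obs/(c·l) with θ_obs in degrees, c in mol residue·cm⁻³, l in cm.
Secondary-structure fractions (regular/distorted helix, regular/distorted
sheet, turn, unordered) are accepted as externally deconvolved percentages —
deconvolution itself is out of scope — validated to sum to 100 ± 0.5, and
differenced per class with a monotonicity report for the canonical
loosening signature (helix and sheet down, unordered up).

## Synthetic data generator

The generator emulates: a Gaussian emission band (center 340 nm, σ 15 nm by
default — the line shape of the real band is not knowable from published
figures, and a Gaussian is the simplest smooth unimodal choice), a linear
red shift of the center with [Q] (matching the ≤3 nm shifts such titrations
show), per-mechanism intensity scaling that inverts each fit's equation
exactly, and additive Gaussian intensity noise (sd = `noise_sd`·amplitude)
drawn from a seeded generator. The two-regime law is made continuous in
F₀/F at the split concentration (an explicit generator parameter): a
discontinuous per-regime law would let F jump upward at the split whenever
Ksv₂ < Ksv₁, violating monotone quenching. Physically impossible requests —
an accessible-fraction configuration whose quenched fraction reaches 1 — are
refused.

What the generator does *not* emulate: instrument baseline drift and
wavelength-dependent detector response, scattering/Raman artefacts, photon
shot noise (noise is homoscedastic Gaussian), lifetime effects and
anisotropy, and any real scattering physics behind the RLS hinge (the hinge
is phenomenology). Passing round-trip tests therefore demonstrates
correctness of the estimators under the models' own assumptions, not
robustness to every artefact of real instrument data.

Default study conditions mirror the motivating experiment: protein at
1×10⁻³ mM, drug titrated over 0–8.33×10⁻⁶ mM, emission scanned 300–500 nm
with maxima near 340–343 nm. Recovery tests use grids self-consistent with
their generating constants (Ksv·[Q] of order 1), since published constants
of ~10¹² M⁻¹ combined with ~10⁻⁹ M quencher would imply quenching ratios
far larger than any published titration shows; the package does not attempt
to reconcile that inconsistency.

## Problem sizes

Tests and the acceptance script run on 10–25-point titrations and ~10²-point
spectra — the sizes of the real experiments they emulate — and the
replicate-noise envelope uses 200 seeded replicates; the whole suite
completes in a few seconds.

## Known limitations

* Temperature-dependent quenching analysis and binding thermodynamics
  (ΔH/ΔS) are out of scope, so static vs dynamic rests on the k_q criterion
  alone.
* The modified-SV two-regime split search fits two independent lines in
  (1/[Q], F₀/(F₀−F)) space; on data whose regimes are defined in
  Stern-Volmer space the upper segment is only approximately linear there,
  so the split index is recovered but the per-segment (f_a, k_a) pairs are
  effective values. Exact two-regime recovery lives in
  `stern_volmer_fit(two_regime=True)`.
* `detect_cciac` assumes a single onset; multi-stage aggregation is not
  modelled.
* CD deconvolution is not performed; fraction tables are trusted inputs.
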