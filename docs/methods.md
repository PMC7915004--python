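# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Mixture theory

Effective atomic number uses the power-law rule Z̄ = (Σᵢ λᵢ Zᵢ^α)^(1/α).
The exponent α nominally lies between 2.94 and 4 depending on which
attenuation process dominates; the default is α = 3.3, the value used for
all packaged reference calculations.  The weights λᵢ are the **mass
fractions** ωᵢ by default: this convention reproduces the packaged phantom
reference values (12.4, 9.8, 13.8, 7.9), which electron-fraction weighting
does not.  Because the literature is split, `weighting="electron"` switches
to normalised electron fractions ωᵢZᵢ/Aᵢ.  A caveat: for PMMA the two
conventions straddle the commonly quoted 6.5 (mass fractions give ≈6.7);
no attempt is made to force one value.

Electron density is ρ·N_A·Σωᵢ Zᵢ/Aᵢ (cm⁻³) with standard atomic weights to
five significant figures; the reference values at their printed precision
(0.1 in Z̄, 0.01×10²³ in ρe) are insensitive to that truncation.

Mixture I-values use the Bragg additivity rule,
ln I = Σ λᵉᵢ ln Iᵢ with electron-fraction weights λᵉᵢ, over a packaged
ICRU-37/PDG element table (H 19.2, C 78.0, N 82.0, O 95.0, … eV;
user-overridable per element).  With the graphite carbon value 78 eV the
phantom mixture I-values come out ~1 eV below commonly printed ones
(e.g. BE-N-10: 73.5 vs 74.0 eV); a carbon value near 81 eV closes the gap,
but the packaged table keeps the ICRU value and the tests assert only a
±2 eV band.  Bragg additivity is known to underestimate I for bound
mixtures by up to ~5%; that bias is inherited by everything downstream.

## Attenuation data layer

Cross sections are consumed per electron (cm²/electron), split into
photoelectric / incoherent / coherent channels on a rectangular (E, Z)
grid covering 30–150 keV, Z = 1..29.  Off-node energies use piecewise-linear
log σ vs log E interpolation — standard for smooth, edge-free cross
sections in this range (no K-edges above 30 keV for Z ≤ 29); the loader
warns if the summed cross section is not decreasing in E, the signature of
an edge.  All spectral integrals (window weights, mean energies, Eq-style
window attenuations and weighted model coefficients) share one quadrature:
composite trapezoid on a 0.1 keV resampled grid.  Sub-0.1% quadrature
accuracy is ample against the ≥1% physics errors of the fitting methods.

## The fitted surfaces

*Two-PFM.*  At each grid energy, σ_pe/Z⁴ and σ_incoh+σ_coh are fitted by
ordinary least squares as quadratics in Z; coefficients are interpolated
linearly in E between grid energies.  Spectrum weighting is linear, so the
window coefficients ⟨F⟩k(Z), ⟨G⟩k(Z) are again exact quadratics with
fluence-averaged coefficients.

*Three-PFM.*  At each grid energy and channel, ln σ_c is fitted as a
quadratic in ln Z, i.e. σ_c = K_c(E)·Z^{q₁+q₂ lnZ} — an energy- and
Z-dependent coefficient *and* exponent (the local exponent is
p_c = ∂lnσ_c/∂lnZ = q₁ + 2q₂ lnZ).  The quadratic order is the lowest that
captures the curvature of real channel data while remaining exact for pure
power laws; it is configurable in principle by refitting.  The window
response σk(Z) requires quadrature over E for every Z, so a dense grid
(ΔZ = 0.01 over [1, 30]) is precomputed for bracketing while final root
polishing re-evaluates the exact quadrature.

Both fit objects record their full relative reconstruction-error surface;
`summary()` reports the maxima.  On any table whose channels are exact
power laws in Z the three-PFM reconstruction is exact to machine precision;
the two-PFM is exact only when σ_pe/Z⁴ and the summed scattering are
quadratic in Z.

## Inversion of four window attenuations

*Z̄, two-PFM.*  The adjacent-window conditions give three equations in one
unknown; they are combined as a least-squares objective with each residual
normalised by ⟨μ⟩k⟨μ⟩k₊₁, making it dimensionless and independent of ρe.
Minimisation is a dense scan (ΔZ = 0.01) plus ~70 golden-section
iterations — deterministic, derivative-free, no random starts.

*ρe, two-PFM.*  The printed two-window form of the electron-density
equation mixes window indices k, k+1, k+2 and is not dimensionally
consistent as published (its derivation appendix is not available); it is
retained verbatim behind `method="literal"` for comparison, but the default
solves ⟨μ⟩k = ρe·Ak(Z̄) by least squares over the four windows, which is
exactly equivalent on noiseless model-consistent data and well defined
under noise.

*Z̄, three-PFM.*  The four-window determinant condition is scanned on the
dense Z grid; **every** sign-change interval is polished by ~50 bisection
iterations on the exact response, and when noise produces multiple roots
the one whose four per-window densities ⟨μ⟩k/σk(Z̄) agree best (smallest
coefficient of variation) is selected — the criterion a physically
consistent solution must satisfy.  No sign change anywhere in [1, 30] is a
convergence failure, reported as such.  ρe is the four-window mean of
⟨μ⟩k/σk(Z̄).

Solver tolerance is ~1e-12 in Z (interval width), bracket Z ∈ [1, 30].
Scale invariance holds by construction: scaling all four ⟨μ⟩k leaves Z̄
fixed and scales ρe.  Batch (per-pixel) solving is vectorised; failed
pixels are masked, never filled, since real reconstructions contain
ring-artefact pixels whose values must not be invented.

## I-value parameterisation and SPR

I(Z̄) is a least-squares quartic.  Two curves are produced: an
**element fit** through the 29 packaged element I-values and a
**mixture fit** through a tissue-like (Z̄, I) point set anchored by the
hydrogen point.  The mixture fit is the default for map conversion (human
tissues are mixtures); the element fit is selectable and is the right
choice for elemental media — through the mixture curve an aluminium rod's
SPR is overestimated by ~8%, through the element curve it is recovered to
~1%.  A plain quartic through all 29 scattered element values runs ~10%
below aluminium's 166 eV at Z = 13; the element-curve option is therefore
best used over the Z-range of interest rather than as a global fit.

The tissue-like point set is **synthetic**: ten ICRU-spirit compositions
(adipose- to cortical-bone-like) evaluated with the package's own Z̄ and
Bragg-additivity rules.  It stands in for published tissue tables, which
are not redistributed here; users may supply their own points.

SPR uses the Bethe–Bloch ratio with β from γ = 1 + T/(m_u c²),
m_u c² = 931.494 MeV (β = 0.6469 at 290 MeV/u, the default carbon-therapy
energy).  The water reference I_w defaults to the package's own Bragg
additivity value ≈69 eV for internal consistency — not the ICRU 75–78 eV —
and is overridable; SPR *ratios* are only weakly sensitive to this choice
when medium and water I-values come from the same convention.

Water-equivalent length: the distal-H% depth (H = 80 by default) is found
by linear interpolation on the distal falloff past the global maximum;
SPR = (R_H,w − R_H,m)/t_m.  The analytic Bragg-curve generator has a
closed-form distal depth, so extraction is verifiable to the 0.1 mm
sampling (tests assert 1e-3).

## CT-number correction

Measured window attenuations from CdTe counting detectors fall below
theoretical values (scatter, charge sharing).  Per window, an offset-free
power law μ_corr = a·μ^b is fitted in log-log space to ≥3 calibration
rods against spectrum-weighted theoretical values.  Offset-free is chosen
because calibration attenuations are positive and span less than a decade;
the form is strictly monotone, so pixel ordering is preserved.  The
physical causes are deliberately not modelled.

## Synthetic data: what it emulates, what it does not

The generator's channel rules are exact power laws σ_c = K_c(E)·Z^{p_c}
with magnitudes matched to per-electron cross sections in the diagnostic
range (incoherent ≈ 0.6 barn/electron at 60 keV and nearly Z-free;
photoelectric ≈1e-26 cm² for oxygen at 60 keV, ~E⁻³ and ~Z^3.6 per
electron; coherent ≈3e-27 cm², ~Z^1.5, ~E⁻¹·⁹).  Two rule sets ship:
`EXACT_RULES` (p_pe = 4, p_inc = 0, p_coh = 2 — inside both model classes,
for machine-precision round-trip tests) and `REALISTIC_RULES` (physical
exponents — inside the three-PFM class only, so the two methods have
genuinely different residuals).  Real tabulated data differ by non-power-law
curvature in ln Z and binding effects; consequently, passing tests
establish solver correctness and the *relative* behaviour of the two
methods, not absolute accuracy figures against measured cross sections.
A loader accepts user-supplied per-electron channel tables for that
purpose.

The toy spectrum is filtered-Kramers-like, Φ ∝ (kVp−E)·exp(−f(60/E)³):
smooth, non-negative, zero at the tube voltage, hardening with f.  It does
not model characteristic lines or detector response distortion.

The rod phantom is a 30 mm water-filled holder with up to seven 5 mm rods
(one central, six on a 9 mm ring), imaged at 0.5 mm pixels on a 64×64
grid; region values are the theoretical spectrum-weighted attenuations,
optionally with multiplicative Gaussian pixel noise.  No projection
physics, reconstruction filter or ring artefacts are simulated.

## Noise robustness study

Study conditions: each material's four theoretical window attenuations are
perturbed by independent multiplicative Gaussian factors N(1, σ), σ = 6%
by default, 4096 replicates, full Z̄→ρe→I→SPR chain, both methods.
Multiplicative noise is chosen because a percentage noise level implies
relative scale; an additive variant (σ in cm⁻¹) is switchable.  Replicates
derive from a single integer seed and are exactly reproducible; σ = 0
degenerates to the noiseless solution with zero spread by construction.

Under these conditions the three-PFM chain shows smaller per-material
standard deviations than the two-PFM chain for Z̄, ρe and SPR on all seven
packaged materials (asserted ordinally by the acceptance suite; the study
prints the actual numbers).  Two caveats the numbers make visible: at 6%
noise the three-PFM root condition loses its sign change for a substantial
fraction of replicates of low-Z̄ materials (up to ~45% for graphite) —
these are excluded and counted, so the reported spreads are conditional on
convergence; and Z̄ itself is strongly biased for scattering-dominated
media at this noise level, because the inter-window contrast carrying the
Z information is comparable to the noise.  Electron density and SPR, the
quantities that matter for range calculation, remain accurate to a few
percent.  Spreads scale linearly with σ in the small-noise regime
(verified at 1% vs 2% within 20%).

## Problem sizes

Defaults used throughout the package and its tests: attenuation grids of
49 energies × 29 elements; dense solver grid ΔZ = 0.01; phantom images
64×64; noise studies at the full 4096 replicates × 7 materials × both
methods.  These sizes make every study exactly reproducible in seconds to
a few tens of seconds on a single core.

## Known limitations

* No CT reconstruction: the pipeline starts from reconstructed window
  images; sinogram processing, beam-hardening and ring corrections are out
  of scope.
* No detector physics (charge sharing, spectral distortion); the power-law
  correction absorbs these effects empirically per window.
* The historical fixed-exponent three-term decomposition (m = 3.62,
  n = 1.86) is not offered as a method; the Z-dependent-exponent form
  supersedes it.
* Bragg curves are inputs (or analytic scaffolding); no energy-loss
  transport is performed.
* The mixture I-curve rests on a synthetic tissue point set; for clinical
  use, fit to a validated tissue table.
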