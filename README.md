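# pcctspr

Stopping-power-ratio (SPR) maps from multi-threshold photon-counting CT.

Particle-therapy dose calculation needs, for every voxel, the ratio of the
medium's ion stopping power to water's.  A photon-counting CT acquires, in a
single exposure, linear-attenuation images in several energy windows
(here 40–60, 60–80, 80–100 and 100–120 keV).  `pcctspr` inverts those four
window attenuations ⟨μ⟩₁..⟨μ⟩₄ per pixel into an effective atomic number Z̄
and an electron density ρe, converts Z̄ to a mean excitation energy I
through a fitted quartic, and evaluates the Bethe–Bloch SPR — producing
co-registered Z̄, ρe, I and SPR maps with ROI statistics.

## The two decomposition models

Both methods approximate the per-electron photon cross section σ(E, Z) of a
tabulated attenuation dataset by smooth surfaces fitted per energy and then
invert the spectrum-weighted window attenuations.

**Two-parameter fitting (two-PFM)** splits attenuation into a photoelectric
and a combined scattering term,

    μ(E, Z) = ρe [ Z⁴ F(E, Z) + G(E, Z) ],

with F and G obtained as quadratic least-squares fits in Z of σ_pe/Z⁴ and
σ_incoh + σ_coh at each energy.  Z̄ solves the three adjacent-window ratio
conditions ⟨μ⟩k·Ak₊₁(Z̄) = ⟨μ⟩k₊₁·Ak(Z̄) (Ak = Z̄⁴⟨F⟩k + ⟨G⟩k) in the
least-squares sense; ρe then solves ⟨μ⟩k = ρe·Ak(Z̄) over the four windows.

**Three-parameter fitting (three-PFM)** keeps the photoelectric, incoherent
and coherent channels separate and gives each an energy- *and* Z-dependent
coefficient and exponent,

    μ(E, Z) = ρe Σ_c K_c(E, Z) · Z^{p_c(E, Z)},

realised as per-energy quadratic fits of ln σ_c versus ln Z.  Z̄ is the root
of the four-window determinant condition

    −⟨μ⟩₂σ₁(Z̄) + (⟨μ⟩₁−⟨μ⟩₃)σ₂(Z̄) + (⟨μ⟩₂−⟨μ⟩₄)σ₃(Z̄) + ⟨μ⟩₃σ₄(Z̄) = 0,

and ρe = ¼ Σk ⟨μ⟩k/σk(Z̄).  The three-channel form reconstructs tabulated
cross sections far more accurately than the two-term form and is measurably
less sensitive to window-attenuation noise.

Around the core sit the supporting pieces: mixture bookkeeping
(Z̄ = (Σωᵢ Zᵢ^α)^(1/α) with α = 3.3, ρe = ρ·N_A·Σωᵢ Zᵢ/Aᵢ, Bragg-additivity
I-values), cubic-spline spectrum handling with per-window weights, a
semi-empirical per-window power-law CT-number correction, Bethe–Bloch SPR
with relativistic ion kinematics, water-equivalent-length extraction from
Bragg curves, and a synthetic-data module (attenuation tables, tube spectra,
rod phantoms, Bragg curves) plus a Gaussian-noise robustness study.

## Worked example

```python
import numpy as np
import pcctspr as p
from pcctspr import simulate as sim

table = sim.make_synthetic_attenuation_table(sim.REALISTIC_RULES)
spectrum = sim.make_toy_spectrum(kvp=150.0)

three = p.fit_three_pfm(table)
print(three.summary())
weighted = three.weighted(spectrum, p.DEFAULT_WINDOWS)

rod = p.packaged_materials()["BE-H-10"]       # cortical-bone phantom rod
mu = [p.spectrum_weighted_mu(table, rod, spectrum, w) for w in p.DEFAULT_WINDOWS]
res = weighted.solve_zeff(mu)

curve = p.fit_ivalue_curve(sim.make_tissue_ivalue_points())
ival = p.ivalue_from_zeff(curve, res.zeff)
spr = p.spr_bethe(res.rhoe, ival, p.BeamSpec(290.0), p.water_reference())
print(f"Z-eff = {res.zeff:.3f}  rho_e = {res.rhoe:.4g}  SPR = {spr:.4f}")
```

prints

```
Three-parameter-fitting model (per-channel ln sigma quadratic in ln Z)
  energy grid : 30.0-150.0 keV (49 points)
  Z range     : 1-29
  max |relative reconstruction error| : 1.420e-13
    channel pe    : max |rel err| = 1.705e-13
    channel incoh : max |rel err| = 1.420e-13
    channel coh   : max |rel err| = 1.563e-13
Z-eff = 12.470  rho_e = 4.726e+23  SPR = 1.3809
```

The fitted model reconstructs the synthetic power-law table to machine
precision (the quoted ~1e-13).  Decomposing the rod's four simulated window
attenuations returns Z̄ = 12.47 and ρe = 4.726×10²³ cm⁻³ against theory
values of 12.37 and 4.731×10²³ from the rod's composition, and an SPR of
1.381 versus 1.379 from the Bragg-additivity I-value — sub-percent recovery
of the quantities that set particle range.

A `pcctspr` console script exposes the same chain
(`fit-model`, `weight-model`, `fit-correction`, `decompose`, `roi-stats`,
`spr`, `noise-study`, `simulate-phantom`); images travel as 32-bit float
TIFF stacks, tables and spectra as CSV, models as JSON.

For a user-supplied cross-section table (e.g. exported from the NIST XCOM
database as per-electron channel values) use
`pcctspr.load_attenuation_table("table.csv")` with columns
`Z,E_keV,sigma_pe,sigma_incoh,sigma_coh`.

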