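# Methods

## Scope and model chain

`tissuelight` models how near-infrared light deposits energy in layered
tissue containing an optically tuned contrast agent, and how that energy
translates into heating and thermal dose.  The chain is:

1. **Tissue and agent optics** — plane-parallel layers, each with absorption
   `mu_a` (mm⁻¹), scattering `mu_s` (mm⁻¹), anisotropy `g` and refractive
   index `n`.  A chromophore uniformly distributed in a layer adds
   `ln(10)·ε·c` (cm⁻¹) of absorption via Beer–Lambert; the mixed layer is a
   linear combination of tissue and agent coefficients.  The agent is
   treated as non-scattering by default (dilute nanoparticle suspension); an
   `agent_mus` hook exists.
2. **Photon transport** — weighted-packet Monte Carlo for a pencil beam:
   exponential free paths in `mu_t = mu_a + mu_s`, weight deposition
   `w·mu_a/mu_t` per interaction, Henyey–Greenstein scattering, unpolarized
   Fresnel reflection/Snell refraction at interfaces, unbiased Russian
   roulette.  Tallies on a cylindrical `(r, z)` grid give the impulse
   response: absorbed energy density per unit delivered energy (mm⁻³) and
   fluence `A/mu_a` (mm⁻²), plus specular/diffuse reflectance,
   transmittance and total absorbed fraction.
3. **Beam convolution** — the layered geometry is laterally invariant, so
   the finite-beam solution is the 2-D convolution of the impulse response
   with the beam irradiance.  For a Gaussian beam (energy `E`, 1/e² radius
   `R`) the azimuthal integral has the closed form
   `K(r,r') = (4E/R²)·exp(−2(r−r')²/R²)·i0e(4rr'/R²)`; the radial integral
   is a refined piecewise-constant quadrature over the tally bins.
4. **Photothermal estimation** — lumped energy balance
   `m·C_p·dT/dt = η·I·(1−10^−Abs) + Q_dis − hS·(T−T_surr)`.  The cooling
   tail gives `τ_c` from the linear `t` vs `ln θ` relation
   (`θ = (T−T_surr)/(T_max−T_surr)`), then `hS = m·C_p/τ_c` and
   `η = [hS·(T_max−T_surr) − Q_dis]/[I·(1−10^−Abs)]`.
5. **Dosimetry** — CEM43 thermal dose `Σ Δt·R^(43−T)` with `R = 0.25` below
   and `0.5` above 43 °C; contrast enhancement as post/baseline signal
   ratio; a photoacoustic initial-pressure proxy `p₀ = Γ·mu_a·Φ`.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| photons per run | 10⁶ | — | desk-scale runs with stable interface peaks after convolution; 10⁷ available by flag |
| depth / radial bins | 10 / 25 | µm | grid resolution of the study design |
| radial extent | 400 bins (10 mm) | — | overflow weight folded into the outermost bin and reported |
| roulette threshold, m | 10⁻⁴, 10 | — | unbiased termination preserving energy conservation |
| refractive indices | tissue 1.37, ambient 1.0 | — | standard soft-tissue NIR value; none are specified for this geometry |
| beam | 1 J, 4 mm | J, mm | 1/e² irradiance radius convention (FWHM by flag) |
| dose, uptake, tumor volume | 5 mg/kg, 1%, 50 mm³ | — | the stated dosing assumption; body mass 20 g (typical mouse), molar mass 775 g/mol |
| cooling-fit guards | skip 2 s, θ ≥ 0.05, 10 s plateau window | — | see below |
| trace noise σ | 0.1 | °C | typical IR-camera noise scale |
| CEM43 interval temperature | left endpoint | — | midpoint by flag; difference vanishes as Δt→0 |

## Numerical and design choices

* **Phase function.** "Anisotropy-informed" scattering is realised as
  Henyey–Greenstein, the convention of the layered-transport programs this
  design follows.
* **Partial steps at boundaries.** The residual dimensionless step length is
  preserved across an interface, not resampled — keeps free paths unbiased
  in heterogeneous stacks.
* **Roulette instead of hard termination.** A packet below the weight
  threshold survives with probability 1/m carrying m× weight; expected
  weight is conserved, so `R_sp + R_d + A + T_t = 1` holds to Monte Carlo
  tolerance in every run (asserted at 10⁻³).
* **Convolution quadrature.** The tallied density is a per-annulus average,
  so the source term is interpolated piecewise-constant per bin; this makes
  the quadrature preserve the tallied total exactly and behaves correctly
  at the sharply peaked axis.  The source grid is auto-refined when the
  beam radius approaches the bin width.  The interface peak is read on axis
  (the first radial bin) in the first tumor depth bin.
* **Cooling-fit robustness.** `T_max` is estimated as the mean of the final
  10 s of the heating plateau rather than the raw trace maximum (whose
  expectation is biased upward by the largest noise excursion); the first
  2 s after laser-off are skipped (sensor lag); cooling samples with
  θ < 0.05 are excluded because their `ln θ` is dominated by sensor noise
  and would otherwise bias the errors-in-variables regression.  With these
  guards, noiseless round trips recover (τ_c, hS, η) to 10⁻³ relative and
  0.1 °C noise leaves η within 5% in ≥95/100 seeded replicates.  The
  recovery experiments heat for ≥8 τ_c so that the plateau is a valid
  steady-state estimate — the estimator assumes `T_max ≈ T_ss`.
* **η clamping.** Estimates outside [0, 1] signal inconsistent inputs; they
  are clamped and flagged rather than silently reported.
* **CEM43 at exactly 43 °C.** The base is defined only for strict
  inequalities; `R = 0.5` is used at the tie, where the contribution is
  `R⁰ = 1` either way.
* **Contrast enhancement direction.** CE is post-injection over baseline
  (the form consistent with enhancement ratios > 1).

## What the synthetic generators emulate — and what they do not

* **Spectra.** Gaussian band models: monomer with a dominant 780 nm band and
  a 710 nm shoulder; J-aggregate with a dominant, red-shifted 890 nm band
  (~110 nm shift) and a minor residual band near 780 nm, calibrated so the
  852 nm and 890 nm extinctions are ≥3× the 808 nm value.  Peak scale is
  2–2.5×10⁵ M⁻¹cm⁻¹; only ratios matter downstream.  These are synthetic
  stand-ins encoding band structure, not measured lineshapes.
* **Optical-property table.** A versioned CSV with literature-style NIR
  magnitudes for epidermis/dermis/fat/tumor at 808/852/890 nm (tissue
  `mu_a` ~0.005–0.02 mm⁻¹, `mu_s` ~8–22 mm⁻¹, `g` = 0.9, `n` = 1.37), with
  weak spectral dispersion so unloaded-tissue transport is nearly
  wavelength-flat — the regime in which wavelength selectivity comes from
  the agent, not the tissue.  The table is a synthetic stand-in, not a
  measurement; everything is overridable via the CSV interface.
* **Traces.** The lumped forward model plus i.i.d. Gaussian noise.  Real
  thermography adds drift, convection transients and spatial averaging that
  the generator does not emulate; passing recovery tests therefore shows
  estimator correctness under the stated noise model, not robustness to
  every laboratory artifact.
* **PA depth series.** The initial-pressure proxy from a single-layer
  phantom run with log-normal multiplicative noise; no acoustic
  propagation, attenuation or transducer response.

## Problem sizes used

Unit and property tests run at 10³–10⁵ photons; the end-to-end spectral
checks run the three-wavelength loaded-tumor comparison at 10⁶ photons and
the seven-depth unloaded scan at 10⁵ photons per run.  The headline
fold-increase is insensitive to photon count beyond ~10⁵ because the
convolution integrates the impulse response over the whole beam area.

## Known limitations

* Steady-state transport only: no time resolution, polarization, or 3-D
  heterogeneity; beams are axisymmetric.
* No heat diffusion: the photothermal model is zero-dimensional (lumped);
  absorbed-energy maps are not coupled to a bioheat equation.
* Wavelength-independent refractive index; no fitting of optical properties
  from measured spectra.
* The PA proxy stops at initial pressure; no image formation or spectral
  unmixing.
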