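# tissuelight

Forward modelling for near-infrared photothermal therapy and photoacoustic
imaging with optically tuned contrast agents — specifically J-aggregated
indocyanine green, whose absorption red-shifts from ~780 nm to ~890 nm and
away from the hemoglobin window.

The package answers the planning question behind that spectral shift: *if a
tumor at depth is loaded with the agent at a realistic systemic dose, how
much more optical energy is deposited at the tumor when the laser moves from
808 nm to 852 or 890 nm?* — and then follows the energy downstream into
heating efficiency and thermal dose.

## What it computes

* **Layered-tissue photon Monte Carlo** (MCML-style): weighted photon
  packets with exponential free paths, `w·μₐ/μₜ` weight deposition,
  Henyey–Greenstein scattering, Fresnel/Snell interfaces and unbiased
  Russian roulette, tallied on an `(r, z)` cylindrical grid as absorbed
  energy density and fluence per unit delivered energy, plus specular and
  diffuse reflectance, transmittance and total absorbed fraction.
* **Gaussian finite-beam convolution** of the impulse response
  (`S(r) = (2E/πR²)·e^(−2r²/R²)`), with depth profiles and the absorbed-energy
  peak at the fat–tumor interface.
* **Contrast-agent optical mixing**: Beer–Lambert conversion of a molar
  extinction spectrum at a dose-derived concentration
  (`c = dose·mass·uptake / (V_tumor·M)`), added linearly to the tumor layer's
  `μₐ`.
* **Photothermal conversion efficiency (η)** from heating/cooling traces via
  the lumped balance `m·C_p·dT/dt = η·I·(1−10^−Abs) + Q_dis − hS·(T−T_surr)`:
  cooling-constant fit (`t` vs `ln θ`), `hS = m·C_p/τ_c`, then
  `η = [hS·ΔT_max − Q_dis]/[I·(1−10^−Abs)]`.
* **CEM43 thermal dose** `Σ Δt·R^(43−T)` (R = 0.25 below / 0.5 above 43 °C),
  contrast-enhancement ratios, and a photoacoustic initial-pressure proxy
  `p₀ = Γ·μₐ·Φ`.
* **Synthetic generators** for every input: band-model absorber spectra, a
  literature-style optical-property table (epidermis/dermis/fat/tumor at
  808/852/890 nm), noisy lumped-model temperature traces with known ground
  truth, and PA-signal-vs-depth series.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

Tumor under 2 mm of fat, loaded at 5 mg/kg with 1% tumor uptake, 10⁵ photons
per wavelength:

```python
from tissuelight import (AgentLoading, BeamProfile, McConfig, SimulationGrid,
                         build_tumor_stack, convolve_beam, run_simulation,
                         tumor_interface_peak)
from tissuelight.synthetic import gen_absorbance_spectra

spectrum = gen_absorbance_spectra("j_aggregate")
beam = BeamProfile(energy=1.0, radius=4.0)   # 1 J, 4 mm 1/e^2 radius
for wl in (808.0, 852.0, 890.0):
    stack = build_tumor_stack(2.0, wl, agent_spectrum=spectrum,
                              loading=AgentLoading())
    imp = run_simulation(stack, wl, SimulationGrid.for_stack(stack),
                         McConfig(n_photons=100_000, seed=1))
    peak = tumor_interface_peak(stack, convolve_beam(imp, beam))
    print(f"{wl:g} nm: interface peak {peak:.3e} J/mm^3, "
          f"A_total {imp.A_total:.3f}")
```

```
808 nm: interface peak 1.860e-03 J/mm^3, A_total 0.334
852 nm: interface peak 6.723e-03 J/mm^3, A_total 0.431
890 nm: interface peak 1.430e-02 J/mm^3, A_total 0.456
```

The peak absorbed energy density in the first tumor depth bin rises ~3.6×
at 852 nm and ~7.7× at 890 nm relative to 808 nm: through tissue whose own
optics are nearly wavelength-flat, the agent's red-shifted band concentrates
the deposited energy at the tumor.

Fitting conversion efficiency from a synthetic trace with known truth
(η = 0.15, τ_c = 180 s, σ = 0.1 °C):

```python
from tissuelight import LumpedThermalParams, estimate_pce_from_trace
from tissuelight.synthetic import TraceSpec, gen_temperature_trace

params = LumpedThermalParams(m=0.3, I=750.0, tau_c=180.0)
trace, truth = gen_temperature_trace(TraceSpec(
    eta=0.15, params=params, on_duration=1500, off_duration=900, seed=3))
res = estimate_pce_from_trace(trace, m=0.3, C_p=4.18, I=750.0, Abs_lambda=1.0)
print(f"eta = {100*res.eta:.2f}%  tau_c = {res.tau_c:.1f} s  "
      f"R^2 = {res.r_squared:.5f}")
```

```
eta = 14.96%  tau_c = 180.8 s  R^2 = 0.99514
```

The same operations are available from the shell:

```bash
tissuelight depth-scan --wavelengths 808,852,890 --fat 0:6:1 --agent --out scan.csv
tissuelight pce-fit trace.csv --blank blank.csv --mass 0.3 --power 750
tissuelight cem43 trace.csv
tissuelight synth spectra --out synth/
```

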