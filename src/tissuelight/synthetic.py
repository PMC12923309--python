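"""Synthetic inputs for the pipeline: spectra, traces, property tables, depth series.

Every generator is pure given (spec, seed) and emulates the *structure* of
the corresponding laboratory input rather than any measured values:

* absorbance spectra — Gaussian band models of monomeric indocyanine green
  (dominant 780 nm band, 710 nm shoulder) and its liposomal J-aggregate
  (dominant, red-shifted 890 nm band with a minor residual-monomer band),
  calibrated so the J-aggregate extinction at 852 and 890 nm is several-fold
  its 808 nm value;
* temperature traces — the lumped heating/cooling model plus i.i.d. Gaussian
  sensor noise;
* the optical-property table — a versioned, packaged literature-style table
  for epidermis/dermis/fat/tumor at 808/852/890 nm (synthetic stand-ins with
  representative NIR magnitudes, not measurements);
* photoacoustic depth series — the initial-pressure proxy read off a
  single-layer Monte Carlo run, with multiplicative noise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .optics import AbsorberSpectrum, Layer, OpticalProperties
from .photothermal import LumpedThermalParams, TemperatureTrace, simulate_heating

__all__ = [
    "SpectrumSpec",
    "TraceSpec",
    "gen_absorbance_spectra",
    "gen_temperature_trace",
    "gen_optical_property_table",
    "default_property_table",
    "gen_pa_depth_series",
]

DEFAULT_WAVELENGTHS = (808.0, 852.0, 890.0)


@dataclass(frozen=True)
class SpectrumSpec:
    """Additive Gaussian band model: centers, 1-sigma widths, peak extinctions."""

    centers: tuple[float, ...]
    widths: tuple[float, ...]
    peaks: tuple[float, ...]
    grid_start: float = 650.0
    grid_stop: float = 1000.0
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.widths) == len(self.peaks)):
            raise ValueError("centers, widths, peaks must have equal length")
        if any(w <= 0 for w in self.widths):
            raise ValueError("band widths must be > 0")
        if any(p < 0 for p in self.peaks):
            raise ValueError("band peaks must be >= 0")


# Monomer: 780 nm main band + 710 nm vibronic shoulder.  J-aggregate: narrow,
# red-shifted 890 nm band of increased magnitude + minor residual band near
# 780 nm.  Peak scale is set relative to a 2e5 M^-1 cm^-1 monomer maximum;
# only ratios matter downstream.
_MONOMER_SPEC = SpectrumSpec(centers=(780.0, 710.0), widths=(30.0, 20.0),
                             peaks=(2.0e5, 0.4e5))
_JAGG_SPEC = SpectrumSpec(centers=(890.0, 780.0), widths=(28.0, 25.0),
                          peaks=(2.5e5, 0.3e5))


def _spectrum_from_spec(name: str, spec: SpectrumSpec) -> AbsorberSpectrum:
    wl = np.arange(spec.grid_start, spec.grid_stop + spec.grid_step / 2, spec.grid_step)
    eps = np.zeros_like(wl)
    for c, w, p in zip(spec.centers, spec.widths, spec.peaks):
        eps += p * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return AbsorberSpectrum(name=name, wavelengths=wl, epsilon=eps)


def gen_absorbance_spectra(kind: str, spec: Optional[SpectrumSpec] = None) -> AbsorberSpectrum:
    """Synthetic molar-extinction spectrum of the monomer or the J-aggregate.

    ``kind`` is ``"monomer"`` (dominant 780 nm band) or ``"j_aggregate"``
    (dominant 890 nm band, ~100 nm red shift); pass ``spec`` to override the
    band model.
    """
    if kind not in ("monomer", "j_aggregate"):
        raise ValueError("kind must be 'monomer' or 'j_aggregate'")
    if spec is None:
        spec = _MONOMER_SPEC if kind == "monomer" else _JAGG_SPEC
    return _spectrum_from_spec(kind, spec)


@dataclass(frozen=True)
class TraceSpec:
    """Specification of a synthetic heating/cooling trace with known truth."""

    eta: float = 0.15
    params: LumpedThermalParams = field(
        default_factory=lambda: LumpedThermalParams(m=0.3, I=750.0, tau_c=180.0))
    on_duration: float = 300.0
    off_duration: float = 600.0
    dt: float = 1.0
    noise_sigma: float = 0.1  # degC, i.i.d. Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.on_duration <= 0 or self.off_duration <= 0 or self.dt <= 0:
            raise ValueError("durations and dt must be > 0")


def gen_temperature_trace(spec: TraceSpec) -> tuple[TemperatureTrace, dict]:
    """Lumped-model trace plus the ground-truth parameters that generated it.

    Noise is additive i.i.d. Gaussian on the temperatures; sigma = 0 returns
    the forward model exactly.  The ground-truth record carries (eta, tau_c,
    hS, T_surr, noise_sigma, seed) for recovery scoring.
    """
    clean = simulate_heating(spec.params, spec.eta, spec.on_duration,
                             spec.off_duration, spec.dt)
    T = clean.temperatures
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        T = T + rng.normal(0.0, spec.noise_sigma, size=T.shape)
    trace = TemperatureTrace(clean.times, T, clean.laser_on, clean.T_surr)
    truth = {
        "eta": spec.eta, "tau_c": spec.params.tau_c, "hS": spec.params.hS,
        "Q_dis": spec.params.Q_dis, "I": spec.params.I,
        "Abs_lambda": spec.params.Abs_lambda, "T_surr": spec.params.T_surr,
        "noise_sigma": spec.noise_sigma, "seed": spec.seed,
    }
    return trace, truth


@lru_cache(maxsize=1)
def _load_packaged_table() -> dict[str, Layer]:
    with resources.files("tissuelight.data").joinpath("optical_properties.csv").open() as fh:
        rows = [r for r in csv.DictReader(
            (line for line in fh if not line.startswith("#")))]
    layers: dict[str, dict] = {}
    for r in rows:
        name = r["layer"]
        scale = 0.1 if r["unit"] == "per_cm" else 1.0
        entry = layers.setdefault(name, {"thickness": float(r["thickness_mm"]), "props": {}})
        entry["props"][float(r["wavelength_nm"])] = OpticalProperties(
            mu_a=float(r["mua"]) * scale, mu_s=float(r["mus"]) * scale,
            g=float(r["g"]), n=float(r["n"]),
        )
    return {name: Layer(name=name, thickness=e["thickness"], props=e["props"])
            for name, e in layers.items()}


def default_property_table() -> dict[str, Layer]:
    """The packaged default epidermis/dermis/fat/tumor property table."""
    return dict(_load_packaged_table())


def gen_optical_property_table(
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS,
    interpolate: bool = False,
) -> dict[str, Layer]:
    """Layer records for the requested wavelengths from the packaged table.

    Wavelengths outside {808, 852, 890} nm require ``interpolate=True`` and
    must lie within that range (linear interpolation per property).
    """
    base = default_property_table()
    out: dict[str, Layer] = {}
    for name, layer in base.items():
        known = sorted(layer.props)
        props = {}
        for wl in wavelengths:
            if wl in layer.props:
                props[float(wl)] = layer.props[wl]
            elif interpolate and known[0] <= wl <= known[-1]:
                vals = {attr: float(np.interp(wl, known,
                                              [getattr(layer.props[k], attr) for k in known]))
                        for attr in ("mu_a", "mu_s", "g", "n")}
                props[float(wl)] = OpticalProperties(**vals)
            else:
                raise ValueError(
                    f"{wl} nm not in the packaged table for {name!r}; "
                    f"pass interpolate=True for wavelengths within {known[0]}-{known[-1]} nm")
        out[name] = Layer(name=name, thickness=layer.thickness, props=props)
    return out


def gen_pa_depth_series(
    spectrum: AbsorberSpectrum,
    wavelength: float,
    depths: Sequence[float],
    concentration: float = 2.0e-5,
    noise_sigma: float = 0.05,
    seed: int = 0,
    n_photons: int = 20_000,
    grueneisen: float = 1.0,
):
    """Photoacoustic signal versus depth in an agent-loaded phantom.

    Runs one single-layer Monte Carlo on a tissue-mimicking phantom with the
    agent's Beer-Lambert absorption mixed in, convolves with the default
    beam, reads the initial-pressure proxy on axis at each depth and applies
    multiplicative log-normal noise.  Returns a DataFrame (depth_mm, signal,
    signal_clean); the clean expectation decreases with depth.
    """
    import pandas as pd

    from .convolution import BeamProfile, convolve_beam, depth_profile
    from .dosimetry import pa_signal_proxy
    from .montecarlo import McConfig, SimulationGrid, run_simulation
    from .optics import TissueStack, mix_properties, molar_to_mua

    depths = np.asarray(list(depths), dtype=float)
    if depths.size == 0 or np.any(depths <= 0) or np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be positive and strictly increasing")

    phantom_base = OpticalProperties(mu_a=0.01, mu_s=1.0, g=0.9, n=1.37)
    agent_mua = molar_to_mua(spectrum, concentration, wavelength)
    mixed = mix_properties(phantom_base, agent_mua)
    span = float(depths[-1] * 1.2)
    stack = TissueStack(layers=[Layer("phantom", span, {wavelength: mixed})])
    grid = SimulationGrid.for_stack(stack, dz=min(0.05, span / 50), dr=0.05, nr=200)
    imp = run_simulation(stack, wavelength, grid,
                         McConfig(n_photons=n_photons, seed=int(seed) & 0x7FFFFFFF))
    fmap = convolve_beam(imp, BeamProfile(energy=1.0, radius=2.0))
    prof = depth_profile(fmap)  # columns z, fluence, absorbed
    proxy = pa_signal_proxy(prof[:, 2], grueneisen)
    clean = np.interp(depths, prof[:, 0], proxy)

    rng = np.random.default_rng(seed)
    noise = rng.lognormal(mean=0.0, sigma=noise_sigma, size=depths.shape) \
        if noise_sigma > 0 else np.ones_like(depths)
    return pd.DataFrame({"depth_mm": depths, "signal": clean * noise,
                         "signal_clean": clean})
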