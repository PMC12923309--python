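"""Layered tissue constructs and contrast-agent optical mixing.

A tissue stack is an ordered sequence of homogeneous plane-parallel layers,
each carrying the four optical properties that drive photon transport in the
near infrared: the absorption coefficient ``mu_a``, the scattering
coefficient ``mu_s`` (both per mm), the scattering anisotropy ``g`` (the mean
cosine of the deflection angle) and the refractive index ``n``.

A contrast agent distributed through a layer adds to that layer's absorption
via Beer-Lambert: a molar concentration ``c`` of a chromophore with decadic
extinction ``epsilon`` (M^-1 cm^-1) contributes ``ln(10) * epsilon * c``
cm^-1 of absorption.  Mixing is a plain linear combination of tissue and
agent coefficients; the agent is treated as non-scattering by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "OpticalProperties",
    "Layer",
    "TissueStack",
    "AbsorberSpectrum",
    "AgentLoading",
    "molar_to_mua",
    "mix_properties",
    "dose_to_concentration",
    "build_tumor_stack",
]

LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class OpticalProperties:
    """Single-wavelength optical properties of a homogeneous medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, per mm.
    mu_s : float
        Scattering coefficient, per mm.
    g : float
        Scattering anisotropy (mean deflection cosine), in (-1, 1).
    n : float
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"g must lie in (-1, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (per mm)."""
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class Layer:
    """A plane-parallel tissue layer with per-wavelength properties.

    ``props`` maps wavelength (nm) to :class:`OpticalProperties`.  The last
    layer of a stack may be flagged semi-infinite, in which case
    ``thickness`` is ignored during transport.
    """

    name: str
    thickness: float
    props: Mapping[float, OpticalProperties]
    semi_infinite: bool = False

    def __post_init__(self) -> None:
        if self.thickness <= 0 and not self.semi_infinite:
            raise ValueError(
                f"layer {self.name!r}: thickness must be > 0 (got {self.thickness})"
            )
        if not self.props:
            raise ValueError(f"layer {self.name!r}: no optical properties given")

    def at(self, wavelength: float) -> OpticalProperties:
        try:
            return self.props[wavelength]
        except KeyError:
            raise KeyError(
                f"layer {self.name!r} has no properties at {wavelength} nm "
                f"(available: {sorted(self.props)})"
            ) from None


@dataclass(frozen=True)
class TissueStack:
    """Ordered layers from the illuminated surface downward.

    Depth z is 0 at the top surface and increases into the tissue.  The
    ambient media above and below are characterised only by their refractive
    indices ``n_above`` and ``n_below``.
    """

    layers: Sequence[Layer]
    n_above: float = 1.0
    n_below: float = 1.0
    fat_thickness_x: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("a tissue stack needs at least one layer")
        if self.n_above < 1.0 or self.n_below < 1.0:
            raise ValueError("ambient refractive indices must be >= 1")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def boundaries(self) -> np.ndarray:
        """Depths of the layer interfaces, 0 first, cumulative thereafter (mm)."""
        t = np.array([lay.thickness for lay in self.layers], dtype=float)
        return np.concatenate([[0.0], np.cumsum(t)])

    @property
    def total_thickness(self) -> float:
        return float(self.boundaries[-1])

    def layer_span(self, name: str) -> tuple[float, float]:
        """Return the (top, bottom) depth of the named layer (mm)."""
        b = self.boundaries
        for i, lay in enumerate(self.layers):
            if lay.name == name:
                return float(b[i]), float(b[i + 1])
        raise KeyError(f"stack has no layer named {name!r}")

    def layer_index_at(self, z: float) -> int:
        """Index of the layer containing depth z (bottom boundary exclusive)."""
        b = self.boundaries
        if z < 0 or z > b[-1]:
            raise ValueError(f"depth {z} mm outside the stack [0, {b[-1]}]")
        idx = int(np.searchsorted(b, z, side="right")) - 1
        return min(idx, len(self.layers) - 1)

    def wavelengths(self) -> list[float]:
        """Wavelengths with a complete property record in every layer."""
        sets = [set(lay.props) for lay in self.layers]
        return sorted(set.intersection(*sets))


@dataclass(frozen=True)
class AbsorberSpectrum:
    """Decadic molar extinction spectrum of a chromophore.

    ``epsilon`` is in M^-1 cm^-1 on a strictly increasing wavelength grid
    (nm).  Queries between grid points use linear interpolation; queries
    outside the grid raise.
    """

    name: str
    wavelengths: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        if wl.ndim != 1 or wl.shape != eps.shape:
            raise ValueError("wavelengths and epsilon must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("spectrum needs at least two grid points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(eps < 0):
            raise ValueError("extinction coefficients must be >= 0")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "epsilon", eps)

    def extinction_at(self, wavelength: float) -> float:
        """Linear interpolation of epsilon (M^-1 cm^-1) at ``wavelength`` nm."""
        wl = self.wavelengths
        if wavelength < wl[0] or wavelength > wl[-1]:
            raise ValueError(
                f"{wavelength} nm outside the spectrum range [{wl[0]}, {wl[-1]}] nm"
            )
        return float(np.interp(wavelength, wl, self.epsilon))


@dataclass(frozen=True)
class AgentLoading:
    """Dose-based uniform loading of a contrast agent into a tumor volume.

    The molar concentration follows from distributing ``uptake_fraction`` of
    the injected dose (``dose`` mg per kg body mass) uniformly through
    ``tumor_volume`` mm^3 of tissue.
    """

    dose: float = 5.0            # mg per kg
    body_mass: float = 0.020     # kg; default 20 g mouse
    uptake_fraction: float = 0.01
    tumor_volume: float = 50.0   # mm^3
    molar_mass: float = 775.0    # g/mol

    def __post_init__(self) -> None:
        for name in ("dose", "body_mass", "uptake_fraction", "tumor_volume", "molar_mass"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.uptake_fraction > 1:
            raise ValueError("uptake_fraction must lie in (0, 1]")

    @property
    def concentration(self) -> float:
        """Molar concentration in the tumor volume."""
        return dose_to_concentration(self)


def dose_to_concentration(loading: AgentLoading) -> float:
    """Molar concentration from a dose-based uniform-distribution assumption.

    mass in tumor [g]   = dose [mg/kg] * body_mass [kg] * uptake_fraction / 1000
    volume [L]          = tumor_volume [mm^3] * 1e-6
    concentration [M]   = mass / (molar_mass * volume)
    """
    mass_g = loading.dose * loading.body_mass * loading.uptake_fraction * 1e-3
    volume_l = loading.tumor_volume * 1e-6
    return mass_g / (loading.molar_mass * volume_l)


def molar_to_mua(
    spectrum: AbsorberSpectrum, concentration: float, wavelength: float
) -> float:
    """Beer-Lambert bridge from molar extinction to an absorption coefficient.

    ``mu_a = ln(10) * epsilon * c`` in cm^-1, returned in mm^-1 (divide by 10).
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    eps = spectrum.extinction_at(wavelength)
    return LN10 * eps * concentration / 10.0


def mix_properties(
    tissue: OpticalProperties, agent_mua: float, agent_mus: float = 0.0
) -> OpticalProperties:
    """Linear combination of tissue and agent coefficients.

    Absorption and scattering add; anisotropy and refractive index are
    inherited from the tissue (the agent is dilute).
    """
    if agent_mua < 0 or agent_mus < 0:
        raise ValueError("agent coefficients must be >= 0")
    return OpticalProperties(
        mu_a=tissue.mu_a + agent_mua,
        mu_s=tissue.mu_s + agent_mus,
        g=tissue.g,
        n=tissue.n,
    )


# Geometry of the four-layer tumor model: thin epidermis, dermis, a fat layer
# of variable thickness x that sets the tumor depth, then the tumor itself.
EPIDERMIS_MM = 0.1
DERMIS_MM = 2.0
TUMOR_MM = 2.0
MAX_FAT_MM = 6.0


def build_tumor_stack(
    fat_thickness: float,
    wavelength: float,
    agent_spectrum: Optional[AbsorberSpectrum] = None,
    loading: Optional[AgentLoading] = None,
    property_table: Optional[Mapping[str, Layer]] = None,
    n_above: float = 1.0,
    n_below: float = 1.0,
) -> TissueStack:
    """Build the epidermis/dermis/fat/tumor stack at one wavelength.

    Parameters
    ----------
    fat_thickness : float
        Fat-layer thickness x in [0, 6] mm; x = 0 omits the fat layer and
        puts the tumor directly under the dermis.
    wavelength : float
        Wavelength (nm); must be present in the property table.
    agent_spectrum, loading : optional
        When both are given, the agent's Beer-Lambert absorption at the
        loading concentration is mixed into the tumor layer.
    property_table : optional
        Mapping layer name -> :class:`Layer`; defaults to the packaged
        literature-style table (see :mod:`tissuelight.synthetic`).
    """
    if not 0.0 <= fat_thickness <= MAX_FAT_MM:
        raise ValueError(
            f"fat thickness must lie in [0, {MAX_FAT_MM}] mm, got {fat_thickness}"
        )
    if (agent_spectrum is None) != (loading is None):
        raise ValueError("agent_spectrum and loading must be given together")
    if property_table is None:
        from .synthetic import default_property_table

        property_table = default_property_table()

    def layer(name: str, thickness: float) -> Layer:
        base = property_table[name]
        base.at(wavelength)  # raises early on a missing wavelength
        return replace(base, thickness=thickness)

    layers = [layer("epidermis", EPIDERMIS_MM), layer("dermis", DERMIS_MM)]
    if fat_thickness > 0:
        layers.append(layer("fat", fat_thickness))

    tumor = layer("tumor", TUMOR_MM)
    if agent_spectrum is not None and loading is not None:
        agent_mua = molar_to_mua(agent_spectrum, loading.concentration, wavelength)
        mixed = {
            wl: mix_properties(op, molar_to_mua(agent_spectrum, loading.concentration, wl))
            if agent_spectrum.wavelengths[0] <= wl <= agent_spectrum.wavelengths[-1]
            else op
            for wl, op in tumor.props.items()
        }
        # ensure the requested wavelength itself is mixed
        mixed[wavelength] = mix_properties(tumor.at(wavelength), agent_mua)
        tumor = replace(tumor, props=mixed)
    layers.append(tumor)

    return TissueStack(
        layers=layers,
        n_above=n_above,
        n_below=n_below,
        fat_thickness_x=fat_thickness,
    )
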