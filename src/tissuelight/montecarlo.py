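"""Weighted photon-packet Monte Carlo through a layered tissue stack.

The transport model is the standard multi-layer scheme for plane-parallel
media: photon packets are launched straight down into the stack from an
infinitesimally narrow beam, take free-path steps drawn from the exponential
distribution of the local total interaction coefficient, deposit the
absorbed fraction ``mu_a / mu_t`` of their weight at each interaction site,
and scatter into a new direction drawn from the Henyey-Greenstein phase
function.  Layer interfaces apply unpolarized Fresnel reflection with
Snell refraction; low-weight packets undergo unbiased Russian roulette.

Absorbed weight is tallied on a cylindrical (r, z) grid.  Normalising by the
photon count and the bin volumes gives the impulse response: absorbed energy
density per unit delivered energy (mm^-3), from which fluence follows as
``A / mu_a``.  The impulse response is later convolved with a finite beam
profile (see :mod:`tissuelight.convolution`).

The inner loop is compiled with numba; the module-level functions
(:func:`sample_step`, :func:`spin`, :func:`boundary_interaction`, ...)
expose the same jitted primitives one interaction at a time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

from .optics import TissueStack

__all__ = [
    "SimulationGrid",
    "McConfig",
    "PhotonState",
    "ImpulseResponse",
    "sample_step",
    "deposit_weight",
    "spin",
    "fresnel_reflectance",
    "boundary_interaction",
    "roulette",
    "launch",
    "run_simulation",
]


@dataclass(frozen=True)
class SimulationGrid:
    """Cylindrical tally grid: depth bins of ``dz`` mm, radial bins of ``dr`` mm."""

    dz: float = 0.010   # 10 um depth step
    dr: float = 0.025   # 25 um radial step
    nz: int = 1000
    nr: int = 400

    def __post_init__(self) -> None:
        if self.dz <= 0 or self.dr <= 0:
            raise ValueError("grid steps must be > 0")
        if self.nz < 1 or self.nr < 1:
            raise ValueError("grid bin counts must be >= 1")

    @classmethod
    def for_stack(cls, stack: TissueStack, dz: float = 0.010, dr: float = 0.025,
                  nr: int = 400) -> "SimulationGrid":
        """Grid whose depth bins exactly span the (finite) stack."""
        nz = max(1, int(round(stack.total_thickness / dz)))
        return cls(dz=dz, dr=dr, nz=nz, nr=nr)

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.nr) + 0.5) * self.dr

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz


@dataclass(frozen=True)
class McConfig:
    """Run parameters: photon count, roulette threshold/survival factor, seed."""

    n_photons: int = 1_000_000
    weight_threshold: float = 1e-4
    roulette_m: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0.0 < self.weight_threshold < 1.0:
            raise ValueError("weight_threshold must lie in (0, 1)")
        if self.roulette_m < 2:
            raise ValueError("roulette survival factor must be >= 2")


@dataclass(frozen=True)
class PhotonState:
    """A photon packet: position (mm), unit direction, weight, layer index."""

    position: np.ndarray
    direction: np.ndarray
    weight: float
    layer_index: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if pos.shape != (3,) or d.shape != (3,):
            raise ValueError("position and direction must be 3-vectors")
        if abs(float(np.linalg.norm(d)) - 1.0) > 1e-9:
            raise ValueError("direction must have unit norm (within 1e-9)")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("weight must lie in (0, 1]")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class ImpulseResponse:
    """Point-source (impulse) response of the stack at one wavelength.

    ``A_rz`` is absorbed energy density per unit delivered energy (mm^-3) on
    the (nr, nz) grid; ``Phi_rz`` is the fluence per unit delivered energy
    (mm^-2), ``A / mu_a`` where ``mu_a > 0``.  The scalar tallies are energy
    fractions: specular reflectance ``R_sp``, diffuse reflectance ``R_d``,
    transmittance ``T_t`` and total absorbed fraction ``A_total``.  Weight
    landing outside the grid is folded into the outermost bins and reported
    in ``overflow_r`` / ``overflow_z``.
    """

    A_rz: np.ndarray
    Phi_rz: np.ndarray
    mu_a_z: np.ndarray
    grid: SimulationGrid
    R_sp: float
    R_d: float
    T_t: float
    A_total: float
    n_photons: int
    seed: int
    wavelength: Optional[float] = None
    overflow_r: float = 0.0
    overflow_z: float = 0.0

    @property
    def r_centers(self) -> np.ndarray:
        return self.grid.r_centers

    @property
    def z_centers(self) -> np.ndarray:
        return self.grid.z_centers

    @property
    def conservation_residual(self) -> float:
        return abs(self.R_sp + self.R_d + self.A_total + self.T_t - 1.0)


# ---------------------------------------------------------------------------
# jitted primitives
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sample_step(mu_t: float, xi: float) -> float:
    return -math.log(xi) / mu_t


@njit(cache=True)
def _hg_cos(g: float, xi: float) -> float:
    if g == 0.0:
        return 2.0 * xi - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    ct = (1.0 + g * g - t * t) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def _spin_dir(ux: float, uy: float, uz: float, g: float,
              xi1: float, xi2: float) -> tuple:
    ct = _hg_cos(g, xi1)
    st = math.sqrt(1.0 - ct * ct)
    psi = 2.0 * math.pi * xi2
    cp = math.cos(psi)
    sp = math.sin(psi)
    if abs(uz) > 0.99999:
        nux = st * cp
        nuy = st * sp
        nuz = ct if uz >= 0.0 else -ct
    else:
        tmp = math.sqrt(1.0 - uz * uz)
        nux = st * (ux * uz * cp - uy * sp) / tmp + ux * ct
        nuy = st * (uy * uz * cp + ux * sp) / tmp + uy * ct
        nuz = -st * cp * tmp + uz * ct
    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True)
def _fresnel(n1: float, n2: float, ca1: float) -> tuple:
    """Unpolarized Fresnel reflectance and transmission cosine.

    ``ca1`` is the magnitude of the incidence cosine.  Returns (R, ca2);
    R = 1 and ca2 = 0 beyond the critical angle.
    """
    if n1 == n2:
        return 0.0, ca1
    if ca1 > 1.0 - 1e-12:
        r = (n2 - n1) / (n2 + n1)
        return r * r, 1.0
    if ca1 < 1e-6:
        return 1.0, 0.0
    sa1 = math.sqrt(1.0 - ca1 * ca1)
    sa2 = n1 * sa1 / n2
    if sa2 >= 1.0:
        return 1.0, 0.0
    ca2 = math.sqrt(1.0 - sa2 * sa2)
    cap = ca1 * ca2 - sa1 * sa2
    cam = ca1 * ca2 + sa1 * sa2
    sap = sa1 * ca2 + ca1 * sa2
    sam = sa1 * ca2 - ca1 * sa2
    r = 0.5 * sam * sam * (cam * cam + cap * cap) / (sap * sap * cam * cam)
    return r, ca2


@njit(cache=True)
def _transport_kernel(mu_a, mu_s, g, n_layer, z_top, z_bot,
                      n_above, n_below,
                      nr, nz, dr, dz,
                      n_photons, seed, w_threshold, m_roulette):
    """Hop-drop-spin loop for all photons; raw weight tallies.

    Returns (A_raw[nr, nz], r_d, t_t, a_total, overflow_r, overflow_z)
    with weights in units of launched-photon weight (not yet normalised).
    """
    np.random.seed(seed)
    n_lay = mu_a.shape[0]
    A = np.zeros((nr, nz))
    r_d = 0.0
    t_t = 0.0
    a_total = 0.0
    ovr_r = 0.0
    ovr_z = 0.0

    tmp = (n_above - n_layer[0]) / (n_above + n_layer[0])
    r_sp = tmp * tmp
    inv_m = 1.0 / m_roulette

    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0 - r_sp
        lay = 0
        sleft = 0.0  # residual dimensionless step, preserved across interfaces
        alive = True

        while alive:
            mut = mu_a[lay] + mu_s[lay]

            # distance to the boundary ahead
            if uz > 0.0:
                db = (z_bot[lay] - z) / uz
            elif uz < 0.0:
                db = (z_top[lay] - z) / uz
            else:
                db = 1e30

            if mut <= 0.0:
                # non-interacting (glass-like) layer: boundary-to-boundary
                if db >= 1e30:
                    break  # trapped parallel ray; drop the packet
                s = db
                hit = True
            else:
                if sleft == 0.0:
                    xi = np.random.random()
                    while xi <= 0.0:
                        xi = np.random.random()
                    sleft = -math.log(xi)
                s = sleft / mut
                hit = db <= s

            if hit:
                # move to the boundary; spend the used part of the step
                x += ux * db
                y += uy * db
                if mut > 0.0:
                    sleft -= db * mut
                going_down = uz > 0.0
                z = z_bot[lay] if going_down else z_top[lay]
                if going_down:
                    n2 = n_layer[lay + 1] if lay + 1 < n_lay else n_below
                else:
                    n2 = n_layer[lay - 1] if lay > 0 else n_above
                refl, ca2 = _fresnel(n_layer[lay], n2, abs(uz))
                if np.random.random() <= refl:
                    uz = -uz
                else:
                    if going_down and lay + 1 >= n_lay:
                        t_t += w
                        alive = False
                    elif (not going_down) and lay == 0:
                        r_d += w
                        alive = False
                    else:
                        ratio = n_layer[lay] / n2
                        ux *= ratio
                        uy *= ratio
                        uz = ca2 if going_down else -ca2
                        # renormalise against rounding drift
                        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= norm
                        uy /= norm
                        uz /= norm
                        lay = lay + 1 if going_down else lay - 1
                continue

            # full step inside the layer
            x += ux * s
            y += uy * s
            z += uz * s
            sleft = 0.0

            # drop: deposit the absorbed fraction of the weight
            dwa = w * mu_a[lay] / mut
            if dwa > 0.0:
                w -= dwa
                r = math.sqrt(x * x + y * y)
                ir = int(r / dr)
                iz = int(z / dz)
                if ir >= nr:
                    ir = nr - 1
                    ovr_r += dwa
                if iz >= nz:
                    iz = nz - 1
                    ovr_z += dwa
                elif iz < 0:
                    iz = 0
                A[ir, iz] += dwa
                a_total += dwa

            # spin: new direction from the Henyey-Greenstein phase function
            xi1 = np.random.random()
            xi2 = np.random.random()
            ux, uy, uz = _spin_dir(ux, uy, uz, g[lay], xi1, xi2)

            # roulette
            if w < w_threshold:
                if w <= 0.0:
                    alive = False
                elif np.random.random() < inv_m:
                    w *= m_roulette
                else:
                    alive = False

    return A, r_d, t_t, a_total, ovr_r, ovr_z


# ---------------------------------------------------------------------------
# per-operation surface
# ---------------------------------------------------------------------------

def sample_step(mu_t: float, uniform_draw: float) -> float:
    """Free-path length (mm): ``-ln(xi) / mu_t`` for xi in (0, 1)."""
    if mu_t <= 0:
        raise ValueError("mu_t must be > 0 (non-interacting layers use "
                         "boundary-to-boundary transport)")
    if not 0.0 < uniform_draw < 1.0:
        raise ValueError("draw must lie in the open interval (0, 1)")
    return float(_sample_step(mu_t, uniform_draw))


def deposit_weight(photon: PhotonState, props) -> tuple[PhotonState, float]:
    """Deposit the absorbed fraction ``w * mu_a / mu_t`` of the packet weight.

    Returns the updated photon and the deposited amount.  Where the photon's
    weight hits exactly zero the state is returned with a zero weight bypassing
    validation, signalling a dead packet.
    """
    mu_t = props.mu_a + props.mu_s
    if mu_t <= 0:
        raise ValueError("deposit requires mu_t > 0")
    dwa = photon.weight * props.mu_a / mu_t
    new_w = photon.weight - dwa
    if new_w > 0:
        new = replace(photon, weight=new_w)
    else:
        new = object.__new__(PhotonState)
        object.__setattr__(new, "position", photon.position)
        object.__setattr__(new, "direction", photon.direction)
        object.__setattr__(new, "weight", 0.0)
        object.__setattr__(new, "layer_index", photon.layer_index)
    return new, float(dwa)


def spin(direction: np.ndarray, g: float, draws: tuple[float, float]) -> np.ndarray:
    """Scatter ``direction`` by a Henyey-Greenstein deflection; returns a unit vector."""
    if not -1.0 < g < 1.0:
        raise ValueError("g must lie in (-1, 1)")
    d = np.asarray(direction, dtype=float)
    ux, uy, uz = _spin_dir(d[0], d[1], d[2], g, draws[0], draws[1])
    return np.array([ux, uy, uz])


def hg_cosine(g: float, uniform_draw: float) -> float:
    """Sample the deflection cosine of the Henyey-Greenstein phase function."""
    if not -1.0 < g < 1.0:
        raise ValueError("g must lie in (-1, 1)")
    return float(_hg_cos(g, uniform_draw))


def fresnel_reflectance(n1: float, n2: float, cos_incidence: float) -> float:
    """Unpolarized Fresnel reflectance at a planar interface."""
    r, _ = _fresnel(n1, n2, abs(cos_incidence))
    return float(r)


def boundary_interaction(
    direction: np.ndarray, n1: float, n2: float, uniform_draw: float
) -> tuple[str, np.ndarray]:
    """Resolve a layer-interface crossing: Fresnel reflect or Snell refract.

    ``direction`` is the unit propagation vector hitting a horizontal
    interface (normal along z).  Returns ("reflect", mirrored direction) or
    ("transmit", refracted direction).  Total internal reflection always
    reflects.
    """
    d = np.asarray(direction, dtype=float)
    uz = d[2]
    if uz == 0.0:
        raise ValueError("direction must have a normal component at the boundary")
    refl, ca2 = _fresnel(n1, n2, abs(uz))
    if uniform_draw <= refl:
        return "reflect", np.array([d[0], d[1], -uz])
    ratio = n1 / n2
    out = np.array([d[0] * ratio, d[1] * ratio, math.copysign(ca2, uz)])
    return "transmit", out / np.linalg.norm(out)


def roulette(
    photon: PhotonState, config: McConfig, uniform_draw: float
) -> Optional[PhotonState]:
    """Unbiased Russian roulette below the weight threshold.

    Above the threshold the photon is returned unchanged.  Below it, the
    packet survives with probability 1/m carrying m times the weight
    (preserving the expected weight) and is otherwise terminated (None).
    """
    if photon.weight >= config.weight_threshold:
        return photon
    if uniform_draw < 1.0 / config.roulette_m:
        return replace(photon, weight=min(photon.weight * config.roulette_m, 1.0))
    return None


def launch(stack: TissueStack) -> tuple[PhotonState, float]:
    """Launch a packet straight down at the origin; returns (photon, R_sp)."""
    n1 = next(iter(stack.layers[0].props.values())).n
    tmp = (stack.n_above - n1) / (stack.n_above + n1)
    r_sp = tmp * tmp
    photon = PhotonState(
        position=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]),
        weight=1.0 - r_sp, layer_index=0,
    )
    return photon, float(r_sp)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def _stack_arrays(stack: TissueStack, wavelength: float):
    props = [lay.at(wavelength) for lay in stack.layers]
    mu_a = np.array([p.mu_a for p in props])
    mu_s = np.array([p.mu_s for p in props])
    g = np.array([p.g for p in props])
    n = np.array([p.n for p in props])
    b = stack.boundaries
    z_top = b[:-1].copy()
    z_bot = b[1:].copy()
    if stack.layers[-1].semi_infinite:
        z_bot[-1] = 1e30
    return mu_a, mu_s, g, n, z_top, z_bot


def _mu_a_profile(stack: TissueStack, wavelength: float, grid: SimulationGrid) -> np.ndarray:
    b = stack.boundaries
    mu_a = np.array([lay.at(wavelength).mu_a for lay in stack.layers])
    z = grid.z_centers
    idx = np.clip(np.searchsorted(b, z, side="right") - 1, 0, len(stack.layers) - 1)
    out = mu_a[idx]
    if not stack.layers[-1].semi_infinite:
        out = np.where(z > b[-1], 0.0, out)
    return out


def run_simulation(
    stack: TissueStack,
    wavelength: float,
    grid: Optional[SimulationGrid] = None,
    config: Optional[McConfig] = None,
) -> ImpulseResponse:
    """Run the hop-drop-spin Monte Carlo and return the impulse response.

    Tallies are normalised per launched photon: ``A_rz`` in mm^-3 (absorbed
    energy density per unit delivered energy), fluence ``Phi_rz = A / mu_a``
    in mm^-2.  Identical (stack, wavelength, grid, config) inputs give
    bit-identical results.
    """
    if config is None:
        config = McConfig()
    if grid is None:
        if stack.layers[-1].semi_infinite:
            grid = SimulationGrid()
        else:
            grid = SimulationGrid.for_stack(stack)

    mu_a, mu_s, g, n, z_top, z_bot = _stack_arrays(stack, wavelength)
    seed32 = int(config.seed) & 0x7FFFFFFF
    A_raw, r_d, t_t, a_tot, ovr_r, ovr_z = _transport_kernel(
        mu_a, mu_s, g, n, z_top, z_bot,
        float(stack.n_above), float(stack.n_below),
        grid.nr, grid.nz, grid.dr, grid.dz,
        int(config.n_photons), seed32,
        float(config.weight_threshold), int(config.roulette_m),
    )

    N = float(config.n_photons)
    tmp = (stack.n_above - n[0]) / (stack.n_above + n[0])
    r_sp = float(tmp * tmp)

    # bin volumes: 2 pi r_center dr dz for annular ring bins
    ring = 2.0 * np.pi * grid.r_centers * grid.dr * grid.dz  # (nr,)
    A_rz = A_raw / (N * ring[:, None])

    mu_a_z = _mu_a_profile(stack, wavelength, grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        Phi = np.where(mu_a_z[None, :] > 0, A_rz / mu_a_z[None, :], 0.0)

    return ImpulseResponse(
        A_rz=A_rz, Phi_rz=Phi, mu_a_z=mu_a_z, grid=grid,
        R_sp=r_sp, R_d=float(r_d / N), T_t=float(t_t / N),
        A_total=float(a_tot / N), n_photons=config.n_photons,
        seed=config.seed, wavelength=wavelength,
        overflow_r=float(ovr_r / N), overflow_z=float(ovr_z / N),
    )
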