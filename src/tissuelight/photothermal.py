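"""Lumped-capacitance photothermal heating and conversion-efficiency estimation.

A well-stirred solution of mass m and specific heat C_p, illuminated by a
laser of incident power I (mW) at a wavelength where its decadic absorbance
is Abs, obeys the energy balance

    m C_p dT/dt = eta * I * (1 - 10^-Abs) + Q_dis - hS (T - T_surr)

where eta is the photothermal conversion efficiency (the fraction of the
absorbed optical power converted to heat), Q_dis the background dissipation
measured from a blank, and hS the lumped heat-transfer coefficient-area
product (mW/degC).  With the laser off the balance reduces to Newtonian
cooling with time constant tau_c = m C_p / hS, so the cooling tail gives

    theta(t) = (T - T_surr)/(T_max - T_surr) = exp(-t / tau_c)

and a linear fit of t against ln(theta) recovers tau_c, hence hS, hence

    eta = [hS (T_max - T_surr) - Q_dis] / [I (1 - 10^-Abs)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "TemperatureTrace",
    "LumpedThermalParams",
    "PCEResult",
    "simulate_heating",
    "theta_transform",
    "plateau_temperature",
    "fit_tau_c",
    "compute_hS",
    "compute_pce",
    "estimate_pce_from_trace",
    "q_dis_from_blank",
]


@dataclass(frozen=True)
class TemperatureTrace:
    """Heating/cooling time series with a per-sample laser on/off marker."""

    times: np.ndarray       # s, strictly increasing
    temperatures: np.ndarray  # degC
    laser_on: np.ndarray    # bool per sample
    T_surr: float           # ambient, degC

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        T = np.asarray(self.temperatures, dtype=float)
        on = np.asarray(self.laser_on, dtype=bool)
        if t.ndim != 1 or t.shape != T.shape or t.shape != on.shape:
            raise ValueError("times, temperatures, laser_on must be 1-D, equal length")
        if t.size < 2:
            raise ValueError("trace needs at least two samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "laser_on", on)

    def cooling_segment(self) -> "TemperatureTrace":
        """The cooling tail, starting at the laser-off transition.

        The last still-on sample is included as t = 0 of the cooling curve
        (it is the moment the source stops, i.e. the temperature maximum for
        a monotone heating phase).
        """
        on = self.laser_on
        if on[0] and not np.any(~on):
            raise ValueError("trace has no cooling (laser-off) segment")
        i0 = max(int(np.argmax(~on)) - 1, 0) if on[0] else 0
        return TemperatureTrace(self.times[i0:], self.temperatures[i0:],
                                on[i0:], self.T_surr)


@dataclass(frozen=True)
class LumpedThermalParams:
    """Parameters of the lumped heating model.

    Units: m (g), C_p (J/g/degC), hS (mW/degC), tau_c (s), Q_dis (mW),
    I (mW), Abs_lambda dimensionless decadic absorbance, temperatures degC.
    ``hS`` and ``tau_c`` are tied by hS = 1000 * m * C_p / tau_c; give one
    and the other is derived.
    """

    m: float = 1.0
    C_p: float = 4.18
    I: float = 300.0
    Abs_lambda: float = 1.0
    T_surr: float = 25.0
    Q_dis: float = 0.0
    tau_c: Optional[float] = None
    hS: Optional[float] = None
    T_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.m <= 0 or self.C_p <= 0 or self.I <= 0:
            raise ValueError("m, C_p and I must be > 0")
        if self.Abs_lambda < 0:
            raise ValueError("Abs_lambda must be >= 0")
        if self.Q_dis < 0:
            raise ValueError("Q_dis must be >= 0")
        if self.tau_c is None and self.hS is None:
            raise ValueError("give tau_c or hS")
        if self.tau_c is None:
            object.__setattr__(self, "tau_c", 1000.0 * self.m * self.C_p / self.hS)
        elif self.hS is None:
            object.__setattr__(self, "hS", compute_hS(self.m, self.C_p, self.tau_c))
        if self.tau_c <= 0 or self.hS <= 0:
            raise ValueError("tau_c and hS must be > 0")


@dataclass(frozen=True)
class PCEResult:
    """Estimated conversion efficiency with fit diagnostics."""

    eta: float
    tau_c: float
    hS: float
    r_squared: float
    n_points: int
    clamped: bool = False
    T_max: float = float("nan")
    T_surr: float = float("nan")


def compute_hS(m: float, C_p: float, tau_c: float) -> float:
    """hS = m C_p / tau_c, converted to mW/degC."""
    if m <= 0 or C_p <= 0 or tau_c <= 0:
        raise ValueError("m, C_p, tau_c must be > 0")
    return 1000.0 * m * C_p / tau_c


def simulate_heating(
    params: LumpedThermalParams,
    eta: float,
    on_duration: float,
    off_duration: float,
    dt: float,
) -> TemperatureTrace:
    """Integrate the lumped balance: exponential approach while the laser is
    on, Newtonian cooling to ambient after it switches off.

    The per-segment solution is analytic: T(t) = T_ss + (T_0 - T_ss) e^{-t/tau}
    with T_ss = T_surr + (eta I (1 - 10^-Abs) + Q_dis)/hS during heating and
    T_ss = T_surr during cooling (source and background terms both vanish).
    """
    if on_duration <= 0 or off_duration < 0 or dt <= 0:
        raise ValueError("durations and dt must be positive")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")

    tau = params.tau_c
    source = eta * params.I * (1.0 - 10.0 ** (-params.Abs_lambda)) + params.Q_dis
    T_ss_on = params.T_surr + source / params.hS

    times = np.arange(0.0, on_duration + off_duration + dt / 2.0, dt)
    on = times <= on_duration
    T = np.empty_like(times)
    T[on] = T_ss_on + (params.T_surr - T_ss_on) * np.exp(-times[on] / tau)
    t_off = times[~on] - on_duration
    T_at_off = T_ss_on + (params.T_surr - T_ss_on) * np.exp(-on_duration / tau)
    T[~on] = params.T_surr + (T_at_off - params.T_surr) * np.exp(-t_off / tau)
    return TemperatureTrace(times, T, on, params.T_surr)


def plateau_temperature(trace: TemperatureTrace, window: float = 10.0) -> float:
    """Noise-robust T_max: mean over the last ``window`` seconds of heating.

    The raw sample maximum of a noisy trace is biased upward by the largest
    noise excursion; averaging the plateau at the end of the on-segment
    estimates the same steady-state temperature without that bias.  With
    ``window = 0`` (or no on-segment) this falls back to the plain maximum.
    """
    on = trace.laser_on
    if window <= 0 or not np.any(on):
        return float(np.max(trace.temperatures))
    t_off = trace.times[on][-1]
    sel = on & (trace.times >= t_off - window)
    return float(np.mean(trace.temperatures[sel]))


def theta_transform(
    trace: TemperatureTrace,
    skip_initial: float = 2.0,
    T_max: Optional[float] = None,
    theta_min: float = 0.0,
) -> np.ndarray:
    """Dimensionless cooling curve: records (t, ln theta) from the laser-off
    sample onward, with theta = (T - T_surr)/(T_max - T_surr).

    ``skip_initial`` seconds after laser-off are discarded (sensor lag);
    samples at or below ambient are excluded (ln undefined), as are samples
    with theta below ``theta_min`` (deep-tail samples whose ln is dominated
    by sensor noise).  ``T_max`` defaults to the trace maximum; pass the
    :func:`plateau_temperature` estimate for noisy data.  Times are
    re-referenced to the start of cooling.
    """
    cool = trace.cooling_segment()
    if T_max is None:
        T_max = float(np.max(trace.temperatures))
    if T_max <= trace.T_surr:
        raise ValueError("degenerate trace: T_max must exceed T_surr")
    t = cool.times - cool.times[0]
    T = cool.temperatures
    keep = (t >= skip_initial) & (T > trace.T_surr)
    theta = (T[keep] - trace.T_surr) / (T_max - trace.T_surr)
    ok = theta >= max(theta_min, 0.0) if theta_min > 0 else np.ones_like(theta, bool)
    return np.column_stack([t[keep][ok], np.log(theta[ok])])


def fit_tau_c(theta_points: np.ndarray) -> tuple[float, dict]:
    """Cooling time constant from the linear t-vs-ln(theta) relation.

    Regresses t on ln(theta); the slope is -tau_c.  Returns (tau_c,
    diagnostics) with the fit's R^2 and point count.
    """
    pts = np.asarray(theta_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (t, ln theta) points")
    t, lnth = pts[:, 0], pts[:, 1]
    res = stats.linregress(lnth, t)
    tau_c = -float(res.slope)
    if tau_c <= 0:
        raise ValueError("cooling fit gave a non-positive time constant")
    diagnostics = {"r_squared": float(res.rvalue**2), "n_points": int(pts.shape[0]),
                   "intercept": float(res.intercept)}
    return tau_c, diagnostics


def compute_pce(params: LumpedThermalParams) -> PCEResult:
    """Conversion efficiency from the lumped parameters.

    eta = [hS (T_max - T_surr) - Q_dis] / [I (1 - 10^-Abs)].  Values outside
    [0, 1] indicate inconsistent inputs; they are clamped with a flag.
    """
    if params.Abs_lambda == 0:
        raise ZeroDivisionError("Abs_lambda = 0: no light absorbed")
    if params.T_max is None or params.T_max <= params.T_surr:
        raise ValueError("T_max must be given and exceed T_surr")
    absorbed = params.I * (1.0 - 10.0 ** (-params.Abs_lambda))
    eta = (params.hS * (params.T_max - params.T_surr) - params.Q_dis) / absorbed
    clamped = False
    if eta < 0.0 or eta > 1.0:
        import warnings

        warnings.warn(f"eta = {eta:.4f} outside [0, 1]; inputs are inconsistent",
                      stacklevel=2)
        eta = float(np.clip(eta, 0.0, 1.0))
        clamped = True
    return PCEResult(eta=float(eta), tau_c=params.tau_c, hS=params.hS,
                     r_squared=float("nan"), n_points=0, clamped=clamped,
                     T_max=params.T_max, T_surr=params.T_surr)


def estimate_pce_from_trace(
    trace: TemperatureTrace,
    m: float,
    C_p: float,
    I: float,
    Abs_lambda: float,
    Q_dis: float = 0.0,
    skip_initial: float = 2.0,
    theta_min: float = 0.05,
    plateau_window: float = 10.0,
) -> PCEResult:
    """Full estimation pipeline: theta transform -> tau_c fit -> hS -> eta.

    Uses the plateau-mean T_max and a theta >= ``theta_min`` cutoff so the
    cooling fit is not dominated by sensor noise near ambient.
    """
    T_max = plateau_temperature(trace, window=plateau_window)
    pts = theta_transform(trace, skip_initial=skip_initial, T_max=T_max,
                          theta_min=theta_min)
    tau_c, diag = fit_tau_c(pts)
    hS = compute_hS(m, C_p, tau_c)
    params = LumpedThermalParams(
        m=m, C_p=C_p, I=I, Abs_lambda=Abs_lambda, T_surr=trace.T_surr,
        Q_dis=Q_dis, tau_c=tau_c, hS=hS, T_max=T_max,
    )
    base = compute_pce(params)
    return PCEResult(eta=base.eta, tau_c=tau_c, hS=hS,
                     r_squared=diag["r_squared"], n_points=diag["n_points"],
                     clamped=base.clamped, T_max=T_max, T_surr=trace.T_surr)


def q_dis_from_blank(
    blank: TemperatureTrace, m: float, C_p: float, skip_initial: float = 2.0,
    theta_min: float = 0.05, plateau_window: float = 10.0,
) -> float:
    """Background dissipation (mW) from a blank-solution trace.

    At the blank's steady state the absorbed background power balances the
    loss term: Q_dis = hS_blank * (T_max_blank - T_surr).
    """
    T_max = plateau_temperature(blank, window=plateau_window)
    pts = theta_transform(blank, skip_initial=skip_initial, T_max=T_max,
                          theta_min=theta_min)
    tau_c, _ = fit_tau_c(pts)
    hS = compute_hS(m, C_p, tau_c)
    return hS * (T_max - blank.T_surr)
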