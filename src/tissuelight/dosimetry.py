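"""Thermal dose (CEM43), contrast-enhancement ratios and a photoacoustic proxy.

CEM43 compounds time spent at temperature into equivalent minutes at 43 degC:

    CEM43 = sum_i  dt_i [min] * R^(43 - T_i),   R = 0.25 (T < 43), 0.5 (T > 43)

so a minute above 43 degC counts for more than a minute, and a minute below
counts for much less.  Contrast enhancement is the post-injection to
baseline signal ratio in a region of interest.  The photoacoustic proxy is
the thermoelastic initial pressure p0 = Gamma * mu_a * Phi, i.e. the
Grueneisen parameter times the absorbed energy density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .photothermal import TemperatureTrace

__all__ = [
    "ThermalDoseResult",
    "ContrastSeries",
    "cem43",
    "contrast_enhancement",
    "pa_signal_proxy",
]


@dataclass(frozen=True)
class ThermalDoseResult:
    """CEM43 in minutes plus its per-interval contributions."""

    cem43: float
    contributions: np.ndarray  # minutes per interval
    times: np.ndarray          # interval left endpoints, s

    def __post_init__(self) -> None:
        if self.cem43 < 0:
            raise ValueError("thermal dose cannot be negative")


@dataclass(frozen=True)
class ContrastSeries:
    """Baseline signal plus post-injection signals keyed by timepoint (h)."""

    baseline: float
    post: Mapping[float, float]

    def __post_init__(self) -> None:
        if not self.baseline > 0:
            raise ValueError("baseline signal must be > 0")


def cem43(trace: TemperatureTrace, midpoint: bool = False) -> ThermalDoseResult:
    """Cumulative equivalent minutes at 43 degC for a temperature trace.

    Each interval between consecutive samples contributes
    ``dt * R^(43 - T)`` with dt in minutes; T is the interval's left-endpoint
    temperature by default (``midpoint=True`` averages the endpoints).  At
    exactly 43 degC the exponent is zero, so the choice of R is immaterial;
    R = 0.5 is used.
    """
    t = trace.times
    temps = trace.temperatures
    dt_min = np.diff(t) / 60.0
    T = 0.5 * (temps[:-1] + temps[1:]) if midpoint else temps[:-1]
    R = np.where(T < 43.0, 0.25, 0.5)
    contributions = dt_min * R ** (43.0 - T)
    return ThermalDoseResult(cem43=float(np.sum(contributions)),
                             contributions=contributions, times=t[:-1])


def contrast_enhancement(series: ContrastSeries) -> dict[float, float]:
    """CE per timepoint: post-injection signal over baseline."""
    return {tp: s / series.baseline for tp, s in sorted(series.post.items())}


def pa_signal_proxy(absorbed: np.ndarray, grueneisen: float = 1.0) -> np.ndarray:
    """Initial-pressure proxy: Grueneisen parameter times absorbed energy density.

    Accepts any array of absorbed energy density (e.g. the FluenceMap grid or
    a depth profile); purely an elementwise scaling.
    """
    if grueneisen < 0:
        raise ValueError("Grueneisen parameter must be >= 0")
    return grueneisen * np.asarray(absorbed, dtype=float)
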