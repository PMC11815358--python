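"""Closed-chamber soil respiration and 13CO2.

CO2 accumulates in a closed chamber and is sampled 0, 10, 20 and 30 min
after closure; the flux follows from the OLS slope of concentration on
time, the chamber geometry and the molar density of air:

    flux = slope * 1e-6 * P/(R T) * V/A * 60 * M_C     [mg C m-2 h-1]

The atom% 13C of the respired CO2 uses the two-point mixing model on the
0 and 30 min gas samples only (the accumulated CO2 is the "flush"):

    AT%_resp = (AT30 c30 - AT0 c0) / (c30 - c0)

and the labelling-derived 13C flux is
(AT%_resp - AT%_nat) / 100 * flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .isotopes import PairingError, PoolStock, excess_13c

R_GAS = 8.314462618  # J mol-1 K-1
M_C = 12.011  # g mol-1

#: chamber geometry defaults: inner volume 4850 cm3 over 270 cm2
DEFAULT_VOLUME_CM3 = 4850.0
DEFAULT_AREA_CM2 = 270.0
#: air state defaults when not measured alongside the gas samples
DEFAULT_AIR_TEMP_K = 298.15
DEFAULT_PRESSURE_PA = 101325.0


@dataclass(frozen=True)
class ChamberSeries:
    """One chamber closure: concentration series plus endpoint isotopes."""

    times: Sequence[float]  # minutes after closure
    co2_ppm: Sequence[float]
    at0: Optional[float] = None  # atom% at t = 0
    at30: Optional[float] = None  # atom% at t = 30
    volume: float = DEFAULT_VOLUME_CM3  # cm3
    area: float = DEFAULT_AREA_CM2  # cm2
    air_temp: float = DEFAULT_AIR_TEMP_K  # K
    pressure: float = DEFAULT_PRESSURE_PA  # Pa

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.co2_ppm, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and co2_ppm must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("CO2 concentrations must be positive")
        if self.volume <= 0 or self.area <= 0:
            raise ValueError("volume and area must be positive")
        if self.air_temp <= 0 or self.pressure <= 0:
            raise ValueError("air temperature and pressure must be positive")


@dataclass(frozen=True)
class FluxResult:
    flux_c: float  # mg C m-2 h-1
    slope: float  # ppm min-1
    r_squared: float
    at_percent_respired: Optional[float] = None
    excess_13co2: Optional[float] = None  # mg 13C m-2 h-1
    flags: tuple = field(default_factory=tuple)


def chamber_slope(s: ChamberSeries) -> tuple[float, float]:
    """OLS slope (ppm min-1) and r2 of concentration on time.

    Negative slopes are legitimate data (flagged downstream), but fewer
    than three time points cannot anchor a regression.
    """
    t = np.asarray(s.times, dtype=float)
    c = np.asarray(s.co2_ppm, dtype=float)
    if t.size < 3:
        raise ValueError(f"need >= 3 time points for a slope, got {t.size}")
    tc = t - t.mean()
    cc = c - c.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ cc) / sxx
    ss_tot = float(cc @ cc)
    if ss_tot == 0.0:
        return slope, 1.0  # constant series: slope 0, perfect (degenerate) fit
    ss_res = ss_tot - slope * float(tc @ cc)
    return slope, 1.0 - ss_res / ss_tot


def flux_from_slope(slope: float, s: ChamberSeries) -> float:
    """Convert a ppm min-1 slope to a carbon flux in mg C m-2 h-1."""
    molar_density = s.pressure / (R_GAS * s.air_temp)  # mol m-3
    height_m = (s.volume * 1e-6) / (s.area * 1e-4)  # V/A in m
    mol_per_m2_h = slope * 1e-6 * molar_density * height_m * 60.0
    return mol_per_m2_h * M_C * 1000.0  # g -> mg


def respired_atom_percent(s: ChamberSeries) -> float:
    """Atom% 13C of chamber-accumulated CO2 from the 0/30-min endpoints.

    Requires accumulation (c30 > c0); otherwise the mixing model has no
    flush and the value is undefined.
    """
    if s.at0 is None or s.at30 is None:
        raise ValueError("endpoint atom% values at t = 0 and t = 30 are required")
    t = np.asarray(s.times, dtype=float)
    c = np.asarray(s.co2_ppm, dtype=float)
    try:
        c0 = float(c[np.nonzero(t == 0.0)[0][0]])
        c30 = float(c[np.nonzero(t == 30.0)[0][0]])
    except IndexError:
        raise ValueError("series must include t = 0 and t = 30 min") from None
    if c30 <= c0:
        raise ValueError(
            f"no CO2 accumulation (c30 = {c30} <= c0 = {c0}); respired atom% undefined"
        )
    return (s.at30 * c30 - s.at0 * c0) / (c30 - c0)


def excess_13co2(fr: FluxResult, natural_at: Optional[float]) -> float:
    """Labelling-derived 13C flux: (AT%_resp - AT%_nat)/100 * flux_C."""
    if fr.at_percent_respired is None:
        raise ValueError("FluxResult has no respired atom%")
    if natural_at is None:
        raise PairingError("no natural-abundance reference for respired CO2")
    pool = PoolStock("CO2", abs(fr.flux_c), "mg C m-2 h-1")
    e = excess_13c(fr.at_percent_respired, natural_at, pool)
    return math.copysign(1.0, fr.flux_c) * e.excess_13c if fr.flux_c < 0 else e.excess_13c


def analyze_series(s: ChamberSeries, natural_at: Optional[float] = None) -> FluxResult:
    """Slope, flux and (when isotopes are present) respired atom% / excess."""
    slope, r2 = chamber_slope(s)
    flux = flux_from_slope(slope, s)
    flags = ("negative_slope",) if slope < 0 else ()
    at_resp = None
    excess = None
    if s.at0 is not None and s.at30 is not None and slope > 0:
        at_resp = respired_atom_percent(s)
        if natural_at is not None:
            fr = FluxResult(flux, slope, r2, at_resp)
            excess = excess_13co2(fr, natural_at)
    return FluxResult(flux, slope, r2, at_resp, excess, flags)
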