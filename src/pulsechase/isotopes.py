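"""Unit-safe 13C isotope arithmetic.

Conversions between delta notation (permil vs. VPDB) and atom% 13C,
scaling of soil concentrations to per-area carbon stocks, and the core
excess-13C computation

    excess 13C = (AT%_sample - AT%_natural) / 100 * C_pool   [mg 13C m-2]

where the natural-abundance reference comes from an unlabelled sample of
the same plot.  Because the first labelling event (D1) used a five-fold
stronger 13C label than the later events, D1 excess values are divided by
5 before any cross-day comparison; that normalization is tracked with an
explicit flag so it can never be applied twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

#: 13C/12C isotope ratio of the VPDB standard used in delta notation.
R_VPDB = 0.0111802

DELTA_SCALE = "delta_permil_VPDB"
ATOM_PERCENT_SCALE = "atom_percent"

#: units accepted for per-area pools entering :func:`excess_13c`
_AREA_UNITS = {
    "g C m-2": 1000.0,  # -> mg C m-2
    "mg C m-2": 1.0,
    "mg C m-2 h-1": 1.0,
    "g C m-2 h-1": 1000.0,
}

DAYS = ("D1", "D2", "RW")
#: label-strength normalization divisor for the first labelling event
D1_LABEL_DIVISOR = 5.0


class UnitError(ValueError):
    """Raised when units are mixed or inconsistent with the pool."""


class PairingError(KeyError):
    """Raised when a labelled sample has no natural-abundance reference."""


@dataclass(frozen=True)
class IsotopeValue:
    """A 13C abundance on an explicit scale (delta permil or atom%)."""

    value: float
    scale: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite isotope value: {self.value!r}")
        if self.scale == DELTA_SCALE:
            if self.value <= -1000.0:
                raise ValueError(f"delta 13C must exceed -1000 permil, got {self.value}")
        elif self.scale == ATOM_PERCENT_SCALE:
            if not 0.0 < self.value < 100.0:
                raise ValueError(f"atom% must lie in (0, 100), got {self.value}")
        else:
            raise UnitError(f"unknown isotope scale {self.scale!r}")


@dataclass(frozen=True)
class StockParams:
    """Soil-core geometry used to scale concentrations to per-area stocks.

    Defaults match a 0-20 cm sampling depth with bulk density
    1.21 g cm-3 on a 1 m2 area basis.
    """

    bulk_density: float = 1.21  # g cm-3
    depth: float = 20.0  # cm
    area_basis: float = 1.0  # m2

    def __post_init__(self) -> None:
        if self.bulk_density <= 0 or self.depth <= 0 or self.area_basis <= 0:
            raise ValueError("bulk_density, depth and area_basis must be positive")


@dataclass(frozen=True)
class PoolStock:
    """A carbon pool amount with its unit tag."""

    pool_name: str
    amount: float
    unit: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.amount):
            raise ValueError("pool amount must be finite")
        if self.amount < 0:
            raise ValueError(f"pool amount must be >= 0, got {self.amount}")


@dataclass(frozen=True)
class ExcessStock:
    """Labelling-derived 13C in a pool, per area (per hour for CO2).

    ``normalized`` records whether the D1 label-strength division has been
    applied; ``flags`` carries data-quality annotations (e.g. a negative
    excess within measurement noise, which is kept, never clamped).
    """

    pool_name: str
    excess_13c: float
    unit: str
    normalized: bool = False
    flags: tuple = field(default_factory=tuple)


def _as_value(x, scale: str) -> float:
    if isinstance(x, IsotopeValue):
        if x.scale != scale:
            raise UnitError(f"expected isotope scale {scale!r}, got {x.scale!r}")
        return x.value
    return float(x)


def delta_to_atom_percent(d) -> IsotopeValue:
    """Convert delta 13C (permil vs. VPDB) to atom% 13C.

    AT% = 100 R / (1 + R) with R = R_VPDB (d/1000 + 1).  The limit
    d -> -1000 permil (no heavy isotope) maps to 0 atom% and is rejected
    as out of domain, like any non-finite input.
    """
    dv = _as_value(d, DELTA_SCALE)
    if not math.isfinite(dv):
        raise ValueError("non-finite delta value")
    if dv <= -1000.0:
        raise ValueError("delta 13C must exceed -1000 permil")
    r = R_VPDB * (dv / 1000.0 + 1.0)
    return IsotopeValue(100.0 * r / (1.0 + r), ATOM_PERCENT_SCALE)


def atom_percent_to_delta(a) -> IsotopeValue:
    """Exact inverse of :func:`delta_to_atom_percent` (atom% in (0, 100))."""
    av = _as_value(a, ATOM_PERCENT_SCALE)
    if not math.isfinite(av) or not 0.0 < av < 100.0:
        raise ValueError(f"atom% must lie in (0, 100), got {av}")
    r = av / (100.0 - av)
    return IsotopeValue(1000.0 * (r / R_VPDB - 1.0), DELTA_SCALE)


def stock_per_area(conc: float, params: StockParams = StockParams(),
                   pool_name: str = "soil") -> PoolStock:
    """Scale a soil concentration (ug C g-1 dry soil) to g C m-2.

    stock = conc * bulk_density * depth * 1e4 cm2 m-2, i.e. the carbon in
    a soil column of the given depth under one square metre.
    """
    if not math.isfinite(conc):
        raise ValueError("concentration must be finite")
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    grams = conc * 1e-6 * params.bulk_density * params.depth * 1e4
    return PoolStock(pool_name, grams, "g C m-2")


def excess_13c(sample, natural, pool: PoolStock) -> ExcessStock:
    """Labelling-derived 13C stock of a pool, in mg 13C m-2.

    excess = (AT%_sample - AT%_natural) / 100 * C_pool.  The natural
    reference must come from the corresponding unlabelled sample of the
    same plot; pairing is the caller's job and a missing reference must be
    raised as :class:`PairingError`, never filled with a global default.
    Negative excess (sample below its natural reference, i.e. within
    measurement noise) is flagged but retained.
    """
    at_s = _as_value(sample, ATOM_PERCENT_SCALE)
    at_n = _as_value(natural, ATOM_PERCENT_SCALE)
    if pool.unit not in _AREA_UNITS:
        raise UnitError(
            f"pool {pool.pool_name!r} must be per-area (one of {sorted(_AREA_UNITS)}), "
            f"got {pool.unit!r}"
        )
    mg_pool = pool.amount * _AREA_UNITS[pool.unit]
    excess = (at_s - at_n) / 100.0 * mg_pool
    unit = "mg 13C m-2 h-1" if pool.unit.endswith("h-1") else "mg 13C m-2"
    flags = ("negative_excess",) if excess < 0 else ()
    return ExcessStock(pool.pool_name, excess, unit, normalized=False, flags=flags)


def normalize_d1_label(e: ExcessStock, day: str) -> ExcessStock:
    """Put excess-13C values from different labelling events on one scale.

    The first labelling (D1) used a label five times stronger than the
    later events, so D1 excess is divided by 5; D2/RW values pass through
    unchanged.  Either way the result is marked ``normalized`` and a
    second application raises.
    """
    if day not in DAYS:
        raise ValueError(f"unknown day {day!r}, expected one of {DAYS}")
    if e.normalized:
        raise ValueError("excess stock already label-normalized")
    value = e.excess_13c / D1_LABEL_DIVISOR if day == "D1" else e.excess_13c
    return replace(e, excess_13c=value, normalized=True)
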