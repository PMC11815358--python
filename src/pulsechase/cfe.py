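"""Chloroform-fumigation-extraction (CFE) arithmetic.

Fumigating soil lyses microbial cells, so the difference between the
extractable organic C of a fumigated and a non-fumigated aliquot (the
"flush") estimates microbial biomass C after division by the extraction
efficiency k_EC:

    C_mic = (C_f - C_nf) / k_EC             (default k_EC = 0.45)

The non-fumigated extract doubles as the extractable organic carbon (EOC)
pool.  The isotopic composition of the microbial biomass follows from a
two-member mixing model of the fumigated extract (biomass + background)
and the non-fumigated extract (background only):

    AT%_Cmic = (AT%_f C_f - AT%_nf C_nf) / (C_f - C_nf)

k_EC cancels in the mixing model; the k_EC-corrected C_mic stock is used
as the pool size when excess 13C is computed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class CFEConstants:
    """Extraction-efficiency factor for the CFE flush."""

    k_ec: float = 0.45

    def __post_init__(self) -> None:
        if not 0.0 < self.k_ec <= 1.0:
            raise ValueError(f"k_EC must lie in (0, 1], got {self.k_ec}")


#: flushes smaller than this (ug C g-1) make the mixing model unstable
DEFAULT_FLUSH_FLOOR = 5.0


@dataclass(frozen=True)
class ExtractPair:
    """Fumigated / non-fumigated extract C with optional atom% values.

    Concentrations are ug C g-1 dry soil.  Atom% fields may be None when
    only pool sizes (not isotopes) were measured.
    """

    c_f: float
    c_nf: float
    at_f: Optional[float] = None
    at_nf: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c_f) and math.isfinite(self.c_nf)):
            raise ValueError("extract concentrations must be finite")
        if self.c_f <= 0 or self.c_nf <= 0:
            raise ValueError("extract concentrations must be positive")
        for name in ("at_f", "at_nf"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v < 100.0:
                raise ValueError(f"{name} must lie in (0, 100), got {v}")


@dataclass(frozen=True)
class CmicResult:
    """Microbial biomass C with the flush bookkeeping retained.

    A non-positive flush (C_f <= C_nf) yields ``value = None`` with a flag
    rather than dropping the record, so downstream models see explicit
    missingness.
    """

    value: Optional[float]  # ug C g-1 dry soil, None if flush non-positive
    flush: float
    flags: tuple = ()


def cmic_content(pair: ExtractPair, constants: CFEConstants = CFEConstants()) -> CmicResult:
    """Microbial biomass C from the CFE flush: (C_f - C_nf) / k_EC."""
    flush = pair.c_f - pair.c_nf
    if flush <= 0:
        return CmicResult(None, flush, ("non_positive_flush",))
    return CmicResult(flush / constants.k_ec, flush)


def eoc_content(pair: ExtractPair) -> float:
    """Extractable organic C: the non-fumigated extract, ug C g-1 dry soil."""
    return pair.c_nf


@dataclass(frozen=True)
class AtomPercentCmic:
    value: float  # atom% 13C of microbial biomass
    flags: tuple = ()


def atom_percent_cmic(pair: ExtractPair,
                      flush_floor: float = DEFAULT_FLUSH_FLOOR) -> AtomPercentCmic:
    """Atom% 13C of microbial biomass via the extract mixing model.

    The estimate is exact mass balance:
    AT%_Cmic (C_f - C_nf) + AT%_nf C_nf = AT%_f C_f.  It can legitimately
    exceed AT%_f when labelled biomass is diluted by unlabelled
    extractable C, and is never clamped.  Flushes below ``flush_floor``
    (ug C g-1) are flagged unstable because the denominator amplifies
    measurement error.
    """
    if pair.at_f is None or pair.at_nf is None:
        raise ValueError("both extract atom% values are required")
    flush = pair.c_f - pair.c_nf
    if flush <= 0:
        raise ValueError(
            f"mixing model requires C_f > C_nf, got flush {flush:.3g} ug C g-1"
        )
    value = (pair.at_f * pair.c_f - pair.at_nf * pair.c_nf) / flush
    flags = ("unstable_flush",) if flush < flush_floor else ()
    return AtomPercentCmic(value, flags)
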