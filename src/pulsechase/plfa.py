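"""PLFA biomarker bookkeeping.

Phospholipid fatty acids (PLFAs) are membrane lipids used as living
biomass markers for microbial groups.  This module assigns markers to
groups, corrects the delta 13C of fatty acid methyl esters (FAMEs) for
the methanol-derived carbon added during derivatization, and aggregates
marker-level C and excess-13C to group level.

Group assignment (extensible via a plain-text registry):

* gram-positive bacteria: a15:0, i15:0, i16:0, i17:0
* gram-negative bacteria: cy17:0, cy19:0
* fungi: 18:2w6,9
* shared bacteria/fungi: 16:1w5 (counts toward total PLFA-C only)

Monoenoic markers are removed before isotope analysis (their
chromatographic fractions are discarded), so they contribute to C totals
but never to excess 13C; with the default registry that concerns 16:1w5.

Methyl correction is a single-carbon mass balance: a FAME with n PLFA
carbons plus one methyl carbon satisfies
(n+1) d_FAME = n d_PLFA + d_MeOH, hence

    d_PLFA = ((n + 1) d_FAME - d_MeOH) / n.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

from . import isotopes
from .isotopes import ExcessStock, PairingError, StockParams

GROUPS = ("gram_positive", "gram_negative", "fungal", "shared")
UNASSIGNED = "unassigned"

#: default derivatization-methanol delta 13C (permil); override per lab
DEFAULT_DELTA_MEOH = -40.0

#: shipped registry: marker, carbon count of the underlying PLFA, group,
#: monoenoic flag (monoenoic fractions are excluded from isotope work)
_DEFAULT_REGISTRY_TEXT = """\
marker,n_carbon,group,monoenoic
a15:0,15,gram_positive,false
i15:0,15,gram_positive,false
i16:0,16,gram_positive,false
i17:0,17,gram_positive,false
cy17:0,17,gram_negative,false
cy19:0,19,gram_negative,false
18:2w6,9,18,fungal,false
16:1w5,16,shared,true
"""


@dataclass(frozen=True)
class PLFAIdentity:
    marker_name: str
    n_carbon: int
    group: str
    monoenoic: bool = False

    def __post_init__(self) -> None:
        if self.n_carbon < 2:
            raise ValueError(f"n_carbon must be >= 2, got {self.n_carbon}")


def normalize_marker_name(name: str) -> str:
    """Canonicalize marker spellings (omega sign, separators, case)."""
    s = name.strip().lower()
    s = s.replace("ω", "w")  # omega
    s = s.replace("w6.9", "w6,9").replace("w6/9", "w6,9")
    if s.endswith("c") and ":" in s:  # cis suffix, e.g. 18:2w6,9c
        s = s[:-1]
    return s


def _parse_registry(lines: Iterable[str]) -> Dict[str, PLFAIdentity]:
    registry: Dict[str, PLFAIdentity] = {}
    header: Optional[List[str]] = None
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if header is None:
            header = [h.strip() for h in line.split(",")]
            continue
        # marker names may themselves contain a comma (18:2w6,9): split
        # from the right, since the trailing three fields are comma-free
        parts = line.rsplit(",", 3)
        if len(parts) != 4:
            raise ValueError(f"malformed registry line: {raw!r}")
        marker, n_carbon, group, mono = (p.strip() for p in parts)
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r} for marker {marker!r}")
        key = normalize_marker_name(marker)
        registry[key] = PLFAIdentity(key, int(n_carbon), group,
                                     mono.lower() in ("true", "1", "yes"))
    if header is None:
        raise ValueError("empty marker registry")
    return registry


def load_registry(path_or_lines) -> Dict[str, PLFAIdentity]:
    """Load a marker registry from a CSV path or iterable of lines."""
    if hasattr(path_or_lines, "read"):
        return _parse_registry(path_or_lines)
    if isinstance(path_or_lines, (list, tuple)):
        return _parse_registry(path_or_lines)
    with open(path_or_lines) as fh:
        return _parse_registry(fh)


DEFAULT_REGISTRY: Dict[str, PLFAIdentity] = _parse_registry(
    io.StringIO(_DEFAULT_REGISTRY_TEXT)
)


@dataclass(frozen=True)
class PLFAMeasurement:
    """One marker measurement: C amount plus FAME delta 13C."""

    marker: str
    c_amount: float  # ug C g-1 dry soil
    delta_fame: Optional[float] = None  # permil, of the methyl ester
    delta_meoh: Optional[float] = None  # permil, derivatization methanol
    identity: Optional[PLFAIdentity] = None

    def __post_init__(self) -> None:
        if self.c_amount < 0:
            raise ValueError("c_amount must be >= 0")


def methyl_correct_delta(m: PLFAMeasurement,
                         registry: Mapping[str, PLFAIdentity] = DEFAULT_REGISTRY,
                         default_delta_meoh: Optional[float] = DEFAULT_DELTA_MEOH) -> float:
    """Delta 13C of the underlying PLFA from its FAME measurement."""
    if m.delta_fame is None:
        raise ValueError(f"marker {m.marker!r} has no FAME delta 13C")
    ident = m.identity or registry.get(normalize_marker_name(m.marker))
    if ident is None:
        raise KeyError(
            f"marker {m.marker!r} not in registry; supply an identity with n_carbon"
        )
    d_meoh = m.delta_meoh if m.delta_meoh is not None else default_delta_meoh
    if d_meoh is None:
        raise ValueError("no methanol delta 13C measured and no default configured")
    n = ident.n_carbon
    return ((n + 1) * m.delta_fame - d_meoh) / n


def remethylate_delta(delta_plfa: float, n_carbon: int, delta_meoh: float) -> float:
    """Inverse of :func:`methyl_correct_delta` (used by the generator)."""
    return (n_carbon * delta_plfa + delta_meoh) / (n_carbon + 1)


def assign_groups(measurements: Iterable[PLFAMeasurement],
                  registry: Mapping[str, PLFAIdentity] = DEFAULT_REGISTRY
                  ) -> Dict[str, List[PLFAMeasurement]]:
    """Bucket measurements by microbial group.

    Unknown markers land in an ``unassigned`` bucket with a warning; they
    are never silently dropped.
    """
    grouped: Dict[str, List[PLFAMeasurement]] = {g: [] for g in GROUPS}
    grouped[UNASSIGNED] = []
    for m in measurements:
        ident = m.identity or registry.get(normalize_marker_name(m.marker))
        if ident is None:
            warnings.warn(f"PLFA marker {m.marker!r} not in registry; left unassigned")
            grouped[UNASSIGNED].append(m)
        else:
            tagged = PLFAMeasurement(m.marker, m.c_amount, m.delta_fame,
                                     m.delta_meoh, ident)
            grouped[ident.group].append(tagged)
    return grouped


def group_c_content(grouped: Mapping[str, List[PLFAMeasurement]]) -> Dict[str, float]:
    """Per-group PLFA-C sums plus a ``total`` including the shared marker."""
    sums = {g: sum(m.c_amount for m in grouped.get(g, ())) for g in GROUPS}
    sums["total"] = sum(sums[g] for g in GROUPS)
    return sums


def group_excess13c(grouped: Mapping[str, List[PLFAMeasurement]],
                    natural: Mapping[str, float],
                    params: StockParams = StockParams(),
                    registry: Mapping[str, PLFAIdentity] = DEFAULT_REGISTRY,
                    default_delta_meoh: Optional[float] = DEFAULT_DELTA_MEOH
                    ) -> Dict[str, ExcessStock]:
    """Per-group excess 13C (mg 13C m-2) from marker-level measurements.

    ``natural`` maps normalized marker names to the methyl-corrected
    natural-abundance atom% of the same marker from the unlabelled area of
    the plot.  Monoenoic markers are skipped (no isotope data by design);
    any other marker lacking a natural reference raises
    :class:`~pulsechase.isotopes.PairingError`.
    """
    out: Dict[str, ExcessStock] = {}
    for group in ("gram_positive", "gram_negative", "fungal"):
        total = 0.0
        flags: tuple = ()
        for m in grouped.get(group, ()):
            ident = m.identity or registry.get(normalize_marker_name(m.marker))
            if ident is not None and ident.monoenoic:
                continue
            key = normalize_marker_name(m.marker)
            if key not in natural:
                raise PairingError(
                    f"no natural-abundance reference for PLFA marker {m.marker!r}"
                )
            d_plfa = methyl_correct_delta(m, registry, default_delta_meoh)
            at_sample = isotopes.delta_to_atom_percent(d_plfa)
            stock = isotopes.stock_per_area(m.c_amount, params, pool_name=key)
            e = isotopes.excess_13c(at_sample, natural[key], stock)
            total += e.excess_13c
            flags = flags + e.flags
        out[group] = ExcessStock(f"PLFA_{group}", total, "mg 13C m-2", flags=flags)
    return out
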