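"""Synthetic raw-measurement generator for the pulse-chase field design.

Emulates a 12-year warming x summer-precipitation trial: 4 complete
blocks, warming (Ta/Te) on main plots, precipitation history (Pa/Pr) on
subplots, and three labelling days (before drought D1, peak drought D2,
two days after rewetting RW) as repeated measures.

Responses are positive and treatment effects are reported as ratios, so
the generator is multiplicative: each response has a baseline (Ta, Pa,
D1) and per-factor multipliers taken from the field results it emulates
(e.g. respiration drops 35% at peak drought and more than doubles after
rewetting; a reduced-precipitation history halves the excess 13C found
in microbial biomass).  Lognormal block, main-plot and AR(1)-correlated
day effects supply the split-plot variance structure.

The generator then *inverts* every analysis stage to emit raw
observables: extract C pairs consistent with the latent microbial
biomass and EOC, extract and gas atom% consistent with the latent excess
13C stocks through the mixing equations, FAME delta 13C via the inverse
methyl correction, and chamber concentration series via the inverse flux
formula.  Because the inversions are exact, running the analysis
pipeline on a zero-variance dataset returns the latent truth exactly.

The first labelling used a five-fold stronger label, so raw D1
observables are emitted at 5x the normalized latent excess; the analysis
divides D1 by 5, recovering the comparable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import chamber as chamber_mod
from . import isotopes, plfa
from .isotopes import StockParams
from .splitplot import DAY_LEVELS, TEMP_LEVELS, design_frame

KEY_COLS = ["block", "temperature", "precipitation", "day"]


def _freeze(d: Mapping) -> Mapping:
    return MappingProxyType(dict(d))


@dataclass(frozen=True)
class EffectRow:
    """Multiplicative treatment/time structure of one response.

    ``baseline`` is the (Ta, Pa, D1) mean in ``unit``; ``day`` maps each
    day to its multiplier (D1 = 1); ``temp`` multiplies all Te cells and
    ``temp_day`` adds day-specific warming multipliers on top; ``precip``
    multiplies all Pr cells.
    """

    baseline: float
    unit: str
    day: Mapping[str, float]
    temp: float = 1.0
    precip: float = 1.0
    temp_day: Mapping[str, float] = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive (multiplicative model)")
        for d in DAY_LEVELS:
            if self.day.get(d, 0.0) <= 0:
                raise ValueError(f"day multiplier for {d} must be positive")
        object.__setattr__(self, "day", _freeze(self.day))
        object.__setattr__(self, "temp_day", _freeze(self.temp_day))

    def mean(self, temperature: str, precipitation: str, day: str) -> float:
        m = self.baseline * self.day[day]
        if temperature == "Te":
            m *= self.temp * self.temp_day.get(day, 1.0)
        if precipitation == "Pr":
            m *= self.precip
        return m


# Calibrated default effect table.  Day/temperature/precipitation ratios
# follow the reported field responses; baselines are typical magnitudes
# for a temperate arable topsoil (0-20 cm).  Excess-13C rows are on the
# normalized (label-strength-corrected) scale.
DEFAULT_EFFECTS: Dict[str, EffectRow] = {
    # soil CO2 efflux: -35% at peak drought; Birch pulse after rewetting
    # (+30% over pre-drought in ambient, +70% in warmed soils); warming
    # raises respiration throughout.
    "respiration": EffectRow(60.0, "mg C m-2 h-1",
                             {"D1": 1.0, "D2": 0.65, "RW": 1.30},
                             temp=1.30, temp_day={"RW": 1.7 / 1.3},
                             note="drought -35%; rewetting +30%/+70% vs D1"),
    "excess13c_co2": EffectRow(0.5, "mg 13C m-2 h-1",
                               {"D1": 1.0, "D2": 1.5, "RW": 1.5},
                               temp=0.7,
                               note="labelled C in respiration rises toward drought"),
    # extractable organic C: +80% at peak drought, partial decline after
    # rewetting (-30% of peak); warming tends to raise EOC (~+30%).
    "eoc": EffectRow(80.0, "ug C g-1",
                     {"D1": 1.0, "D2": 1.80, "RW": 1.80 * 0.70},
                     temp=1.30, note="drought +80%; rewetting -30% of peak"),
    "excess13c_eoc": EffectRow(1.0, "mg 13C m-2",
                               {"D1": 1.0, "D2": 3.0, "RW": 9.0},
                               temp=0.7,
                               note="label in EOC triples to D2 and again to RW"),
    # microbial biomass C: +10-25% at peak drought, further +25-40% after
    # rewetting (midpoints used); insensitive to warming/precipitation.
    "cmic": EffectRow(250.0, "ug C g-1",
                      {"D1": 1.0, "D2": 1.175, "RW": 1.175 * 1.325},
                      note="drought +17.5%; rewetting +32.5% (range midpoints)"),
    # the headline legacy effect: reduced-precipitation history halves
    # the labelled C found in microbial biomass; warming also lowers it.
    "excess13c_cmic": EffectRow(2.0, "mg 13C m-2",
                                {"D1": 1.0, "D2": 0.45, "RW": 1.0},
                                temp=0.6, precip=0.5,
                                note="drought -55% (midpoint); Pr history -50%"),
    "gram_positive_c": EffectRow(12.0, "ug C g-1",
                                 {"D1": 1.0, "D2": 0.85, "RW": 0.85 * 1.2},
                                 temp=0.9, note="drought -15%; rewetting +20%"),
    "gram_negative_c": EffectRow(8.0, "ug C g-1",
                                 {"D1": 1.0, "D2": 1.0, "RW": 1.2},
                                 temp=0.9, note="no drought effect; rewetting +20%"),
    "fungal_c": EffectRow(3.0, "ug C g-1", {"D1": 1.0, "D2": 1.0, "RW": 1.0},
                          note="fungal biomass stable through the experiment"),
    "shared_c": EffectRow(2.0, "ug C g-1", {"D1": 1.0, "D2": 1.0, "RW": 1.1},
                          note="16:1w5, counted in total PLFA-C only"),
    "excess13c_gram_positive": EffectRow(0.04, "mg 13C m-2",
                                         {"D1": 1.0, "D2": 0.5, "RW": 7.5},
                                         temp=0.7,
                                         note="10-20x rewetting recovery vs peak"),
    "excess13c_gram_negative": EffectRow(0.03, "mg 13C m-2",
                                         {"D1": 1.0, "D2": 1.0, "RW": 15.0},
                                         temp=0.7,
                                         note="10-20x rewetting recovery vs peak"),
    # fungi: label uptake collapses at peak drought (-85%) and recovers;
    # warming reduces fungal label by ~70% at every timepoint.
    "excess13c_fungal": EffectRow(0.05, "mg 13C m-2",
                                  {"D1": 1.0, "D2": 0.15, "RW": 1.0},
                                  temp=0.30,
                                  note="drought -85%; warming -70% at each day"),
    # root sugars: 3-4x increase by peak drought, back near pre-drought
    # after rewetting; warming +110% before drought, weaker later.
    "root_sugars": EffectRow(1.5, "g C m-2",
                             {"D1": 1.0, "D2": 3.5, "RW": 1.0},
                             temp_day={"D1": 2.1, "D2": 1.2, "RW": 1.2},
                             note="warming +110% at D1 only (significant)"),
    "excess13c_root_sugars": EffectRow(0.3, "mg 13C m-2",
                                       {"D1": 1.0, "D2": 1.2, "RW": 0.9},
                                       temp=0.8),
    "shoot_biomass": EffectRow(30.0, "g C m-2", {"D1": 1.0, "D2": 8.0, "RW": 10.0},
                               temp=1.4, note="~10-fold growth over the season"),
    "root_biomass": EffectRow(20.0, "g C m-2", {"D1": 1.0, "D2": 2.0, "RW": 2.0},
                              temp=1.3, note="belowground biomass doubles"),
    "excess13c_shoot": EffectRow(8.0, "mg 13C m-2", {"D1": 1.0, "D2": 8.0, "RW": 10.0},
                                 temp=1.1, note="tracks aboveground growth"),
    "excess13c_root": EffectRow(3.0, "mg 13C m-2", {"D1": 1.0, "D2": 0.4, "RW": 0.4},
                                temp=0.7, note="root allocation drops at drought"),
}

#: marker composition within each PLFA group (fractions of group C)
GP_MARKERS = (("a15:0", 0.35), ("i15:0", 0.30), ("i16:0", 0.20), ("i17:0", 0.15))
GN_MARKERS = (("cy17:0", 0.60), ("cy19:0", 0.40))
FUNGAL_MARKER = "18:2w6,9"
SHARED_MARKER = "16:1w5"

#: soil-temperature offsets of warmed plots by depth (deg C)
TEMP_OFFSETS_BY_DEPTH = {4: 2.1, 15: 1.5, 30: 1.1}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the emulated experiment.

    Variance components are log-scale standard deviations (approximately
    coefficients of variation); ``rho`` is the AR(1) correlation between
    adjacent labelling days within a subplot.
    """

    seed: int = 20210426  # drought start date
    n_blocks: int = 4
    sigma_block: float = 0.08
    sigma_mainplot: float = 0.08
    sigma_resid: float = 0.15
    rho: float = 0.4
    effects: Mapping[str, EffectRow] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    at_natural: float = 1.08  # atom% 13C natural abundance baseline
    at_natural_jitter: float = 0.002  # per-plot sd of the natural baseline
    measurement_cv: float = 0.0  # optional extra instrument noise
    delta_meoh: float = plfa.DEFAULT_DELTA_MEOH
    stock: StockParams = field(default_factory=StockParams)
    k_ec: float = 0.45
    chamber_c0_ppm: float = 420.0
    drought_days: int = 58
    label_divisor_d1: float = isotopes.D1_LABEL_DIVISOR

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for name in ("sigma_block", "sigma_mainplot", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")


def _rng_for(cfg: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=tuple(key)))


def generate_design(cfg: GeneratorConfig) -> pd.DataFrame:
    """Full factorial key set: blocks x temperature x precipitation x day."""
    return design_frame(cfg.n_blocks)


def generate_true_means(cfg: GeneratorConfig,
                        responses: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Deterministic latent means per design cell and response."""
    names = list(responses) if responses is not None else list(cfg.effects)
    missing = [r for r in names if r not in cfg.effects]
    if missing:
        raise KeyError(f"no effect-table row for response(s): {missing}")
    design = generate_design(cfg)
    frames = []
    for name in names:
        row = cfg.effects[name]
        vals = [row.mean(t, p, d) for t, p, d in
                zip(design["temperature"], design["precipitation"], design["day"])]
        frames.append(design.assign(response=name, mean=vals, unit=row.unit))
    return pd.concat(frames, ignore_index=True)


def generate_latent(cfg: GeneratorConfig, dataset_index: int = 0,
                    responses: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Latent per-plot values: means x lognormal split-plot noise.

    Column ``value`` is the normalized-scale truth the analysis pipeline
    should recover for each plot and day.
    """
    means = generate_true_means(cfg, responses)
    lag = np.abs(np.arange(3)[:, None] - np.arange(3)[None, :])
    R = cfg.sigma_resid ** 2 * cfg.rho ** lag
    chol = np.linalg.cholesky(R + 1e-15 * np.eye(3))
    day_pos = {d: i for i, d in enumerate(DAY_LEVELS)}

    out = []
    for r_i, (name, sub) in enumerate(means.groupby("response", sort=True)):
        rng = _rng_for(cfg, dataset_index, r_i)
        b = {blk: rng.normal(0.0, cfg.sigma_block)
             for blk in range(1, cfg.n_blocks + 1)}
        p = {(blk, t): rng.normal(0.0, cfg.sigma_mainplot)
             for blk in range(1, cfg.n_blocks + 1) for t in TEMP_LEVELS}
        sub = sub.reset_index(drop=True)
        eps = np.zeros(len(sub))
        for (blk, t, pr), plot in sub.groupby(["block", "temperature",
                                               "precipitation"], sort=True):
            e = chol @ rng.standard_normal(3)
            pos = plot["day"].map(day_pos).to_numpy()
            eps[plot.index.to_numpy()] = b[blk] + p[(blk, t)] + e[pos]
        sub["value"] = sub["mean"].to_numpy() * np.exp(eps)
        out.append(sub)
    latent = pd.concat(out, ignore_index=True)
    return latent[KEY_COLS + ["response", "value", "mean", "unit"]]


def _noisy(rng: np.random.Generator, value, cv: float):
    if cv <= 0:
        return value
    return value * np.exp(rng.normal(0.0, cv, size=np.shape(value) or None))


def _stock_mg(conc_ug_g: float, cfg: GeneratorConfig) -> float:
    return isotopes.stock_per_area(conc_ug_g, cfg.stock).amount * 1000.0


def generate_raw_tables(cfg: GeneratorConfig, dataset_index: int = 0) -> Dict[str, pd.DataFrame]:
    """One complete raw-measurement bundle plus its truth table.

    Returns ``extracts`` (fumigated/non-fumigated pairs), ``plfa``
    (per-marker C and FAME delta 13C), ``chamber`` (concentration series
    with endpoint atom%), ``plants`` (biomass/sugar pools with atom%) and
    ``truth`` (normalized latent values per plot, day and response).
    """
    for attempt in range(5):
        try:
            return _generate_raw_tables_once(cfg, dataset_index, attempt)
        except _ImpossibleObservable:
            continue
    raise RuntimeError("could not generate observables in valid ranges "
                       "(atom% bounds) after 5 resampling attempts")


class _ImpossibleObservable(Exception):
    pass


def _check_at(at: float) -> float:
    if not 0.0 < at < 100.0:
        raise _ImpossibleObservable(f"atom% out of range: {at}")
    return at


def _generate_raw_tables_once(cfg: GeneratorConfig, dataset_index: int,
                              attempt: int) -> Dict[str, pd.DataFrame]:
    latent = generate_latent(cfg, dataset_index * 31 + attempt)
    wide = latent.pivot_table(index=KEY_COLS, columns="response",
                              values="value").reset_index()
    rng = _rng_for(cfg, dataset_index * 31 + attempt, 10_000)

    extracts, plfa_rows, chamber_rows, plant_rows = [], [], [], []
    for _, row in wide.iterrows():
        key = {c: row[c] for c in KEY_COLS}
        d1_factor = cfg.label_divisor_d1 if key["day"] == "D1" else 1.0
        at_nat = cfg.at_natural + rng.normal(0.0, cfg.at_natural_jitter)

        # --- extracts (Cmic / EOC and their label content) -----------
        eoc = _noisy(rng, row["eoc"], cfg.measurement_cv)
        cmic = _noisy(rng, row["cmic"], cfg.measurement_cv)
        c_nf = eoc
        c_f = c_nf + cfg.k_ec * cmic
        at_nf = _check_at(
            at_nat + 100.0 * d1_factor * row["excess13c_eoc"] / _stock_mg(eoc, cfg))
        at_cmic = _check_at(
            at_nat + 100.0 * d1_factor * row["excess13c_cmic"] / _stock_mg(cmic, cfg))
        flush = c_f - c_nf
        at_f = _check_at((at_cmic * flush + at_nf * c_nf) / c_f)
        extracts.append({**key, "labelled": True, "c_f": c_f, "c_nf": c_nf,
                         "at_f": at_f, "at_nf": at_nf, "unit": "ug C g-1"})
        extracts.append({**key, "labelled": False, "c_f": c_f, "c_nf": c_nf,
                         "at_f": at_nat, "at_nf": at_nat, "unit": "ug C g-1"})

        # --- PLFA markers ---------------------------------------------
        def marker_rows(markers, group_c, group_excess):
            for name, frac in markers:
                c_amt = group_c * frac
                ident = plfa.DEFAULT_REGISTRY[plfa.normalize_marker_name(name)]
                at_m = _check_at(at_nat + 100.0 * d1_factor * group_excess * frac
                                 / _stock_mg(c_amt, cfg))
                d_plfa = isotopes.atom_percent_to_delta(at_m).value
                d_fame = plfa.remethylate_delta(d_plfa, ident.n_carbon, cfg.delta_meoh)
                d_plfa_nat = isotopes.atom_percent_to_delta(at_nat).value
                d_fame_nat = plfa.remethylate_delta(d_plfa_nat, ident.n_carbon,
                                                    cfg.delta_meoh)
                yield {**key, "labelled": True, "marker": name, "c_amount": c_amt,
                       "delta_fame": d_fame, "unit": "ug C g-1"}
                yield {**key, "labelled": False, "marker": name, "c_amount": c_amt,
                       "delta_fame": d_fame_nat, "unit": "ug C g-1"}

        plfa_rows.extend(marker_rows(GP_MARKERS, row["gram_positive_c"],
                                     row["excess13c_gram_positive"]))
        plfa_rows.extend(marker_rows(GN_MARKERS, row["gram_negative_c"],
                                     row["excess13c_gram_negative"]))
        plfa_rows.extend(marker_rows(((FUNGAL_MARKER, 1.0),), row["fungal_c"],
                                     row["excess13c_fungal"]))
        for lab in (True, False):  # monoenoic shared marker: no isotope data
            plfa_rows.append({**key, "labelled": lab, "marker": SHARED_MARKER,
                              "c_amount": row["shared_c"], "delta_fame": np.nan,
                              "unit": "ug C g-1"})

        # --- chamber series -------------------------------------------
        flux = _noisy(rng, row["respiration"], cfg.measurement_cv)
        probe = chamber_mod.ChamberSeries(times=(0.0, 10.0, 20.0, 30.0),
                                          co2_ppm=(1.0,) * 4)
        slope = flux / chamber_mod.flux_from_slope(1.0, probe)
        c0 = cfg.chamber_c0_ppm
        conc = {t: c0 + slope * t for t in (0.0, 10.0, 20.0, 30.0)}
        at_resp = _check_at(at_nat + 100.0 * d1_factor * row["excess13c_co2"] / flux)
        c30 = conc[30.0]
        at30 = _check_at((at_resp * (c30 - c0) + at_nat * c0) / c30)
        for t in (0.0, 10.0, 20.0, 30.0):
            at_val = at_nat if t == 0.0 else (at30 if t == 30.0 else np.nan)
            chamber_rows.append({**key, "labelled": True, "time_min": t,
                                 "co2_ppm": conc[t], "at_percent": at_val})
            chamber_rows.append({**key, "labelled": False, "time_min": t,
                                 "co2_ppm": conc[t],
                                 "at_percent": at_nat if t in (0.0, 30.0) else np.nan})

        # --- plant pools -----------------------------------------------
        for pool, amount_col, excess_col in (
                ("shoot", "shoot_biomass", "excess13c_shoot"),
                ("root", "root_biomass", "excess13c_root"),
                ("root_sugars", "root_sugars", "excess13c_root_sugars")):
            amount = _noisy(rng, row[amount_col], cfg.measurement_cv)
            at_s = _check_at(at_nat + 100.0 * d1_factor * row[excess_col]
                             / (amount * 1000.0))
            plant_rows.append({**key, "labelled": True, "pool": pool,
                               "c_amount": amount, "unit": "g C m-2",
                               "at_percent": at_s})
            plant_rows.append({**key, "labelled": False, "pool": pool,
                               "c_amount": amount, "unit": "g C m-2",
                               "at_percent": at_nat})

    return {
        "extracts": pd.DataFrame(extracts),
        "plfa": pd.DataFrame(plfa_rows),
        "chamber": pd.DataFrame(chamber_rows),
        "plants": pd.DataFrame(plant_rows),
        "truth": latent.rename(columns={"value": "true_value"}),
    }


def generate_microclimate(cfg: GeneratorConfig,
                          pre_days: int = 30,
                          post_days: int = 14) -> pd.DataFrame:
    """Daily soil temperature (by depth) and volumetric water content.

    Temperature: a smooth seasonal warming trend with daily noise; warmed
    plots are offset by 2.1/1.5/1.1 deg C at 4/15/30 cm depth.  Moisture:
    ~14% (ambient) / 12% (warmed) VWC before drought, a linear drawdown
    converging to the 5% minimum at the end of the 58-day drought, then a
    19% spike at rewetting relaxing over the following days.
    """
    rng = _rng_for(cfg, 424242)
    n_days = pre_days + cfg.drought_days + post_days
    t_axis = np.arange(n_days)
    drought_start = pre_days
    drought_end = pre_days + cfg.drought_days

    season = 12.0 + 8.0 * (t_axis / max(n_days - 1, 1))  # spring -> summer
    rows = []
    for depth, offset in TEMP_OFFSETS_BY_DEPTH.items():
        damp = {4: 1.0, 15: 0.8, 30: 0.6}[depth]
        base = season * damp + rng.normal(0.0, 0.3, n_days)
        for treatment, off in (("Ta", 0.0), ("Te", offset)):
            noise = rng.normal(0.0, 0.15, n_days)
            for d, temp in zip(t_axis, base + off + noise):
                rows.append({"day_index": int(d), "depth_cm": depth,
                             "temperature": treatment, "soil_temp_c": float(temp)})
    temp_df = pd.DataFrame(rows)

    vwc_rows = []
    for treatment, pre_level in (("Ta", 14.0), ("Te", 12.0)):
        vwc = np.empty(n_days)
        vwc[:drought_start] = pre_level
        frac = (np.arange(drought_start, drought_end) - drought_start + 1) / cfg.drought_days
        vwc[drought_start:drought_end] = pre_level + (5.0 - pre_level) * frac
        post = np.arange(drought_end, n_days) - drought_end
        vwc[drought_end:] = 19.0 + (12.0 - 19.0) * (post / max(post_days, 1))
        vwc = np.clip(vwc + rng.normal(0.0, 0.3, n_days), 4.0, None)
        vwc[drought_end - 1] = 5.0  # the observed drought minimum
        vwc[drought_end] = 19.0  # the rewetting spike
        for d, v in zip(t_axis, vwc):
            vwc_rows.append({"day_index": int(d), "temperature": treatment,
                             "vwc_percent": float(v)})
    vwc_df = pd.DataFrame(vwc_rows)
    return temp_df.merge(vwc_df, on=["day_index", "temperature"], how="left")
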