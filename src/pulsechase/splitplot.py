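"""Split-plot repeated-measures mixed model, estimated by REML.

The design has warming randomized at the main-plot level within complete
blocks, precipitation history at the subplot level, and three repeated
measurement days per subplot:

    y_hijk = mu + b_h + T_i + P_j + D_k + TD_ik + PD_jk + TP_ij
             + TPD_ijk + p_hi + e_hijk

with random block effects ``b_h``, random main-plot errors ``p_hi`` and
residuals ``e_hijk`` correlated across days within a subplot.  Candidate
residual structures are iid, AR(1) with a common day variance, and AR(1)
with a separate variance per day; the best structure is chosen by REML
AIC (penalty counts covariance parameters only, fixed effects constant).

Fixed effects are tested with Wald F statistics using containment
denominator degrees of freedom: the warming main effect is tested in the
main-plot stratum with (n_blocks - 1)(n_temp - 1) df, every other term in
the residual stratum with n - rank([X Z]) df.  Backward elimination
drops the least significant currently droppable fixed term (respecting
marginality, highest interaction order first) until everything remaining
is significant; the random structure is never touched.

On balanced complete data with iid errors the REML solution coincides
with the classical expected-mean-squares ANOVA estimators, and the Wald F
statistics reproduce the split-plot ANOVA table exactly; the optimizer
therefore starts from those method-of-moments values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

TEMP_LEVELS = ("Ta", "Te")
PRECIP_LEVELS = ("Pa", "Pr")
DAY_LEVELS = ("D1", "D2", "RW")

FIXED_TERMS = ("T", "P", "D", "TP", "TD", "PD", "TPD")
_TERM_ORDER = {t: len(t) for t in FIXED_TERMS}

_STRUCTURES = ("iid", "ar1_homogeneous", "ar1_heterogeneous")

_LOG2PI = math.log(2.0 * math.pi)


def _contains(outer: str, inner: str) -> bool:
    """True if fixed term ``outer`` strictly contains ``inner`` (TPD > TP)."""
    return outer != inner and set(inner) < set(outer)


@dataclass(frozen=True)
class CovarianceSpec:
    """Residual covariance across the three days within a subplot."""

    structure: str = "iid"
    rho: Optional[float] = None
    day_variances: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.structure not in _STRUCTURES:
            raise ValueError(f"unknown residual structure {self.structure!r}")
        if self.rho is not None and not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")

    @property
    def n_residual_params(self) -> int:
        return {"iid": 1, "ar1_homogeneous": 2, "ar1_heterogeneous": 4}[self.structure]

    @property
    def n_covariance_params(self) -> int:
        """All variance-covariance parameters incl. block and main plot."""
        return 2 + self.n_residual_params


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure; random terms are always block + block:T."""

    fixed_terms: Tuple[str, ...] = FIXED_TERMS

    def __post_init__(self) -> None:
        for t in self.fixed_terms:
            if t not in FIXED_TERMS:
                raise ValueError(f"unknown fixed term {t!r}")
        present = set(self.fixed_terms)
        for t in present:
            # marginality: every lower-order margin of an interaction present
            for k in range(1, len(t)):
                for sub in itertools.combinations(t, k):
                    margin = "".join(s for s in "TPD" if s in sub)
                    if margin not in present:
                        raise ValueError(
                            f"marginality violation: {t} requires {margin} in the model"
                        )

    def drop(self, term: str) -> "ModelSpec":
        return ModelSpec(tuple(t for t in self.fixed_terms if t != term))


def design_frame(n_blocks: int = 4) -> pd.DataFrame:
    """Complete 4 x 2 x 2 x 3 factorial key frame (blocks x T x P x day)."""
    rows = [
        {"block": b, "temperature": t, "precipitation": p, "day": d}
        for b in range(1, n_blocks + 1)
        for t in TEMP_LEVELS
        for p in PRECIP_LEVELS
        for d in DAY_LEVELS
    ]
    return pd.DataFrame(rows)


def _effect_codes(level: str, levels: Sequence[str]) -> np.ndarray:
    """Sum-to-zero (deviation) contrast codes for one factor level."""
    k = len(levels)
    if level == levels[-1]:
        return -np.ones(k - 1)
    out = np.zeros(k - 1)
    out[levels.index(level)] = 1.0
    return out


class SplitPlotModel:
    """Design matrices and grouping structure for one response."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec = ModelSpec(),
                 response: str = "y"):
        required = {"block", "temperature", "precipitation", "day", response}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns: {sorted(missing)}")
        df = data.copy()
        for col, levels in (("temperature", TEMP_LEVELS),
                            ("precipitation", PRECIP_LEVELS),
                            ("day", DAY_LEVELS)):
            bad = set(df[col]) - set(levels)
            if bad:
                raise ValueError(f"invalid {col} levels: {sorted(map(str, bad))}")
        df = df[np.isfinite(pd.to_numeric(df[response], errors="coerce"))]
        if df.empty:
            raise ValueError("no non-missing observations")
        df = df.assign(_day_idx=df["day"].map({d: i for i, d in enumerate(DAY_LEVELS)}))
        df = df.sort_values(["block", "temperature", "precipitation", "_day_idx"],
                            kind="mergesort").reset_index(drop=True)
        self.data = df
        self.spec = spec
        self.response = response
        self.y = df[response].to_numpy(dtype=float)
        self.n = len(df)

        self.X, self.term_slices = self._fixed_matrix(df, spec)
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            raise ValueError(
                f"aliased fixed effects: design matrix rank {rank} < "
                f"{self.X.shape[1]} columns for terms {spec.fixed_terms}"
            )
        self.p = self.X.shape[1]

        blocks = sorted(df["block"].unique())
        self.block_levels = blocks
        self.Zb = np.column_stack(
            [(df["block"] == b).to_numpy(float) for b in blocks])
        mainplots = sorted(set(zip(df["block"], df["temperature"])))
        self.mainplot_levels = mainplots
        self.Zp = np.column_stack(
            [((df["block"] == b) & (df["temperature"] == t)).to_numpy(float)
             for b, t in mainplots])

        # residual blocks: observations of one subplot, ordered by day
        self.subplots: List[Tuple[np.ndarray, np.ndarray]] = []
        for _, sub in df.groupby(["block", "temperature", "precipitation"], sort=True):
            self.subplots.append((sub.index.to_numpy(),
                                  sub["_day_idx"].to_numpy()))
        self._gram_b = self.Zb @ self.Zb.T
        self._gram_p = self.Zp @ self.Zp.T
        self.rank_xz = np.linalg.matrix_rank(
            np.hstack([self.X, self.Zb, self.Zp]))
        self.ddf_mainplot = (len(blocks) - 1) * (len(TEMP_LEVELS) - 1)
        self.ddf_residual = self.n - self.rank_xz

    @staticmethod
    def _fixed_matrix(df: pd.DataFrame,
                      spec: ModelSpec) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
        n = len(df)
        codes = {
            "T": np.array([_effect_codes(v, TEMP_LEVELS) for v in df["temperature"]]),
            "P": np.array([_effect_codes(v, PRECIP_LEVELS) for v in df["precipitation"]]),
            "D": np.array([_effect_codes(v, DAY_LEVELS) for v in df["day"]]),
        }
        cols = [np.ones((n, 1))]
        term_slices: Dict[str, np.ndarray] = {}
        start = 1
        for term in spec.fixed_terms:
            block = codes[term[0]]
            for letter in term[1:]:
                block = np.einsum("ni,nj->nij", block, codes[letter]).reshape(n, -1)
            cols.append(block)
            term_slices[term] = np.arange(start, start + block.shape[1])
            start += block.shape[1]
        return np.hstack(cols), term_slices

    def fixed_row(self, temperature: str, precipitation: str, day: str) -> np.ndarray:
        """Design row for one treatment cell (for cell-mean predictions)."""
        probe = pd.DataFrame({"temperature": [temperature],
                              "precipitation": [precipitation], "day": [day]})
        X, _ = self._fixed_matrix(probe, self.spec)
        return X[0]


def build_model(data: pd.DataFrame, spec: ModelSpec = ModelSpec(),
                response: str = "y") -> SplitPlotModel:
    """Validate the design and assemble model matrices."""
    return SplitPlotModel(data, spec, response)


# ---------------------------------------------------------------------------
# REML machinery


def _unpack(theta: np.ndarray, cov: CovarianceSpec):
    s2b, s2p = np.exp(theta[0]), np.exp(theta[1])
    if cov.structure == "iid":
        day_vars = np.full(3, math.exp(theta[2]))
        rho = 0.0
    elif cov.structure == "ar1_homogeneous":
        day_vars = np.full(3, math.exp(theta[2]))
        rho = math.tanh(theta[3])
    else:
        day_vars = np.exp(theta[2:5])
        rho = math.tanh(theta[5])
    return s2b, s2p, day_vars, rho


def _build_v(model: SplitPlotModel, s2b: float, s2p: float,
             day_vars: np.ndarray, rho: float) -> np.ndarray:
    V = s2b * model._gram_b + s2p * model._gram_p
    sd = np.sqrt(day_vars)
    for idx, days in model.subplots:
        lag = np.abs(days[:, None] - days[None, :])
        R = np.outer(sd[days], sd[days]) * rho ** lag
        V[np.ix_(idx, idx)] += R
    return V


def _profile_loglik(model: SplitPlotModel, V: np.ndarray):
    """REML log-likelihood with profiled GLS fixed effects."""
    cho = linalg.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
    ViX = linalg.cho_solve(cho, model.X)
    Viy = linalg.cho_solve(cho, model.y)
    XtViX = model.X.T @ ViX
    cho2 = linalg.cho_factor(XtViX, lower=True)
    beta = linalg.cho_solve(cho2, model.X.T @ Viy)
    logdet_x = 2.0 * np.sum(np.log(np.diag(cho2[0])))
    r = model.y - model.X @ beta
    quad = float(r @ linalg.cho_solve(cho, r))
    ll = -0.5 * ((model.n - model.p) * _LOG2PI + logdet_v + logdet_x + quad)
    cov_beta = linalg.cho_solve(cho2, np.eye(model.p))
    return ll, beta, cov_beta, cho


def _neg_reml(theta: np.ndarray, model: SplitPlotModel, cov: CovarianceSpec) -> float:
    theta = np.clip(theta, -30.0, 30.0)
    try:
        V = _build_v(model, *_unpack(theta, cov))
        ll, *_ = _profile_loglik(model, V)
    except (linalg.LinAlgError, FloatingPointError, ValueError):
        return 1e10
    if not math.isfinite(ll):
        return 1e10
    return -ll


def _mom_start(model: SplitPlotModel) -> Tuple[float, float, float]:
    """Method-of-moments (expected-mean-squares) variance start values.

    Exact classical estimators on balanced complete data; a pooled
    fallback otherwise.  Floored at a small positive value because the
    optimizer works on log variances.
    """
    df = model.data
    y = model.y
    floor = max(1e-8, 1e-8 * float(np.var(y) + 1.0))

    A = np.hstack([model.X, model.Zp])  # Zp spans the block space too
    resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    ddf = model.n - np.linalg.matrix_rank(A)
    s2e = float(resid @ resid) / max(ddf, 1)

    counts = df.groupby(["block", "temperature", "precipitation"]).size()
    balanced = (len(counts) == len(model.block_levels) * 4
                and counts.nunique() == 1 and counts.iloc[0] == 3)
    if balanced and len(model.block_levels) > 1:
        m = 3 * len(PRECIP_LEVELS)  # obs per main plot
        gm = y.mean()
        blk = df.groupby("block")[model.response].mean()
        tmp = df.groupby("temperature")[model.response].mean()
        mp = df.groupby(["block", "temperature"])[model.response].mean()
        nb = len(blk)
        ms_block = m * len(TEMP_LEVELS) * float(((blk - gm) ** 2).sum()) / (nb - 1)
        dev = mp.copy()
        for (b, t), v in mp.items():
            dev.loc[(b, t)] = v - blk.loc[b] - tmp.loc[t] + gm
        ms_mpe = m * float((dev ** 2).sum()) / ((nb - 1) * (len(TEMP_LEVELS) - 1))
        s2p = (ms_mpe - s2e) / m
        s2b = (ms_block - ms_mpe) / (m * len(TEMP_LEVELS))
    else:
        s2p = s2e / 2.0
        s2b = s2e / 2.0
    return max(s2b, floor), max(s2p, floor), max(s2e, floor)


def _pack_start(cov: CovarianceSpec, s2b: float, s2p: float, s2e: float) -> np.ndarray:
    if cov.structure == "iid":
        return np.log([s2b, s2p, s2e])
    if cov.structure == "ar1_homogeneous":
        return np.array([math.log(s2b), math.log(s2p), math.log(s2e), 0.0])
    return np.array([math.log(s2b), math.log(s2p)]
                    + [math.log(s2e)] * 3 + [0.0])


@dataclass
class FitResult:
    """REML fit: estimates, covariance parameters, tests, diagnostics."""

    model: SplitPlotModel
    covariance: CovarianceSpec
    beta: np.ndarray
    cov_beta: np.ndarray
    fixed_estimates: pd.DataFrame
    variance_components: Dict[str, float]
    reml_loglik: float
    aic: float
    wald_table: pd.DataFrame
    residuals: np.ndarray  # conditional (subject-specific) residuals
    converged: bool
    flags: Tuple[str, ...] = ()

    def cell_mean(self, temperature: str, precipitation: str, day: str) -> float:
        return float(self.model.fixed_row(temperature, precipitation, day) @ self.beta)

    def cell_means(self) -> pd.DataFrame:
        rows = []
        for t in TEMP_LEVELS:
            for p in PRECIP_LEVELS:
                for d in DAY_LEVELS:
                    rows.append({"temperature": t, "precipitation": p, "day": d,
                                 "mean": self.cell_mean(t, p, d)})
        return pd.DataFrame(rows)


def _wald_table(model: SplitPlotModel, beta: np.ndarray,
                cov_beta: np.ndarray) -> pd.DataFrame:
    rows = []
    for term, idx in model.term_slices.items():
        L = beta[idx]
        C = cov_beta[np.ix_(idx, idx)]
        q = len(idx)
        ddf = model.ddf_mainplot if term == "T" else model.ddf_residual
        if ddf <= 0:
            rows.append({"term": term, "F": np.nan, "num_df": q,
                         "den_df": ddf, "p": np.nan, "note": "untestable"})
            continue
        F = float(L @ np.linalg.solve(C, L)) / q
        p = float(stats.f.sf(F, q, ddf))
        rows.append({"term": term, "F": F, "num_df": q, "den_df": ddf,
                     "p": p, "note": ""})
    if not rows:  # intercept-only model: no testable terms
        return pd.DataFrame(columns=["F", "num_df", "den_df", "p", "note"])
    return pd.DataFrame(rows).set_index("term")


def reml_fit(model: SplitPlotModel, cov: CovarianceSpec = CovarianceSpec("iid"),
             seed: int = 0, n_restarts: int = 1) -> FitResult:
    """Maximize the REML log-likelihood over the covariance parameters.

    Starts from method-of-moments ANOVA values (with rho = 0) plus
    seed-controlled jittered restarts; if no restart improves on the
    start by more than 1e-9 the start values are returned as already
    optimal (on balanced iid data they are the exact REML solution).
    """
    s2b, s2p, s2e = _mom_start(model)
    theta0 = _pack_start(cov, s2b, s2p, s2e)
    nll0 = _neg_reml(theta0, model, cov)

    rng = np.random.default_rng(seed)
    best_theta, best_nll = theta0, nll0
    any_success = False
    for k in range(n_restarts + 1):
        start = theta0 if k == 0 else theta0 + rng.normal(0.0, 0.4, size=theta0.size)
        res = optimize.minimize(_neg_reml, start, args=(model, cov),
                                method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-12,
                                         "gtol": 1e-9})
        if np.isfinite(res.fun):
            any_success = any_success or res.success
            if res.fun < best_nll:
                best_theta, best_nll = res.x, res.fun
    if best_nll >= 1e10:
        raise RuntimeError(
            f"REML did not converge for structure {cov.structure!r}; "
            f"start {theta0}, best objective {best_nll}"
        )
    if nll0 - best_nll < 1e-9:
        best_theta, best_nll = theta0, nll0  # start already optimal

    s2b_h, s2p_h, day_vars, rho = _unpack(np.clip(best_theta, -30, 30), cov)
    V = _build_v(model, s2b_h, s2p_h, day_vars, rho)
    ll, beta, cov_beta, cho = _profile_loglik(model, V)

    vc: Dict[str, float] = {"sigma2_block": s2b_h, "sigma2_mainplot": s2p_h}
    if cov.structure == "ar1_heterogeneous":
        for d, v in zip(DAY_LEVELS, day_vars):
            vc[f"sigma2_{d}"] = float(v)
    else:
        vc["sigma2_residual"] = float(day_vars[0])
    if cov.structure != "iid":
        vc["rho"] = float(rho)

    flags: Tuple[str, ...] = ()
    tiny = 1e-6 * max(float(np.var(model.y)), 1e-12)
    if s2b_h < tiny or s2p_h < tiny or np.min(day_vars) < tiny:
        flags += ("boundary_variance",)

    aic = -2.0 * ll + 2.0 * cov.n_covariance_params
    se = np.sqrt(np.diag(cov_beta))
    names = ["intercept"] + [
        f"{term}[{i}]" for term, idx in model.term_slices.items()
        for i in range(len(idx))
    ]
    fixed = pd.DataFrame({"estimate": beta, "se": se}, index=names)
    wald = _wald_table(model, beta, cov_beta)

    # conditional residuals: subtract BLUPs of block and main-plot effects
    r = model.y - model.X @ beta
    Vir = linalg.cho_solve(cho, r)
    ub = s2b_h * (model.Zb.T @ Vir)
    up = s2p_h * (model.Zp.T @ Vir)
    cond_resid = r - model.Zb @ ub - model.Zp @ up

    fitted_cov = replace(cov, rho=(float(rho) if cov.structure != "iid" else None),
                         day_variances=tuple(float(v) for v in day_vars))
    return FitResult(model, fitted_cov, beta, cov_beta, fixed, vc, float(ll),
                     float(aic), wald, cond_resid, converged=True, flags=flags)


def wald_f_table(fit: FitResult) -> pd.DataFrame:
    """Per-term Wald F tests with containment denominator df."""
    return fit.wald_table


def select_covariance_aic(data: pd.DataFrame,
                          candidates: Sequence[CovarianceSpec] = (
                              CovarianceSpec("iid"),
                              CovarianceSpec("ar1_homogeneous"),
                              CovarianceSpec("ar1_heterogeneous"),
                          ),
                          spec: ModelSpec = ModelSpec(),
                          response: str = "y",
                          seed: int = 0) -> Tuple[CovarianceSpec, pd.DataFrame, FitResult]:
    """Fit each candidate residual structure and pick the minimum AIC.

    The fixed and random structure is identical across candidates so the
    REML AICs are comparable.  Non-convergent candidates are excluded
    with a note in the table (never silently).
    """
    model = build_model(data, spec, response)
    rows = []
    fits: Dict[str, FitResult] = {}
    for cand in candidates:
        try:
            fit = reml_fit(model, cand, seed=seed)
        except RuntimeError as exc:
            rows.append({"structure": cand.structure, "aic": np.nan,
                         "reml_loglik": np.nan, "n_cov_params": cand.n_covariance_params,
                         "note": f"non-convergent: {exc}"})
            continue
        fits[cand.structure] = fit
        rows.append({"structure": cand.structure, "aic": fit.aic,
                     "reml_loglik": fit.reml_loglik,
                     "n_cov_params": cand.n_covariance_params, "note": ""})
    table = pd.DataFrame(rows).set_index("structure")
    if not fits:
        raise RuntimeError("no covariance candidate converged")
    best = min(fits.values(), key=lambda f: f.aic)
    return best.covariance, table, best


def backward_eliminate(data: pd.DataFrame,
                       cov: CovarianceSpec = CovarianceSpec("iid"),
                       alpha: float = 0.05,
                       spec: ModelSpec = ModelSpec(),
                       response: str = "y",
                       seed: int = 0) -> Tuple[ModelSpec, List[dict], FitResult]:
    """Marginality-respecting backward elimination of fixed effects.

    At each step, among currently droppable terms (no higher-order
    interaction containing them remains) with p > alpha, the one with the
    highest interaction order is removed (largest p breaking ties), and
    the model is refitted.  Blocks and the main-plot error are structural
    and never dropped; the degenerate end state is intercept + blocks.
    """
    current = spec
    trace: List[dict] = []
    fit = reml_fit(build_model(data, current, response), cov, seed=seed)
    while True:
        wt = fit.wald_table
        droppable = [t for t in current.fixed_terms
                     if not any(_contains(u, t) for u in current.fixed_terms)]
        over = [(t, float(wt.loc[t, "p"])) for t in droppable
                if np.isfinite(wt.loc[t, "p"]) and wt.loc[t, "p"] > alpha]
        if not over:
            break
        over.sort(key=lambda tp: (_TERM_ORDER[tp[0]], tp[1]), reverse=True)
        term, p = over[0]
        trace.append({"dropped": term, "p": p,
                      "remaining": tuple(t for t in current.fixed_terms if t != term)})
        current = current.drop(term)
        fit = reml_fit(build_model(data, current, response), cov, seed=seed)
    return current, trace, fit


def residual_diagnostics(fit: FitResult) -> dict:
    """Machine-readable residual checks (normality, day variances)."""
    r = fit.residuals
    out: dict = {"flags": []}
    scale = float(np.std(r))
    if scale < 1e-12 * (1.0 + float(np.std(fit.model.y))):
        out["flags"].append("degenerate_residuals")
        out["standardized"] = np.zeros_like(r)
        out["skewness"] = 0.0
        out["day_variances"] = {d: 0.0 for d in DAY_LEVELS}
        out["qq"] = (np.array([]), np.array([]))
        return out
    std = r / scale
    out["standardized"] = std
    out["skewness"] = float(stats.skew(std))
    day_idx = fit.model.data["_day_idx"].to_numpy()
    day_var = {d: float(np.var(r[day_idx == i]))
               for i, d in enumerate(DAY_LEVELS) if np.any(day_idx == i)}
    out["day_variances"] = day_var
    n = len(std)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    out["qq"] = (theo, np.sort(std))
    if abs(out["skewness"]) > 1.0:
        out["flags"].append("skewed_residuals")
    vals = [v for v in day_var.values() if v > 0]
    if vals and max(vals) / min(vals) > 4.0:
        out["flags"].append("heterogeneous_day_variance")
    return out


def simulate_response(cell_means: Optional[Mapping[Tuple[str, str, str], float]] = None,
                      sigma_block: float = 0.5,
                      sigma_mainplot: float = 0.5,
                      day_sds: Sequence[float] | float = 1.0,
                      rho: float = 0.0,
                      n_blocks: int = 4,
                      rng: Optional[np.random.Generator] = None,
                      seed: Optional[int] = None) -> pd.DataFrame:
    """Gaussian split-plot simulator used for model calibration checks.

    Draws block and main-plot random intercepts and AR(1)-correlated
    day residuals (optionally with day-specific standard deviations)
    around the supplied cell means (default all zero).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    sds = np.full(3, float(day_sds)) if np.isscalar(day_sds) else np.asarray(day_sds, float)
    if sds.size != 3:
        raise ValueError("day_sds must be a scalar or length-3 sequence")
    lag = np.abs(np.arange(3)[:, None] - np.arange(3)[None, :])
    R = np.outer(sds, sds) * rho ** lag
    chol = np.linalg.cholesky(R + 1e-12 * np.eye(3))

    df = design_frame(n_blocks)
    b_eff = {b: rng.normal(0.0, sigma_block) for b in range(1, n_blocks + 1)}
    p_eff = {(b, t): rng.normal(0.0, sigma_mainplot)
             for b in range(1, n_blocks + 1) for t in TEMP_LEVELS}
    y = np.empty(len(df))
    for (b, t, p), sub in df.groupby(["block", "temperature", "precipitation"],
                                     sort=False):
        e = chol @ rng.standard_normal(3)
        order = sub["day"].map({d: i for i, d in enumerate(DAY_LEVELS)}).to_numpy()
        mu = np.array([0.0 if cell_means is None
                       else cell_means.get((t, p, d), 0.0) for d in DAY_LEVELS])
        y[sub.index] = mu[order] + b_eff[b] + p_eff[(b, t)] + e[order]
    return df.assign(y=y)
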