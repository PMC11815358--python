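"""Independent oracles used by the test suite.

These are deliberately naive implementations (closed forms, brute-force
sums, classical ANOVA mean squares) kept separate from the package code
paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def anova_split_plot_f(df: pd.DataFrame) -> dict:
    """Closed-form split-plot ANOVA F statistics on balanced complete data.

    Expected-mean-squares construction: warming is tested against the
    block x warming interaction mean square (main-plot error, 3 df), all
    subplot/day terms against the pooled residual mean square (30 df).
    """
    y = df["y"].to_numpy()
    gm = y.mean()

    def ss(cols):
        g = df.groupby(list(cols))["y"].agg(["mean", "size"])
        return float((g["size"] * (g["mean"] - gm) ** 2).sum())

    s_t = ss(["temperature"])
    s_p = ss(["precipitation"])
    s_d = ss(["day"])
    s_b = ss(["block"])
    s_bt = ss(["block", "temperature"]) - s_b - s_t
    s_tp = ss(["temperature", "precipitation"]) - s_t - s_p
    s_td = ss(["temperature", "day"]) - s_t - s_d
    s_pd = ss(["precipitation", "day"]) - s_p - s_d
    s_tpd = (ss(["temperature", "precipitation", "day"])
             - s_t - s_p - s_d - s_tp - s_td - s_pd)
    s_tot = float(((y - gm) ** 2).sum())
    s_res = s_tot - s_b - s_bt - s_t - s_p - s_d - s_tp - s_td - s_pd - s_tpd
    n_blocks = df["block"].nunique()
    df_bt = n_blocks - 1
    df_res = len(y) - 1 - (n_blocks - 1) - df_bt - 11
    ms_res = s_res / df_res
    ms_bt = s_bt / df_bt
    return {"T": s_t / ms_bt, "P": s_p / ms_res, "D": s_d / 2 / ms_res,
            "TP": s_tp / ms_res, "TD": s_td / 2 / ms_res,
            "PD": s_pd / 2 / ms_res, "TPD": s_tpd / 2 / ms_res}


def ols_slope(t: np.ndarray, c: np.ndarray) -> float:
    """Textbook OLS slope sum formula."""
    tbar, cbar = t.mean(), c.mean()
    return float(((t - tbar) * (c - cbar)).sum() / ((t - tbar) ** 2).sum())


def delta_to_atom_percent_closed_form(delta: float,
                                      r_vpdb: float = 0.0111802) -> float:
    r = r_vpdb * (delta / 1000.0 + 1.0)
    return 100.0 * r / (1.0 + r)
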