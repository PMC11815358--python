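import numpy as np
import pytest

from pulsechase import splitplot as sp
from oracles import anova_split_plot_f


def _sim(seed, **kw):
    rng = np.random.default_rng(seed)
    kw.setdefault("sigma_block", 1.0)
    kw.setdefault("sigma_mainplot", 0.7)
    kw.setdefault("day_sds", 0.5)
    return sp.simulate_response(rng=rng, **kw)


class TestBuildModel:
    def test_full_factorial_rank(self):
        m = sp.build_model(_sim(0))
        assert m.X.shape == (48, 12)
        assert np.linalg.matrix_rank(m.X) == 12
        assert m.ddf_mainplot == 3
        assert m.ddf_residual == 30  # 48 - rank([X Zb Zp]) = 48 - 18

    def test_intercept_only(self):
        m = sp.build_model(_sim(0), sp.ModelSpec(()))
        assert m.X.shape[1] == 1

    def test_marginality_violation_rejected(self):
        with pytest.raises(ValueError):
            sp.ModelSpec(("T", "P", "D", "TD", "PD", "TPD"))  # TPD needs TP

    def test_invalid_levels_rejected(self):
        d = _sim(0)
        d.loc[0, "day"] = "D9"
        with pytest.raises(ValueError):
            sp.build_model(d)

    def test_missing_observations_drop_smoothly(self):
        d = _sim(3)
        d.loc[5, "y"] = np.nan
        m = sp.build_model(d)
        assert m.n == 47
        assert m.ddf_residual == 29
        fit = sp.reml_fit(m, sp.CovarianceSpec("ar1_homogeneous"))
        assert fit.converged


class TestREMLFit:
    def test_matches_classical_anova_on_balanced_iid(self):
        d = _sim(42, sigma_block=8.0, sigma_mainplot=1.5, day_sds=0.3)
        fit = sp.reml_fit(sp.build_model(d), sp.CovarianceSpec("iid"))
        oracle = anova_split_plot_f(d)
        for term, F in oracle.items():
            assert float(fit.wald_table.loc[term, "F"]) == pytest.approx(
                F, abs=1e-8)

    def test_zero_block_variance_recovered_at_boundary(self):
        # degenerate truth: with sigma2_block = 0 the REML estimate sits
        # at (or sampling-noise-close to) the boundary
        ests, flagged = [], 0
        for seed in range(6):
            d = _sim(700 + seed, sigma_block=0.0, sigma_mainplot=0.0,
                     day_sds=0.3)
            fit = sp.reml_fit(sp.build_model(d), sp.CovarianceSpec("iid"))
            ests.append(fit.variance_components["sigma2_block"])
            flagged += "boundary_variance" in fit.flags
        assert np.median(ests) < 0.02
        assert flagged >= 1

    def test_ar1_with_rho_fixed_at_zero_equals_iid(self):
        # nested equivalence: the AR(1) covariance at rho = 0 is the iid
        # covariance, so the REML objective must agree exactly
        from pulsechase.splitplot import _neg_reml, _pack_start
        d = _sim(11)
        m = sp.build_model(d)
        for s2b, s2p, s2e in [(0.5, 0.5, 1.0), (2.0, 0.1, 0.3)]:
            nll_iid = _neg_reml(_pack_start(sp.CovarianceSpec("iid"),
                                            s2b, s2p, s2e),
                                m, sp.CovarianceSpec("iid"))
            nll_ar1 = _neg_reml(_pack_start(sp.CovarianceSpec("ar1_homogeneous"),
                                            s2b, s2p, s2e),
                                m, sp.CovarianceSpec("ar1_homogeneous"))
            assert nll_ar1 == pytest.approx(nll_iid, abs=1e-6)
        # and the estimated ar1 fit can only improve on iid
        f_iid = sp.reml_fit(m, sp.CovarianceSpec("iid"))
        f_ar1 = sp.reml_fit(m, sp.CovarianceSpec("ar1_homogeneous"))
        assert f_ar1.reml_loglik >= f_iid.reml_loglik - 1e-8

    def test_loglik_not_below_moments_start(self):
        for seed in range(5):
            d = _sim(100 + seed, day_sds=[1.5, 1.0, 0.7], rho=0.3)
            m = sp.build_model(d)
            for struct in ("iid", "ar1_homogeneous", "ar1_heterogeneous"):
                fit = sp.reml_fit(m, sp.CovarianceSpec(struct))
                assert np.isfinite(fit.reml_loglik)
                assert fit.aic == pytest.approx(
                    -2 * fit.reml_loglik
                    + 2 * sp.CovarianceSpec(struct).n_covariance_params)

    def test_nested_structures_ordered_by_loglik(self):
        d = _sim(13, day_sds=[2.0, 1.0, 1.0], rho=0.4)
        m = sp.build_model(d)
        ll = [sp.reml_fit(m, sp.CovarianceSpec(s)).reml_loglik
              for s in ("iid", "ar1_homogeneous", "ar1_heterogeneous")]
        assert ll[0] <= ll[1] + 1e-7 and ll[1] <= ll[2] + 1e-7

    def test_variance_components_recovered_in_median(self):
        # small-sample widths are large with 4 blocks, but the median
        # REML estimate over replicates tracks the truth
        truth = {"sigma2_block": 1.0, "sigma2_mainplot": 0.49,
                 "sigma2_residual": 0.25}
        ests = {k: [] for k in truth}
        for seed in range(40):
            d = _sim(500 + seed, sigma_block=1.0, sigma_mainplot=0.7,
                     day_sds=0.5)
            fit = sp.reml_fit(sp.build_model(d), sp.CovarianceSpec("iid"),
                              seed=seed)
            for k in truth:
                ests[k].append(fit.variance_components[k])
        assert np.median(ests["sigma2_residual"]) == pytest.approx(
            truth["sigma2_residual"], rel=0.25)
        for k in ("sigma2_block", "sigma2_mainplot"):
            assert np.median(ests[k]) == pytest.approx(truth[k], rel=0.5)

    def test_rho_recovered_with_correct_sign(self):
        est = []
        for seed in range(8):
            d = _sim(200 + seed, day_sds=1.0, rho=0.6,
                     sigma_block=0.3, sigma_mainplot=0.3)
            fit = sp.reml_fit(sp.build_model(d),
                              sp.CovarianceSpec("ar1_homogeneous"))
            est.append(fit.variance_components["rho"])
        assert np.median(est) > 0.2


class TestCovarianceSelection:
    def test_single_candidate_returned_unconditionally(self):
        d = _sim(1)
        best, table, fit = sp.select_covariance_aic(
            d, [sp.CovarianceSpec("ar1_homogeneous")])
        assert best.structure == "ar1_homogeneous"
        assert len(table) == 1

    def test_aic_table_complete(self):
        d = _sim(2)
        best, table, _ = sp.select_covariance_aic(d)
        assert set(table.index) == {"iid", "ar1_homogeneous",
                                    "ar1_heterogeneous"}
        assert table["aic"].min() == pytest.approx(
            table.loc[best.structure, "aic"])


class TestBackwardElimination:
    def test_null_data_reduces_toward_intercept(self):
        hits = 0
        for seed in range(6):
            d = _sim(300 + seed)
            final, trace, _ = sp.backward_eliminate(d, alpha=0.05)
            hits += len(final.fixed_terms) <= 2
            assert len(trace) <= 7
        assert hits >= 4  # most null datasets lose (almost) all terms

    def test_strong_interaction_protects_everything(self):
        means = {(t, p, d): (5.0 if (t, p, d) == ("Te", "Pr", "D2") else 0.0)
                 for t in ("Ta", "Te") for p in ("Pa", "Pr")
                 for d in ("D1", "D2", "RW")}
        d = sp.simulate_response(cell_means=means, sigma_block=0.2,
                                 sigma_mainplot=0.2, day_sds=0.2,
                                 seed=9)
        final, trace, _ = sp.backward_eliminate(d, alpha=0.05)
        assert "TPD" in final.fixed_terms
        assert final.fixed_terms == sp.FIXED_TERMS  # marginality keeps all
        assert trace == []

    def test_trace_records_dropped_terms_in_order(self):
        d = _sim(17)
        final, trace, _ = sp.backward_eliminate(d, alpha=0.05)
        dropped = [t["dropped"] for t in trace]
        assert len(dropped) == len(set(dropped))
        # interactions must be dropped before their margins
        for i, t in enumerate(dropped):
            for later in dropped[i + 1:]:
                assert not (set(later) > set(t))


class TestDiagnostics:
    def test_well_specified_residuals_unflagged(self):
        flags = []
        for seed in range(5):
            d = _sim(400 + seed)
            fit = sp.reml_fit(sp.build_model(d), sp.CovarianceSpec("iid"))
            flags.append(sp.residual_diagnostics(fit)["flags"])
        assert sum(f == [] for f in flags) >= 4

    def test_lognormal_response_flags_skew(self):
        d = _sim(5, sigma_block=0.05, sigma_mainplot=0.05, day_sds=1.2)
        d["y"] = np.exp(d["y"])
        fit = sp.reml_fit(sp.build_model(d), sp.CovarianceSpec("iid"))
        diag = sp.residual_diagnostics(fit)
        assert "skewed_residuals" in diag["flags"]

    def test_constant_response_degenerate(self):
        d = _sim(6)
        d["y"] = 3.14
        fit = sp.reml_fit(sp.build_model(d), sp.CovarianceSpec("iid"))
        diag = sp.residual_diagnostics(fit)
        assert "degenerate_residuals" in diag["flags"]


class TestAgainstStatsmodels:
    def test_variance_components_match_mixedlm(self):
        """Independent cross-check of the iid REML fit against
        statsmodels MixedLM (random block intercept + main-plot variance
        component)."""
        smf = pytest.importorskip("statsmodels.formula.api")
        d = _sim(11)
        d2 = d.assign(mainplot=d["block"].astype(str) + d["temperature"])
        md = smf.mixedlm("y ~ C(temperature)*C(precipitation)*C(day)", d2,
                         groups="block", re_formula="1",
                         vc_formula={"mainplot": "0 + C(mainplot)"})
        ours = sp.reml_fit(sp.build_model(d), sp.CovarianceSpec("iid"))
        ref = md.fit(reml=True, method="lbfgs")
        assert ours.variance_components["sigma2_block"] == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=0.02, abs=0.01)
        assert ours.variance_components["sigma2_mainplot"] == pytest.approx(
            float(ref.vcomp[0]), rel=0.02, abs=0.01)
        assert ours.variance_components["sigma2_residual"] == pytest.approx(
            float(ref.scale), rel=0.02)
        # fixed cell means agree (GLS on balanced data)
        cm = ours.cell_mean("Ta", "Pa", "D1")
        obs = ref.predict(d2.iloc[:1]).iloc[0]
        assert cm == pytest.approx(float(obs), abs=0.02)
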