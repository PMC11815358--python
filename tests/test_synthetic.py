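import numpy as np
import pandas as pd
import pytest

from pulsechase import pipeline as pl
from pulsechase import synthetic as syn


class TestDesign:
    def test_default_design_has_48_unique_keys(self, default_config):
        d = syn.generate_design(default_config)
        assert len(d) == 48
        assert not d.duplicated().any()

    def test_single_block_design(self):
        cfg = syn.GeneratorConfig(seed=1, n_blocks=1)
        assert len(syn.generate_design(cfg)) == 12


class TestTrueMeans:
    def test_calibrated_ratios(self, default_config):
        m = syn.generate_true_means(default_config)
        piv = m.pivot_table(index="response",
                            columns=["temperature", "precipitation", "day"],
                            values="mean")

        def ratio(resp, num, den):
            return piv.loc[resp, num] / piv.loc[resp, den]

        # drought lowers respiration by 35% in every treatment
        assert ratio("respiration", ("Ta", "Pa", "D2"),
                     ("Ta", "Pa", "D1")) == pytest.approx(0.65)
        assert ratio("respiration", ("Te", "Pr", "D2"),
                     ("Te", "Pr", "D1")) == pytest.approx(0.65)
        # rewetting: +30% over pre-drought ambient, +70% warmed
        assert ratio("respiration", ("Ta", "Pa", "RW"),
                     ("Ta", "Pa", "D1")) == pytest.approx(1.30)
        assert ratio("respiration", ("Te", "Pa", "RW"),
                     ("Te", "Pa", "D1")) == pytest.approx(1.70)
        # gram-positive C drops 15% at peak drought
        assert ratio("gram_positive_c", ("Ta", "Pa", "D2"),
                     ("Ta", "Pa", "D1")) == pytest.approx(0.85)
        # precipitation history halves microbial excess 13C
        assert ratio("excess13c_cmic", ("Ta", "Pr", "D1"),
                     ("Ta", "Pa", "D1")) == pytest.approx(0.5)
        # fungal excess 13C: -85% at drought, -70% under warming
        assert ratio("excess13c_fungal", ("Ta", "Pa", "D2"),
                     ("Ta", "Pa", "D1")) == pytest.approx(0.15)
        assert ratio("excess13c_fungal", ("Te", "Pa", "D1"),
                     ("Ta", "Pa", "D1")) == pytest.approx(0.30)
        # EOC +80% at peak drought; root sugars +110% under warming at D1
        assert ratio("eoc", ("Ta", "Pa", "D2"),
                     ("Ta", "Pa", "D1")) == pytest.approx(1.8)
        assert ratio("root_sugars", ("Te", "Pa", "D1"),
                     ("Ta", "Pa", "D1")) == pytest.approx(2.1)

    def test_unit_effects_give_flat_means(self):
        flat = {"resp": syn.EffectRow(10.0, "u", {"D1": 1, "D2": 1, "RW": 1})}
        cfg = syn.GeneratorConfig(seed=1, effects=flat)
        m = syn.generate_true_means(cfg)
        assert (m["mean"] == 10.0).all()
        assert (m["mean"] > 0).all()

    def test_missing_effect_row_names_response(self):
        cfg = syn.GeneratorConfig(seed=1)
        with pytest.raises(KeyError, match="nope"):
            syn.generate_true_means(cfg, responses=["nope"])


class TestRawTables:
    def test_seed_determinism_byte_identical(self, default_config):
        a = syn.generate_raw_tables(default_config, dataset_index=3)
        b = syn.generate_raw_tables(default_config, dataset_index=3)
        for name in a:
            pd.testing.assert_frame_equal(a[name], b[name])
        c = syn.generate_raw_tables(default_config, dataset_index=4)
        assert not a["extracts"]["c_f"].equals(c["extracts"]["c_f"])

    def test_atom_percent_ranges(self, raw_bundle):
        ex = raw_bundle["extracts"]
        assert ((ex[["at_f", "at_nf"]] > 0) & (ex[["at_f", "at_nf"]] < 100)).all().all()
        ch = raw_bundle["chamber"]["at_percent"].dropna()
        assert ((ch > 0) & (ch < 100)).all()
        assert (raw_bundle["plfa"]["c_amount"] >= 0).all()
        assert (raw_bundle["extracts"][["c_f", "c_nf"]] > 0).all().all()

    def test_zero_noise_pipeline_identity(self, zero_noise_bundle):
        # with all variance components at zero the analysis recovers the
        # latent truth exactly (inverse-pipeline identity)
        rec = pl.recover_responses(zero_noise_bundle)
        truth = zero_noise_bundle["truth"]
        m = rec.merge(truth, on=syn.KEY_COLS + ["response"])
        rel = (m["value"] - m["true_value"]).abs() / m["true_value"].abs()
        # every latent response except the shared marker (which only
        # feeds the PLFA total) is recovered at all 48 cells
        assert len(m) == 48 * (truth["response"].nunique() - 1)
        assert rel.max() < 1e-8

    def test_variance_components_recovered_from_latent(self, default_config):
        # empirical log-scale day-to-day residual spread matches sigma_resid
        vals = []
        for i in range(30):
            lat = syn.generate_latent(default_config, dataset_index=i,
                                      responses=["cmic"])
            lat["log_ratio"] = np.log(lat["value"] / lat["mean"])
            vals.append(lat.pivot_table(index=["block", "temperature",
                                               "precipitation"],
                                        columns="day", values="log_ratio"))
        allv = pd.concat(vals)
        # within-subplot day contrasts isolate the residual component:
        # var(D1 - D2)/2 = sigma_resid^2 (1 - rho)
        contrast = (allv["D1"] - allv["D2"]).to_numpy()
        expected = default_config.sigma_resid ** 2 * (1 - default_config.rho)
        assert np.var(contrast) / 2 == pytest.approx(expected, rel=0.25)

    def test_d1_raw_excess_emitted_at_label_strength(self, zero_noise_config):
        # raw D1 observables carry 5x the normalized latent excess
        tabs = syn.generate_raw_tables(zero_noise_config)
        rec = pl.recover_responses(tabs)
        truth = tabs["truth"]
        m = rec.merge(truth, on=syn.KEY_COLS + ["response"])
        d1 = m[(m["day"] == "D1") & (m["response"] == "excess13c_cmic")]
        # recovery includes the /5 normalization, so it matches truth ...
        assert d1["value"].to_numpy() == pytest.approx(
            d1["true_value"].to_numpy(), rel=1e-9)
        # ... while the raw enrichment in the extract is 5x the truth
        ex = tabs["extracts"]
        mask = ((ex["day"] == "D1") & (ex["block"] == 1)
                & (ex["temperature"] == "Ta") & (ex["precipitation"] == "Pa"))
        lab = ex[mask & ex["labelled"]].iloc[0]
        nat = ex[mask & ~ex["labelled"]].iloc[0]
        eoc_stock_mg = lab["c_nf"] * 1e-6 * 1.21 * 20 * 1e4 * 1000
        raw_excess = (lab["at_nf"] - nat["at_nf"]) / 100.0 * eoc_stock_mg
        true_eoc = truth[(truth["response"] == "excess13c_eoc")
                         & (truth["block"] == 1) & (truth["day"] == "D1")
                         & (truth["temperature"] == "Ta")
                         & (truth["precipitation"] == "Pa")]["true_value"].iloc[0]
        assert raw_excess == pytest.approx(5.0 * true_eoc, rel=1e-9)


class TestMicroclimate:
    def test_warming_offsets_by_depth(self, default_config):
        mc = syn.generate_microclimate(default_config)
        for depth, expected in syn.TEMP_OFFSETS_BY_DEPTH.items():
            sub = mc[mc["depth_cm"] == depth].pivot_table(
                index="day_index", columns="temperature", values="soil_temp_c")
            assert (sub["Te"] - sub["Ta"]).mean() == pytest.approx(
                expected, abs=0.15)

    def test_moisture_trajectory(self, default_config):
        mc = syn.generate_microclimate(default_config)
        vwc = mc[mc["depth_cm"] == 4].pivot_table(
            index="day_index", columns="temperature", values="vwc_percent")
        drought_end = 30 + default_config.drought_days
        # drought minimum of 5% VWC reached at the end of the drought
        assert vwc["Ta"].loc[drought_end - 1] == pytest.approx(5.0, abs=0.01)
        assert vwc["Ta"].min() == pytest.approx(5.0, abs=1.0)
        # rewetting spikes to the series maximum of 19%
        assert vwc["Ta"].max() == pytest.approx(19.0, abs=0.01)
        assert vwc["Ta"].idxmax() == drought_end
        # warmed soils are drier before the drought
        pre = vwc.loc[: 30 - 1]
        assert pre["Te"].mean() < pre["Ta"].mean()

    def test_no_warming_config_has_zero_offset(self):
        cfg = syn.GeneratorConfig(seed=3)
        mc = syn.generate_microclimate(cfg)
        # offsets are constants of the treatment; Ta series at one depth
        # differ from Te only by offset + noise, so removing the offset
        # leaves a zero-mean difference
        sub = mc[mc["depth_cm"] == 15].pivot_table(
            index="day_index", columns="temperature", values="soil_temp_c")
        resid = (sub["Te"] - sub["Ta"]) - syn.TEMP_OFFSETS_BY_DEPTH[15]
        assert abs(resid.mean()) < 0.1
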