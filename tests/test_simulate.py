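"""Tree-level generators: needle model, dendrometer truth, sap-flow truth, biomass."""

import numpy as np
import pandas as pd
import pytest

import pinedrought as pdr
from pinedrought.design import NeedleParams
from pinedrought.simulate import (
    BIOMASS_DEFAULTS,
    SLA_DEFAULTS,
    needle_length_true,
    sapflow_true_flux,
)
from pinedrought.environment import night_id, night_mean_vpd


class TestNeedleObs:
    def test_noiseless_matches_piecewise_model(self, design):
        p = {tr: pdr.TreatmentParams(needle=NeedleParams(
                threshold_doy=thr, noise_sd=0.0, tree_threshold_sd=0.0, tree_b1_sd=0.0))
             for tr, thr in zip(design.treatments, (205.0, 183.0, 202.0, 173.0))}
        obs = pdr.gen_needle_obs(design, p, treatments=("early",))
        expected = needle_length_true(p["early"].needle, obs["doy"].to_numpy())
        np.testing.assert_allclose(obs["length_mm"], expected, atol=1e-12)
        # flat after cessation, linear ramp before
        post = obs[obs["doy"] > 183]
        assert post["length_mm"].nunique() == 1

    def test_threshold_gap_sets_final_length_difference(self, design, params):
        """Early cessation at DOY 183 vs control 205 shortens needles by ~b1*22 mm."""
        obs = pdr.gen_needle_obs(design, params)
        finals = obs[obs["doy"] == obs["doy"].max()].groupby("treatment")["length_mm"].mean()
        gap = finals["control"] - finals["early"]
        assert gap == pytest.approx(0.8 * 22, abs=7.0)

    def test_lengths_non_negative(self, needles):
        assert (needles["length_mm"] >= 0).all()

    def test_deterministic_under_seed(self, design, params):
        a = pdr.gen_needle_obs(design, params)
        b = pdr.gen_needle_obs(design, params)
        pd.testing.assert_frame_equal(a, b)

    def test_adding_trees_preserves_existing_streams(self, design, params):
        import dataclasses

        small = pdr.gen_needle_obs(design, params)
        bigger = pdr.gen_needle_obs(
            dataclasses.replace(design, n_trees_per_treatment=10), params
        )
        merged = bigger.merge(
            small, on=["tree_id", "treatment", "doy", "needle_id"], suffixes=("_b", "_s")
        )
        np.testing.assert_allclose(merged["length_mm_b"], merged["length_mm_s"])


class TestDendroGen:
    def test_truth_components_reconstruct_signal_without_noise(self, design, env):
        import dataclasses

        p = pdr.default_params()
        p = {tr: dataclasses.replace(v, stem=dataclasses.replace(v.stem, sensor_noise_sd=0.0))
             for tr, v in p.items()}
        dendro, truth = pdr.gen_dendro(design, p, env)
        one = dendro[dendro["tree_id"] == "control_D1"]
        t = truth[truth["tree_id"] == "control_D1"]
        d0 = one["initial_diameter_mm"].iloc[0]
        np.testing.assert_allclose(
            one["diameter_mm"], d0 + t["growth_mm"] - t["twd_mm"], atol=1e-12
        )

    def test_no_water_signal_gives_pure_growth_curve(self, design, env):
        import dataclasses

        p = pdr.default_params()
        p = {tr: dataclasses.replace(
                v, stem=dataclasses.replace(v.stem, sensor_noise_sd=0.0, shrink_gain=0.0))
             for tr, v in p.items()}
        dendro, truth = pdr.gen_dendro(design, p, env)
        one = dendro[dendro["tree_id"] == "control_D1"]
        assert one["diameter_mm"].is_monotonic_increasing
        assert (truth[truth["tree_id"] == "control_D1"]["twd_mm"] == 0).all()

    def test_drought_deficit_exceeds_control(self, design, dendro_data):
        _, truth = dendro_data
        truth = truth.assign(doy=pd.DatetimeIndex(truth["timestamp"]).dayofyear)
        peak = design.peak_drought_days[0]
        midday = truth[(truth["doy"] == peak) & (pd.DatetimeIndex(truth["timestamp"]).hour == 14)]
        by_tr = midday.groupby("treatment")["twd_mm"].mean()
        assert by_tr["early"] > by_tr["control"]

    def test_second_window_growth_reduction_in_truth(self, design, dendro_data):
        """Stress-window growth in stressed trees is 50-60% below control."""
        _, truth = dendro_data
        truth = truth.assign(doy=pd.DatetimeIndex(truth["timestamp"]).dayofyear)
        s, e = design.stress_windows[1]

        def mean_window_growth(tr):
            vals = []
            for _, sub in truth[truth["treatment"] == tr].groupby("tree_id"):
                sub = sub.sort_values("timestamp")
                g = sub[sub["doy"] <= e]["growth_mm"].iloc[-1] - sub[sub["doy"] >= s]["growth_mm"].iloc[0]
                vals.append(g)
            return np.mean(vals)

        reduction = 100 * (1 - mean_window_growth("late") / mean_window_growth("control"))
        assert 50.0 <= reduction <= 60.0


class TestSapflowGen:
    def test_calm_nights_have_exactly_zero_true_flux(self, design, params, env):
        env_t = pdr.env_for_treatment(env, "control", design)
        flux = sapflow_true_flux(design, params["control"], env_t)
        nm = night_mean_vpd(env_t)
        calm = set(nm.index[nm < 0.2])
        nid = night_id(env_t["timestamp"])
        calm_mask = np.array([(not pd.isna(n)) and n in calm for n in nid])
        assert calm_mask.sum() > 100
        assert (flux[calm_mask] == 0).all()

    def test_no_drift_no_noise_signal_is_pure_heat_balance(self, design, env):
        import dataclasses

        p = pdr.default_params()
        p = {tr: dataclasses.replace(v, sapflow=dataclasses.replace(v.sapflow, noise_sd=0.0))
             for tr, v in p.items()}
        sap, truth = pdr.gen_sapflow(design, p, env, drift="none")
        one = sap[sap["tree_id"] == "control_S5"]
        t = truth[truth["tree_id"] == "control_S5"]
        np.testing.assert_allclose(
            pdr.heat_balance_flux(one["signal_w"].to_numpy()), t["flux_kg_h"], atol=1e-12
        )

    def test_early_seasonal_truth_reduced_vs_control(self, design, sapflow_data):
        """Early-stress leaf-area trajectory cuts seasonal transpiration ~40-50%."""
        _, truth = sapflow_data
        tot = truth.groupby(["treatment", "tree_id"])["flux_kg_h"].sum().groupby("treatment").mean()
        reduction = 100 * (1 - tot["early"] / tot["control"])
        assert 40.0 <= reduction <= 50.0

    def test_deterministic_under_seed(self, design, params, env):
        a, _ = pdr.gen_sapflow(design, params, env)
        b, _ = pdr.gen_sapflow(design, params, env)
        pd.testing.assert_frame_equal(a, b)


class TestBiomass:
    def test_zero_se_gives_exact_treatment_means(self, design):
        bio, area, sla = pdr.gen_biomass(design, se_scale=0.0)
        for organ, table in BIOMASS_DEFAULTS.items():
            means = bio.groupby("treatment")[organ].mean()
            for tr, (mean, _) in table.items():
                assert means[tr] == pytest.approx(mean)
        assert bio.groupby("treatment")["bud_g"].std().max() == 0

    def test_default_control_bud_mass_near_table_value(self, design):
        bio, _, _ = pdr.gen_biomass(design)
        assert bio[bio["treatment"] == "control"]["bud_g"].mean() == pytest.approx(3.09, abs=0.9)

    def test_early_bud_mass_below_control_in_truth(self):
        assert BIOMASS_DEFAULTS["bud_g"]["early"][0] < BIOMASS_DEFAULTS["bud_g"]["control"][0]

    def test_leaf_area_defaults_give_35pct_reduction(self):
        """SLA x age-class biomass means: early total leaf area ~35% below control."""

        def la(tr):
            return sum(
                BIOMASS_DEFAULTS[f"needles_{age}_g"][tr][0] * SLA_DEFAULTS[age][tr]
                for age in ("current", "old")
            )

        reduction = 100 * (1 - la("early") / la("control"))
        assert reduction == pytest.approx(35.0, abs=3.0)

    def test_psi_leaf_descriptive_shape(self, design, params, env):
        psi = pdr.gen_psi_leaf(design, params, env, campaign_doys=[150, 189, 251])
        assert (psi["psi_mpa"] < 0).all()
        by = psi.groupby(["treatment", "doy"])["psi_mpa"].mean()
        # drought depresses midday water potential at the first peak ...
        assert by.loc[("early", 189)] < by.loc[("control", 189)]
        # ... and the early-late trees fare better than late trees at the second
        assert by.loc[("early_late", 251)] > by.loc[("late", 251)]
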