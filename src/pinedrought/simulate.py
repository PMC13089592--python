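"""Synthetic tree-level data for the drought-timing experiment.

Every generator is a pure function of (design, params, seed): per-tree random
streams are derived from the master seed with fixed integer offsets, so adding
trees or treatments never reshuffles existing series.  The dendrometer and
sap-flow generators also return their noise-free truth components (growth,
water deficit, flux) so downstream processing can be tested against an exact
oracle when noise and drift are switched off.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .design import WINDOW_TREATMENTS, ExperimentDesign, TreatmentParams, default_params
from .environment import env_for_treatment, gen_environment, night_id, night_mean_vpd

logger = logging.getLogger(__name__)

# fixed stream offsets per generator (master seed + these -> child rngs)
_STREAM_NEEDLE = 201
_STREAM_DENDRO = 202
_STREAM_SAPFLOW = 203
_STREAM_BIOMASS = 204
_STREAM_PSI = 205

# heat-balance constants used to emit the raw sensor signal
WATER_HEAT_CAPACITY = 4186.0  # J / (kg K)
DELTA_T = 4.0  # K


def _tree_rng(design: ExperimentDesign, stream: int, treatment_ix: int, tree_ix: int):
    return np.random.default_rng([int(design.rng_seed), stream, treatment_ix, tree_ix])


def needle_length_true(params, doy):
    """Noise-free needle length (mm): piecewise-linear with growth onset,
    cessation at the threshold day, and slope b2 afterwards."""
    doy = np.asarray(doy, dtype=float)
    p = params
    pre = p.b1 * np.clip(np.minimum(doy, p.threshold_doy) - p.onset_doy, 0.0, None)
    post = p.b2 * np.clip(doy - p.threshold_doy, 0.0, None)
    return pre + post


def gen_needle_obs(
    design: ExperimentDesign,
    params: dict[str, TreatmentParams] | None = None,
    sampling_doys=None,
    treatments=None,
) -> pd.DataFrame:
    """Weekly needle-length observations, two needles per tree.

    Gaussian measurement noise is added to the piecewise-linear truth;
    negative draws are truncated at 0 mm and the truncation count logged.
    """
    params = params or default_params()
    treatments = treatments or design.treatments
    if sampling_doys is None:
        d0, d1 = design.season_span
        sampling_doys = np.arange(max(d0, 120), min(d1, 290) + 1, 7)
    sampling_doys = np.asarray(sampling_doys)

    rows = []
    n_clipped = 0
    for ti, tr in enumerate(design.treatments):
        if tr not in treatments:
            continue
        np_ = params[tr].needle
        for tree in range(1, design.n_trees_per_treatment + 1):
            rng = _tree_rng(design, _STREAM_NEEDLE, ti, tree)
            thr_tree = np_.threshold_doy
            if np_.tree_threshold_sd > 0:
                thr_tree = max(
                    np_.onset_doy + 5.0,
                    rng.normal(np_.threshold_doy, np_.tree_threshold_sd),
                )
            b1_tree = np_.b1
            if np_.tree_b1_sd > 0:
                b1_tree = max(0.05, rng.normal(np_.b1, np_.tree_b1_sd))
            truth = needle_length_true(
                dataclasses.replace(np_, threshold_doy=thr_tree, b1=b1_tree),
                sampling_doys,
            )
            for needle in (1, 2):
                noise = rng.normal(0.0, np_.noise_sd, sampling_doys.size)
                length = truth + noise
                n_clipped += int((length < 0).sum())
                length = np.clip(length, 0.0, None)
                rows.append(
                    pd.DataFrame(
                        {
                            "tree_id": f"{tr}_T{tree}",
                            "treatment": tr,
                            "doy": sampling_doys,
                            "needle_id": needle,
                            "length_mm": length,
                        }
                    )
                )
    if n_clipped:
        logger.info("gen_needle_obs: truncated %d negative lengths at 0", n_clipped)
    return pd.concat(rows, ignore_index=True)


def _soil_stress(swc, ref=30.0, span=15.0):
    return np.clip((ref - np.asarray(swc)) / span, 0.0, 1.0)


def gen_dendro(
    design: ExperimentDesign,
    params: dict[str, TreatmentParams] | None = None,
    env: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Half-hourly stem-diameter series for the dendrometer trees.

    diameter = initial + true growth - true water deficit + sensor noise.
    The true deficit scales with above-threshold VPD, is amplified under dry
    soil, and (for early_late trees in the second window) damped by the
    leaf-area legacy factor.  Returns ``(dendro, truth)`` frames.
    """
    params = params or default_params()
    env = env if env is not None else gen_environment(design)

    data_rows, truth_rows = [], []
    n_dendro = design.n_dendro_per_treatment
    size_factors = np.linspace(0.92, 1.08, n_dendro)  # fixed, balanced spread
    d0s = np.linspace(7.0, 9.0, n_dendro)
    for ti, tr in enumerate(design.treatments):
        env_t = env_for_treatment(env, tr, design)
        doy = env_t["doy"].to_numpy()
        p = params[tr].stem

        # window-masked Gaussian-bell growth rate, normalised so the control
        # (no windows) accumulates season_total mm over the season
        shape = np.exp(-0.5 * ((doy - p.season_mid) / p.season_sd) ** 2)
        norm = shape.sum()
        factor = np.ones(doy.size)
        for i, (s, e) in enumerate(design.stress_windows):
            if tr in WINDOW_TREATMENTS[i]:
                factor[(doy >= s) & (doy <= e)] = p.stress_growth_factor

        vpd = env_t["VPD"].to_numpy()
        stress = _soil_stress(env_t["SWC"].to_numpy())
        legacy = np.ones(doy.size)
        s2, e2 = design.stress_windows[1]
        legacy[(doy >= s2) & (doy <= e2)] = p.legacy_twd_factor
        twd_true = p.shrink_gain * np.clip(vpd - 0.2, 0.0, None) * (1.0 + p.drought_twd_gain * stress) * legacy

        for tree in range(1, n_dendro + 1):
            rng = _tree_rng(design, _STREAM_DENDRO, ti, tree)
            growth = np.cumsum(shape * factor) / norm * p.season_total * size_factors[tree - 1]
            d0 = d0s[tree - 1]
            noise = rng.normal(0.0, p.sensor_noise_sd, doy.size)
            diameter = d0 + growth - twd_true + noise
            tree_id = f"{tr}_D{tree}"
            data_rows.append(
                pd.DataFrame(
                    {
                        "tree_id": tree_id,
                        "treatment": tr,
                        "timestamp": env_t["timestamp"],
                        "diameter_mm": diameter,
                        "initial_diameter_mm": d0,
                    }
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "tree_id": tree_id,
                        "treatment": tr,
                        "timestamp": env_t["timestamp"],
                        "growth_mm": growth,
                        "twd_mm": twd_true,
                    }
                )
            )
    return pd.concat(data_rows, ignore_index=True), pd.concat(truth_rows, ignore_index=True)


def leaf_area_rel(params: TreatmentParams, doy):
    """Relative leaf-area trajectory: linear ramp from onset to cessation."""
    sp, np_ = params.sapflow, params.needle
    frac = np.clip(
        (np.asarray(doy, dtype=float) - np_.onset_doy) / (np_.threshold_doy - np_.onset_doy),
        0.0,
        1.0,
    )
    return sp.la_start + (sp.la_final - sp.la_start) * frac


def sapflow_true_flux(design, params: TreatmentParams, env_t: pd.DataFrame) -> np.ndarray:
    """Noise-free sap flux (kg/h): leaf area x conductance(VPD, SWC) x VPD,
    a reduced fraction at night, and exactly zero on calm nights."""
    sp = params.sapflow
    doy = env_t["doy"].to_numpy()
    vpd = env_t["VPD"].to_numpy()
    swc = env_t["SWC"].to_numpy()
    la = leaf_area_rel(params, doy)
    g = 1.0 / (1.0 + vpd / sp.vpd_half)
    f_swc = np.clip((swc - sp.swc_wilt) / (sp.swc_ref - sp.swc_wilt), 0.05, 1.0)
    flux = sp.flux_scale * la * g * vpd * f_swc

    nid = night_id(env_t["timestamp"])
    is_night = ~pd.isna(nid)
    flux = np.where(is_night, flux * sp.night_frac, flux)
    nm = night_mean_vpd(env_t)
    calm_nights = set(nm.index[nm < 0.2])
    calm_mask = np.array([n in calm_nights if not pd.isna(n) else False for n in nid])
    flux[calm_mask] = 0.0
    return flux


def gen_sapflow(
    design: ExperimentDesign,
    params: dict[str, TreatmentParams] | None = None,
    env: pd.DataFrame | None = None,
    drift: str = "random_walk",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw heat-balance sensor series (W) for the sap-flow trees.

    signal = flux * c_w * delta_T / 3600 + baseline drift + noise.  The drift
    is a piecewise-linear random walk with daily knots (``drift="random_walk"``),
    a fixed affine trend (``"affine"``), or absent (``"none"``).
    Returns ``(sapflow, truth)``; truth carries the noise-free flux and drift.
    """
    params = params or default_params()
    env = env if env is not None else gen_environment(design)

    n_dendro = design.n_dendro_per_treatment
    n_sap = design.n_trees_per_treatment - n_dendro
    size_factors = np.linspace(0.9, 1.1, n_sap)
    data_rows, truth_rows = [], []
    for ti, tr in enumerate(design.treatments):
        env_t = env_for_treatment(env, tr, design)
        ts = env_t["timestamp"]
        doy = env_t["doy"].to_numpy()
        flux_base = sapflow_true_flux(design, params[tr], env_t)
        sp = params[tr].sapflow
        for j in range(n_sap):
            tree = n_dendro + 1 + j
            rng = _tree_rng(design, _STREAM_SAPFLOW, ti, tree)
            flux = flux_base * size_factors[j]
            power = flux * WATER_HEAT_CAPACITY * DELTA_T / 3600.0
            days = np.unique(doy)
            if drift == "random_walk":
                knots = sp.baseline_start + rng.normal(0.3, 0.1) + np.concatenate(
                    [[0.0], np.cumsum(rng.normal(0.0, sp.drift_step_sd, days.size - 1))]
                )
            elif drift == "affine":
                knots = sp.baseline_start + 0.005 * (days - days[0])
            elif drift == "none":
                knots = np.zeros(days.size)
            else:
                raise ValueError(f"unknown drift model {drift!r}")
            hour = ts.dt.hour.to_numpy() + ts.dt.minute.to_numpy() / 60.0
            baseline = np.interp(doy + hour / 24.0, days + 0.5, knots)
            noise = rng.normal(0.0, sp.noise_sd, doy.size) if sp.noise_sd > 0 else 0.0
            signal = power + baseline + noise
            tree_id = f"{tr}_S{tree}"
            data_rows.append(
                pd.DataFrame(
                    {
                        "tree_id": tree_id,
                        "treatment": tr,
                        "timestamp": ts,
                        "signal_w": signal,
                    }
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "tree_id": tree_id,
                        "treatment": tr,
                        "timestamp": ts,
                        "flux_kg_h": flux,
                        "baseline_w": baseline,
                    }
                )
            )
    return pd.concat(data_rows, ignore_index=True), pd.concat(truth_rows, ignore_index=True)


#: end-of-season treatment means (+- SE, n = 4 destructive harvests) for the
#: biomass table; leaf biomass is split into current-year and 1-year-old
#: needles so leaf area per age class is computable via SLA.
BIOMASS_DEFAULTS = {
    # organ: {treatment: (mean, se)}
    "bud_g": {
        "early_late": (1.41, 0.17),
        "early": (1.97, 0.21),
        "late": (2.49, 0.07),
        "control": (3.09, 0.45),
    },
    "needles_current_g": {
        "early_late": (20.0, 4.0),
        "early": (36.0, 9.0),
        "late": (58.0, 5.0),
        "control": (70.0, 8.0),
    },
    "needles_old_g": {
        "early_late": (32.7, 8.0),
        "early": (30.9, 9.0),
        "late": (46.0, 4.0),
        "control": (47.3, 5.5),
    },
    "wood_g": {
        "early_late": (91.8, 5.4),
        "early": (110.3, 10.5),
        "late": (127.3, 13.2),
        "control": (156.1, 15.6),
    },
    "root_g": {
        "early_late": (69.7, 7.7),
        "early": (84.8, 12.2),
        "late": (94.7, 14.1),
        "control": (106.9, 15.0),
    },
}

NEEDLE_AREA_DEFAULTS = {  # surface area per needle, cm2 (n = 8)
    "early_late": (0.39, 0.03),
    "early": (0.36, 0.02),
    "late": (0.62, 0.03),
    "control": (0.57, 0.03),
}

#: specific leaf area (cm2 / g DW) per needle age class; stressed current-year
#: needles are shorter and thinner, hence a higher SLA
SLA_DEFAULTS = {
    "current": {"control": 55.0, "late": 55.0, "early": 69.0, "early_late": 69.0},
    "old": {"control": 45.0, "late": 45.0, "early": 45.0, "early_late": 45.0},
}


def gen_biomass(
    design: ExperimentDesign,
    n_harvest: int = 4,
    se_scale: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """End-of-season biomass table, per-needle surface area and SLA samples.

    Per-tree values are drawn around the treatment means with per-tree SD =
    SE * sqrt(n) * ``se_scale`` (so ``se_scale=0`` gives every tree exactly
    its treatment mean).  Returns ``(biomass, needle_area, sla)``.
    """
    if n_harvest < 1:
        raise ValueError("need at least one harvested tree per treatment")
    rows = []
    for ti, tr in enumerate(design.treatments):
        for tree in range(1, n_harvest + 1):
            rng = _tree_rng(design, _STREAM_BIOMASS, ti, tree)
            rec = {"tree_id": f"{tr}_B{tree}", "treatment": tr}
            for organ, table in BIOMASS_DEFAULTS.items():
                mean, se = table[tr]
                sd = se * np.sqrt(n_harvest) * se_scale
                rec[organ] = max(0.0, mean + rng.normal(0.0, sd) if sd > 0 else mean)
            rows.append(rec)
    biomass = pd.DataFrame(rows)

    area_rows = []
    for ti, tr in enumerate(design.treatments):
        mean, se = NEEDLE_AREA_DEFAULTS[tr]
        sd = se * np.sqrt(design.n_trees_per_treatment) * se_scale
        for tree in range(1, design.n_trees_per_treatment + 1):
            rng = _tree_rng(design, _STREAM_BIOMASS, ti, 100 + tree)
            area_rows.append(
                {
                    "tree_id": f"{tr}_T{tree}",
                    "treatment": tr,
                    "needle_area_cm2": max(0.0, mean + rng.normal(0.0, sd) if sd > 0 else mean),
                }
            )
    needle_area = pd.DataFrame(area_rows)

    sla_rows = []
    for ti, tr in enumerate(design.treatments):
        for tree in range(1, n_harvest + 1):
            rng = _tree_rng(design, _STREAM_BIOMASS, ti, 200 + tree)
            for age in ("current", "old"):
                for sample in range(1, 4):
                    sla_rows.append(
                        {
                            "tree_id": f"{tr}_B{tree}",
                            "treatment": tr,
                            "age_class": age,
                            "sample": sample,
                            "sla_cm2_g": max(
                                1.0, SLA_DEFAULTS[age][tr] + rng.normal(0.0, 3.0) * se_scale
                            ),
                        }
                    )
    sla = pd.DataFrame(sla_rows)
    return biomass, needle_area, sla


def gen_psi_leaf(
    design: ExperimentDesign,
    params: dict[str, TreatmentParams] | None = None,
    env: pd.DataFrame | None = None,
    campaign_doys=None,
) -> pd.DataFrame:
    """Descriptive midday leaf water potential campaigns (MPa).

    A phenomenological response to midday VPD and soil drought, scaled by the
    treatment's leaf-area trajectory so early-stressed trees decline less
    during the late window.  Context output only; nothing downstream fits it.
    """
    params = params or default_params()
    env = env if env is not None else gen_environment(design)
    if campaign_doys is None:
        d0, d1 = design.season_span
        campaign_doys = np.arange(d0 + 25, d1 - 20, 14)
    rows = []
    for ti, tr in enumerate(design.treatments):
        env_t = env_for_treatment(env, tr, design)
        midday = env_t[(env_t["timestamp"].dt.hour >= 12) & (env_t["timestamp"].dt.hour < 14)]
        vpd_mid = midday.groupby("doy")["VPD"].mean()
        swc_mid = midday.groupby("doy")["SWC"].mean()
        for doy in campaign_doys:
            la = float(leaf_area_rel(params[tr], doy))
            stress = float(_soil_stress(swc_mid.loc[doy]))
            mu = -0.45 - 0.18 * float(vpd_mid.loc[doy]) * la - 1.1 * stress * (0.5 + 0.5 * la)
            for tree in range(1, design.n_trees_per_treatment + 1):
                rng = _tree_rng(design, _STREAM_PSI, ti, 1000 * int(doy) + tree)
                rows.append(
                    {
                        "tree_id": f"{tr}_T{tree}",
                        "treatment": tr,
                        "doy": int(doy),
                        "psi_mpa": mu + rng.normal(0.0, 0.08),
                    }
                )
    return pd.DataFrame(rows)


def simulate_scenario(
    design: ExperimentDesign | None = None,
    params: dict[str, TreatmentParams] | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate every input the analysis pipeline consumes.

    Returns a dict with keys ``env, needles, dendro, sapflow, biomass,
    needle_area, sla, psi_leaf, dendro_truth, sapflow_truth``.
    """
    design = design or ExperimentDesign()
    params = params or default_params()
    env = gen_environment(design)
    needles = gen_needle_obs(design, params)
    dendro, dendro_truth = gen_dendro(design, params, env)
    sapflow, sapflow_truth = gen_sapflow(design, params, env)
    biomass, needle_area, sla = gen_biomass(design)
    psi = gen_psi_leaf(design, params, env)
    return {
        "env": env,
        "needles": needles,
        "dendro": dendro,
        "sapflow": sapflow,
        "biomass": biomass,
        "needle_area": needle_area,
        "sla": sla,
        "psi_leaf": psi,
        "dendro_truth": dendro_truth,
        "sapflow_truth": sapflow_truth,
    }
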