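"""End-to-end pipeline: simulate -> fit phenology -> dendro -> sapflow ->
bootstrap -> report.

Each stage writes its artifacts into a fixed run-directory layout
(``inputs/``, ``fits/``, ``dendro/``, ``sapflow/``, ``bootstrap/``,
``report.json``).  A stage failure halts its downstream dependents, which the
report marks as ``"not run"``.  Every artifact carries the configuration hash
and master seed in a sidecar.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .dendro import relative_twd_at_peak, twd_basal_area, window_growth, zero_growth_partition
from .design import default_params
from .environment import env_for_treatment
from .io import config_hash, validate_and_read, validate_frame, write_csv_with_meta
from .phenology import ConvergenceError, PriorBox, compare_thresholds, fit_truncated_mcmc
from .sapflow import cumulative_transpiration, process_sapflow
from .simulate import simulate_scenario
from .stats import bootstrap_contrast, leaf_area_from_biomass, one_way_anova, slope_test, tukey_hsd

logger = logging.getLogger(__name__)

STAGE_DEPS = {
    "simulate": (),
    "phenology": ("simulate",),
    "dendro": ("simulate",),
    "sapflow": ("simulate",),
    "bootstrap": ("simulate", "dendro", "sapflow"),
    "report": (),
}


_STAGE_IDS = {"simulate": 1, "phenology": 2, "dendro": 3, "sapflow": 4, "bootstrap": 5, "report": 6}


def _seed_for(config: PipelineConfig, stage: str) -> int:
    return int(np.random.default_rng([config.seed, _STAGE_IDS[stage]]).integers(0, 2**31 - 1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the machine-readable report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config_hash(config.to_payload()), "seed": config.seed}
    report: dict = {"config_hash": meta["config_hash"], "seed": config.seed, "stages": {}}
    state: dict = {}
    status: dict[str, str] = {}

    for stage in [s for s in ("simulate", "phenology", "dendro", "sapflow", "bootstrap") if s in config.stages]:
        blocked = [d for d in STAGE_DEPS[stage] if d in config.stages and status.get(d) != "ok"]
        if blocked or any(
            d in STAGE_DEPS[stage] and status.get(d) == "failed" for d in STAGE_DEPS[stage]
        ):
            status[stage] = "not run"
            report["stages"][stage] = {"status": "not run", "blocked_by": blocked}
            continue
        try:
            runner = globals()[f"_stage_{stage}"]
            report["stages"][stage] = runner(config, out, meta, state)
            report["stages"][stage]["status"] = "ok"
            status[stage] = "ok"
        except Exception as err:  # halt downstream, keep the report honest
            logger.exception("stage %s failed", stage)
            status[stage] = "failed"
            report["stages"][stage] = {"status": "failed", "error": f"{type(err).__name__}: {err}"}

    if "report" in config.stages:
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _load_inputs(config: PipelineConfig, out: Path, meta: dict) -> dict:
    if config.input_dir is not None:
        src = Path(config.input_dir)
        data = {name: validate_and_read(src / f"{name}.csv", name) for name in ("env", "needles", "dendro", "sapflow", "biomass")}
        for extra in ("sla", "needle_area"):
            p = src / f"{extra}.csv"
            if p.exists():
                data[extra] = pd.read_csv(p)
        return data
    raise RuntimeError("inputs requested before the simulate stage ran")


def _stage_simulate(config: PipelineConfig, out: Path, meta: dict, state: dict) -> dict:
    if config.input_dir is not None:
        state.update(_load_inputs(config, out, meta))
        return {"source": str(config.input_dir), "rows": {k: int(len(v)) for k, v in state.items()}}
    data = simulate_scenario(config.design)
    for name in ("env", "needles", "dendro", "sapflow", "biomass"):
        validate_frame(data[name], name)
    inputs = out / "inputs"
    for name, df in data.items():
        target = inputs / ("truth" if name.endswith("_truth") else "") / f"{name}.csv"
        write_csv_with_meta(df, target, meta)
    state.update(data)
    logger.info("simulate: wrote %d tables", len(data))
    return {"rows": {k: int(len(v)) for k, v in data.items()}}


def _exclude(df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    if not config.exclude_trees:
        return df
    return df[~df["tree_id"].isin(config.exclude_trees)]


def _stage_phenology(config: PipelineConfig, out: Path, meta: dict, state: dict) -> dict:
    needles = _exclude(state["needles"], config)
    d0, d1 = config.design.season_span
    prior = PriorBox(threshold=(float(needles["doy"].min()), float(needles["doy"].max())))
    onset = None
    if config.fit_onset:
        onset = float(default_params()["control"].needle.onset_doy)
    fits = {}
    rows = []
    draw_frames = []
    seed0 = _seed_for(config, "phenology")
    for i, tr in enumerate(config.design.treatments):
        sub = needles[needles["treatment"] == tr]
        if sub.empty:
            continue
        post = fit_truncated_mcmc(
            sub,
            prior=prior,
            n_iter=config.mcmc.n_iter,
            burn_in=config.mcmc.burn_in,
            n_chains=config.mcmc.n_chains,
            seed=seed0 + i,
            onset=onset,
        )
        fits[tr] = post
        s = post.summaries.reset_index()
        s.insert(0, "treatment", tr)
        rows.append(s)
        thin = post.chains[:, ::10, :]
        for c in range(thin.shape[0]):
            df = pd.DataFrame(thin[c], columns=["b1", "b2", "threshold", "sigma"])
            df.insert(0, "chain", c)
            df.insert(0, "treatment", tr)
            draw_frames.append(df)
    state["phenology_fits"] = fits
    fits_dir = out / "fits"
    write_csv_with_meta(pd.concat(rows, ignore_index=True), fits_dir / "summaries.csv", meta)
    write_csv_with_meta(pd.concat(draw_frames, ignore_index=True), fits_dir / "draws.csv", meta)

    result = {"treatments": {}, "comparisons": {}}
    for tr, post in fits.items():
        result["treatments"][tr] = {
            "threshold_median": post.median("threshold"),
            "threshold_ci": list(post.ci("threshold")),
            "max_rhat": max(post.rhat.values()),
            "converged": post.converged,
            "acceptance_rate": [float(a) for a in post.acceptance_rate],
        }
    if "control" in fits:
        for tr in fits:
            if tr == "control":
                continue
            try:
                cmp_ = compare_thresholds(fits[tr], fits["control"])
            except ConvergenceError as err:
                result["comparisons"][f"{tr}_vs_control"] = {"refused": str(err)}
                continue
            result["comparisons"][f"{tr}_vs_control"] = {
                "disjoint": cmp_.disjoint,
                "diff_median": cmp_.diff_median,
                "diff_ci": list(cmp_.diff_ci),
            }
    (fits_dir / "fit_report.json").write_text(
        json.dumps({**result, "prior": {"threshold": list(prior.threshold)}, "seed": seed0, **meta}, indent=1, default=str)
    )
    return result


def _stage_dendro(config: PipelineConfig, out: Path, meta: dict, state: dict) -> dict:
    dendro = _exclude(state["dendro"], config)
    partitions: dict[str, dict] = {}
    daily_frames = []
    for (tree, tr), sub in dendro.groupby(["tree_id", "treatment"], sort=False):
        part = zero_growth_partition(sub, initial_diameter=float(sub["initial_diameter_mm"].iloc[0]))
        twd_basal_area(part)
        partitions.setdefault(tr, {})[tree] = part
        d = part.daily.copy()
        d.insert(0, "treatment", tr)
        d.insert(0, "tree_id", tree)
        daily_frames.append(d)
    state["dendro_partitions"] = partitions
    write_csv_with_meta(pd.concat(daily_frames, ignore_index=True), out / "dendro" / "daily.csv", meta)

    seed = _seed_for(config, "dendro")
    result: dict = {"window_growth": {}, "twd_at_peak": {}}
    control_parts = partitions.get("control", {})
    for wi, (s, e) in enumerate(config.design.stress_windows):
        ctrl = [window_growth(p, s, e) for p in control_parts.values()]
        per_tr = {}
        for tr, parts in partitions.items():
            vals = [window_growth(p, s, e) for p in parts.values()]
            entry = {"mean_mm": float(np.mean(vals))}
            if tr != "control" and len(ctrl) >= 2 and len(vals) >= 2:
                bs = bootstrap_contrast(vals, ctrl, n_iter=config.bootstrap_n_iter, mode="relative", seed=seed + wi)
                entry.update(rel_diff_pct=bs.median, ci95=list(bs.ci95), significant=bs.significant)
            per_tr[tr] = entry
        result["window_growth"][f"window_{wi + 1}"] = per_tr
    for wi, peak in enumerate(config.design.peak_drought_days):
        per_tr = {}
        for tr, parts in partitions.items():
            daily = {t: p.daily for t, p in parts.items()}
            mean_twd = float(
                np.mean([d.loc[d["doy"] == peak, "twd_ba_mm2"].iloc[0] for d in daily.values()])
            )
            entry = {"mean_twd_ba_mm2": mean_twd}
            if tr != "control" and control_parts:
                bs = relative_twd_at_peak(
                    daily, {t: p.daily for t, p in control_parts.items()}, peak,
                    n_iter=config.bootstrap_n_iter, seed=seed + 10 + wi,
                )
                entry.update(rel_diff_pct=bs.median, ci95=list(bs.ci95), significant=bs.significant)
            per_tr[tr] = entry
        result["twd_at_peak"][str(peak)] = per_tr
    return result


def _stage_sapflow(config: PipelineConfig, out: Path, meta: dict, state: dict) -> dict:
    sap = _exclude(state["sapflow"], config)
    env = state["env"]
    flux_frames = []
    cumulative: dict[str, dict[str, float]] = {}
    quality = {}
    d0, d1 = config.design.season_span
    for (tree, tr), sub in sap.groupby(["tree_id", "treatment"], sort=False):
        env_t = env_for_treatment(env, tr, config.design)
        flux, q = process_sapflow(sub.reset_index(drop=True), env_t, config.baseline)
        quality[tree] = {"n_anchors": q.n_anchors, "clip_fraction": q.clip_fraction}
        cumulative.setdefault(tr, {})[tree] = cumulative_transpiration(flux, d0 + 1, d1 - 1)
        keep = flux[["tree_id", "treatment", "timestamp", "flux_kg_h", "clipped"]]
        flux_frames.append(keep)
    write_csv_with_meta(pd.concat(flux_frames, ignore_index=True), out / "sapflow" / "flux.csv", meta)
    cum_rows = [
        {"tree_id": t, "treatment": tr, "litres": v}
        for tr, trees in cumulative.items()
        for t, v in trees.items()
    ]
    write_csv_with_meta(pd.DataFrame(cum_rows), out / "sapflow" / "cumulative.csv", meta)
    state["cumulative_transpiration"] = cumulative

    seed = _seed_for(config, "sapflow")
    result = {"seasonal_litres": {}, "contrast_vs_control": {}, "quality": quality}
    ctrl = list(cumulative.get("control", {}).values())
    for tr, trees in cumulative.items():
        vals = list(trees.values())
        result["seasonal_litres"][tr] = {"mean": float(np.mean(vals)), "per_tree": vals}
        if tr != "control" and len(ctrl) >= 2:
            bs = bootstrap_contrast(vals, ctrl, n_iter=config.bootstrap_n_iter, mode="relative", seed=seed)
            result["contrast_vs_control"][tr] = {
                "rel_diff_pct": bs.median,
                "ci95": list(bs.ci95),
                "significant": bs.significant,
            }
    return result


def _stage_bootstrap(config: PipelineConfig, out: Path, meta: dict, state: dict) -> dict:
    """Treatment contrasts and classical tests on the end-of-season tables."""
    biomass = state["biomass"]
    sla = state.get("sla")
    seed = _seed_for(config, "bootstrap")
    result: dict = {}

    # leaf area per tree from needle biomass x age-class SLA
    sla_means = (
        sla.groupby(["treatment", "age_class"])["sla_cm2_g"].mean() if sla is not None else None
    )
    la_rows = []
    for _, row in biomass.iterrows():
        tr = row["treatment"]
        sla_c = float(sla_means.loc[(tr, "current")]) if sla_means is not None else 55.0
        sla_o = float(sla_means.loc[(tr, "old")]) if sla_means is not None else 45.0
        la = leaf_area_from_biomass(
            {"current": row["needles_current_g"], "old": row["needles_old_g"]},
            {"current": sla_c, "old": sla_o},
        )
        la_rows.append(
            {
                "tree_id": row["tree_id"],
                "treatment": tr,
                "leaf_area_cm2": la["total_cm2"],
                "proportion_old": la["proportion_old"],
            }
        )
    la_df = pd.DataFrame(la_rows)
    write_csv_with_meta(la_df, out / "bootstrap" / "leaf_area.csv", meta)
    state["leaf_area"] = la_df

    ctrl_la = la_df.loc[la_df["treatment"] == "control", "leaf_area_cm2"].to_numpy()
    result["leaf_area_vs_control"] = {}
    result["proportion_old_vs_control"] = {}
    for tr in config.design.treatments:
        if tr == "control":
            continue
        vals = la_df.loc[la_df["treatment"] == tr, "leaf_area_cm2"].to_numpy()
        bs = bootstrap_contrast(vals, ctrl_la, n_iter=config.bootstrap_n_iter, mode="relative", seed=seed)
        result["leaf_area_vs_control"][tr] = {
            "rel_diff_pct": bs.median,
            "ci95": list(bs.ci95),
            "significant": bs.significant,
        }
        props = la_df.loc[la_df["treatment"] == tr, "proportion_old"].to_numpy()
        ctrl_p = la_df.loc[la_df["treatment"] == "control", "proportion_old"].to_numpy()
        bsp = bootstrap_contrast(props, ctrl_p, n_iter=config.bootstrap_n_iter, mode="absolute", seed=seed + 1)
        result["proportion_old_vs_control"][tr] = {
            "diff": bsp.median,
            "ci95": list(bsp.ci95),
            "significant": bsp.significant,
        }

    # ANOVA + Tukey letters on the biomass table
    letters = {}
    for organ in ("bud_g", "wood_g", "root_g"):
        tk = tukey_hsd(biomass[organ].to_numpy(), biomass["treatment"].to_numpy())
        letters[organ] = tk.letters
    result["tukey_letters"] = letters

    # pooled bud-mass ~ leaf-area slope
    merged = biomass.merge(la_df[["tree_id", "leaf_area_cm2"]], on="tree_id")
    st = slope_test(merged["leaf_area_cm2"], merged["bud_g"])
    result["bud_mass_slope"] = {"slope": st.slope, "F": st.f, "p": st.p, "n": st.n}
    anova = one_way_anova(biomass["bud_g"].to_numpy(), biomass["treatment"].to_numpy())
    result["bud_mass_anova"] = {"F": anova.f, "p": anova.p}
    (out / "bootstrap" / "summary.json").write_text(json.dumps({**result, **meta, "seed": seed}, indent=1, default=str))
    return result
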