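"""Half-hourly greenhouse environment generator.

Two adjacent compartments ("ambient" and "stress") share one daily weather
programme; during each stress window the stress compartment ramps stepwise
towards the configured temperature/VPD maxima and its soil dries down
exponentially because watering is suspended.  Outside the windows the two
compartments differ only by small sensor noise.

VPD is always computed from the emitted temperature and relative humidity
with the Magnus saturation-vapour-pressure formula (Alduchov-Eskridge
coefficients), so the consistency invariant VPD = es(T) * (1 - RH/100)
holds at every timestamp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ExperimentDesign, WINDOW_TREATMENTS

# Magnus formula, Alduchov & Eskridge coefficients (kPa, degC)
_MAGNUS_A = 0.61094
_MAGNUS_B = 17.625
_MAGNUS_C = 243.04

COMPARTMENTS = ("ambient", "stress")


def saturation_vapor_pressure(t_air):
    """Saturation vapour pressure (kPa) at air temperature ``t_air`` (degC)."""
    t = np.asarray(t_air, dtype=float)
    return _MAGNUS_A * np.exp(_MAGNUS_B * t / (_MAGNUS_C + t))


def vpd_from_t_rh(t_air, rh):
    """Vapour pressure deficit (kPa) from air temperature (degC) and RH (%).

    Monotonically increasing in temperature and decreasing in relative
    humidity; zero at saturation.
    """
    t = np.asarray(t_air, dtype=float)
    r = np.asarray(rh, dtype=float)
    if np.any(t < -40) or np.any(t > 60):
        raise ValueError("air temperature outside supported range [-40, 60] degC")
    if np.any(r < 0) or np.any(r > 100):
        raise ValueError("relative humidity outside [0, 100] %")
    out = saturation_vapor_pressure(t) * (1.0 - r / 100.0)
    if np.isscalar(t_air) and np.isscalar(rh):
        return float(out)
    return out


def doy_timestamps(design: ExperimentDesign) -> pd.DatetimeIndex:
    """Half-hourly timestamps covering the design's season span."""
    d0, d1 = design.season_span
    start = pd.Timestamp(design.year, 1, 1) + pd.Timedelta(days=d0 - 1)
    end = pd.Timestamp(design.year, 1, 1) + pd.Timedelta(days=d1) - pd.Timedelta(minutes=30)
    return pd.date_range(start, end, freq="30min")


def _daily_programme(design: ExperimentDesign):
    """Per-day climate programme shared by both compartments, plus the
    stress-compartment overrides during the windows."""
    d0, d1 = design.season_span
    days = np.arange(d0, d1 + 1)
    rng = np.random.default_rng([int(design.rng_seed), 101])
    humid = rng.random(days.size) < design.humid_day_prob
    t_max = design.ambient_t_max - 4.0 * humid + rng.normal(0, 0.8, days.size)
    t_min = design.ambient_t_min - 1.5 * humid + rng.normal(0, 0.5, days.size)
    rh_day = np.clip(design.ambient_rh_day + 25.0 * humid + rng.normal(0, 2.0, days.size), 5, 98)
    rh_night = np.clip(design.ambient_rh_night + 7.0 * humid + rng.normal(0, 1.0, days.size), 5, 98)

    amb = dict(t_max=t_max, t_min=t_min, rh_day=rh_day, rh_night=rh_night)
    stress = {k: v.copy() for k, v in amb.items()}

    ambient_vpd_day = float(
        saturation_vapor_pressure(design.ambient_t_max) * (1 - design.ambient_rh_day / 100.0)
    )
    for i, (s, e) in enumerate(design.stress_windows):
        in_w = (days >= s) & (days <= e)
        ds = days[in_w] - s
        steps = 1 + ds // design.ramp_day_step
        tmax_w = np.minimum(design.ambient_t_max + design.ramp_t_day * steps, design.stress_t_max[i])
        tmin_w = np.minimum(
            design.ambient_t_min + design.ramp_t_night * steps, design.ambient_t_min + 6.0
        )
        frac = (tmax_w - design.ambient_t_max) / (design.stress_t_max[i] - design.ambient_t_max)
        vpd_target = ambient_vpd_day + frac * (design.stress_vpd_max[i] - ambient_vpd_day)
        rh_day_w = np.clip(100.0 * (1.0 - vpd_target / saturation_vapor_pressure(tmax_w)), 5, 98)
        stress["t_max"][in_w] = tmax_w
        stress["t_min"][in_w] = tmin_w
        stress["rh_day"][in_w] = rh_day_w
        stress["rh_night"][in_w] = design.stress_rh_night
    return days, humid, amb, stress


def _swc_daily(design: ExperimentDesign, days: np.ndarray, compartment: str) -> np.ndarray:
    """Daily-resolution soil water content for one compartment.

    Ambient pots follow a shallow watering sawtooth around the baseline; the
    stress compartment dries down exponentially towards a floor during each
    unwatered window and is rewatered to baseline at the window end.
    """
    floor = design.swc_drought_min - 1.0
    swc = np.empty(days.size)
    level = design.swc_baseline + 1.5
    for j, d in enumerate(days):
        drying = compartment == "stress" and bool(design.in_window(d))
        if drying:
            level = floor + (level - floor) * np.exp(-design.swc_decay_rate)
        else:
            just_left_window = compartment == "stress" and any(
                d == e + 1 for (_, e) in design.stress_windows
            )
            if just_left_window or (d - days[0]) % design.watering_interval == 0:
                level = design.swc_baseline + 1.5
            else:
                level = 30.0 + (level - 30.0) * np.exp(-0.02)
        swc[j] = level
    return swc


def gen_environment(design: ExperimentDesign) -> pd.DataFrame:
    """Generate the half-hourly environmental record for both compartments.

    Returns a long-format frame with columns ``timestamp, compartment, doy,
    T_air, RH, VPD, PAR, SWC``.
    """
    ts = doy_timestamps(design)
    doy = ts.dayofyear.to_numpy()
    hour = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    days, humid, amb, stress = _daily_programme(design)
    day_ix = doy - days[0]
    diurn = np.cos(2 * np.pi * (hour - 14.5) / 24.0)  # +1 at 14:30, -1 at 02:30

    rng = np.random.default_rng([int(design.rng_seed), 102])
    frames = []
    for comp, prog in (("ambient", amb), ("stress", stress)):
        t_mean = (prog["t_max"][day_ix] + prog["t_min"][day_ix]) / 2
        t_amp = (prog["t_max"][day_ix] - prog["t_min"][day_ix]) / 2
        t_air = t_mean + t_amp * diurn + rng.normal(0, 0.15, ts.size)
        rh_mean = (prog["rh_day"][day_ix] + prog["rh_night"][day_ix]) / 2
        rh_amp = (prog["rh_night"][day_ix] - prog["rh_day"][day_ix]) / 2
        rh = np.clip(rh_mean - rh_amp * diurn + rng.normal(0, 1.0, ts.size), 2, 100)
        vpd = vpd_from_t_rh(t_air, rh)

        par_peak = design.par_max * np.where(humid[day_ix], 0.55, 1.0)
        sun = np.clip(np.sin(np.pi * (hour - 6.0) / 15.0), 0, None) * (hour >= 6) * (hour <= 21)
        par = np.clip(par_peak * sun + rng.normal(0, 15.0, ts.size) * (sun > 0), 0, None)

        swc_d = _swc_daily(design, days, comp)
        swc = np.interp(doy + hour / 24.0, days + 0.5, swc_d)
        swc = np.clip(swc + rng.normal(0, 0.25, ts.size), 0, 60)

        frames.append(
            pd.DataFrame(
                {
                    "timestamp": ts,
                    "compartment": comp,
                    "doy": doy,
                    "T_air": t_air,
                    "RH": rh,
                    "VPD": vpd,
                    "PAR": par,
                    "SWC": swc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def env_for_treatment(env: pd.DataFrame, treatment: str, design: ExperimentDesign) -> pd.DataFrame:
    """Environmental series experienced by one treatment.

    A treatment sits in the stress compartment during the stress windows it
    is assigned to and in the ambient compartment otherwise (the physical
    experiment swaps pots between compartments; the composite series is
    equivalent).
    """
    amb = env[env["compartment"] == "ambient"].reset_index(drop=True)
    if treatment == "control":
        return amb.copy()
    st = env[env["compartment"] == "stress"].reset_index(drop=True)
    if not amb["timestamp"].equals(st["timestamp"]):
        raise ValueError("compartment series are not aligned")
    mask = np.zeros(len(amb), dtype=bool)
    for i, treatments in enumerate(WINDOW_TREATMENTS):
        if treatment in treatments:
            mask |= design.in_window(amb["doy"].to_numpy(), which=i)
    out = amb.copy()
    out.loc[mask, ["T_air", "RH", "VPD", "PAR", "SWC"]] = st.loc[
        mask, ["T_air", "RH", "VPD", "PAR", "SWC"]
    ].to_numpy()
    out["compartment"] = np.where(mask, "stress", "ambient")
    return out


def night_id(timestamps: pd.Series | pd.DatetimeIndex, night_start: int = 21, night_end: int = 5):
    """Label each timestamp with the date its night belongs to (NaT by day).

    A night runs from ``night_start`` (inclusive) through ``night_end``
    (exclusive) the next morning and is labelled with the evening's date.
    """
    ts = pd.DatetimeIndex(timestamps)
    hours = ts.hour
    evening = hours >= night_start
    morning = hours < night_end
    nid = pd.Series(pd.NaT, index=range(len(ts)), dtype="datetime64[ns]")
    nid[evening] = ts.normalize()[evening]
    nid[morning] = (ts.normalize() - pd.Timedelta(days=1))[morning]
    return nid.to_numpy()


def night_mean_vpd(env: pd.DataFrame, night_start: int = 21, night_end: int = 5) -> pd.Series:
    """Mean VPD per night (indexed by night date) for a single-compartment frame."""
    nid = night_id(env["timestamp"], night_start, night_end)
    mask = ~pd.isna(nid)
    return env.loc[mask, "VPD"].groupby(nid[mask]).mean()
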