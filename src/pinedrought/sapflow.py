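"""Heat-balance sap-flow processing: baselining and cumulative transpiration.

The raw signal of a stem heat-balance sensor carries a slowly varying
instrumental baseline.  Transpiration is assumed to be truly zero only on
calm nights (mean VPD below a threshold, default 0.2 kPa); the minimum signal
of each such night anchors a piecewise-linear baseline which is subtracted
from the raw record.  The corrected power is converted to mass flow through
the heat balance at the configured probe temperature difference, and tree
transpiration accumulates as the time-integral of flux (1 kg = 1 l).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import night_id


class BaselineError(RuntimeError):
    pass


@dataclass(frozen=True)
class BaselineConfig:
    vpd_night_threshold: float = 0.2  # kPa
    night_start: int = 21  # hour, local solar time
    night_end: int = 5
    delta_t: float = 4.0  # K between heated and reference probes
    c_water: float = 4186.0  # J / (kg K)

    def __post_init__(self) -> None:
        if self.vpd_night_threshold <= 0 or self.delta_t <= 0 or self.c_water <= 0:
            raise ValueError("baseline configuration values must be positive")


def find_zero_flow_anchors(
    series: pd.DataFrame,
    env: pd.DataFrame,
    config: BaselineConfig | None = None,
) -> pd.DataFrame:
    """Zero-flow anchors: one per calm night, at the night's minimum signal.

    A night qualifies when its mean VPD is below ``vpd_night_threshold``.
    Returns a frame (night, timestamp, signal_w) sorted by time; raises
    :class:`BaselineError` when no night qualifies.
    """
    config = config or BaselineConfig()
    env_nid = night_id(env["timestamp"], config.night_start, config.night_end)
    mask = ~pd.isna(env_nid)
    nm = env.loc[mask, "VPD"].groupby(env_nid[mask]).mean()
    calm = set(nm.index[nm < config.vpd_night_threshold])
    if not calm:
        raise BaselineError(
            "no night with mean VPD below "
            f"{config.vpd_night_threshold} kPa; widen the threshold or extend the record"
        )
    s_nid = night_id(series["timestamp"], config.night_start, config.night_end)
    s_mask = np.array([(not pd.isna(n)) and n in calm for n in s_nid])
    if not s_mask.any():
        raise BaselineError("series does not cover any calm night")
    sub = series.loc[s_mask, ["timestamp", "signal_w"]].copy()
    sub["night"] = s_nid[s_mask]
    ix = sub.groupby("night")["signal_w"].idxmin()
    anchors = sub.loc[ix.to_numpy()].sort_values("timestamp").reset_index(drop=True)
    return anchors[["night", "timestamp", "signal_w"]]


def baseline_correct(series: pd.DataFrame, anchors: pd.DataFrame) -> pd.DataFrame:
    """Subtract the anchor-interpolated baseline from the raw signal.

    The baseline passes linearly through the anchor points and is held
    constant before the first and after the last anchor.  Negative corrected
    values are clipped to zero and flagged (``clipped`` column); the clip
    fraction is available from :func:`quality_summary`.
    """
    if len(anchors) < 1:
        raise ValueError("need at least one anchor")
    t = pd.DatetimeIndex(series["timestamp"]).asi8.astype(float)
    ta = pd.DatetimeIndex(anchors["timestamp"]).asi8.astype(float)
    baseline = np.interp(t, ta, anchors["signal_w"].to_numpy(dtype=float))
    corrected = series["signal_w"].to_numpy(dtype=float) - baseline
    clipped = corrected < 0
    corrected = np.clip(corrected, 0.0, None)
    out = series.copy()
    out["baseline_w"] = baseline
    out["corrected_w"] = corrected
    out["clipped"] = clipped
    return out


def heat_balance_flux(corrected_w, config: BaselineConfig | None = None):
    """Convert corrected heating power (W) to sap flux (kg/h).

    flux = P / (c_water * delta_T), converted from kg/s to kg/h; linear in
    the signal.
    """
    config = config or BaselineConfig()
    p = np.asarray(corrected_w, dtype=float)
    out = p / (config.c_water * config.delta_t) * 3600.0
    return float(out) if out.ndim == 0 else out


def cumulative_transpiration(
    flux: pd.DataFrame,
    doy_from: int | None = None,
    doy_to: int | None = None,
    flux_col: str = "flux_kg_h",
) -> float:
    """Trapezoidal time-integral of sap flux over a DOY window, in litres.

    Gaps longer than one day are reported with a warning and the integral is
    accumulated over the contiguous segments only.
    """
    ts = pd.DatetimeIndex(flux["timestamp"])
    doy = ts.dayofyear
    doy_from = int(doy.min()) if doy_from is None else doy_from
    doy_to = int(doy.max()) if doy_to is None else doy_to
    if doy_from < doy.min() or doy_to > doy.max() or doy_from > doy_to:
        raise ValueError(f"window [{doy_from}, {doy_to}] outside record")
    sel = (doy >= doy_from) & (doy <= doy_to)
    t = ts[sel].asi8.astype(float) / 3.6e12  # hours
    f = flux.loc[sel, flux_col].to_numpy(dtype=float)
    if t.size < 2:
        return 0.0
    dt = np.diff(t)
    gaps = np.nonzero(dt > 24.0)[0]
    if gaps.size:
        inventory = [(str(ts[sel][i]), str(ts[sel][i + 1])) for i in gaps]
        warnings.warn(f"gaps > 1 day inside window: {inventory}; integrating available segments")
    seg = dt <= 24.0
    return float(np.sum(0.5 * (f[1:] + f[:-1]) * dt * seg))


@dataclass
class SapflowQuality:
    n_anchors: int
    clip_fraction: float
    anchor_nights: list = field(default_factory=list)


def process_sapflow(
    series: pd.DataFrame,
    env: pd.DataFrame,
    config: BaselineConfig | None = None,
) -> tuple[pd.DataFrame, SapflowQuality]:
    """Full chain for one tree: anchors -> baseline -> flux (kg/h).

    Returns the per-timestamp frame (with ``flux_kg_h``) and a quality
    summary (anchor count, clipped fraction).
    """
    config = config or BaselineConfig()
    anchors = find_zero_flow_anchors(series, env, config)
    corrected = baseline_correct(series, anchors)
    corrected["flux_kg_h"] = heat_balance_flux(corrected["corrected_w"].to_numpy(), config)
    quality = SapflowQuality(
        n_anchors=len(anchors),
        clip_fraction=float(corrected["clipped"].mean()),
        anchor_nights=list(anchors["night"]),
    )
    return corrected, quality
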