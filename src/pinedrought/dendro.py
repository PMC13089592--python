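"""Zero-growth partitioning of dendrometer series.

A point-dendrometer signal mixes irreversible radial growth with reversible
shrinking/swelling of elastic bark tissue.  Under the zero-growth assumption,
growth occurs only when the diameter exceeds its previously recorded maximum;
the shortfall below the running maximum is the tree water deficit (TWD).
TWD is also expressed in basal-area units (mm^2) to remove stem-size effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import BootstrapResult, bootstrap_contrast


@dataclass
class DendroPartition:
    """Result of the zero-growth partition for a single tree.

    ``frame`` holds per-timestamp columns (diameter, running_max, twd_mm);
    ``daily`` holds per-day net growth (mm) and, once
    :func:`twd_basal_area` has run, the mean basal-area deficit (mm^2).
    The reconstruction identity diameter = running_max - twd_mm holds exactly
    at every timestamp.
    """

    frame: pd.DataFrame
    daily: pd.DataFrame
    initial_diameter: float

    @property
    def cumulative_growth(self) -> float:
        return float(self.daily["daily_growth_mm"].sum())


def zero_growth_partition(
    series: pd.DataFrame,
    diameter_col: str = "diameter_mm",
    time_col: str = "timestamp",
    initial_diameter: float | None = None,
) -> DendroPartition:
    """Partition a diameter series into net growth and tree water deficit.

    running_max(t) is the maximum diameter recorded up to t; daily growth is
    the day-over-day increase of the end-of-day running maximum (zero on the
    first day); twd(t) = running_max(t) - diameter(t) >= 0.
    """
    if len(series) < 2:
        raise ValueError("need at least two timestamps to partition")
    ts = pd.DatetimeIndex(series[time_col])
    if not ts.is_monotonic_increasing or ts.has_duplicates:
        raise ValueError("timestamps must be strictly increasing")
    d = series[diameter_col].to_numpy(dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    running_max = np.maximum.accumulate(d)
    twd = running_max - d

    frame = pd.DataFrame(
        {
            "timestamp": ts,
            "diameter_mm": d,
            "running_max_mm": running_max,
            "twd_mm": twd,
        }
    )
    date = ts.normalize()
    eod = frame.groupby(date)["running_max_mm"].last()
    growth = eod.diff().fillna(0.0)
    daily = pd.DataFrame(
        {
            "date": eod.index,
            "doy": eod.index.dayofyear,
            "daily_growth_mm": growth.to_numpy(),
        }
    ).reset_index(drop=True)
    d0 = float(initial_diameter) if initial_diameter is not None else float(d[0])
    return DendroPartition(frame=frame, daily=daily, initial_diameter=d0)


def twd_basal_area(
    partition: DendroPartition,
    initial_diameter: float | None = None,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Basal-area tree water deficit (mm^2) per timestamp and per day.

    The absolute stem diameter is reconstructed from the pre-installation
    caliper value plus the sensor displacement; the deficit at a timestamp is
    (pi/4) * (d_max^2 - d^2).  The daily value is the mean (default) or the
    time-integral of the half-hourly deficits.
    """
    d0 = float(initial_diameter) if initial_diameter is not None else partition.initial_diameter
    if d0 <= 0:
        raise ValueError("initial diameter must be positive")
    f = partition.frame
    disp = f["diameter_mm"].to_numpy() - f["diameter_mm"].iloc[0]
    d_abs = d0 + disp
    if np.any(d_abs <= 0):
        raise ValueError("reconstructed diameter is non-positive; check initial_diameter")
    d_max = np.maximum.accumulate(d_abs)
    ba = np.pi / 4.0 * (d_max**2 - d_abs**2)
    per_ts = pd.DataFrame({"timestamp": f["timestamp"], "twd_ba_mm2": ba})
    date = pd.DatetimeIndex(f["timestamp"]).normalize()
    if aggregate == "mean":
        daily_ba = per_ts.groupby(date)["twd_ba_mm2"].mean()
    elif aggregate == "integral":
        # sum of half-hourly values scaled to a one-day unit
        daily_ba = per_ts.groupby(date)["twd_ba_mm2"].sum() / 48.0
    else:
        raise ValueError("aggregate must be 'mean' or 'integral'")
    daily_col = daily_ba.rename("twd_ba_mm2").rename_axis("date").reset_index()
    if "twd_ba_mm2" in partition.daily.columns:
        partition.daily = partition.daily.drop(columns="twd_ba_mm2")
    partition.daily = partition.daily.merge(daily_col, on="date", how="left")
    return per_ts.assign(date=date)


def window_growth(partition: DendroPartition, doy_start: int, doy_end: int) -> float:
    """Net diameter growth (mm) over a DOY window: running max at the window
    end minus at the window start (non-negative by construction)."""
    f = partition.frame
    doy = pd.DatetimeIndex(f["timestamp"]).dayofyear
    if doy_start < doy.min() or doy_end > doy.max() or doy_start > doy_end:
        raise ValueError(f"window [{doy_start}, {doy_end}] outside record [{doy.min()}, {doy.max()}]")
    rm = f["running_max_mm"].to_numpy()
    start_ix = np.nonzero(doy >= doy_start)[0][0]
    end_ix = np.nonzero(doy <= doy_end)[0][-1]
    return float(rm[end_ix] - rm[start_ix])


def daily_twd_ba(series: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Convenience: partition a raw series and return its daily frame with
    growth and basal-area TWD columns."""
    part = zero_growth_partition(series, **kwargs)
    twd_basal_area(part)
    return part.daily


def relative_twd_at_peak(
    treatment_daily: dict[str, pd.DataFrame],
    control_daily: dict[str, pd.DataFrame],
    peak_doy: int,
    n_iter: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap contrast of per-tree basal-area TWD at the peak-drought day.

    Inputs map tree_id -> daily partition frame (with ``doy`` and
    ``twd_ba_mm2`` columns).  Trees missing the peak day are excluded with a
    warning.  The contrast is relative (% of the control mean).
    """

    def extract(group: dict[str, pd.DataFrame]) -> np.ndarray:
        vals, missing = [], []
        for tree, daily in group.items():
            sel = daily.loc[daily["doy"] == peak_doy, "twd_ba_mm2"]
            if sel.empty or sel.isna().all():
                missing.append(tree)
            else:
                vals.append(float(sel.iloc[0]))
        if missing:
            warnings.warn(f"trees missing peak day {peak_doy}: {missing}; excluded")
        return np.asarray(vals)

    t_vals, c_vals = extract(treatment_daily), extract(control_daily)
    if t_vals.size < 2 or c_vals.size < 2:
        raise ValueError("need >= 2 trees per group with data at the peak day")
    return bootstrap_contrast(t_vals, c_vals, n_iter=n_iter, mode="relative", seed=seed)
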