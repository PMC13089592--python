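"""Experiment design and simulation-truth parameters.

The default :class:`ExperimentDesign` encodes a greenhouse drought-timing
experiment on Scots pine saplings: four treatments (control, early-season hot
drought, late-season hot drought, and both), two stress windows in which
watering stops and air temperature ramps stepwise to a configured maximum,
and soil water content drying down from ~35-40% to ~22% volumetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

TREATMENTS = ("control", "early", "late", "early_late")

#: treatments exposed to the hot-drought compartment during each stress window
WINDOW_TREATMENTS = (("early", "early_late"), ("late", "early_late"))


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout and environmental targets of the drought-timing experiment.

    Parameters
    ----------
    n_trees_per_treatment:
        Saplings per treatment; the first ``n_dendro_per_treatment`` carry
        point dendrometers, the rest carry sap-flow sensors.
    season_span:
        Day-of-year interval covered by the half-hourly record.
    stress_windows:
        Two DOY intervals during which watering stops and the stress
        compartment ramps; must lie within ``season_span`` and not overlap.
    peak_drought_days:
        DOY of maximum drought intensity within each window.
    ramp_day_step:
        Days between stepwise temperature increments during a ramp.
    stress_t_max / stress_vpd_max:
        Per-window daytime maxima reached at full ramp (degC, kPa).
    swc_baseline / swc_drought_min:
        Volumetric soil water content (%) under regular watering and the
        level approached at the end of an unwatered stress window.
    humid_day_prob:
        Fraction of days with a cool, humid weather pattern; only such days
        produce calm nights (mean VPD < 0.2 kPa) usable as zero-flow anchors.
    """

    treatments: tuple[str, ...] = TREATMENTS
    n_trees_per_treatment: int = 8
    n_dendro_per_treatment: int = 4
    season_span: tuple[int, int] = (100, 300)
    stress_windows: tuple[tuple[int, int], tuple[int, int]] = ((163, 191), (225, 253))
    peak_drought_days: tuple[int, int] = (189, 251)
    ramp_day_step: int = 2
    ramp_t_day: float = 2.0
    ramp_t_night: float = 1.25
    ambient_t_max: float = 26.5
    ambient_t_min: float = 11.0
    stress_t_max: tuple[float, float] = (36.5, 38.2)
    stress_vpd_max: tuple[float, float] = (3.5, 4.0)
    ambient_rh_day: float = 45.0
    ambient_rh_night: float = 90.0
    stress_rh_night: float = 75.0
    humid_day_prob: float = 0.25
    par_max: float = 1400.0
    swc_baseline: float = 37.0
    swc_drought_min: float = 22.0
    swc_decay_rate: float = 0.095
    watering_interval: int = 3
    year: int = 2019
    rng_seed: int = 42
    excluded_trees: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        d0, d1 = self.season_span
        if not d0 < d1:
            raise ValueError("season_span must be an increasing DOY interval")
        prev_end = None
        for (s, e) in self.stress_windows:
            if not (d0 <= s < e <= d1):
                raise ValueError(f"stress window ({s}, {e}) outside season span {self.season_span}")
            if prev_end is not None and s <= prev_end:
                raise ValueError("stress windows must not overlap")
            prev_end = e
        if not self.swc_drought_min < self.swc_baseline:
            raise ValueError("swc_drought_min must be below swc_baseline")
        if self.n_dendro_per_treatment > self.n_trees_per_treatment:
            raise ValueError("more dendrometer trees than trees per treatment")

    def with_seed(self, seed: int) -> "ExperimentDesign":
        return replace(self, rng_seed=int(seed))

    def in_window(self, doy, which: int | None = None):
        """Boolean mask: DOY lies inside a stress window (optionally a specific one)."""
        import numpy as np

        doy = np.asarray(doy)
        if which is not None:
            s, e = self.stress_windows[which]
            return (doy >= s) & (doy <= e)
        mask = np.zeros(doy.shape, dtype=bool)
        for s, e in self.stress_windows:
            mask |= (doy >= s) & (doy <= e)
        return mask


@dataclass(frozen=True)
class NeedleParams:
    """Truth parameters of the piecewise-linear needle elongation model.

    Needle length grows at ``b1`` mm/day from ``onset_doy`` until the
    treatment-specific cessation day ``threshold_doy``, then at ``b2``.
    Individual trees cease growth at days scattered around the treatment
    mean (``tree_threshold_sd``), which is what widens the credible interval
    of the population-level fit the way real needle data do.
    """

    b1: float = 0.8
    b2: float = 0.0
    threshold_doy: float = 205.0
    onset_doy: float = 118.0
    noise_sd: float = 2.0
    tree_threshold_sd: float = 2.0  # between-tree spread of the cessation day
    tree_b1_sd: float = 0.12  # between-tree spread of the elongation rate

    def __post_init__(self) -> None:
        if self.b1 <= 0:
            raise ValueError("b1 must be positive")
        if self.b2 < 0:
            raise ValueError("b2 must be non-negative")
        if not self.onset_doy < self.threshold_doy:
            raise ValueError("onset_doy must precede threshold_doy")


@dataclass(frozen=True)
class StemParams:
    """Truth parameters for the dendrometer signal generator.

    ``season_total`` is the control-level seasonal diameter increment (mm),
    distributed over a Gaussian-bell daily growth rate.  During a treatment's
    stress windows the rate is multiplied by ``stress_growth_factor``.
    Water-deficit shrinkage scales with daytime VPD (``shrink_gain`` mm/kPa),
    is amplified under dry soil (``drought_twd_gain``), and for trees with a
    prior-stress leaf-area legacy is damped by ``legacy_twd_factor`` during
    the second window.
    """

    initial_diameter: float = 8.0
    season_total: float = 3.0
    season_mid: float = 190.0
    season_sd: float = 45.0
    stress_growth_factor: float = 0.45
    shrink_gain: float = 0.03
    drought_twd_gain: float = 2.0
    legacy_twd_factor: float = 1.0
    sensor_noise_sd: float = 0.002


@dataclass(frozen=True)
class SapflowParams:
    """Truth parameters for the heat-balance sap-flow generator.

    Relative leaf area ramps linearly from ``la_start`` at needle onset to
    ``la_final`` at the treatment's cessation day.  True flux is
    leaf area x conductance(VPD, SWC) x VPD, with nocturnal flux a fixed
    fraction of the daytime response and exactly zero on calm nights
    (mean VPD < 0.2 kPa).  The emitted sensor signal is the heat-balance
    power equivalent plus a piecewise-linear random-walk baseline drift
    (daily knots) plus Gaussian noise.
    """

    la_start: float = 0.10
    la_final: float = 1.0
    flux_scale: float = 0.15  # kg/h at unit leaf area and unit VPD response
    vpd_half: float = 1.5  # kPa, conductance half-saturation
    swc_wilt: float = 16.0
    swc_ref: float = 30.0
    night_frac: float = 0.15
    baseline_start: float = 0.3  # W
    drift_step_sd: float = 0.01  # W per daily knot
    noise_sd: float = 0.0015  # W, after half-hourly averaging

    def __post_init__(self) -> None:
        if self.la_final < 0 or self.la_start < 0:
            raise ValueError("leaf area must be non-negative")


@dataclass(frozen=True)
class TreatmentParams:
    needle: NeedleParams = field(default_factory=NeedleParams)
    stem: StemParams = field(default_factory=StemParams)
    sapflow: SapflowParams = field(default_factory=SapflowParams)


#: treatment-specific defaults anchored on the experiment's headline effects:
#: needle-growth cessation days 205/183/202/173, a ~45% seasonal transpiration
#: reduction in early-stressed trees via reduced final leaf area, and a damped
#: second-window water deficit in early_late trees.
def default_params() -> dict[str, TreatmentParams]:
    thresholds = {"control": 205.0, "early": 183.0, "late": 202.0, "early_late": 173.0}
    la_final = {"control": 1.0, "early": 0.52, "late": 0.95, "early_late": 0.48}
    legacy = {"control": 1.0, "early": 1.0, "late": 1.0, "early_late": 0.6}
    out = {}
    for tr in TREATMENTS:
        out[tr] = TreatmentParams(
            needle=NeedleParams(threshold_doy=thresholds[tr]),
            stem=StemParams(legacy_twd_factor=legacy[tr]),
            sapflow=SapflowParams(la_final=la_final[tr]),
        )
    return out
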