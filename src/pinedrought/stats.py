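"""Bootstrap treatment contrasts and classical utility statistics.

The central procedure is a two-group bootstrap: both the treatment and the
control group are resampled with replacement (same size as the original
group), the difference of resampled means is recorded, and after 1,000
iterations the contrast is declared significant when the equal-tailed 95%
percentile interval of the differences excludes zero.  One-way ANOVA with a
Tukey(-Kramer) HSD post-hoc and a least-squares slope test accompany it for
the end-of-season tables, together with the SLA-based leaf-area derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class BootstrapResult:
    """Distribution of resampled treatment-minus-control differences.

    ``mode="absolute"`` records mean_t - mean_c; ``mode="relative"`` records
    100 * (mean_t - mean_c) / mean_c (percent of the control mean).
    ``significant`` is True when the 95% percentile interval excludes zero.
    """

    n_iter: int
    differences: np.ndarray
    ci95: tuple[float, float]
    significant: bool
    mode: str
    seed: int
    statistic: str = "mean"

    @property
    def median(self) -> float:
        return float(np.median(self.differences))


def bootstrap_contrast(
    treatment,
    control,
    n_iter: int = 1000,
    mode: str = "absolute",
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap the difference in group means against the control."""
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("absolute", "relative"):
        raise ValueError("mode must be 'absolute' or 'relative'")
    if mode == "relative" and np.isclose(c.mean(), 0.0):
        raise ValueError("control mean is zero; relative contrast undefined")
    rng = np.random.default_rng(int(seed))
    t_means = t[rng.integers(0, t.size, size=(n_iter, t.size))].mean(axis=1)
    c_means = c[rng.integers(0, c.size, size=(n_iter, c.size))].mean(axis=1)
    if mode == "absolute":
        diff = t_means - c_means
    else:
        diff = 100.0 * (t_means - c_means) / c_means
    lo, hi = np.percentile(diff, [2.5, 97.5])
    significant = bool(lo > 0.0 or hi < 0.0)
    return BootstrapResult(
        n_iter=n_iter,
        differences=diff,
        ci95=(float(lo), float(hi)),
        significant=significant,
        mode=mode,
        seed=int(seed),
    )


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float
    ss_total: float
    ms_within: float


def _group_arrays(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    arrays = [values[groups == g] for g in labels]
    return labels, arrays


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA from the between/within decomposition."""
    labels, arrays = _group_arrays(values, groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    n_total = pooled.size
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_total = float(((pooled - grand) ** 2).sum())
    df_b = len(labels) - 1
    df_w = n_total - len(labels)
    if ss_within <= 0:
        if np.isclose(ss_between, 0.0):
            raise ValueError("degenerate input: zero variance within and between groups")
        return AnovaResult(np.inf, df_b, df_w, 0.0, float(ss_between), 0.0, float(ss_total), 0.0)
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p, float(ss_between), float(ss_within), float(ss_total), float(ms_w))


@dataclass(frozen=True)
class TukeyResult:
    pairs: pd.DataFrame  # group_a, group_b, diff, q, p, significant
    letters: dict[str, str]
    alpha: float


def _letters_from_pairs(labels, means, sig) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm: groups
    sharing a letter are not significantly different."""
    order = np.argsort(-np.asarray(means))  # letters follow descending means
    labels = [labels[i] for i in order]
    sets = [set(labels)]
    for (a, b), is_sig in sig.items():
        if not is_sig:
            continue
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            for new in (s - {a}, s - {b}):
                if not any(new <= other for other in sets):
                    sets.append(new)
    sets = [s for s in sets if s]
    # deterministic letter order: by best (highest-mean) member
    rank = {lab: i for i, lab in enumerate(labels)}
    sets.sort(key=lambda s: min(rank[x] for x in s))
    letters = {lab: "" for lab in labels}
    for i, s in enumerate(sets):
        ch = chr(ord("a") + i)
        for lab in s:
            letters[lab] += ch
    return {lab: "".join(sorted(v)) for lab, v in letters.items()}


def tukey_hsd(values, groups, alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD pairwise comparisons with Tukey-Kramer standard errors and
    a compact letter display (shared letter = not significantly different)."""
    labels, arrays = _group_arrays(values, groups)
    anova = one_way_anova(values, groups)
    k = len(labels)
    rows = []
    sig = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            se = np.sqrt(anova.ms_within / 2.0 * (1.0 / a.size + 1.0 / b.size))
            diff = a.mean() - b.mean()
            q = np.abs(diff) / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, k, anova.df_within)) if np.isfinite(q) else 0.0
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "diff": float(diff),
                    "q": float(q),
                    "p": p,
                    "significant": p < alpha,
                }
            )
            sig[(labels[i], labels[j])] = p < alpha
    means = [a.mean() for a in arrays]
    letters = _letters_from_pairs(list(labels), means, sig)
    return TukeyResult(pairs=pd.DataFrame(rows), letters=letters, alpha=alpha)


@dataclass(frozen=True)
class SlopeTestResult:
    slope: float
    intercept: float
    f: float
    p: float
    n: int


def slope_test(x, y) -> SlopeTestResult:
    """Least-squares line with an F-test of zero slope (pooled single-slope
    fit, as used for the bud-mass ~ leaf-area relationship)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 points")
    if np.isclose(x.var(), 0.0):
        raise ValueError("x is constant; slope is not identifiable")
    res = sps.linregress(x, y)
    f = float(res.rvalue**2 / (1 - res.rvalue**2) * (x.size - 2)) if abs(res.rvalue) < 1 else np.inf
    return SlopeTestResult(float(res.slope), float(res.intercept), f, float(res.pvalue), int(x.size))


def leaf_area_from_biomass(biomass_by_class, sla_by_class):
    """Leaf area per age class from needle biomass (g DW) and SLA (cm^2/g).

    Returns a dict with per-class areas (cm^2), the total, and the
    proportion of 1-year-old ("old") needles in the total leaf area.
    """
    areas = {}
    for cls, b in biomass_by_class.items():
        if b < 0:
            raise ValueError(f"negative biomass for class {cls!r}")
        sla = sla_by_class[cls]
        if sla <= 0:
            raise ValueError(f"SLA must be positive for class {cls!r}")
        areas[cls] = float(b) * float(sla)
    total = sum(areas.values())
    old = areas.get("old", 0.0)
    proportion_old = old / total if total > 0 else np.nan
    return {"areas_cm2": areas, "total_cm2": total, "proportion_old": proportion_old}
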