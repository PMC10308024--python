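"""Lifespan trajectory analytics for per-subfield volumes.

Pipeline, given a long-format subject table (subject_id, age, sex, region,
volume_mm3):

1. per (region, sex), ordinary-least-squares fit of volume on a natural
   cubic spline (NCS) basis of age — piecewise cubic, smooth at interior
   knots, linear beyond the boundary knots, quantile-placed knots;
2. spline degrees of freedom chosen by minimizing the Akaike Information
   Criterion over a candidate range (ties resolved toward the smaller,
   more parsimonious df);
3. inflection ages of the fitted trajectory detected with the kneedle
   knee-point procedure (curve normalized to the unit square, difference
   from the chord, local maxima above a sensitivity threshold), applied
   separately to the rising and falling segments split at the boundary of
   the global-maximum plateau so both the end of growth and the onset of
   decay are found;
4. within each period between consecutive inflection ages, where the
   age-volume relation is taken as locally linear, an OLS regression
   ``volume ~ age * sex`` tests the age slope, the sex offset and their
   interaction; p-values are corrected with the Benjamini-Hochberg
   step-up false-discovery-rate procedure across the analysis family;
5. a normalized anteroposterior composition profile: per subject and per
   slice along the head-tail axis, the fraction of each subfield among
   hippocampus voxels, positions rescaled to 0-100% and averaged across
   subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices, dmatrix
from statsmodels.stats.multitest import multipletests

from .loss import CANONICAL_NAMES

__all__ = [
    "TrajectoryFit",
    "PeriodResult",
    "fit_ncs",
    "select_df_aic",
    "detect_inflections",
    "period_regressions",
    "bh_fdr",
    "anteroposterior_profile",
    "analyze_cohort",
]

REQUIRED_COLUMNS = ("subject_id", "age", "sex", "region", "volume_mm3")


def _subset(table: pd.DataFrame, region: str, sex: str | None):
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"subject table lacks columns {missing}")
    sub = table[table.region == region]
    if sex is not None:
        sub = sub[sub.sex == sex]
    if sub.duplicated(["subject_id"]).any():
        raise ValueError(f"duplicate subject rows for region {region!r}")
    return sub


# ---------------------------------------------------------------------------
# natural cubic spline fits


@dataclass
class TrajectoryFit:
    """An NCS volume-age fit for one (region, sex)."""

    region: str
    sex: str
    df: int
    knots: np.ndarray
    coefficients: np.ndarray
    aic: float
    r_squared: float
    p_value: float
    age_range: tuple
    inflection_ages: list = field(default_factory=list)
    _design_info: object = None
    _results: object = None

    def predict(self, ages):
        ages = np.asarray(ages, dtype=float)
        basis = build_design_matrices([self._design_info],
                                      {"age": ages})[0]
        return np.asarray(basis) @ self.coefficients


def fit_ncs(table: pd.DataFrame, region: str, sex: str | None,
            df: int) -> TrajectoryFit:
    """OLS fit of volume on a df-degree natural cubic spline basis of age."""
    if df < 2:
        raise ValueError("spline df must be >= 2")
    sub = _subset(table, region, sex)
    n = len(sub)
    if n < df + 2:
        raise ValueError(f"need at least df+2={df + 2} observations for "
                         f"df={df}, got {n}")
    ages = sub.age.to_numpy(dtype=float)
    vols = sub.volume_mm3.to_numpy(dtype=float)
    # the cr() basis spans constants, so the intercept is dropped from the
    # formula to keep the design full-rank (model df = spline df)
    design = dmatrix("cr(age, df=%d) - 1" % df, {"age": ages})
    x = np.asarray(design)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"rank-deficient spline design for region {region!r} "
                         f"(df={df}, n={n})")
    res = sm.OLS(vols, x).fit()

    # knots live in the memorized state of the cr() stateful transform
    fi = list(design.design_info.factor_infos.values())[0]
    cr_obj = next(iter(fi.state["transforms"].values()))
    knots = np.asarray(cr_obj._all_knots, dtype=float)

    return TrajectoryFit(
        region=region, sex=sex if sex is not None else "all", df=df,
        knots=knots, coefficients=np.asarray(res.params),
        aic=float(res.aic), r_squared=float(res.rsquared),
        p_value=float(res.f_pvalue),
        age_range=(float(ages.min()), float(ages.max())),
        _design_info=design.design_info, _results=res)


def select_df_aic(table: pd.DataFrame, region: str, sex: str | None,
                  df_range) -> int:
    """df minimizing the AIC; ties go to the smallest df."""
    df_range = sorted(set(int(d) for d in df_range))
    if not df_range:
        raise ValueError("df_range is empty")
    best_df, best_aic = None, np.inf
    for d in df_range:
        aic = fit_ncs(table, region, sex, d).aic
        if aic < best_aic:
            best_df, best_aic = d, aic
    return best_df


# ---------------------------------------------------------------------------
# kneedle inflection detection


def _kneedle_segment(x, y, sensitivity):
    """Knee x-positions of one monotone-ish curve segment (kneedle).

    Canonicalizes the segment to concave-increasing (flipping for
    decreasing direction, point-reflecting for convex shape), takes the
    difference between the normalized curve and the chord, and returns
    local maxima exceeding the sensitivity threshold
    ``S * mean(delta x_normalized)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        return []
    y_span = np.ptp(y)
    if y_span < 1e-12 * max(1.0, np.abs(y).max()) or np.ptp(x) == 0:
        return []                                   # flat: no knee
    xn = (x - x.min()) / np.ptp(x)
    yn = (y - y.min()) / y_span
    flip_index = False
    if yn[-1] < yn[0]:                              # decreasing -> increasing
        yn = 1.0 - yn
    if np.mean(yn - xn) < 0:                        # convex -> concave
        xn, yn = 1.0 - xn[::-1], 1.0 - yn[::-1]
        flip_index = True
    d = yn - xn
    threshold = sensitivity * np.mean(np.diff(xn))
    interior = np.arange(1, len(d) - 1)
    is_lmx = (d[interior] >= d[interior - 1]) & (d[interior] >= d[interior + 1])
    knees = []
    for i in interior[is_lmx]:
        if d[i] > threshold:
            j = len(x) - 1 - i if flip_index else i
            knees.append(float(x[j]))
    return knees


def detect_inflections(fit: TrajectoryFit, step: float = 0.5,
                       sensitivity: float = 1.0,
                       plateau_tolerance: float = 0.02) -> list:
    """Knee/elbow ages of a fitted trajectory.

    Evaluates the fitted curve on a `step`-year grid, splits it at the
    global-maximum plateau into a rising and a falling segment (each
    retaining the plateau), and runs kneedle on each.  The split points are
    the first/last ages whose value is within ``plateau_tolerance`` of the
    maximum (relative to the curve's range) rather than the literal argmax:
    on fitted curves the plateau is gently humped, and splitting at the
    hump's peak would shorten the falling segment, steepen its chord and
    bias the detected knee away from the true curvature change.  An empty
    result is valid (straight or flat trajectories have no inflection).
    """
    lo, hi = fit.age_range
    grid = np.arange(lo, hi + step / 2, step)
    y = fit.predict(grid)
    near_max = y >= y.max() - plateau_tolerance * max(np.ptp(y), 1e-12)
    i_first = int(np.argmax(near_max))                 # plateau entry
    i_last = len(y) - 1 - int(np.argmax(near_max[::-1]))   # plateau exit

    knees = []
    if i_last >= 2:
        knees += _kneedle_segment(grid[:i_last + 1], y[:i_last + 1], sensitivity)
    if i_first <= len(y) - 3:
        knees += _kneedle_segment(grid[i_first:], y[i_first:], sensitivity)

    # deduplicate within one grid step
    out = []
    for k in sorted(knees):
        if not out or k - out[-1] > step:
            out.append(round(k, 6))
    fit.inflection_ages = out
    return out


# ---------------------------------------------------------------------------
# per-period linear models


@dataclass
class PeriodResult:
    """OLS of volume ~ age * sex within one lifespan period."""

    region: str
    period: tuple               # [age_lo, age_hi)
    n: int
    slope_age: float
    effect_sex: float | None
    interaction_age_sex: float | None
    p_values: dict              # term -> raw p
    p_adjusted: dict = field(default_factory=dict)


def period_regressions(table: pd.DataFrame, region: str, periods,
                       min_per_sex: int = 4) -> list:
    """Fit volume ~ age + sex + age:sex by OLS within each period.

    Periods with fewer than `min_per_sex` observations in some present sex
    are skipped with a warning.  Single-sex tables drop the sex terms and
    still estimate the age slope.
    """
    results = []
    for lo, hi in periods:
        sub = _subset(table, region, None)
        sub = sub[(sub.age >= lo) & (sub.age < hi)]
        sexes = sorted(sub.sex.unique())
        if len(sub) == 0:
            warnings.warn(f"empty period [{lo}, {hi}) for region {region!r}; "
                          "skipped")
            continue
        if any((sub.sex == s).sum() < min_per_sex for s in sexes) or \
                len(sub) < 2 * min_per_sex:
            warnings.warn(f"period [{lo}, {hi}) for region {region!r} has "
                          "too few observations; skipped")
            continue
        if len(sexes) > 1:
            fit = smf.ols("volume_mm3 ~ age * C(sex)", data=sub).fit()
            sex_term = next(t for t in fit.params.index
                            if t.startswith("C(sex)"))
            inter_term = next(t for t in fit.params.index
                              if t.startswith("age:C(sex)"))
            results.append(PeriodResult(
                region=region, period=(float(lo), float(hi)), n=len(sub),
                slope_age=float(fit.params["age"]),
                effect_sex=float(fit.params[sex_term]),
                interaction_age_sex=float(fit.params[inter_term]),
                p_values={"age": float(fit.pvalues["age"]),
                          "sex": float(fit.pvalues[sex_term]),
                          "age_x_sex": float(fit.pvalues[inter_term])}))
        else:
            fit = smf.ols("volume_mm3 ~ age", data=sub).fit()
            results.append(PeriodResult(
                region=region, period=(float(lo), float(hi)), n=len(sub),
                slope_age=float(fit.params["age"]),
                effect_sex=None, interaction_age_sex=None,
                p_values={"age": float(fit.pvalues["age"])}))
    return results


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def periods_from_inflections(age_range, inflection_ages):
    """Half-open periods partitioning the age range at the inflection ages."""
    lo, hi = age_range
    cuts = [lo] + [a for a in sorted(inflection_ages) if lo < a < hi] + [hi]
    # np.nextafter so the last period includes the upper boundary age
    return [(cuts[i], cuts[i + 1] if i + 2 < len(cuts)
             else np.nextafter(cuts[-1], np.inf))
            for i in range(len(cuts) - 1)]


# ---------------------------------------------------------------------------
# anteroposterior composition profile


def anteroposterior_profile(labelmaps, axis: int = 1, n_points: int = 101,
                            class_ids=None) -> pd.DataFrame:
    """Mean per-slice subfield composition from head (0%) to tail (100%).

    For each label map, every slice along `axis` containing hippocampus
    voxels contributes the fraction of each class among the hippocampus
    voxels of that slice; slice positions are normalized to [0, 100]%
    between the first and last non-empty slice, resampled on a common
    grid, and averaged across subjects.  Per-position fractions sum to 1.
    """
    if class_ids is None:
        class_ids = sorted(set(
            int(c) for lm in labelmaps for c in np.unique(lm.data) if c != 0))
    positions = np.linspace(0.0, 100.0, n_points)
    curves = []
    for lm in labelmaps:
        data = np.asarray(lm.data)
        fg = data > 0
        if not fg.any():
            raise ValueError("empty label map in anteroposterior profile")
        other = tuple(a for a in range(data.ndim) if a != axis)
        per_slice_fg = fg.sum(axis=other)
        nonempty = np.where(per_slice_fg > 0)[0]
        j0, j1 = nonempty[0], nonempty[-1]
        idx = nonempty
        pos = (idx - j0) / max(j1 - j0, 1) * 100.0
        fracs = np.stack([(data == c).sum(axis=other)[idx] / per_slice_fg[idx]
                          for c in class_ids])
        resampled = np.stack([np.interp(positions, pos, fracs[k])
                              for k in range(len(class_ids))])
        resampled /= resampled.sum(axis=0, keepdims=True)
        curves.append(resampled)
    mean_curve = np.mean(curves, axis=0)
    mean_curve /= mean_curve.sum(axis=0, keepdims=True)
    cols = {"position_pct": positions}
    for k, c in enumerate(class_ids):
        cols[CANONICAL_NAMES.get(c, str(c))] = mean_curve[k]
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# whole-cohort analysis


def analyze_cohort(table: pd.DataFrame, df_range=range(3, 8),
                   step: float = 0.5, sensitivity: float = 1.0,
                   merge_within: float = 2.0) -> dict:
    """Full trajectory analysis of a subject table.

    Per (region, sex): AIC df selection, NCS fit, inflection detection.
    Per region: periods from the union of both sexes' inflection ages
    (ages closer than `merge_within` years merged), then per-period OLS
    with the age x sex interaction; BH-FDR across all (region, period,
    term) tests of the analysis.
    """
    regions = sorted(table.region.unique())
    fits, periods_by_region, all_period_results = {}, {}, []
    for region in regions:
        ages_union = []
        for sex in sorted(table[table.region == region].sex.unique()):
            df = select_df_aic(table, region, sex, df_range)
            fit = fit_ncs(table, region, sex, df)
            detect_inflections(fit, step=step, sensitivity=sensitivity)
            fits[(region, sex)] = fit
            ages_union += fit.inflection_ages
        merged = []
        for a in sorted(ages_union):
            if merged and a - merged[-1][-1] <= merge_within:
                merged[-1].append(a)
            else:
                merged.append([a])
        inflections = [float(np.mean(g)) for g in merged]
        sub = table[table.region == region]
        age_range = (float(sub.age.min()), float(sub.age.max()))
        periods = periods_from_inflections(age_range, inflections)
        periods_by_region[region] = {"inflections": inflections,
                                     "periods": periods}
        all_period_results += period_regressions(table, region, periods)

    flat_p = [(i, term, pr.p_values[term])
              for i, pr in enumerate(all_period_results)
              for term in pr.p_values]
    if flat_p:
        adjusted = bh_fdr([p for _, _, p in flat_p])
        for (i, term, _), adj in zip(flat_p, adjusted):
            all_period_results[i].p_adjusted[term] = float(adj)

    return {"fits": fits, "regions": periods_by_region,
            "period_results": all_period_results}
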