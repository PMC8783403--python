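"""Summary measures of health inequality: D, R, PAR and PAF.

Given disaggregated subgroup estimates ``y_g`` and the national average
``mu`` (the weighted rate over all records, not the mean of subgroup
estimates), the four measures are

* Difference      ``D = y_adv - y_dis`` (favorable) or ``y_dis - y_adv``
  (adverse): the absolute gap between the two extreme subgroups, on the
  indicator's scale.
* Ratio           ``R = y_adv / y_dis`` (favorable) or ``y_dis / y_adv``
  (adverse): the same pairing, as a quotient.
* Population Attributable Risk  ``PAR = y_ref - mu`` where the reference is
  the best-off subgroup; non-negative for favorable indicators and
  non-positive for adverse ones, because the best-off extreme brackets the
  weighted average.
* Population Attributable Fraction ``PAF = PAR / mu * 100``: the relative
  headroom — by how much (in %) the national value would improve if every
  subgroup attained the reference level.

Reference-group rules: for ordered and binary stratifiers the reference is
the *declared* advantaged level (richest quintile, secondary+ education,
urban residence, female neonates) even when it is not empirically the best;
for non-ordered stratifiers (region) the reference is the empirical extreme
— highest estimate for favorable indicators, lowest for adverse ones — and
the comparator is the opposite extreme, so non-ordered D >= 0 and R >= 1 by
construction.

Uncertainty intervals for measures come from a stratified cluster bootstrap:
PSUs are resampled with replacement within strata, the full
disaggregate-then-measure computation is repeated, and percentile intervals
are taken.  The subgroup pairing is held fixed at the point-estimate
selection across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import DimensionSpec, IndicatorSpec, as_indicator
from .estimation import NATIONAL_LABEL, _eligible, disaggregate
from .exceptions import MeasureError

__all__ = [
    "SummaryMeasureResult", "select_reference", "difference", "ratio", "par",
    "paf", "compute_measures", "measure_uncertainty", "bootstrap_measures",
    "InequalitySummary", "MEASURES",
]

MEASURES = ("D", "R", "PAR", "PAF")


@dataclass(frozen=True)
class SummaryMeasureResult:
    """One summary measure with its uncertainty interval and provenance."""

    measure: str
    value: float
    ui_low: float
    ui_high: float
    reference_subgroup: str
    comparator_subgroup: str
    dimension: str
    indicator: str
    survey_year: int | None = None


def _subgroup_values(estimates: pd.DataFrame, dim: DimensionSpec) -> dict[str, float]:
    """Level -> estimate map, skipping absent (NaN) levels with a warning."""
    sub = estimates[estimates["subgroup"] != NATIONAL_LABEL]
    values: dict[str, float] = {}
    absent = []
    for level in dim.levels:
        row = sub[sub["subgroup"] == level]
        if row.empty or not np.isfinite(row["estimate"].iloc[0]):
            absent.append(level)
            continue
        values[level] = float(row["estimate"].iloc[0])
    if absent:
        warnings.warn(f"subgroup(s) without estimates excluded: {absent}",
                      stacklevel=3)
    return values


def _national_value(estimates: pd.DataFrame, national) -> float:
    if national is not None:
        if isinstance(national, pd.Series):
            return float(national["estimate"])
        if hasattr(national, "estimate"):
            return float(national.estimate)
        return float(national)
    row = estimates[estimates["subgroup"] == NATIONAL_LABEL]
    if row.empty:
        raise MeasureError("national average not found in estimates and not given")
    return float(row["estimate"].iloc[0])


def select_reference(
    estimates: pd.DataFrame, dim: DimensionSpec, ind: IndicatorSpec | str
) -> tuple[str, str]:
    """Pick the (reference, comparator) subgroup pair for a stratifier.

    Ordered/binary: reference is the declared advantaged level, comparator
    the opposite declared extreme.  Non-ordered: reference is the
    empirically best-off level (max for favorable, min for adverse) and the
    comparator the opposite empirical extreme; ties keep the first declared
    level and are logged with a warning.
    """
    ind = as_indicator(ind)
    values = _subgroup_values(estimates, dim)
    if len(values) < 2:
        raise MeasureError("need at least 2 subgroups with estimates")
    if dim.kind in ("ordered", "binary"):
        ref, comp = dim.advantaged_level, dim.disadvantaged_level
        if ref not in values or comp not in values:
            raise MeasureError(
                f"reference pair ({ref!r}, {comp!r}) not fully estimated")
        return ref, comp
    # non-ordered: empirical extremes, first-declared tie-break
    levels = [l for l in dim.levels if l in values]
    best = (max if ind.polarity == "favorable" else min)(
        levels, key=lambda l: values[l])
    worst = (min if ind.polarity == "favorable" else max)(
        levels, key=lambda l: values[l])
    for kind, chosen in (("best", best), ("worst", worst)):
        tied = [l for l in levels if values[l] == values[chosen]]
        if len(tied) > 1:
            warnings.warn(f"tie at the {kind} extreme among {tied}; "
                          f"keeping {chosen!r} (first declared)", stacklevel=2)
    return best, worst


def _paired_values(estimates, dim, ind):
    ind = as_indicator(ind)
    ref, comp = select_reference(estimates, dim, ind)
    values = _subgroup_values(estimates, dim)
    return ind, ref, comp, values[ref], values[comp]


def difference(
    estimates: pd.DataFrame, dim: DimensionSpec, ind: IndicatorSpec | str,
    survey_year: int | None = None,
) -> SummaryMeasureResult:
    """Absolute gap between the extreme subgroups, on the indicator scale.

    Favorable: advantaged minus disadvantaged; adverse: most-burdened minus
    reference, so D quantifies the excess burden.  Non-ordered dimensions
    give max minus min, hence D >= 0.
    """
    ind, ref, comp, y_ref, y_comp = _paired_values(estimates, dim, ind)
    d = y_ref - y_comp if ind.polarity == "favorable" else y_comp - y_ref
    return SummaryMeasureResult("D", d, np.nan, np.nan, ref, comp,
                                dim.name, ind.name, survey_year)


def ratio(
    estimates: pd.DataFrame, dim: DimensionSpec, ind: IndicatorSpec | str,
    survey_year: int | None = None,
) -> SummaryMeasureResult:
    """Relative gap between the same subgroup pair as :func:`difference`."""
    ind, ref, comp, y_ref, y_comp = _paired_values(estimates, dim, ind)
    num, den = ((y_ref, y_comp) if ind.polarity == "favorable"
                else (y_comp, y_ref))
    if den <= 0:
        raise MeasureError(f"ratio undefined: denominator subgroup estimate "
                           f"is {den}")
    return SummaryMeasureResult("R", num / den, np.nan, np.nan, ref, comp,
                                dim.name, ind.name, survey_year)


def par(
    estimates: pd.DataFrame, dim: DimensionSpec, ind: IndicatorSpec | str,
    national=None, survey_year: int | None = None,
) -> SummaryMeasureResult:
    """Population Attributable Risk: reference subgroup minus national average.

    ``national`` may be a value, a SubgroupEstimate, or omitted when the
    estimates frame carries a ``national`` row.
    """
    ind = as_indicator(ind)
    mu = _national_value(estimates, national)
    ref, _ = select_reference(estimates, dim, ind)
    y_ref = _subgroup_values(estimates, dim)[ref]
    return SummaryMeasureResult("PAR", y_ref - mu, np.nan, np.nan, ref,
                                NATIONAL_LABEL, dim.name, ind.name, survey_year)


def paf(par_value: float, national: float) -> float:
    """Population Attributable Fraction: ``PAR / mu * 100``."""
    if national <= 0:
        raise MeasureError("PAF undefined: national average must be positive")
    return par_value / national * 100.0


def compute_measures(
    estimates: pd.DataFrame, dim: DimensionSpec, ind: IndicatorSpec | str,
    measures=MEASURES, national=None, survey_year: int | None = None,
    on_undefined: str = "raise",
) -> list[SummaryMeasureResult]:
    """All requested point measures from one disaggregation table.

    ``on_undefined="skip"`` drops (with a warning) measures that are
    undefined on these estimates — e.g. a ratio whose denominator subgroup
    sits at zero — instead of raising :class:`MeasureError`.
    """
    ind = as_indicator(ind)
    out: list[SummaryMeasureResult] = []
    par_res = None
    for m in measures:
        try:
            if m == "D":
                out.append(difference(estimates, dim, ind, survey_year))
            elif m == "R":
                out.append(ratio(estimates, dim, ind, survey_year))
            elif m in ("PAR", "PAF"):
                if par_res is None:
                    par_res = par(estimates, dim, ind, national, survey_year)
                if m == "PAR":
                    out.append(par_res)
                else:
                    mu = _national_value(estimates, national)
                    out.append(replace(par_res, measure="PAF",
                                       value=paf(par_res.value, mu)))
            else:
                raise ValueError(f"unknown measure {m!r}")
        except MeasureError:
            if on_undefined != "skip":
                raise
            warnings.warn(f"measure {m} undefined for {dim.name} "
                          f"({ind.name}); skipped", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# cluster bootstrap


def _cluster_sums(elig: pd.DataFrame, ycol: str, dim: DimensionSpec):
    """Per-PSU sums of w*y and w, split by subgroup level plus overall.

    Returns (Swy, Sw, stratum_of_cluster) with arrays shaped
    (n_clusters, n_levels + 1); the last column is the all-records total
    feeding the national average.
    """
    levels = list(dim.levels)
    col = elig[dim.name]
    cat = pd.Categorical(col, categories=levels)
    codes = np.asarray(cat.codes)  # -1 for missing/unknown
    wy = (elig["weight"] * elig[ycol]).to_numpy(float)
    w = elig["weight"].to_numpy(float)

    key = pd.MultiIndex.from_arrays(
        [elig["stratum_id"], elig["cluster_id"]])
    cluster_codes, cluster_index = pd.factorize(key, sort=True)
    n_c, n_l = len(cluster_index), len(levels)
    Swy = np.zeros((n_c, n_l + 1))
    Sw = np.zeros((n_c, n_l + 1))
    in_level = codes >= 0
    np.add.at(Swy, (cluster_codes[in_level], codes[in_level]), wy[in_level])
    np.add.at(Sw, (cluster_codes[in_level], codes[in_level]), w[in_level])
    np.add.at(Swy[:, n_l], cluster_codes, wy)
    np.add.at(Sw[:, n_l], cluster_codes, w)
    strata = np.asarray([k[0] for k in cluster_index])
    return Swy, Sw, strata


def _stratum_groups(strata: np.ndarray) -> list[np.ndarray]:
    """Cluster-index groups per stratum; single-PSU strata merge into the
    previous stratum in sorted order (the first merges forward), with a
    warning."""
    labels, inverse = np.unique(strata, return_inverse=True)
    groups = [np.flatnonzero(inverse == i) for i in range(len(labels))]
    merged: list[np.ndarray] = []
    pending: list[np.ndarray] = []
    n_single = 0
    for g in groups:
        if len(g) < 2:
            n_single += 1
            pending.append(g)
            continue
        if pending:
            g = np.concatenate(pending + [g])
            pending = []
        merged.append(g)
    if pending:
        if merged:
            merged[-1] = np.concatenate([merged[-1]] + pending)
        else:
            merged.append(np.concatenate(pending))
    if n_single:
        warnings.warn(f"{n_single} single-PSU stratum/strata merged with a "
                      "neighboring stratum for the bootstrap", stacklevel=3)
    return merged


def _measure_from_level_estimates(
    est: np.ndarray, mu: np.ndarray, measure: str, polarity: str,
    ref_i: int, comp_i: int,
) -> np.ndarray:
    """Vectorized measure arithmetic on bootstrap subgroup estimates."""
    y_ref, y_comp = est[:, ref_i], est[:, comp_i]
    if measure == "D":
        return y_ref - y_comp if polarity == "favorable" else y_comp - y_ref
    if measure == "R":
        num, den = ((y_ref, y_comp) if polarity == "favorable"
                    else (y_comp, y_ref))
        return np.where(den > 0, num / np.where(den > 0, den, np.nan), np.nan)
    if measure == "PAR":
        return y_ref - mu
    if measure == "PAF":
        return np.where(mu > 0, (y_ref - mu) / np.where(mu > 0, mu, np.nan)
                        * 100.0, np.nan)
    raise ValueError(f"unknown measure {measure!r}")


def bootstrap_measures(
    records: pd.DataFrame,
    indicator: IndicatorSpec | str,
    dimension: DimensionSpec,
    measures=MEASURES,
    B: int = 1000,
    seed: int = 0,
    *,
    window_years: int | None = None,
    denominator: str = "all_births",
    survey_year: int | None = None,
    on_undefined: str = "raise",
) -> list[SummaryMeasureResult]:
    """Point measures with percentile cluster-bootstrap 95% UIs.

    PSUs are resampled with replacement within strata, ``B`` times; the
    subgroup estimates, national average and measures are recomputed from
    the resampled PSU totals, and the 2.5/97.5 percentiles of each measure
    form its interval.  Deterministic given ``seed``.  Replicates in which a
    needed subgroup loses all its records are dropped from the percentiles
    (with a warning when any occur).
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    ind = as_indicator(indicator)
    elig, ycol = _eligible(records, ind, window_years, denominator)
    point = disaggregate(records, ind, dimension,
                         window_years=window_years, denominator=denominator)
    ref, comp = select_reference(point, dimension, ind)
    ref_i = dimension.levels.index(ref)
    comp_i = dimension.levels.index(comp)
    mu_point = _national_value(point, None)

    Swy, Sw, strata = _cluster_sums(elig, ycol, dimension)
    groups = _stratum_groups(strata)
    rng = np.random.default_rng(seed)
    k = ind.scale_factor

    boot_wy = np.zeros((B, Swy.shape[1]))
    boot_w = np.zeros((B, Sw.shape[1]))
    for g in groups:
        n_h = len(g)
        idx = rng.integers(0, n_h, size=(B, n_h))
        boot_wy += Swy[g][idx].sum(axis=1)
        boot_w += Sw[g][idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(boot_w > 0, boot_wy / np.where(boot_w > 0, boot_w, np.nan),
                       np.nan) * k
    mu = est[:, -1]

    point_measures = compute_measures(point, dimension, ind, measures,
                                      survey_year=survey_year,
                                      on_undefined=on_undefined)
    out = []
    n_bad_any = 0
    for res in point_measures:
        vals = _measure_from_level_estimates(
            est[:, :-1], mu, res.measure, ind.polarity, ref_i, comp_i)
        bad = ~np.isfinite(vals)
        n_bad_any = max(n_bad_any, int(bad.sum()))
        if bad.all():
            lo = hi = res.value
        else:
            lo, hi = np.nanpercentile(vals, [2.5, 97.5])
        # percentile intervals are widened, if needed, to contain the point
        lo, hi = min(float(lo), res.value), max(float(hi), res.value)
        out.append(replace(res, ui_low=lo, ui_high=hi))
    if n_bad_any:
        warnings.warn(f"{n_bad_any}/{B} bootstrap replicates dropped "
                      "(empty subgroup or zero denominator)", stacklevel=2)
    return out


def measure_uncertainty(
    records: pd.DataFrame,
    indicator: IndicatorSpec | str,
    dimension: DimensionSpec,
    measure: str,
    B: int = 1000,
    seed: int = 0,
    **kwargs,
) -> tuple[float, float]:
    """95% UI for one measure via the stratified cluster bootstrap."""
    res = bootstrap_measures(records, indicator, dimension, (measure,),
                             B=B, seed=seed, **kwargs)[0]
    return res.ui_low, res.ui_high


class InequalitySummary(BaseEstimator):
    """Compute D/R/PAR/PAF with bootstrap UIs from survey microdata.

    Parameters
    ----------
    indicator : IndicatorSpec or {"sba", "nmr"}, default "sba"
    dimension : DimensionSpec
    measures : tuple of str, default ("D", "R", "PAR", "PAF")
    bootstrap_reps : int, default 1000
        Cluster-bootstrap replicates for the uncertainty intervals.
    random_state : int, default 0
    window_years, denominator
        Passed through to the disaggregation (see
        :class:`~equimeasure.estimation.SurveyDisaggregator`).

    Attributes
    ----------
    results_ : DataFrame
        One row per measure: measure, value, ui_low, ui_high, reference,
        comparator, dimension, indicator.
    estimates_ : DataFrame
        The underlying disaggregation table.
    """

    def __init__(self, indicator="sba", dimension: DimensionSpec | None = None,
                 measures=MEASURES, bootstrap_reps: int = 1000,
                 random_state: int = 0, window_years: int | None = None,
                 denominator: str = "all_births"):
        self.indicator = indicator
        self.dimension = dimension
        self.measures = measures
        self.bootstrap_reps = bootstrap_reps
        self.random_state = random_state
        self.window_years = window_years
        self.denominator = denominator

    def fit(self, X: pd.DataFrame, y=None) -> "InequalitySummary":
        if self.dimension is None:
            raise ValueError("dimension must be provided")
        ind = as_indicator(self.indicator)
        self.estimates_ = disaggregate(
            X, ind, self.dimension, window_years=self.window_years,
            denominator=self.denominator)
        results = bootstrap_measures(
            X, ind, self.dimension, self.measures, B=self.bootstrap_reps,
            seed=self.random_state, window_years=self.window_years,
            denominator=self.denominator)
        self.results_ = pd.DataFrame(
            [{"dimension": r.dimension, "measure": r.measure,
              "value": r.value, "ui_low": r.ui_low, "ui_high": r.ui_high,
              "reference": r.reference_subgroup,
              "comparator": r.comparator_subgroup, "indicator": r.indicator}
             for r in results])
        return self
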