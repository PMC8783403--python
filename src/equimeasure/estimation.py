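"""Design-based estimation of disaggregated coverage and mortality rates.

Every table cell the pipeline reports is a weighted rate

    estimate = k * sum(w_i y_i) / sum(w_i),     k = 100 (percent) or 1000,

with a Taylor-linearized standard error that honors the two-stage design
(strata, primary sampling units).  Subgroup ("domain") estimates keep the
full PSU structure: records outside the domain contribute zero to the
linearized score but their clusters still count, which is the standard
complex-survey treatment of domains.

95% uncertainty intervals are symmetric on a transformed scale and
back-transformed: logit for proportions (percent indicators), log for
per-1000 rates.  Boundary estimates (0 or the scale maximum) fall back to
one-sided exact binomial (Clopper-Pearson) limits when the unweighted
denominator is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datamodel import (DimensionSpec, IndicatorSpec, as_indicator)
from .exceptions import EstimationError, SchemaError

__all__ = [
    "sba_eligible", "neonatal_death", "weighted_rate", "uncertainty_interval",
    "disaggregate", "SubgroupEstimate", "SurveyDisaggregator", "NATIONAL_LABEL",
]

#: Reserved subgroup label for the national (all-records) estimate.
NATIONAL_LABEL = "national"

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class SubgroupEstimate:
    """One disaggregated table cell: weighted estimate, SE, 95% UI, count."""

    dimension: str
    subgroup: str
    estimate: float
    se: float
    ui_low: float
    ui_high: float
    pop_n: int


# ---------------------------------------------------------------------------
# record-level predicates


def sba_eligible(records: pd.DataFrame, window_years: int) -> pd.Series:
    """True for births within ``window_years`` before the interview.

    The window is half-open in months: a birth is eligible iff
    ``interview_cmc - birth_cmc < 12 * window_years``, so a birth exactly
    ``12 * window_years`` months old falls outside.
    """
    age_months = records["interview_cmc"] - records["birth_cmc"]
    return (age_months < 12 * window_years) & (age_months >= 0)


def neonatal_death(records: pd.DataFrame) -> pd.Series:
    """1 for deaths in the first 28 completed days (ages 0-27), else 0.

    An absent age at death means the child was alive at 28 days.
    """
    aad = records["age_at_death_days"]
    return (aad.notna() & (aad < 28)).astype(np.int64)


# ---------------------------------------------------------------------------
# core estimator


def weighted_rate(
    records: pd.DataFrame,
    outcome,
    scale: str,
    *,
    domain=None,
    weight_col: str = "weight",
    stratum_col: str = "stratum_id",
    cluster_col: str = "cluster_id",
) -> tuple[float, float]:
    """Design-weighted rate and Taylor-linearized standard error.

    Parameters
    ----------
    records : DataFrame
        Microdata with weight and (optionally) stratum/PSU columns.
    outcome : column name or array-like of {0, 1}
        Per-record outcome.
    scale : {"percent", "per_1000"}
    domain : boolean array-like, optional
        Subgroup membership; when given, the rate is a domain mean but the
        variance uses the full stratum/PSU structure.

    Returns
    -------
    (estimate, se) on the requested scale.

    Raises
    ------
    EstimationError
        If no records (or no domain records / weight mass) are available.

    Notes
    -----
    Variance follows the with-replacement first-stage approximation used by
    the DHS programs: with ratio ``r = sum(w y) / sum(w)`` and linearized
    scores ``u_i = w_i (y_i - r)`` summed to PSU totals ``U_hc``,

        var(r) = sum_h  n_h / (n_h - 1) * sum_c (U_hc - mean_h)^2 / W^2.

    Strata with a single PSU contribute no variance (a warning is issued);
    without design columns each record is its own PSU in one stratum, which
    reduces to the usual weighted-SRS formula.
    """
    if len(records) == 0:
        raise EstimationError("cannot estimate a rate from an empty record set")
    y = (records[outcome] if isinstance(outcome, str) else pd.Series(
        np.asarray(outcome), index=records.index)).astype(float)
    w = records[weight_col].astype(float)
    if not np.all(w > 0):
        raise EstimationError("all weights must be positive")
    m = (pd.Series(np.asarray(domain, dtype=bool), index=records.index)
         if domain is not None else pd.Series(True, index=records.index))

    W = float((w * m).sum())
    if W <= 0:
        raise EstimationError("no weight mass in the requested domain")
    r = float((w * y * m).sum() / W)

    u = w * m * (y - r)
    if stratum_col in records.columns and cluster_col in records.columns:
        totals = u.groupby(
            [records[stratum_col], records[cluster_col]], observed=True).sum()
        var = 0.0
        single_psu = []
        for stratum, U in totals.groupby(level=0, observed=True):
            n_h = len(U)
            if n_h < 2:
                single_psu.append(stratum)
                continue
            var += n_h / (n_h - 1) * float(((U - U.mean()) ** 2).sum())
        if single_psu:
            warnings.warn(
                f"{len(single_psu)} stratum/strata with a single PSU "
                "contribute no variance", stacklevel=2)
    else:
        n = len(u)
        var = n / (n - 1) * float(((u - u.mean()) ** 2).sum()) if n > 1 else 0.0
    se = float(np.sqrt(var) / W)

    ind_scale = 100.0 if scale == "percent" else 1000.0
    if scale not in ("percent", "per_1000"):
        raise ValueError(f"unknown scale {scale!r}")
    return r * ind_scale, se * ind_scale


def uncertainty_interval(
    estimate: float, se: float, scale: str, n: int | None = None
) -> tuple[float, float]:
    """95% uncertainty interval for a rate, respecting its natural bounds.

    Proportions (percent scale) use a symmetric interval on the logit scale;
    per-1000 rates use the log scale.  Both are back-transformed, so the
    interval always stays within [0, scale maximum].  For estimates exactly
    at a boundary the transformed SE is undefined: with ``n`` given the
    one-sided exact binomial (Clopper-Pearson) limit is used, otherwise the
    interval degenerates to the point.
    """
    k = 100.0 if scale == "percent" else 1000.0
    if scale not in ("percent", "per_1000"):
        raise ValueError(f"unknown scale {scale!r}")
    if se < 0:
        raise ValueError("se must be non-negative")
    p = estimate / k
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"estimate {estimate} outside [0, {k}]")
    if se == 0.0:
        return estimate, estimate
    if p == 0.0 or p == 1.0:
        if n is None or n <= 0:
            warnings.warn("boundary estimate without a denominator: "
                          "degenerate interval", stacklevel=2)
            return estimate, estimate
        if p == 0.0:  # exact one-sided upper limit at x = 0
            hi = float(stats.beta.ppf(0.975, 1, n))
            return 0.0, hi * k
        lo = float(stats.beta.ppf(0.025, n, 1))  # x = n
        return lo * k, k

    se_p = se / k
    if scale == "percent":
        t = np.log(p / (1 - p))
        se_t = se_p / (p * (1 - p))
        lo_t, hi_t = t - _Z95 * se_t, t + _Z95 * se_t
        lo = 1.0 / (1.0 + np.exp(-lo_t))
        hi = 1.0 / (1.0 + np.exp(-hi_t))
    else:
        se_t = se_p / p
        lo = p * np.exp(-_Z95 * se_t)
        hi = min(p * np.exp(_Z95 * se_t), 1.0)
    return float(lo * k), float(hi * k)


# ---------------------------------------------------------------------------
# disaggregation


def _eligible(records: pd.DataFrame, ind: IndicatorSpec,
              window_years: int | None, denominator: str) -> tuple[pd.DataFrame, str]:
    """Apply the indicator's recall window and pick the outcome column."""
    window = window_years if window_years is not None else ind.recall_window_years
    mask = sba_eligible(records, window)  # same half-open month rule for both
    elig = records.loc[mask].copy()
    if ind.name == "nmr" or ind.scale == "per_1000":
        elig["_outcome"] = neonatal_death(elig)
    else:
        elig["_outcome"] = elig["sba"].astype(np.int64)
        if denominator == "last_birth":
            # most recent eligible birth per woman; ties keep the first row
            idx = (elig.sort_values("birth_cmc", kind="stable")
                   .groupby("woman_id", observed=True).tail(1).index)
            elig = elig.loc[elig.index.intersection(idx)]
        elif denominator != "all_births":
            raise ValueError(f"unknown denominator mode {denominator!r}")
    return elig, "_outcome"


def disaggregate(
    records: pd.DataFrame,
    indicator: IndicatorSpec | str,
    dimension: DimensionSpec,
    *,
    window_years: int | None = None,
    denominator: str = "all_births",
) -> pd.DataFrame:
    """Survey-weighted subgroup estimates plus the national average.

    Returns one row per declared subgroup level and a final row labelled
    ``national`` holding the average over *all* eligible records (not the
    mean of subgroup estimates).  Records with a missing or undeclared
    subgroup label are excluded from the subgroup rows (with a warning) but
    still enter the national average.  Levels with zero records yield a row
    with NaN estimate, flagged by a warning; downstream measures skip them.

    Columns: dimension, subgroup, estimate, se, ui_low, ui_high, pop_n.
    """
    ind = as_indicator(indicator)
    if dimension.name not in records.columns:
        raise SchemaError(f"dimension column {dimension.name!r} not in records")
    elig, ycol = _eligible(records, ind, window_years, denominator)
    if elig.empty:
        raise EstimationError("no records within the indicator's recall window")

    col = elig[dimension.name]
    n_excluded = int((col.isna() | ~col.isin(dimension.levels)).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} record(s) with missing/unknown {dimension.name!r} "
            "labels excluded from subgroup estimates", stacklevel=2)

    rows = []
    for level in dimension.levels:
        in_level = (col == level).fillna(False)
        pop_n = int(in_level.sum())
        if pop_n == 0:
            warnings.warn(f"no records for {dimension.name}={level!r}; "
                          "estimate flagged absent", stacklevel=2)
            rows.append((dimension.name, level, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        est, se = weighted_rate(elig, ycol, ind.scale, domain=in_level)
        lo, hi = uncertainty_interval(est, se, ind.scale, n=pop_n)
        rows.append((dimension.name, level, est, se, lo, hi, pop_n))

    est, se = weighted_rate(elig, ycol, ind.scale)
    lo, hi = uncertainty_interval(est, se, ind.scale, n=len(elig))
    rows.append((dimension.name, NATIONAL_LABEL, est, se, lo, hi, len(elig)))

    return pd.DataFrame(
        rows, columns=["dimension", "subgroup", "estimate", "se",
                       "ui_low", "ui_high", "pop_n"])


class SurveyDisaggregator(BaseEstimator):
    """Disaggregate a survey indicator across an equity stratifier.

    A fit-style estimator in the scikit-learn idiom: ``fit`` takes the
    birth-level microdata frame and exposes the disaggregation table as
    fitted attributes.

    Parameters
    ----------
    indicator : IndicatorSpec or {"sba", "nmr"}, default "sba"
    dimension : DimensionSpec
        Equity stratifier to disaggregate over.
    window_years : int, optional
        Override of the indicator's recall window (e.g. 2 instead of 3 for
        SBA).
    denominator : {"all_births", "last_birth"}, default "all_births"
        Whether every eligible birth or only the most recent birth per woman
        enters the SBA denominator.

    Attributes
    ----------
    estimates_ : DataFrame
        Subgroup rows plus the ``national`` row (see :func:`disaggregate`).
    national_ : SubgroupEstimate
        The national average row.
    zero_levels_ : list of str
        Declared levels observed with zero records.
    n_used_ : int
        Eligible records entering the national estimate.
    """

    def __init__(self, indicator="sba", dimension: DimensionSpec | None = None,
                 window_years: int | None = None, denominator: str = "all_births"):
        self.indicator = indicator
        self.dimension = dimension
        self.window_years = window_years
        self.denominator = denominator

    def fit(self, X: pd.DataFrame, y=None) -> "SurveyDisaggregator":
        if self.dimension is None:
            raise ValueError("dimension must be provided")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a microdata DataFrame")
        frame = disaggregate(
            X, self.indicator, self.dimension,
            window_years=self.window_years, denominator=self.denominator)
        self.estimates_ = frame
        nat = frame[frame["subgroup"] == NATIONAL_LABEL].iloc[0]
        self.national_ = SubgroupEstimate(
            nat["dimension"], NATIONAL_LABEL, float(nat["estimate"]),
            float(nat["se"]), float(nat["ui_low"]), float(nat["ui_high"]),
            int(nat["pop_n"]))
        sub = frame[frame["subgroup"] != NATIONAL_LABEL]
        self.zero_levels_ = sub.loc[sub["pop_n"] == 0, "subgroup"].tolist()
        self.n_used_ = int(nat["pop_n"])
        return self
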