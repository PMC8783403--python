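"""Over-time change classified by uncertainty-interval overlap.

Two surveys' estimates (or summary measures) are compared through their 95%
uncertainty intervals: disjoint intervals signal a real increase or decrease
(by the direction of the point values); any overlap — including exact
endpoint contact, intervals being treated as closed — is classified as a
constant pattern.  Because "small" and "large" overlaps deserve different
narrative weight but no numeric cutoff separates them, the fraction of the
shorter interval that is shared is reported alongside the verdict and left
uninterpreted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import SchemaCompatibilityError

__all__ = ["TrendResult", "classify_trend", "trend_table"]


@dataclass(frozen=True)
class TrendResult:
    """Classification of change in one quantity between two surveys."""

    quantity: str
    year_a: int | None
    year_b: int | None
    classification: str  # increased | decreased | constant
    overlap_fraction: float  # shared length / shorter interval length


def _check_interval(value: float, lo: float, hi: float, label: str) -> None:
    if not (lo <= hi):
        raise ValueError(f"{label}: reversed interval bounds ({lo} > {hi})")
    if not (lo <= value <= hi):
        raise ValueError(f"{label}: value {value} outside its interval "
                         f"[{lo}, {hi}]")


def classify_trend(
    a: tuple[float, float, float],
    b: tuple[float, float, float],
    *,
    quantity: str = "",
    year_a: int | None = None,
    year_b: int | None = None,
) -> TrendResult:
    """Classify the change from survey ``a`` to survey ``b``.

    Each argument is ``(value, ui_low, ui_high)``.  Disjoint closed
    intervals give ``increased`` when ``b``'s value exceeds ``a``'s, else
    ``decreased``; overlapping (or touching) intervals give ``constant``.

    The overlap fraction is the shared closed-interval length divided by the
    shorter interval's length (1.0 when a zero-width interval lies inside
    the other; exact endpoint contact gives 0.0 yet still counts as
    overlap).
    """
    va, lo_a, hi_a = (float(x) for x in a)
    vb, lo_b, hi_b = (float(x) for x in b)
    _check_interval(va, lo_a, hi_a, "a")
    _check_interval(vb, lo_b, hi_b, "b")

    shared = min(hi_a, hi_b) - max(lo_a, lo_b)
    overlap = shared >= 0.0  # closed intervals: touching endpoints overlap
    shorter = min(hi_a - lo_a, hi_b - lo_b)
    if not overlap:
        frac = 0.0
    elif shorter == 0.0:
        frac = 1.0  # a point inside (or on the edge of) the other interval
    else:
        frac = max(shared, 0.0) / shorter

    if overlap:
        cls = "constant"
    else:
        cls = "increased" if vb > va else "decreased"
    return TrendResult(quantity, year_a, year_b, cls, frac)


def trend_table(
    by_year: dict[int, pd.DataFrame],
    value_col: str = "value",
    key_cols: Sequence[str] = ("dimension", "measure"),
    levels_by_year: dict[int, Iterable[str]] | None = None,
    pairs: Iterable[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Classify trends for every quantity across pairs of surveys.

    Parameters
    ----------
    by_year : dict
        Survey year -> frame with ``key_cols``, ``value_col``, ``ui_low``,
        ``ui_high``.
    levels_by_year : dict, optional
        Subgroup schema (e.g. region levels) per survey; a pair of surveys
        with different schemas is refused with
        :class:`SchemaCompatibilityError`, since their quantities are not
        comparable (Guinea's 1999 survey used 5 regions, later ones 8).
    pairs : iterable of (year_a, year_b), optional
        Defaults to all ordered pairs of available years.

    Returns
    -------
    DataFrame with key columns, both years and values, classification and
    overlap fraction.
    """
    years = sorted(by_year)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(years) for b in years[i + 1:]]
    rows = []
    for ya, yb in pairs:
        if levels_by_year is not None:
            la = set(levels_by_year.get(ya, ()))
            lb = set(levels_by_year.get(yb, ()))
            if la != lb:
                raise SchemaCompatibilityError(
                    f"surveys {ya} and {yb} use incompatible subgroup "
                    f"schemas ({sorted(la)} vs {sorted(lb)}); their "
                    "quantities are not comparable")
        fa, fb = by_year[ya], by_year[yb]
        merged = fa.merge(fb, on=list(key_cols), suffixes=("_a", "_b"))
        for _, row in merged.iterrows():
            res = classify_trend(
                (row[f"{value_col}_a"], row["ui_low_a"], row["ui_high_a"]),
                (row[f"{value_col}_b"], row["ui_low_b"], row["ui_high_b"]),
                quantity=" ".join(str(row[k]) for k in key_cols),
                year_a=ya, year_b=yb)
            rows.append({**{k: row[k] for k in key_cols},
                         "year_a": ya, "year_b": yb,
                         "value_a": row[f"{value_col}_a"],
                         "value_b": row[f"{value_col}_b"],
                         "classification": res.classification,
                         "overlap_fraction": res.overlap_fraction})
    return pd.DataFrame(rows)
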