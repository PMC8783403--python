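"""Shared fixtures: small deterministic microdata frames and helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from equimeasure.datamodel import CANONICAL_COLUMNS, cmc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_microdata(
    n: int = 20,
    *,
    weights=None,
    sba=None,
    age_at_death=None,
    n_clusters: int = 4,
    n_strata: int = 2,
    survey_year: int = 2012,
    seed: int = 0,
    **columns,
) -> pd.DataFrame:
    """A small canonical microdata frame with controllable columns."""
    rng = np.random.default_rng(seed)
    interview = cmc(survey_year, 6)
    df = pd.DataFrame({
        "survey_year": survey_year,
        "stratum_id": [f"s{i % n_strata}" for i in range(n)],
        "cluster_id": [f"c{i % n_clusters}" for i in range(n)],
        "household_id": [f"h{i}" for i in range(n)],
        "woman_id": [f"w{i}" for i in range(n)],
        "weight": np.ones(n) if weights is None else np.asarray(weights, float),
        "region": "Conakry",
        "residence": np.where(np.arange(n) % 2 == 0, "urban", "rural"),
        "education": [["none", "primary", "secondary+"][i % 3] for i in range(n)],
        "wealth_quintile": [f"Q{i % 5 + 1}" for i in range(n)],
        "birth_cmc": interview - rng.integers(0, 60, size=n),
        "interview_cmc": interview,
        "sba": (rng.integers(0, 2, size=n) if sba is None
                else np.asarray(sba, dtype=np.int64)),
        "child_sex": np.where(np.arange(n) % 2 == 0, "male", "female"),
        "age_at_death_days": pd.array(
            [pd.NA] * n if age_at_death is None else age_at_death,
            dtype="Int64"),
    })
    for name, value in columns.items():
        df[name] = value
    return df[list(CANONICAL_COLUMNS)]


def estimates_frame(dimension: str, values: dict[str, float],
                    national: float | None = None) -> pd.DataFrame:
    """Build a disaggregation-shaped frame from subgroup values."""
    rows = [{"dimension": dimension, "subgroup": k, "estimate": v,
             "se": 0.0, "ui_low": v, "ui_high": v, "pop_n": 100}
            for k, v in values.items()]
    if national is not None:
        rows.append({"dimension": dimension, "subgroup": "national",
                     "estimate": national, "se": 0.0, "ui_low": national,
                     "ui_high": national, "pop_n": 100 * len(values)})
    return pd.DataFrame(rows)


@pytest.fixture
def microdata():
    return make_microdata(40, seed=7)


@pytest.fixture
def small_population():
    """A modest synthetic population shared by sampling/estimation tests."""
    from equimeasure.synthetic import generate_population, guinea_like_population
    cfg = guinea_like_population(n_women=6000)
    return generate_population(cfg, seed=42)
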