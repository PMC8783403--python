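"""Synthetic DHS/MICS-like populations and two-stage survey samples.

The generator builds a household population with the statistical structure
the analysis assumes — regions split into urban/rural enumeration areas
(clusters), one woman aged 15-49 per household, education depending on
residence, a latent-wealth asset battery scored into PCA quintiles — and
attaches a five-year birth history to each woman.  Every birth carries its
true skilled-birth-attendance probability and neonatal-death probability, so
subgroup truth is known exactly and estimator recovery can be tested.

Survey samples mimic the DHS design: stratification by region x residence,
stage one a probability-proportional-to-size (PPS) systematic draw of
clusters within strata, stage two a systematic draw of 28-30 households per
selected cluster; design weights are inverse overall inclusion
probabilities.

Deliberate simplifications (documented in the methods note): full response,
one eligible woman per household, births dated uniformly over the recall
window with a Poisson count per woman, neonatal death ages uniform on 0-27
days, and assets independent of the other stratifiers so that population
wealth quintiles have exact 20% shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datamodel import (CANONICAL_COLUMNS, EDUCATION_LEVELS,
                        RESIDENCE_LEVELS, SEX_LEVELS, WEALTH_LEVELS,
                        DimensionSpec, IndicatorSpec, as_indicator, cmc)
from .exceptions import (ConfigurationError, DegenerateInputError,
                         EmptyInputError)

__all__ = [
    "RegionConfig", "ProbabilityMap", "PopulationConfig", "SampleDesignConfig",
    "Population", "generate_population", "compute_wealth_index",
    "draw_survey_sample", "true_summary_measures", "measures_from_values",
    "guinea_like_population",
]


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class RegionConfig:
    """One subnational region: population share and urban fraction."""

    name: str
    share: float
    urban_share: float

    def __post_init__(self):
        if not 0 < self.share <= 1 or not 0 <= self.urban_share <= 1:
            raise ConfigurationError(f"invalid region shares for {self.name}")


@dataclass(frozen=True)
class ProbabilityMap:
    """Subgroup-specific outcome probability.

    ``base`` is the probability when no effects apply.  ``by`` maps
    stratifier column names to level -> probability tables.  With a single
    stratifier the probability is looked up directly; with several, the
    level-specific deviations from ``base`` are combined additively on the
    logit scale, which keeps every combination inside (0, 1).
    """

    base: float = 0.5
    by: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        probs = [self.base] + [p for t in self.by.values() for p in t.values()]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")

    def lookup(self, cells: pd.DataFrame) -> np.ndarray:
        """Vectorized probability per row of ``cells``."""
        if not self.by:
            return np.full(len(cells), float(self.base))
        if len(self.by) == 1:
            (dim, table), = self.by.items()
            if dim not in cells.columns:
                raise ConfigurationError(f"probability keyed on missing "
                                         f"column {dim!r}")
            try:
                return cells[dim].map(dict(table)).to_numpy(float)
            except TypeError:  # non-mappable values
                raise ConfigurationError(f"unmapped level in {dim!r}")
        if not 0.0 < self.base < 1.0:
            raise ConfigurationError(
                "combining several stratifier effects needs 0 < base < 1")
        x = np.full(len(cells), _logit(self.base))
        for dim, table in self.by.items():
            p = cells[dim].map(dict(table)).to_numpy(float)
            if np.isnan(p).any():
                raise ConfigurationError(f"missing probability for some "
                                         f"level of {dim!r}")
            p = np.clip(p, 1e-9, 1 - 1e-9)
            x += _logit(p) - _logit(self.base)
        return _expit(x)

    def level_probability(self, dim: str, level: str) -> float:
        """Marginal probability for one level, other effects at base."""
        cells = pd.DataFrame({dim: [level]})
        for other in self.by:
            if other != dim:
                cells[other] = None
        if len(self.by) <= 1:
            return float(self.lookup(cells)[0]) if dim in self.by else self.base
        x = _logit(self.base)
        table = self.by.get(dim)
        if table and level in table:
            p = np.clip(table[level], 1e-9, 1 - 1e-9)
            x += _logit(p) - _logit(self.base)
        return float(_expit(x))


@dataclass(frozen=True)
class PopulationConfig:
    """Ground-truth description of the simulated population.

    ``n_women`` is the target number of women (= households; one eligible
    woman per household); the realized count varies slightly because cluster
    sizes are Poisson.  ``births_per_woman`` is the Poisson mean number of
    live births per woman over the five-year recall window.
    """

    regions: tuple[RegionConfig, ...]
    education_dist: Mapping[str, Sequence[float]]  # residence -> P over 3 levels
    sba_prob: ProbabilityMap
    nmr_prob: ProbabilityMap
    n_women: int = 10_000
    births_per_woman: float = 1.0
    survey_year: int = 2012
    mean_cluster_size: float = 120.0  # households per enumeration area
    n_binary_assets: int = 7
    n_continuous_assets: int = 2
    asset_noise_sd: float = 0.8

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        total = sum(r.share for r in self.regions)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"region shares sum to {total}, not 1")
        for res, dist in self.education_dist.items():
            if res not in RESIDENCE_LEVELS:
                raise ConfigurationError(f"unknown residence {res!r}")
            if len(dist) != len(EDUCATION_LEVELS) or abs(sum(dist) - 1) > 1e-9:
                raise ConfigurationError(
                    f"education distribution for {res!r} must be 3 "
                    "probabilities summing to 1")
        if self.births_per_woman <= 0:
            raise ConfigurationError("births_per_woman must be positive")
        if self.n_binary_assets + self.n_continuous_assets < 2:
            raise ConfigurationError("need at least 2 asset variables")

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)


@dataclass(frozen=True)
class SampleDesignConfig:
    """Two-stage sample design: PPS clusters, then 28-30 households each."""

    n_clusters: int
    households_per_cluster: tuple[int, int] = (28, 30)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.households_per_cluster
        if not (28 <= lo <= hi <= 30):
            raise ConfigurationError(
                "households_per_cluster must lie within [28, 30]")
        if self.n_clusters <= 0:
            raise ConfigurationError("n_clusters must be positive")


@dataclass
class Population:
    """A generated population: households, births, clusters, and truth."""

    config: PopulationConfig
    households: pd.DataFrame
    births: pd.DataFrame
    clusters: pd.DataFrame  # cluster_id, stratum_id, region, residence, n_households
    ground_truth: pd.DataFrame  # indicator, dimension, subgroup, true_value

    @property
    def n_births(self) -> int:
        return len(self.births)

    def _household_rows(self) -> dict:
        """Cluster -> household row positions (sorted by household id),
        cached because repeated sample draws reuse it."""
        cache = getattr(self, "_hh_rows_cache", None)
        if cache is None:
            ordered = self.households.sort_values(
                ["cluster_id", "household_id"], kind="stable")
            cache = {cid: pos.to_numpy() if hasattr(pos, "to_numpy") else pos
                     for cid, pos in ordered.groupby(
                         "cluster_id", observed=True).indices.items()}
            # indices are positions into `ordered`; store the ordered frame too
            object.__setattr__(self, "_hh_rows_cache", cache)
            object.__setattr__(self, "_hh_ordered", ordered.reset_index(drop=True))
        return cache


# ---------------------------------------------------------------------------
# wealth index


def compute_wealth_index(
    assets: pd.DataFrame | np.ndarray, weights=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Asset-based wealth score (first principal component) and quintiles.

    Columns are standardized internally, so the component is that of the
    asset correlation matrix (DHS practice).  The score's sign is fixed so
    the summed loadings are positive — more assets means wealthier.
    Quintiles are weighted fifths of the score distribution, Q1 poorest.

    Returns ``(scores, quintile_labels, loadings)``; excluded constant
    columns carry zero loading.

    Raises
    ------
    DegenerateInputError
        If fewer than 2 non-constant asset columns remain.
    """
    X = np.asarray(assets, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 5:
        raise DegenerateInputError("need >= 5 households and >= 2 asset columns")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if keep.sum() < X.shape[1]:
        warnings.warn(f"{int((~keep).sum())} constant asset column(s) "
                      "excluded from the wealth index", stacklevel=2)
    if keep.sum() < 2:
        raise DegenerateInputError("fewer than 2 non-constant asset columns")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(Z)[:, 0]
    load = pca.components_[0]
    if load.sum() < 0 or (load.sum() == 0 and load[np.nonzero(load)[0][0]] < 0):
        scores, load = -scores, -load
    loadings = np.zeros(X.shape[1])
    loadings[keep] = load

    w = (np.ones(len(scores)) if weights is None
         else np.asarray(weights, dtype=float))
    order = np.argsort(scores, kind="stable")
    cw = np.cumsum(w[order])
    mid = (cw - 0.5 * w[order]) / cw[-1]  # weighted CDF at interval midpoints
    q_sorted = np.minimum((mid * 5).astype(int), 4)
    quintiles = np.empty(len(scores), dtype=object)
    quintiles[order] = np.asarray(WEALTH_LEVELS, dtype=object)[q_sorted]
    return scores, quintiles.astype(str), loadings


# ---------------------------------------------------------------------------
# population generation


def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``shares``."""
    shares = np.asarray(shares, dtype=float)
    raw = total * shares / shares.sum()
    alloc = np.floor(raw).astype(int)
    rem = total - alloc.sum()
    if rem > 0:
        order = np.argsort(-(raw - alloc), kind="stable")
        alloc[order[:rem]] += 1
    return alloc


def generate_population(config: PopulationConfig, seed: int) -> Population:
    """Generate a household population with birth histories and known truth.

    Deterministic given ``(config, seed)``.  The ground-truth table holds,
    for each standard stratifier level and nationally, the mean assigned SBA
    probability (x100) and neonatal-death probability (x1000) over the
    generated births — the exact values a census of this population would
    show in expectation.
    """
    if config.n_women <= 0:
        raise EmptyInputError("n_women must be positive")
    rng = np.random.default_rng(seed)

    # --- clusters: region x residence strata
    n_clusters = max(len(config.regions), int(round(
        config.n_women / config.mean_cluster_size)))
    per_region = _largest_remainder(
        n_clusters, np.array([r.share for r in config.regions]))
    regions, residences = [], []
    for r, n_r in zip(config.regions, per_region):
        n_urban = int(round(r.urban_share * n_r))
        regions += [r.name] * n_r
        residences += ["urban"] * n_urban + ["rural"] * (n_r - n_urban)
    clusters = pd.DataFrame({
        "cluster_id": [f"c{i:05d}" for i in range(len(regions))],
        "region": regions, "residence": residences})
    clusters["stratum_id"] = clusters["region"] + "/" + clusters["residence"]
    sizes = rng.poisson(config.mean_cluster_size, len(clusters))
    clusters["n_households"] = np.maximum(sizes, 5)

    # --- households (one eligible woman each)
    hh = clusters.loc[clusters.index.repeat(clusters["n_households"]),
                      ["cluster_id", "stratum_id", "region", "residence"]
                      ].reset_index(drop=True)
    n_hh = len(hh)
    hh["household_id"] = [f"h{i:06d}" for i in range(n_hh)]
    hh["woman_id"] = [f"w{i:06d}" for i in range(n_hh)]
    edu = np.empty(n_hh, dtype=object)
    for res in RESIDENCE_LEVELS:
        m = (hh["residence"] == res).to_numpy()
        edu[m] = rng.choice(EDUCATION_LEVELS, size=int(m.sum()),
                            p=list(config.education_dist[res]))
    hh["education"] = edu

    # --- assets and wealth quintiles (independent of other stratifiers)
    z = rng.normal(size=n_hh)
    cols = []
    for j in range(config.n_binary_assets):
        alpha = -1.0 + 2.0 * j / max(config.n_binary_assets - 1, 1)
        lam = 0.8 + 0.1 * (j % 5)
        cols.append((rng.random(n_hh) < _expit(alpha + lam * z)).astype(float))
    for j in range(config.n_continuous_assets):
        cols.append(1.1 * z + rng.normal(scale=config.asset_noise_sd, size=n_hh))
    assets = np.column_stack(cols)
    scores, quintiles, _ = compute_wealth_index(assets)
    hh["wealth_score"] = scores
    hh["wealth_quintile"] = quintiles

    # --- birth histories over the 5-year recall window
    interview = cmc(config.survey_year, 6)
    n_births = rng.poisson(config.births_per_woman, n_hh)
    births = hh.loc[hh.index.repeat(n_births)].reset_index(drop=True)
    nb = len(births)
    births["survey_year"] = config.survey_year
    births["interview_cmc"] = interview
    births["birth_cmc"] = interview - rng.integers(0, 60, size=nb)
    births["child_sex"] = np.asarray(SEX_LEVELS, dtype=object)[
        rng.integers(0, 2, size=nb)]
    births["weight"] = 1.0  # census weight; survey weights come from sampling

    p_sba = config.sba_prob.lookup(births)
    p_death = config.nmr_prob.lookup(births)
    if np.isnan(p_sba).any() or np.isnan(p_death).any():
        raise ConfigurationError("outcome probability undefined for some "
                                 "generated subgroup")
    births["sba"] = (rng.random(nb) < p_sba).astype(np.int64)
    died = rng.random(nb) < p_death
    aad = np.where(died, rng.integers(0, 28, size=nb), -1)
    births["age_at_death_days"] = pd.array(
        np.where(died, aad, np.nan), dtype="Int64")
    births["true_p_sba"] = p_sba
    births["true_p_death"] = p_death

    truth = _ground_truth(births)
    cols_order = [c for c in CANONICAL_COLUMNS] + ["true_p_sba", "true_p_death"]
    return Population(config, hh, births[cols_order], clusters, truth)


_TRUTH_DIMS = ("wealth_quintile", "education", "residence", "region", "child_sex")


def _ground_truth(births: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for ind, col, k in (("sba", "true_p_sba", 100.0),
                        ("nmr", "true_p_death", 1000.0)):
        for dim in _TRUTH_DIMS:
            for level, g in births.groupby(dim, observed=True):
                rows.append((ind, dim, str(level), float(g[col].mean() * k),
                             len(g)))
        rows.append((ind, "national", "national",
                     float(births[col].mean() * k), len(births)))
    return pd.DataFrame(rows, columns=["indicator", "dimension", "subgroup",
                                       "true_value", "n_births"])


# ---------------------------------------------------------------------------
# two-stage sampling


def pps_inclusion_probabilities(sizes: np.ndarray, n: int) -> np.ndarray:
    """First-stage inclusion probabilities of a systematic PPS draw
    (``n * size / total``, capped at 1 for certainty clusters)."""
    sizes = np.asarray(sizes, dtype=float)
    return np.minimum(n * sizes / sizes.sum(), 1.0)


def _pps_systematic(sizes: np.ndarray, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Systematic PPS draw of ``n`` of ``len(sizes)`` units.

    Returns (selected indices, first-stage inclusion probabilities for the
    selected units).  Units whose size exceeds the sampling interval are
    taken with certainty and the rest re-drawn, as in standard practice.
    """
    sizes = np.asarray(sizes, dtype=float)
    idx = np.arange(len(sizes))
    certain: list[int] = []
    while n > 0 and len(idx) > 0:
        tot = sizes[idx].sum()
        big = idx[n * sizes[idx] / tot >= 1.0]
        if len(big) == 0:
            break
        certain += list(big)
        idx = np.setdiff1d(idx, big)
        n -= len(big)
    if n == 0 or len(idx) == 0:
        sel = np.array(certain, dtype=int)
        return sel, np.ones(len(sel))
    tot = sizes[idx].sum()
    interval = tot / n
    start = rng.uniform(0, interval)
    points = start + interval * np.arange(n)
    cum = np.cumsum(sizes[idx])
    picks = idx[np.searchsorted(cum, points, side="right")]
    sel = np.concatenate([np.array(certain, dtype=int), picks])
    pi_sel = np.concatenate([np.ones(len(certain)),
                             n * sizes[picks] / tot])
    return sel, pi_sel


def draw_survey_sample(population: Population, design: SampleDesignConfig
                       ) -> pd.DataFrame:
    """Draw a stratified two-stage cluster sample from a population.

    Stage 1 allocates ``design.n_clusters`` across region x residence strata
    proportionally to household counts (largest remainder) and draws
    clusters within each stratum by systematic PPS on household counts.
    Stage 2 draws 28-30 households per selected cluster systematically;
    clusters smaller than the take are kept whole with an adjusted weight
    (and a warning).  The design weight of every birth is the inverse
    overall inclusion probability of its household.  Deterministic given
    ``design.seed``.
    """
    clusters = population.clusters
    if len(clusters) < design.n_clusters:
        raise ConfigurationError(
            f"population has {len(clusters)} clusters, fewer than the "
            f"{design.n_clusters} requested")
    rng = np.random.default_rng(design.seed)

    strata = clusters.groupby("stratum_id", observed=True)["n_households"].sum()
    alloc = _largest_remainder(design.n_clusters, strata.to_numpy())
    # every stratum with an allocation must have that many clusters
    sel_rows = []
    small = 0
    lo, hi = design.households_per_cluster
    for (stratum, tot_hh), n_h in zip(strata.items(), alloc):
        grp = clusters[clusters["stratum_id"] == stratum].sort_values(
            "cluster_id", kind="stable")
        n_h = min(n_h, len(grp))
        if n_h == 0:
            continue
        sel, pi1 = _pps_systematic(grp["n_households"].to_numpy(), n_h, rng)
        for i, p1 in zip(sel, pi1):
            row = grp.iloc[i]
            m = int(rng.integers(lo, hi + 1))
            M = int(row["n_households"])
            if M <= m:
                m_eff, pi2 = M, 1.0
                small += 1
            else:
                m_eff, pi2 = m, m / M
            sel_rows.append((row["cluster_id"], p1, pi2, m_eff))
    if small:
        warnings.warn(f"{small} cluster(s) smaller than the household take; "
                      "kept whole with adjusted weight", stacklevel=2)

    rows_by_cluster = population._household_rows()
    hh_ordered = population._hh_ordered
    hh_ids = hh_ordered["household_id"].to_numpy()
    take_ids, take_w = [], []
    for cluster_id, p1, pi2, m_eff in sel_rows:
        pos = np.sort(np.asarray(rows_by_cluster[cluster_id]))
        M = len(pos)
        if m_eff < M:  # systematic draw of m_eff of M households
            interval = M / m_eff
            start = rng.uniform(0, interval)
            sel2 = np.minimum((start + interval * np.arange(m_eff)).astype(int),
                              M - 1)
            pos = pos[sel2]
        take_ids.append(hh_ids[pos])
        take_w.append(np.full(len(pos), 1.0 / (p1 * pi2)))
    selected = pd.DataFrame({
        "household_id": np.concatenate(take_ids),
        "weight": np.concatenate(take_w)})

    births = population.births.drop(columns=["weight"]).merge(
        selected, on="household_id", how="inner")
    return births[[c for c in CANONICAL_COLUMNS] +
                  ["true_p_sba", "true_p_death"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# design-truth summary measures (oracle for recovery tests)


def measures_from_values(
    values: Mapping[str, float], shares: Mapping[str, float],
    dim: DimensionSpec, ind: IndicatorSpec | str,
) -> dict[str, float]:
    """Apply the summary-measure arithmetic to known subgroup values.

    ``values`` are subgroup outcomes on the indicator scale, ``shares`` the
    population shares (summing to 1); the national average is the
    share-weighted mean.  Returns D, R, PAR, PAF and the national average.
    """
    ind = as_indicator(ind)
    mu = sum(shares[l] * values[l] for l in values)
    if dim.kind in ("ordered", "binary"):
        ref, comp = dim.advantaged_level, dim.disadvantaged_level
    else:
        order = sorted(values, key=values.__getitem__)
        lo_l, hi_l = order[0], order[-1]
        ref, comp = (hi_l, lo_l) if ind.polarity == "favorable" else (lo_l, hi_l)
    y_ref, y_comp = values[ref], values[comp]
    if ind.polarity == "favorable":
        d, r = y_ref - y_comp, (y_ref / y_comp if y_comp > 0 else np.nan)
    else:
        d, r = y_comp - y_ref, (y_comp / y_ref if y_ref > 0 else np.nan)
    par = y_ref - mu
    paf = par / mu * 100.0 if mu > 0 else np.nan
    return {"D": d, "R": r, "PAR": par, "PAF": paf, "national": mu,
            "reference": ref, "comparator": comp}


def true_summary_measures(
    config: PopulationConfig, dim: DimensionSpec, ind: IndicatorSpec | str
) -> dict[str, float]:
    """D/R/PAR/PAF implied by the configured true probabilities.

    Enumerates the joint region x residence x education x wealth x sex cells
    of the design (wealth quintiles independent with 20% shares, sex 50/50),
    averages the configured outcome probability within each level of ``dim``,
    and applies the measure arithmetic with the share-weighted national
    average.  This is the design truth that large-sample estimates should
    recover.
    """
    ind = as_indicator(ind)
    prob_map = config.sba_prob if ind.name == "sba" else config.nmr_prob
    cells = []
    for r in config.regions:
        for res, res_share in (("urban", r.urban_share),
                               ("rural", 1 - r.urban_share)):
            edu_dist = config.education_dist[res]
            for e, pe in zip(EDUCATION_LEVELS, edu_dist):
                for q in WEALTH_LEVELS:
                    for s in SEX_LEVELS:
                        share = r.share * res_share * pe * 0.2 * 0.5
                        cells.append((r.name, res, e, q, s, share))
    frame = pd.DataFrame(cells, columns=["region", "residence", "education",
                                         "wealth_quintile", "child_sex",
                                         "share"])
    frame["p"] = prob_map.lookup(frame)
    if frame["p"].isna().any():
        raise ConfigurationError(
            "outcome probability not configured for some subgroup cell")
    if dim.name not in frame.columns:
        raise ConfigurationError(f"unknown dimension {dim.name!r}")
    grouped = frame.groupby(dim.name, observed=True).apply(
        lambda g: np.average(g["p"], weights=g["share"]), include_groups=False)
    missing = [l for l in dim.levels if l not in grouped.index]
    if missing:
        raise ConfigurationError(
            f"no configured probability mass for level(s) {missing}")
    shares = frame.groupby(dim.name, observed=True)["share"].sum()
    values = {l: float(grouped[l]) * ind.scale_factor for l in dim.levels}
    level_shares = {l: float(shares[l]) for l in dim.levels}
    return measures_from_values(values, level_shares, dim, ind)


# ---------------------------------------------------------------------------
# a plausible West-African default configuration


def guinea_like_population(
    survey_year: int = 2012, n_women: int = 10_000, **overrides
) -> PopulationConfig:
    """A population patterned on Guinea around the 2012 survey.

    Eight regions with a strongly urban capital, ~30% urban population
    overall, education rare outside cities, SBA coverage rising steeply with
    household wealth (national level near 45%), and neonatal mortality near
    40 per 1000 with a male excess.  Values are round numbers chosen to sit
    inside the published subgroup ranges, not estimates of them.
    """
    regions = (
        RegionConfig("Boke", 0.11, 0.25),
        RegionConfig("Conakry", 0.16, 1.00),
        RegionConfig("Faranah", 0.09, 0.20),
        RegionConfig("Kankan", 0.17, 0.22),
        RegionConfig("Kindia", 0.14, 0.25),
        RegionConfig("Labe", 0.10, 0.18),
        RegionConfig("Mamou", 0.08, 0.18),
        RegionConfig("Nzerekore", 0.15, 0.25),
    )
    cfg = dict(
        regions=regions,
        education_dist={"urban": (0.55, 0.20, 0.25),
                        "rural": (0.85, 0.10, 0.05)},
        sba_prob=ProbabilityMap(base=0.45, by={
            "wealth_quintile": {"Q1": 0.18, "Q2": 0.28, "Q3": 0.40,
                                "Q4": 0.65, "Q5": 0.90}}),
        nmr_prob=ProbabilityMap(base=0.040, by={
            "child_sex": {"male": 0.046, "female": 0.034}}),
        n_women=n_women,
        births_per_woman=1.0,
        survey_year=survey_year,
    )
    cfg.update(overrides)
    return PopulationConfig(**cfg)
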