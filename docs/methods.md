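# Methods

## Data model

The unit of analysis is the live birth. Each record carries the mother's
survey-design variables (stratum, primary sampling unit/cluster, household,
design weight), her equity stratifiers (wealth quintile, education,
residence, region), the birth date and interview date as DHS century-month
codes (`cmc = (year − 1900)·12 + month`, month 1–12), a binary
skilled-birth-attendance flag, the neonate's sex, and the age at death in
days (absent = alive at 28 days). Hard invariants (positive weight, birth
not after interview, SBA ∈ {0, 1}, non-negative age at death) are enforced
at read time; violating rows are dropped and counted. Missing stratifier
*values* are retained and excluded only from analyses of that stratifier,
because denominators legitimately differ by dimension.

Stratifiers come in three kinds. *Ordered* dimensions (wealth, education)
declare their levels worst-off → best-off with the advantaged level last;
*binary* dimensions (residence, neonate sex) declare the advantaged level
explicitly (urban; female, the lower-risk sex); *non-ordered* dimensions
(region) declare no advantage — the best-off region is found from the data.
Guinea's 1999 survey used five subnational domains and later surveys eight,
so the region dimension is year-specific.

Indicators carry a polarity and scale: SBA is favorable on the percent
scale with a default 3-year recall window (configurable to 2 — survey
programs use both); NMR is adverse, per 1000 live births, over births in
the 5 years preceding the interview. Neonatal death means age at death
strictly below 28 days ("first 28 completed days" read as days 0–27). The
recall window is half-open in months: a birth exactly `12·w` months before
the interview falls outside a `w`-year window. The SBA denominator defaults
to all eligible births (matching birth-level outcome coding) and can be
restricted to each woman's most recent birth.

## Estimation

Every reported cell is the ratio estimator
`r = Σ wᵢyᵢ / Σ wᵢ` on the indicator scale (×100 or ×1000). Variance uses
Taylor linearization with the with-replacement first-stage approximation
standard for DHS-type designs: linearized scores `uᵢ = wᵢ(yᵢ − r)` are
summed to PSU totals and the between-PSU variance is accumulated within
strata with the `n_h/(n_h − 1)` factor. Subgroup (domain) estimates keep
all PSUs in the variance computation, with records outside the domain
contributing zero score. Strata with a single PSU contribute no variance
(with a warning); without design columns each record is its own PSU, which
reduces to the weighted-SRS formula. Estimates and SEs are invariant to
rescaling all weights.

95% uncertainty intervals for rates are symmetric on a transformed scale —
logit for proportions, log for per-1000 rates — and back-transformed, so
they respect the natural bounds. Boundary estimates (0 or the maximum) fall
back to one-sided exact binomial (Clopper–Pearson) limits when the
unweighted denominator is known. The normal 0.975 quantile is used
throughout; a design-df t quantile would widen small-survey intervals
slightly but the survey sizes of interest (hundreds of PSUs) make the
difference negligible.

The national average μ is the weighted rate over *all* eligible records,
not the mean of subgroup estimates, so records with missing stratifier
labels still inform it.

## Summary measures

Definitions and reference rules are in the README. Implementation choices:

* For ordered/binary dimensions the reference is the *declared* advantaged
  level even if it is not empirically best — the fixed
  richest/secondary+/urban/female rule — while non-ordered dimensions use
  the empirical extreme with ties broken by declared order (and logged).
* PAF = PAR/μ·100 holds as an exact identity because PAF is computed from
  the PAR value, never re-derived.
* Negative PAR/PAF values for adverse indicators are reported as such;
  polarity handles signs, nothing is clamped.
* Values are computed at full precision; rounding (1 decimal, 2 for ratios
  when wanted) is left to presentation.

Uncertainty intervals for the measures come from a stratified cluster
bootstrap: PSUs are resampled with replacement within strata (single-PSU
strata are merged with a neighboring stratum, with a warning), subgroup and
national totals are rebuilt from the resampled PSU sums, the measure is
recomputed, and the 2.5/97.5 percentiles of B replicates (default B = 1000)
form the interval, widened if necessary to contain the point estimate. The
subgroup pairing is held fixed at the point-estimate selection across
replicates so that the interval describes the named contrast. Replicates in
which a needed subgroup loses all records are dropped from the percentiles
and counted. The bootstrap was chosen because it is assumption-light,
applies identically to all four measures, and its nominal coverage is
directly testable by simulation; the coverage simulations in the acceptance
suite place it at 93–96% for D, R, PAR and PAF under the synthetic design
below.

## Trend classification

Two surveys' 95% UIs are compared as closed intervals: disjoint intervals
classify the change as increased/decreased by the point values; any
overlap — including exact endpoint contact, a deliberately conservative
convention — classifies the pattern as constant. Because narrative
interpretation distinguishes small from large overlaps without a numeric
cutoff, the shared length divided by the shorter interval's length is
reported alongside the verdict and left uninterpreted. Surveys with
incompatible stratifier schemas (5-region vs 8-region) are refused for
trend comparison; the pipeline logs and skips such pairs.

## Synthetic populations and sampling

The generator emulates the features the estimators rely on:

* **Structure.** Regions (with population shares and urban fractions) split
  into wholly urban or wholly rural enumeration areas; strata are
  region × residence. Cluster sizes are Poisson around a mean of 120
  households; each household holds one woman aged 15–49.
* **Stratifiers.** Education is drawn per residence. Household assets
  (7 binary + 2 continuous by default) load on a latent standard-normal
  wealth factor; the wealth score is the first principal component of the
  standardized (correlation-matrix) asset battery, sign-fixed so that more
  assets mean a higher score, cut into weighted fifths (Q1 poorest). Assets
  are independent of the other stratifiers, so population quintile shares
  are exactly 20% and the design truth is computable by enumeration.
* **Outcomes.** Births per woman are Poisson (default mean 1.0 over the
  5-year window, a plausible West-African birth-history density), dated
  uniformly over the window. SBA and neonatal death are Bernoulli with
  subgroup-specific probabilities configured per stratifier and combined on
  the logit scale when several stratifiers act; death ages are uniform on
  0–27 days (only the under-28-day event matters downstream). Every birth
  keeps its true probabilities, giving an exact ground-truth table.
* **Sampling.** Stage 1 allocates clusters to strata proportionally to
  household counts (largest remainder) and draws them by systematic PPS on
  household counts, with oversized clusters taken with certainty. Stage 2
  draws 28–30 households per cluster systematically; clusters smaller than
  the take are kept whole with adjusted weight. Design weights are inverse
  overall inclusion probabilities, so weighted sample totals estimate
  population totals (verified to ±10% at 100 clusters).

Deliberately *not* modeled: non-response, household rosters with several
eligible women, seasonal fertility, within-cluster outcome correlation
beyond stratifier composition, and finite-population corrections (the
bootstrap is slightly conservative at large sampling fractions). Passing
recovery tests therefore show that the estimators are correct for the
declared design, not that real DHS data meet these assumptions.

`guinea_like_population()` provides the default study conditions: eight
regions with a fully urban capital, ~30% urban population, education rare
outside cities, SBA rising steeply across wealth quintiles around a
national level near 45%, and NMR near 40 per 1000 with a male excess —
round values placed inside the published Guinea subgroup ranges.

## Validation problem sizes

The acceptance suite exercises the published worked examples (instant), the
algebraic identities and sign conventions on 1000 random configurations,
the weighted-rate oracle on 1000 random record sets, and a recovery study
sized to the method: a census of ≈3.1×10⁵ recall-window births (350,000
women) recovers D, R, PAR and PAF within 5% (observed ≤ 2%) of the design
truth, and 300 replicated surveys of 300 clusters × 28–30 households with
B = 500 bootstrap replicates measure UI coverage (required 90–98%, observed
93–96%). The full suite runs in about two minutes on one core.

## Known limitations

* Standard errors ignore finite-population corrections and treat the first
  stage as with-replacement, as DHS convention does.
* NMR is a weighted birth-level rate, not a synthetic-cohort life-table
  probability; at the neonatal horizon the two are practically identical.
* The reported unweighted denominators (`pop_n`) follow the convention of
  published equity-toolkit tables; weighted denominators are not reported.
* PAF is undefined when μ = 0 and ratios when the denominator subgroup sits
  at 0; the pipeline skips (and logs) such measures rather than imputing.
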