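# Methods

`bipindex` constructs a composite, rank-based index of each country's
capacity to generate, curate and publish primary biodiversity occurrence
records, from a database of country-level indicator variables. This note
documents the statistical procedure, its assumptions, the tunable
parameters, the synthetic-data generator used for validation, and the
numerical choices made where the method left them open.

## The model

Let a *dimension* be one of four response axes measured for countries that
already publish data through a biodiversity data-sharing network:

- **DAT** — occurrence records documented within the country,
- **GRF** — the geo-referenced subset of DAT,
- **HOST** — records published (hosted) by the country,
- **SPCS** — distinct taxa among the country's records.

Candidate predictors are country-level indicator variables grouped into
nine thematic *drivers*: GEO and POP (intrinsic physical/population size),
BIO and ENV (biological and environmental state), ICT, DVE, DVH, PWR and
PWF (information technology, development, resource and financial power).

The construction proceeds in five stages.

**1. Working table.** Long-format records (source, category, driver,
variable, year, country, value) are collapsed to a country × variable grid
holding, per cell, the value of the latest year with data, together with
its provenance year. Ratio derivations (relativizing a quantity by a
size-like variable) and natural-log transforms of skewed variables are
appended as new columns; originals are retained. Because every later stage
is rank-based, the log base is immaterial to all downstream results (a
tested property), and nonpositive log inputs or zero denominators yield
missing cells rather than errors.

**2. Screening.** Each variable is correlated with each dimension by
Spearman's rank correlation over all complete (predictor, response) pairs.
A variable survives for a dimension only if the correlation is significant
(two-sided α = 0.05) and |ρ| ≥ 0.5; by default the threshold is applied to
|ρ|, since a reliably negative predictor carries the same information up to
sign (a signed mode is available). Screens with fewer than `min_pairs = 10`
complete pairs are ineligible: tiny overlaps produce spuriously perfect
correlations. Survivors are replaced by midranks and min-max rescaled,

    x(n) = [X − X(min)] / [X(max) − X(min)],

so every retained variable lives on [0, 1] with 0 the lowest and 1 the
highest rank. Missing values pass through untouched. A constant survivor
maps to 0.5 everywhere, with a loud warning, rather than being dropped.

**3. Driver models.** For each driver × dimension pair with a non-empty
screened pool, a stepwise multiple regression of the dimension's
normalized response ranks on the driver's normalized variables is fitted:
forward selection (entry α = 0.05, candidate with the smallest p-value
enters, ties broken lexicographically) interleaved with backward
elimination (removal α = 0.10), listwise-complete over the terms currently
considered, deterministic given input order. Retained terms are checked
for collinearity by variance inflation factor, VIF = 1/(1 − R²). Terms
with VIF > 4 are linked whenever their pairwise |r| ≥ 0.7, and each
connected component of that graph (size ≥ 2) is replaced by the first
principal component of its correlation matrix; the component's sign is
oriented so it correlates positively with the response, which makes the
serialized loadings comparable across runs without affecting the fit. The
regression is then re-run with the direct survivors plus the composites.
Because a composite can itself turn out collinear with a surviving direct
term, the check-substitute-refit loop iterates (≤ 5 rounds), merging a
violating composite's raw members with its new partners and re-extracting
one component, so composites never nest and the final term set satisfies
the VIF bound on complete rows.

The fitted driver score for country *c* is

    D_dk(c) = [ Σ_i c_i·x_i(c) + Σ_j c_j·( Σ_a z_aj·w_aj(c) ) ] / m(c),

where the x_i are directly retained variables with coefficients c_i, the
j-th composite has members w_aj with loadings z_aj and coefficient c_j,
and m(c) counts the components (direct or composite) for which the country
has any data. This *flexible indexing* divides by what is available
instead of imputing what is not; a country with no data for any component
scores missing. A composite is available if at least one member is.

**4. Driver weights.** Within each dimension the driver scores are
combined as a flexible weighted average (same available-count denominator,
restricted to drivers with positive weight) and the weights f_dk ≥ 0 are
optimized by a Monte-Carlo random walk maximizing the Spearman correlation
between the combination and the response ranks. One weight is perturbed
per iteration by a Gaussian step with s.d. 0.05·(weight + 0.1), clamped at
zero; a proposal is accepted only if the objective strictly improves, so
the objective trace is non-decreasing and the final objective can never be
worse than at the seed. The walk stops after 500 consecutive rejections or
50,000 proposals. Seed weights are the nonnegative-clamped OLS
coefficients of the response on the driver-score columns (equal weights if
that regression is degenerate): seeding from the regression rather than
from an arbitrary point matters in practice, because the relative step
size shrinks with the weight and a decoy driver started at a large weight
can stall at a small but nonzero value — the rejection-counter expires
while no single proposal crosses the next rank-inversion boundary. The
objective is Spearman rather than Pearson correlation because every input
is a standardized rank and only the ordering is meaningful.

**5. Composite score and ranking.** Each dimension score M_d is the
flexible weighted driver average, rank-normalized to [0, 1] across
countries so that the dimension weights that follow act on comparable
scales. The final score is the weighted Euclidean distance to the origin

    BIP = sqrt( Σ_d (e_d·M_d)² ),

with expert-judgment importance weights defaulting to e = (DAT 0.1,
GRF 0.2, HOST 0.4, SPCS 0.3); dimensions missing for a country are
excluded from its sum. All four dimensions enter the score as axes; the
merged DAT-GRF view (weighted 1:2, i.e. proportional to e_DAT : e_GRF) and
the two-axis generation/hosting coordinates (generation = DAT-GRF merged
with SPCS, weighted (e_DAT+e_GRF) : e_SPCS; hosting = HOST) are reporting
projections, not the score. With defaults and M_d ∈ [0, 1] the score is
bounded by sqrt(0.30) ≈ 0.5477. Dividing the distance by the number of
dimensions would rescale every score equally and change no rank, so the
undivided distance is used.

Each country's *relative reliability score* (RRS) is the percentage of the
model's variables — the union of direct terms and composite members over
every fitted driver model, all dimensions — for which the country has
data. Countries with RRS below 75% keep their scores in the output but
receive no rank. Eligible countries are ranked by descending BIP, ties
broken by higher RRS, then by ISO code.

## Parameters

| parameter | default | role |
|---|---|---|
| `alpha` | 0.05 | two-sided screening significance |
| `rho_min` | 0.5 | minimum (absolute) Spearman for retention |
| `min_pairs` | 10 | complete pairs needed to evaluate a screen |
| `alpha_enter` / `alpha_remove` | 0.05 / 0.10 | stepwise entry/removal levels |
| `vif_max` | 4 | collinearity trigger |
| `collinear_r` | 0.7 | |r| linking high-VIF terms into one set |
| `e_weights` | 0.1/0.2/0.4/0.3 | dimension importance (DAT/GRF/HOST/SPCS) |
| `rrs_min` | 75 | eligibility threshold, percent |
| `mc.step_scale`, `mc.step_floor` | 0.05, 0.1 | proposal s.d. = scale·(w + floor) |
| `mc.patience`, `mc.max_iterations` | 500, 50,000 | stopping rules |
| `year_min`–`year_max` | 1990–2009 | accepted record years |

All of these live in one `BipConfig` object (YAML-loadable for the CLI).

## Synthetic data

The generator plants two independent uniform(0, 1) latent capacities per
country — generation g and hosting h — and emits predictors
v = link(±(w·g + (1−w)·h) + ε), ε ~ N(0, noise_sd²), with w = 1 for
BIO/ENV/GEO/POP, w = 0 for ICT/PWR/PWF, w = ½ for DVE/DVH; links cycle
through identity, exp, cube and arctan, and a quarter of the variables
carry a negative sign. Responses mimic heavy-tailed indexed record counts:
DAT ∝ round(exp(6g)·s), GRF = round(DAT·(0.3 + 0.7g)) (so GRF ≤ DAT by
construction), SPCS ∝ round(20g·s), HOST ∝ round(exp(5h)·s), with a
pre-rounding scale s = 10⁶ fine enough that the rounded counts stay
strictly monotone in the latent at zero noise for realistic country
counts. About 30% of cells also carry an earlier-year decoy record so the
latest-available logic is exercised; missing cells (default MCAR; an
optional mode concentrates missingness in low-capacity countries to
stress the reliability gate) have all their years removed. Everything is
reproducible from one integer seed.

The generator emulates the statistical structure the method assumes —
informative monotone predictors, heavy-tailed responses, missingness —
and nothing else: real indicator databases have correlated drivers,
informative (non-random) missingness patterns beyond the capacity mode,
measurement revisions across years, and far larger variable rosters.
Passing tests on this generator demonstrate that the machinery recovers
planted structure under the stated conditions, not that the index is
valid for real countries.

Study conditions used by the test suite and the acceptance script:
150 countries, 4 variables per driver, noise_sd 0.1, 10% missing. At
those sizes one full construction takes a few seconds, and the end-to-end
Spearman correlation between the planted e-weighted capacity mix and the
estimated score is ≈ 0.97–0.99.

## Numerical choices and edge cases

- Duplicate (variable, country, year) records: last in file order wins,
  with a warning — deterministic and auditable.
- Ties rank as midranks everywhere (the standard Spearman convention).
- Spearman p-values come from `scipy.stats.spearmanr`; the retention
  decision, not the p-value's sixth digit, is the contract.
- Stepwise fitting skips any candidate with fewer complete rows than
  terms + 2, with a warning; an empty final model is a legal outcome and
  the driver is simply absent from that dimension (a zero row in the
  coefficient table).
- Perfect collinearity reports VIF = +inf and is substituted like any
  other violation; a collinear set with fewer than 3 complete rows is left
  unsubstituted with a warning.
- PCA is computed on the correlation matrix of the members over complete
  rows (members are re-standardized even though they arrive on [0, 1]).
- Classical stepwise selection at entry α = 0.05 admits some pure-noise
  candidate with probability ≈ 1 − (1−α)^p when p independent noise
  candidates are screened; with five noise candidates roughly a quarter of
  fits carry one spurious extra term. This is a property of the classical
  variant, not a defect of the implementation; the greedy path still
  matches the exhaustive best-subset R² at the same model size to within
  0.02 in the tested designs.
- The optimizer accepts only strict improvements; equal-objective
  proposals are rejected, keeping the trace strictly interpretable.
- Rank-normalization at scoring time is computed over the scored set, so
  the model transfers to countries outside the fitting set; scores are
  comparable within one scored table, as befits a ranking instrument.

## Known limitations

- Scores are functions of standardized ranks: differences in BIP between
  countries order them but do not measure capacity gaps on any absolute
  scale.
- No multiple-testing correction is applied across the per-dimension
  screens, matching the method's design; with thousands of candidates
  some false survivors are expected and are meant to be pruned by the
  stepwise stage.
- No uncertainty is attached to scores or ranks.
- The hill climb is a local optimizer; with strongly correlated drivers
  different seeds can reach different weight vectors of equal objective.
  The seed rule and the recorded optimizer trace make any run exactly
  reproducible.
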