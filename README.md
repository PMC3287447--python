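# bipindex

Capacity for *biodiversity informatics* — digitizing, curating and openly
publishing records of where and when species occur — is spread very
unevenly across countries, and investment in it has to be prioritized.
`bipindex` builds a per-country composite index of biodiversity
informatics potential: a single rank-based score of how able a country is
to generate primary biodiversity data and to host and share them. It is
aimed at analysts constructing or auditing such composite indicators from
heterogeneous country-level statistics (economic, environmental,
infrastructural), where missing data are pervasive and distributions are
anything but normal.

## Method in brief

Starting from a long-format database of indicator records
(source, category, driver, variable, year, country, value), the pipeline:

1. collapses records to a country × variable **working table** of
   latest-available values, adding ratio- and log-derived variables;
2. **screens** each candidate against four response dimensions —
   DAT (occurrence records in the country), GRF (its geo-referenced
   subset), HOST (records published by the country), SPCS (distinct taxa)
   — keeping variables with significant Spearman |ρ| ≥ 0.5, then replaces
   survivors by min-max–rescaled midranks,
   `x(n) = [X − X(min)]/[X(max) − X(min)]`;
3. fits one **stepwise regression** per driver × dimension (nine thematic
   drivers: GEO, POP, BIO, ENV, ICT, DVE, DVH, PWR, PWF), replacing
   collinear term sets (VIF > 4) by first principal components, giving
   driver scores
   `D_dk = [Σ c_i·x_i + Σ c_j·(Σ z_aj·w_aj)] / m` with `m` the number of
   components the country has data for (*flexible indexing*: no
   imputation);
4. optimizes nonnegative **driver weights** `f_dk` per dimension by a
   Monte-Carlo random walk maximizing Spearman correlation with the
   response, and rank-normalizes the weighted driver averages into
   dimension scores `M_d ∈ [0, 1]`;
5. combines dimensions into the final score
   `BIP = sqrt(Σ_d (e_d·M_d)²)` with importance weights
   e = (DAT 0.1, GRF 0.2, HOST 0.4, SPCS 0.3), computes each country's
   **relative reliability score** (RRS, the percentage of model variables
   with data), and ranks countries by descending BIP — countries with
   RRS < 75% are reported but not ranked.

Everything after screening operates on standardized ranks, so the entire
output is invariant under strictly increasing transforms of any raw input.
See `docs/methods.md` for the full account.

## Worked example

A six-country toy with two drivers, three variables each; country AAA
tops every variable, FFF has no data at all:

```python
from bipindex import (BipConfig, build_working_table, fit_bip,
                      score_countries, ranking_table)
from bipindex.synthdata import make_worked_toy

records, responses = make_worked_toy()
table = build_working_table(records)
model = fit_bip(table, responses, BipConfig(min_pairs=3), rng_seed=0)
scores = score_countries(model, table)
print(ranking_table(scores).to_string(index=False))
```

```
Rank Country ISO BIP Index  RRS (%)
   1     AAA AAA    0.5477    100.0
   2     BBB BBB    0.4108    100.0
   3     CCC CCC    0.2739    100.0
   4     DDD DDD    0.1369    100.0
   5     EEE EEE       0.0    100.0
         FFF FFF                0.0
```

AAA sits at the composite's geometric ceiling: with every dimension score
at its maximum, `BIP = sqrt(0.1² + 0.2² + 0.4² + 0.3²) = sqrt(0.30) ≈
0.5477`. FFF has data for none of the model's variables (RRS = 0), so it
appears in the output but receives no rank. The remaining countries space
out evenly because the toy's ranks are evenly spaced on every variable.

The same lifecycle is available from the shell:

```sh
bipindex simulate --seed 3 --out sim/
bipindex fit sim/records.csv sim/responses.csv --seed 3 --out fitted/
bipindex score fitted/model.json sim/records.csv --out scored/
bipindex report scored/scores.csv
```

`simulate` writes a synthetic long-format fixture with planted
generation/hosting capacities and known ground truth; `fit` produces the
model JSON, the screening attrition report and the dimension × driver
coefficient table; `score` writes per-country scores, the ranking table
(Rank, Country, ISO, BIP Index, RRS (%)) and generation/hosting plot
coordinates. Every run writes a manifest (config snapshot, input digests,
seeds, stage counts) sufficient to reproduce it.

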