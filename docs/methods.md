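# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
experiments do and do not demonstrate.

## Data model and integration

An SRS extract is a relational bundle keyed by a case identifier: a
demographics table, a drug table (one row per reported medication, with a
role code and a sequence number), a reaction table (MedDRA Preferred
Terms), and auxiliary tables (medical history for JADER-style sources;
indications, therapy dates and outcomes for FAERS-style sources).

- **Deduplication.** FAERS-style cases may appear under several
  `caseversion`s; only the highest version per `caseid` is retained, with
  ties broken by the lexicographically greatest report id so the result is
  independent of input order (idempotent by construction). JADER-style
  sources carry one row per case (version fixed at 0).
- **Linkage.** Non-demo rows whose key is absent from the retained
  demographics are *orphans*: dropped and counted, never an error. Cases
  with no drug rows are retained with an empty exposure set. The
  patient-level integrated dataset (PLID) has exactly one record per
  retained case.
- **Dates.** Only complete year-month-day dates are accepted. Partial
  dates (year or year-month) are treated as missing — never coerced to a
  sentinel — and tallied in the parse log. The TTO analysis therefore uses
  only date-complete pairs, mirroring how such analyses are restricted in
  practice.
- **Ages.** FAERS-style (value, unit) pairs are floored to integer years.
  JADER publishes decade bands only; bands are kept as bands and resolved
  at stratification time (20s–60s → 20–69, 70s–90s → 70–99, other decades
  excluded). The decade bands nest exactly inside the 70-year cut, so no
  interpolation is invented.
- **Drug names** are standardized by a user-editable synonym dictionary:
  exact match after trimming/whitespace-collapsing/casefolding, else the
  longest listed synonym that prefixes the name at a word boundary. No
  fuzzy matching — a miss is a miss.
- **Roles.** FAERS PS/SS/C/I map to primary-suspected / suspected /
  concomitant / interacting; JADER's vocabulary (被疑薬 / 併用薬 /
  相互作用) has a single suspected category with no primary split. The
  main analysis counts exposure for any of suspected, concomitant or
  interacting roles. In the primary-suspected-only sensitivity scenario
  the effective filter is PS for FAERS-style sources and 被疑薬 for
  JADER-style ones — the closest faithful reading for a vocabulary without
  the PS/SS distinction.

## Disproportionality metrics

All metrics are computed from the per-drug 2×2 table against the rest of
the database ("drug versus rest"; an option removes the other screened
drugs from the comparator instead, since published table layouts are
ambiguous on this point). Cells always sum to the PLID size.

- **ROR** with lognormal Wald CI, `z = 1.959964` fixed. Undefined (and
  flagged) on any zero cell; no continuity correction by default — the
  n11 ≥ 3 gate removes the cases where one would matter, and a
  Haldane-style option exists but is off.
- **Fisher exact test**, two-sided by the minimum-likelihood rule: the sum
  of hypergeometric probabilities of all tables with the observed margins
  no more probable than the observed table. For grand totals up to 2,000
  the weights are compared as exact integers (ties are exact); above that
  the computation moves to log space with a 1e-7 relative tie tolerance.
- **PRR** with its lognormal CI, and the **Yates-corrected χ²** with the
  correction clamped at zero (`(max(|O−E|−0.5, 0))²/E`); uncorrected
  Pearson is selectable.
- **BCPNN IC.** The Bayesian model places independent Beta posteriors on
  the joint and the two marginal reporting probabilities, with the classic
  priors α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1 and the adaptive
  γ = γ₁₁(N+α)(N+β)/((n1₊+α₁)(n₊1+β₁)) that centres the prior IC at zero.
  IC = log₂p₁₁ − log₂p₁₊ − log₂p₊₁ is a sum of independent log-Beta
  variables, so its posterior cumulants are exact polygamma expressions;
  the point estimate is the exact posterior mean, and the 95% bounds use a
  Cornish-Fisher skewness correction from the exact third cumulant. This
  matters: at the small co-report counts this analysis gates on (n11 just
  above 3) the posterior of the joint term is visibly skewed, and a plain
  normal approximation misplaces the lower bound by several tenths of an
  IC unit. Against a 10⁵-draw Monte-Carlo sample of the same posterior the
  implementation agrees to <0.005 on the point and <0.03 on the bounds for
  n11 ≥ 1 (a tested property).

**Criteria** are applied exactly as printed, with strict `>` comparisons:
ROR₀₂₅ > 1 ∧ p < 0.05; PRR₀₂₅ > 2 ∧ χ² > 4 (sensitivity: PRR₀₂₅ > 1);
IC₀₂₅ > 0 with weak `(0, 1.5)`, medium `[1.5, 3.0)`, strong `[3.0, ∞)`.
Tables with n11 < 3 are excluded: no metrics, no flags.

## Stratification

Variables: sex (male/female; unknown excluded), age band (20–69 / 70–99;
outside 20–99 excluded), and medication count proxied by the maximum drug
sequence number, cut at ≥ 5 (polypharmacy). The proxy counts reported
medications, not simultaneous use — a known limitation. Exclusion for
missingness is **per variable**: a case without sex still contributes to
the age strata (listwise exclusion is available). Both rows of the
stratified 2×2 are restricted to the stratum by default (a full-database
comparator mode exists). The per-level tables of a variable sum cell-wise
to the table over the cases with that variable non-missing — a tested
partition invariant. Volcano coordinates are x = ln ROR,
y = −log₁₀p, point size n11, with reference lines at x = 0 and
y = 1.30103 (p = 0.05).

## Time-to-onset

TTO = (onset − start) + 1 days, so a same-day onset is day 1 (the +1 also
keeps the likelihood finite for shapes below 1). Start dates come from the
drug table (JADER-style) or the therapy table keyed by drug sequence
(FAERS-style); onsets from the reaction table (JADER-style) or the
demographic event date (FAERS-style). When several complete dates coexist,
the default rule pairs the earliest start with the earliest onset on or
after it; the alternative (earliest start with the overall earliest onset)
is selectable. Negative intervals are discarded and logged, not clamped.

The Weibull shape β solves the profile score equation
`Σxᵢ^β ln xᵢ / Σxᵢ^β − 1/β − mean(ln xᵢ) = 0`, which is strictly
increasing in β, by safeguarded Newton iteration inside an expanding
bisection bracket to a relative tolerance of 1e-10; powers are computed on
max-normalized data for overflow safety. The scale is then
`(mean xᵢ^β)^{1/β}`. All-equal samples have no finite MLE and are a hard
error (or a skipped, counted resample inside the bootstrap). Integer day
counts are fitted as-is; the discreteness bias is negligible at the scales
involved (tested recovery: <5% at n = 10,000, grid-search agreement to
3 decimals).

The 95% CI for β is a percentile bootstrap (B = 10,000 in production;
tests and the acceptance script scale B down — coverage is a tested
property at B = 500). Bootstrap quantiles, like the MLE itself, are
seeded; the pipeline derives every stage seed from one master seed by
fixed offsets, so a rerun is byte-identical. Failure types: wear-out if
the CI's lower bound exceeds 1, early if the upper bound is below 1,
random otherwise (a bound exactly at 1 is random). With n in the single
digits the bootstrap interval is honest but wide — small-sample fits are
exploratory, and the tested small-n property (n = 5 intervals wider than
n = 77) keeps that visible.

Summaries use linear-interpolation quantiles (the mainstream numerical
default). The cumulative-onset curve is the empirical CDF in percent
(Kaplan-Meier with no censoring); display truncation at 730 days never
renormalizes, so the truncated curve equals the full curve on its domain.
Histograms use half-open 5-day bins inside a half-open window.

## Synthetic study conditions

The generator's defaults define the conditions every end-to-end test runs
under; they were chosen once, to give a realistic yet desk-scale version
of a two-database screening study, and are not tuned per test:

| parameter | default | rationale |
|---|---|---|
| cases per database | 20,000 | desk-scale stand-in for multi-million-report extracts; keeps planted n11 ≈ 27 |
| screened drugs | 8 targets + negative control, exposure 0.03 each | low-prevalence exposures, comparator dominated by other drugs |
| event baseline | 0.015 | rare-event regime where ROR ≈ PRR |
| planted ratio ρ | 3 for two drugs, 1 elsewhere | a clearly detectable but not caricatural signal; ρ = 1 defines the control |
| TTO model | Weibull(0.56, 120 days) | an early-failure onset pattern with most onsets inside a year |
| missingness | start/onset 0.3, sex 0.05, age 0.1 | date-completeness is the binding constraint in real TTO analyses |
| FAERS version duplication | 0.10 | exercises the caseversion rule |
| roles for catalogued drugs | suspected 0.7 / concomitant 0.25 / interacting 0.05 (PS = 70% of suspected) | exercises role-restriction scenarios |

Every case also receives a background reaction row and background
co-medication rows filling its drawn sequence count, so reaction and drug
tables look structurally realistic. What the generator does **not**
emulate: correlated co-prescription, duplicate mechanisms other than
versioning, reporting-propensity drift over time, term miscoding. Passing
tests therefore demonstrate the pipeline's statistical behaviour under a
clean generative model — not robustness to real-world reporting biases,
which no synthetic check can establish.

Closed-form expected 2×2 cells (exposure × capped baseline·ρ, with the
maximum ρ over co-exposed associated drugs) serve as the calibration
oracle; observed cell means match them within Monte-Carlo error over
seeds, and the null configuration's ROR CI shows ~95% coverage of 1.

## Pipeline and outputs

Stage order: ingest/integrate per database → primary screen of all drugs →
replication gate (advance = any criterion met in both databases; a strict
all-criteria mode is configurable) → stratified screens and TTO for
advanced drugs → the four scenarios with the negative control. Every
output is a delimited text table with a documented column order; the run
manifest records the configuration, seeds, per-stage record counts and
every exclusion (orphans, low counts, missing strata, incomplete dates),
so no row disappears silently. The problem sizes used by the test suite
and the acceptance script (e.g. 100 seeded database pairs for the
power/specificity study, B = 500 bootstrap at n = 2,000 for coverage) are
the package's chosen study sizes for those experiments.

## Known limitations

- Disproportionality measures relative reporting, not incidence or risk;
  the package deliberately offers no causal readout.
- PT-code/term matching only; no MedDRA hierarchy traversal.
- No censoring-aware survival modelling; the KM curve is descriptive.
- The polypharmacy proxy and the earliest-pair TTO rule are heuristics
  with selectable alternatives, not validated constructs.
- Real-extract ingestion supports the published file conventions via
  configurable column maps, but quarter-to-quarter schema drift in real
  downloads may require custom mappings.
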