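# pvsignal

Disproportionality and time-to-onset signal analysis for spontaneous
adverse-event reporting systems.

## The problem

Spontaneous reporting systems (SRSs) such as Japan's JADER and the U.S.
FAERS collect voluntary reports of suspected adverse drug reactions. They
have no denominators — we observe only who reported what — so the standard
screening question is *disproportionality*: is an event reported with a
drug more often than the database's own background would predict? This
package implements a complete SRS screening pipeline, motivated by the
question of atrial-fibrillation (AF) reporting with the eight overactive-
bladder (OAB) drugs (antimuscarinics and β3-agonists), with vibegron
carried through every step as a negative control. It is written for
pharmacoepidemiologists who want a tested, reproducible version of this
workflow that runs end-to-end on synthetic data with known ground truth.

## The methods

Each drug is summarized against the rest of its database by the 2×2 table
(n11 = event reports with the drug, n12, n21, n22), one deduplicated case
per cell. Three measures are computed, each with its pre-specified signal
criterion (all on the lower 95% bound, `*_025`):

- **ROR** = (n11·n22)/(n12·n21), lognormal Wald CI; signal when
  ROR₀₂₅ > 1 *and* two-sided Fisher exact p < 0.05.
- **PRR** = (n11/n1₊)/(n21/n2₊), lognormal CI, with Yates-corrected χ²;
  signal when PRR₀₂₅ > 2 and χ² > 4 (a deliberately stringent threshold;
  the conventional PRR₀₂₅ > 1 is a sensitivity setting).
- **BCPNN IC** = log₂ of the shrunk observed/expected co-reporting ratio
  under the classic Bayesian priors; signal when IC₀₂₅ > 0, with strength
  bands weak/medium/strong cut at 1.5 and 3.0.

Tables with n11 < 3 are excluded for minimal statistical stability. A drug
*advances* only if it meets at least one criterion in **both** databases
(the replication gate). Advanced drugs get stratified screens (sex, age
20–69 vs 70–99, <5 vs ≥5 medications by maximum drug sequence number) and
a time-to-onset (TTO) analysis: days from therapy start to event onset
(+1 to avoid zero), Weibull shape β by maximum likelihood with a
10,000-resample percentile bootstrap CI, and a failure type read off the
CI — early (hazard decreasing, CI < 1), random (CI covers 1), wear-out
(CI > 1). Three sensitivity scenarios (conventional PRR threshold,
primary-suspected-only roles, prior-history/indication exclusion) rerun
everything, negative control included.

The synthetic generator emulates both database dialects — FAERS-style
`$`-delimited tables with caseversion deduplication, JADER-style CSVs with
decade-band ages — with planted reporting-rate ratios, Weibull onset
times, and missing-date mechanisms, so every stage is testable against
ground truth.

## Worked example

```bash
python analysis/01_generate_data.py      # two synthetic databases (scratch/data)
python analysis/02_primary_screen.py     # per-drug screening tables (results/)
python analysis/03_stratified_screen.py  # strata + volcano coordinates
python analysis/04_time_to_onset.py      # Weibull TTO summaries
python analysis/05_sensitivity_scenarios.py
```

The primary screen prints, per database, one row per drug (excerpt from
the JADER-style draw):

```
        drug  n11   ROR  ROR_lo  fisher_p  PRR_lo  chi2  IC_lo  met_ROR  met_PRR  met_IC ic_strength
 solifenacin   19 1.985   1.240     0.008   1.238 7.566  0.123     True    False    True        weak
  mirabegron   21 2.089   1.333     0.004   1.329 9.794  0.224     True    False    True        weak
    vibegron    8 0.808   0.399     0.742   0.404 0.186 -1.415    False    False   False        none

replicated signals (advance to stratified/TTO): ['solifenacin', 'mirabegron']
```

The two drugs with a planted reporting-rate ratio of 3 are flagged (ROR
≈ 2–3.5 with lower bounds above 1, weak IC) and clear the replication
gate; the ρ = 1 negative control does not. The TTO stage then prints, for
the advanced drugs:

```
database        drug  n  median_days    q1     q3  beta  beta_lo  beta_hi failure_type  pct_within_365
   JADER  mirabegron 12         35.0  9.25 200.50 0.465    0.381    0.789        early          83.333
   FAERS  mirabegron 16         49.0 13.00 289.75 0.523    0.422    0.787        early          81.250
```

i.e. the estimated Weibull shape is below 1 with a bootstrap CI entirely
under 1 — an early-failure pattern, consistent with the generator's
planted shape of 0.56 — and most onsets fall within the first year. The
negative-control report confirms vibegron meets no criterion in any
scenario or stratum.

A `pvsignal` CLI exposes the same steps (`generate`, `screen`,
`stratify`, `tto`, `scenarios`, `run`); see `pvsignal --help`.

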