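# Methods

`pvfaers` implements the standard signal-detection workflow applied to
spontaneous adverse-event report streams of the FAERS type, packaged so the
whole chain — data engineering, disproportionality statistics, onset
modelling, risk-factor regression — runs and is testable on synthetic data
with known ground truth.

## Report model and deduplication

A *case* (CASEID) can accumulate several report *versions* (PRIMARYID) as
follow-ups arrive.  All analyses count deduplicated reports: within a
CASEID the version with the most recent FDA_DT wins, ties broken by the
highest PRIMARYID.  A version with a missing FDA_DT never displaces a dated
one (it sorts below every real date); the rule as usually stated covers
only dated records, and keeping an undated duplicate over a dated one is
indefensible.  Dates live as YYYYMMDD integers.  Partial dates (YYYYMM,
YYYY) are padded to the 1st where only an ordering is needed (dedup) and
treated as missing wherever day-level arithmetic is required
(time-to-onset); the two repairs are logged separately.

## Cohort extraction

Drug matching is exact on normalised strings (lower-cased, trimmed,
trailing punctuation stripped) against a lexicon of generic + brand
spellings, on DRUG.drugname or DRUG.prod_ai, restricted by default to
suspect roles {PS, SS} (configurable).  Substring matching is deliberately
not used: it creates false positives on combination-product strings, and
the synthetic generator controls the spellings that occur.  Event
restriction goes through a PT -> SOC stub dictionary (a licensed MedDRA
hierarchy is out of scope); a report qualifies when at least one of its PTs
maps to the requested SOC (dermatologic = 10040785).  Ages convert to years
(MON/12, DY/365.25), weights to kg (LBS x 0.453592); unknown unit codes
make the value missing.

The characteristics table uses half-open bands chosen so the printed labels
partition: weight <80 = [0,80), 80-100 = [80,100], >100 = (100,inf); age
<18 = [0,18), 18-44 = [18,45), 45-65 = [45,65], >65 = (65,inf).
Percentages are computed on the stratum total and rounded half-up to two
decimals (`decimal.Decimal`, not float rounding, so 0.125% -> 0.13%).

## Disproportionality statistics

For a drug-event pair, the deduplicated universe is cross-classified into
the 2x2 table (a, b, c, d); E = (a+b)(a+c)/N is the independence
expectation.  The four statistics are the standard published forms:

* **ROR** = ad/bc with Wald 95% CI: exp(ln ROR +- 1.96 sqrt(1/a + 1/b +
  1/c + 1/d)).  Signal rule: lower bound > 1 and a >= 3.
* **PRR** = [a/(a+b)] / [c/(c+d)] with the Pearson chi-square of the table
  (no continuity correction by default; Yates available behind a flag).
* **IC** (BCPNN information component), closed-form shrinkage version:
  IC = log2((a+0.5)/(E+0.5)), IC025 = IC - 3.3 (a+0.5)^-1/2
  - 2 (a+0.5)^-3/2.  Defined at a = 0; the shrinkage washes out as a
  grows.
* **EBGM** (gamma-Poisson shrinker): the count a is Poisson(lam E) with a
  two-component gamma mixture prior on the relative reporting rate lam —
  w Gamma(a1, b1) + (1-w) Gamma(a2, b2), default (0.2, 0.1) / (2.0, 4.0)
  with w = 1/3 (the canonical starting prior of the method).  The
  posterior is again a two-component gamma mixture with
  marginal-likelihood-updated weights; EBGM = exp(E[ln lam]) via the
  digamma function, EBGM05 is the 5th posterior percentile, root-found
  from the mixture CDF with a bracket built from the component quantiles.

Hyperparameters can instead be fitted by empirical Bayes: EM on the
negative-binomial mixture marginal (responsibilities in the E-step,
weighted NB maximum likelihood per component in the M-step, Nelder-Mead on
log hyperparameters), which guarantees a non-decreasing marginal
log-likelihood up to the inner optimiser tolerance.  Components are
reported ordered by ascending prior mean to remove label switching.  The
scan itself uses the fixed default prior for determinism.

**Zero cells.** The Haldane-Anscombe +0.5 is added to all four cells, but
only when some cell is zero, and the result is flagged — clean tables keep
exact arithmetic.  With the correction disabled a zero-cell ROR/PRR is NaN,
never silently dropped.

**Counting unit.** Default is the deduplicated report (a report counts once
per PT, and once at SOC level no matter how many of its PTs fall in the
SOC).  A report x PT unit is available behind a flag for the drug-level
summary, since published per-drug report counts are sometimes tallied that
way; the two conventions are not reconcilable from printed tables alone.

**Ordering.** The PT scan sorts by ROR descending, ties by (a descending,
PT name ascending), so output is permutation-invariant in record order.

## Time-to-onset

Onset = event date - earliest valid therapy start of the matched drug
(linked through THER.dsg_drug_seq), in whole days; only onsets > 0 enter.
Exclusions carry reason codes that partition the dropped reports:
missing_date, erroneous_date (start after event), zero_onset.  Medians are
the middle order statistic (mean of the two central values at even n, hence
half-day medians); quartiles use linear interpolation.

The Weibull model f(t) = (k/lam)(t/lam)^(k-1) exp(-(t/lam)^k) is fitted by
MLE on (log k, log lam) — BFGS with analytic gradients on the mean
log-likelihood (per-observation gradient tolerance 1e-8, Nelder-Mead polish
fallback), method-of-moments initialisation (k0 = cv^-1.086,
lam0 = mean / Gamma(1 + 1/k0)).  Wald 95% CIs come from the
finite-difference observed information on the log scale and are
back-transformed, so bounds stay positive.  Hazard classification by the
shape CI: entirely below 1 = early-failure, covering 1 = random, entirely
above 1 = late-failure.  `fix_shape=1` gives the exponential special case
(scale MLE = sample mean, closed form).  No censoring model: only observed
onsets are fitted.

## Risk factors

Within one drug's deduplicated universe the outcome is dermatologic-event
occurrence; covariates are hospitalization (HO outcome code), age >= 65
years, and extreme weight (< 50 or > 100 kg; reference 50-100 kg).  Reports
missing age or weight are excluded (count logged).  The fit is plain ML
logistic regression with intercept by IRLS with step-halving (deviance
non-increasing by construction, score-norm convergence at 1e-8); Wald CIs
exp(beta +- 1.96 SE) and two-sided Wald p-values.  Quasi-complete
separation raises an explicit error naming the covariate.  No interactions,
no regularisation.  A single-binary-covariate fit reproduces the analytic
2x2 odds ratio and its Woolf standard error exactly.

## Synthetic data generator

The generator emulates the failure modes that make spontaneous-report data
hard: duplicate case versions (same CASEID, new PRIMARYID, FDA_DT 5-60 days
later, all child rows copied), erroneous therapy dates (start planted after
the event), missing demographics and dates, generic-vs-brand drug
spellings in random letter case, multi-drug and multi-PT reports.

Planted associations are exact, not approximate: for a planted pair with
margins (pD, pP) and target odds ratio m, the joint cell p11 solves the
Plackett closed form for a 2x2, and the PT is drawn conditionally on the
drug (p11/pD on-drug, (pP-p11)/(1-pD) off-drug).  The returned truth object
carries the expected cells n(p11, pD-p11, pP-p11, 1-...) of the
pre-duplication stream, so recovery tests compare against a closed form.
One PT may be planted against at most one drug (validated), which keeps the
conditional draws consistent.  Reports that would otherwise carry no drug
or no reaction get a fallback from the non-suspect background catalogs
only, leaving planted margins untouched.

Onset clocks: for configured (drug, PT) pairs, onset ~ Weibull(k, lam)
rounded up to whole days, and the therapy start is back-dated from the
event so dates are mutually consistent.  Unconfigured pairs get a uniform
1-365-day exposure gap — deliberately not Weibull, so only planted clocks
should fit cleanly.

Default study conditions (chosen once): three aromatase inhibitor generics
with brand spellings (anastrozole/Arimidex, exemestane/Aromasin,
letrozole/Femara) as suspect drugs on a breast-cancer-like background;
~96.7% female; age centred at 66 y (sd 11, small paediatric admixture);
weight centred at 68 kg; the recurrent dermatologic PTs mapped to SOC
10040785 plus non-dermatologic background PTs; outcome-code mix dominated
by other-serious and hospitalization; missing-data rates near the unknown
fractions typical of such case series (age ~33%, weight ~31%);
duplicate_rate 0.05; bad_date_rate 0.02.  Default planted pairs:
anastrozole-alopecia (OR 3), anastrozole-night sweats (OR 4),
exemestane-nail disorder (OR 5), letrozole-nail toxicity (OR 8), with
Weibull onset clocks on those pairs and on the urticaria pairs.

What the generator does *not* emulate: drug-drug co-prescription
correlation, reporting-rate drift across quarters, country-specific
reporting cultures, PT co-occurrence structure beyond independence, or
free-text misspellings beyond case/brand variation.  Passing tests
therefore demonstrate correctness of the pipeline's logic and statistics
under controlled conditions — not that real-database headline estimates
would be reproduced, which requires the full multi-decade download.

## Problem sizes and numerical choices

Tests run the generator at 3,000-8,000 reports for unit-level checks and
50,000 deduplicated reports x 20 seeds for planted-signal recovery; the
acceptance script uses one 30,000-report quarter.  These sizes give planted
cells large enough for stable estimates while keeping the whole suite quick
to run.  Tolerances: statistic oracles at 1e-10 relative; closed-form
identities at 1e-8; EBGM05 root-finding at 1e-12; stochastic recovery
checks at the binomial thresholds stated in the tests (e.g. >= 18/20 seeds
for nominal-95% CI coverage per parameter, since the joint coverage of two
95% intervals is only ~90% and would make a 90% joint threshold a coin
flip for a correct estimator).

## Known limitations

* The MedDRA stub maps each PT to exactly one SOC; real MedDRA has
  multi-axiality and HLT/HLGT levels.
* Exact name matching will not match misspelled or combination-product
  drug strings; no RxNorm normalisation.
* The IC uses the closed-form shrinkage approximation, not the full BCPNN
  posterior; the MGPS default prior is the canonical starting prior, not a
  database-wide empirical fit (the EM fitter exists but the scan defaults
  to the fixed prior for determinism).
* Onset fitting ignores censoring and the integer-day rounding of
  intervals; at typical scales (lam >= 30 d) the rounding bias is well
  inside the CI width.
* Old quarterly file-layout variants and the XML dialect are not parsed;
  one canonical $-delimited dialect is supported.
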