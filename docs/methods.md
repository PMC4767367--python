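# Methods

## CGM summary statistics

A trace is a sequence of interstitial glucose values (mmol/L) on a nominal
5-minute grid. Parsing snaps timestamps to the nearest grid slot (tolerance
half an interval); when two rows land in one slot the first is kept and a
warning logged; interior gaps become explicit missing slots. Values outside
the physiologic band (0, 40) mmol/L are dropped at parse time. The first
and last recorded calendar days are discarded before any statistic is
computed (sensor run-in and run-out are the least accurate), leaving 72 h
for a 5-day recording. Day boundaries are calendar midnights of the
sensor's local timestamps, since the insertion time is generally unknown.
Trimming is implemented idempotently (a trimmed series carries a flag and
is returned unchanged), so the retained span is stable under
re-application.

Numerical conventions, where the metric definitions leave room:

- **SD denominator.** Sample SD (n−1) everywhere (24-h SD, CONGA); this is
  what standard statistical software computes by default.
- **24-h SD and range over the pooled 72 h**, not averaged per day. The
  statistics are computed once per participant; a per-day-then-average
  variant of the SD is available behind `per_day_average=True`.
- **Clock windows are half-open** [start, end): nocturnal [3:00, 6:00),
  diurnal [6:00, 24:00). The stretch 0:00–3:00 belongs to neither window;
  that gap is part of the analysis definition and is reproduced rather than
  absorbed into the nocturnal window.
- **Window means pool all valid samples across analysis days** and require
  ≥ 70% of the window's grid slots to be valid (configurable
  `min_coverage`); below that the participant-metric is missing (NaN), and
  missingness never aborts a cohort run.
- **CONGA** skips pairs with either member missing; no interpolation.
- **MODD** matches "the same time of day" as the same grid slot after
  snapping; with 3 analysis days, the slot-wise absolute differences from
  both consecutive pairs (1→2, 2→3) are pooled into a single mean —
  equivalent to averaging two daily MODDs under complete coverage and
  better behaved with gaps.

## Association model

For outcome y, risk-group indicator g (CT/TT = 1) and covariates
(age, sex, offspring/partner status), OLS of y (or log y) on (1, g, x).
The variance is the cluster-robust sandwich grouped by family with the
small-sample factor [G/(G−1)]·[(N−1)/(N−k)] and t(G−1) inference — the
clustered-robust behaviour of the major commercial packages, chosen for
comparability with the published inference style; statsmodels reproduces
this exactly (verified against a hand-computed sandwich in the tests, and
it collapses to HC1 with singleton clusters). Adjusted group means are the
fit evaluated at the covariate means of the analysis sample, with CIs from
the same robust covariance; on the log scale everything is exponentiated
(geometric means). Fasting insulin is log-scale by default — it is the one
clearly right-skewed outcome — with a per-outcome override
(`log_scale_outcomes`), since which outcomes warrant a geometric mean is a
judgement call.

**Permutation test.** Reference statistic |β| from the observed fit.
Genotype is family-correlated, so labels are not individually
exchangeable; the permutation unit is the family cluster. Each cluster's
*vector* of group labels moves as a unit and vectors are shuffled across
clusters of equal size (clusters of the same size are exchangeable under
the null). This reduces to shuffling scalar labels when genotype is
constant within family, and remains exact when siblings differ in genotype
— which happens in roughly a third of simulated pairs. Individual-level
shuffling is available via `unit="individual"`. The p-value uses the
add-one estimator (1 + #{|β*| ≥ |β|})/(n_perm + 1), which cannot return 0;
ties are counted with a 1e-12 tolerance. The minimum sample size for a
permutation refit is residual-degrees-of-freedom based (covariates + 4
rows), so small exhaustive checks are possible.

**Mediation.** Percent of effect explained,
100·(β_unadj − β_adj)/β_unadj, computed from unrounded coefficients on a
common complete-case set (rows complete on outcome, covariates and all
mediators), with a group × mediator interaction test per mediator first; an
interaction p < 0.05 flags the result as not interpretable as mediation
but it is still returned. The estimate may fall outside [0, 100]
(suppression, or smallness of the unadjusted effect); it is flagged, not
truncated. Note that with rounded inputs the arithmetic shifts visibly:
coefficients printed as 0.17 and 0.11 give 35.3%, while the unrounded pair
behind such a report can give ~34.6% — this package always uses unrounded
estimates. At n ≈ 235 the percent-mediated estimate is highly variable
(its denominator has SE comparable to its magnitude); recovery of a
configured mediated fraction is only expected, and only tested, in cohorts
of several thousand.

**HWE.** 1-df chi-square goodness of fit of (n_CC, n_CT, n_TT) against
expectations from the observed allele frequency; a monomorphic sample is
trivially in equilibrium (p = 1). Significance is two-sided 0.05
throughout, with no multiple-testing correction across the nine outcomes —
a deliberate mirror of the single-candidate-SNP analysis style, and a known
limitation.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes, with
known ground truth; it emulates a family-based cohort of middle-aged
participants without diabetes.

**Genotypes and families.** A `sibling_fraction` of participants form
2-person family clusters; each pair draws one allele from each of two
simulated parents (alleles Bernoulli at `t_allele_freq`, default 0.30, the
frequency typical of European-ancestry populations), so siblings' genotype
dosages correlate at ~0.5 while marginal frequencies stay at
Hardy–Weinberg proportions. Singletons draw two independent alleles. The
generator's genotypes pass the package's own HWE test at α = 0.001 in
≥ 99% of replicate cohorts (a generator-vs-tester calibration in the test
suite).

**Effect structure.** With risk = (genotype ≠ CC):

- weight = 76.7 + 2.5·risk + noise (SD 12), pbf = 30.3 + 1.5·risk + noise
  (SD 8.2), noise correlated at 0.5 — magnitudes of the body-composition
  contrasts seen in cohorts of this kind.
- mediator composite s = (z_weight + z_pbf)/√(2(1+ρ)), standardized to
  unit variance under the null; glucose receives `mediator_to_glucose`·s
  uniformly across the day (body composition affects glucose at all
  hours).
- the direct genotype effect `direct_effect`·risk is applied with a
  raised-cosine weight over 0:00–7:00, normalised so its mean over the
  [3:00, 6:00) analysis window is exactly 1. Consequently
  `direct_effect + mediator_to_glucose·Δs` is the exact ground-truth
  contrast in the nocturnal-mean outcome, and `with_effects(total,
  fraction)` can target any decomposition; defaults give a 0.19 mmol/L
  total nocturnal contrast, 35% mediated.

**Trace model.** circadian cosine with nadir 4.455 mmol/L at 4:00 and
amplitude 0.85, plus Gaussian meal excursions (8:00, 12:30, 18:30;
amplitude 1.3 mmol/L, SD 50 min) — these values were chosen by solving the
window-mean equations so the CC group sits at nocturnal/24-h/diurnal means
of ≈ 4.48/5.21/5.45 mmol/L, the regime reported for non-diabetic
middle-aged cohorts — plus person-level (SD 0.55 mmol/L) and family-level
(SD 0.1 mmol/L) random intercepts, AR(1) sensor noise (coefficient 0.7,
marginal SD 0.45 mmol/L, stationary initialisation), and uniform random
missingness (3%). The person-level SD is essential: between-participant
variation dominates the SE of group contrasts in real cohorts (robust SE
≈ 0.08 mmol/L at n = 235 here), and without it every calibration would run
in an unrealistically easy regime. The family random-intercept SD is a
guess exposed as configuration — within-family outcome correlation is not
identifiable from published group summaries. Traces start at a virtual
midnight, so a 5-day recording spans exactly 5 calendar days and trimming
leaves exactly 72 h. Values are clipped to [0.5, 39.5] mmol/L to respect
the physiologic parser bounds (the clip is essentially never active at
default noise levels). Each participant's stream derives from
(seed, participant index), so cohorts and traces are bit-reproducible and
independent of generation order.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: no day-to-day behavioural variation (meals and
activity repeat identically each day), so interday variability is lower
than in real cohorts (MODD ≈ 0.5 vs ≈ 0.85 mmol/L typically reported); no
sensor calibration drift or structured dropout (missingness is uniform);
no diabetic excursion dynamics. One deliberate artefact: because the direct
effect lifts the nocturnal trough toward the daily mean, risk carriers
have slightly *lower* pooled SD, CONGA and range (β ≈ −0.02 to −0.1
mmol/L with small SEs), a mechanical consequence of the nocturnal-shaped
shift rather than an emulated biological finding.

## Validation design

There is no public cohort against which the pipeline's headline numbers
could be recomputed, so validation is property-based:

1. exact golden values (hand-computed CONGA/MODD/SD/HWE cases);
2. brute-force oracle equivalence of every CGM statistic on random gappy
   series (1e-9 relative);
3. type-I calibration of the cluster permutation test at the study's size
   and clustering (rejection rate at 0.05 within [0.03, 0.07] over 500
   null cohorts);
4. recovery of the adjusted β and 93–97% robust-CI coverage over 1000
   replicate cohorts of 235;
5. recovery of a configured 35% mediated fraction within ±5 points at
   n = 5000 (50 replicates);
6. byte-identical pipeline outputs under a fixed seed.

Replicate counts balance Monte Carlo resolution against runtime on one
CPU: 500/1000/50 replicates put the MC standard error of each checked
quantity several times below its acceptance band. Permutation counts are
200 in replicate studies and 1000 in single analyses.
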