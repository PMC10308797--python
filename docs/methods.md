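# Methods

`ddpsim` simulates stylized two-trial drug-development segments and
estimates their operating characteristics by seeded Monte Carlo. This note
records the statistical models, the defaults and why they were chosen, the
numerical choices, and what the simulations do and do not show.

## Segment models and gating

A segment is two consecutive trials with a gate: the first trial's final
analysis decides whether the second runs, and its estimates parameterize
the second trial's design. Segment-level metrics are estimated as plain
Monte-Carlo means over replicates:

* **segment power** — fraction of replicates in which the first trial is
  positive *and* the triggered second trial is positive;
* **expected total enrollment** — mean of (first-trial n + second-trial n
  when triggered);
* **unsafe/ineffective exposure** (Segment B) — mean over replicates of
  the within-replicate fraction of patients treated at a dose whose true
  DLT probability exceeds the toxicity target or whose true ORR does not
  beat the reference. The per-replicate-fraction reading (rather than the
  ratio of expectations) answers "what is the chance that a randomly
  chosen patient in this program was exposed?";
* **expected duration** — mean of accrual time + follow-up per trial plus
  a between-trial gap (see enrollment model);
* **selection distribution** — probability of each dose (Segment B) or
  final cutoff (Segment C) plus "none" (program stopped); sums to 1 by
  construction.

Proportions carry the binomial standard error sqrt(p(1−p)/n); means carry
the sample standard error.

### Segment A: exact binomial phase II → Fisher phase III

Phase II rejects when the responder count reaches the smallest r with
P(X ≥ r | Binomial(n₂, ORR₀)) ≤ α (ties at exactly α reject; this is the
standard exact-test convention). Exact power follows by evaluating the
same tail at the alternative; the sample-size search scans n linearly
because exact power is a sawtooth in n and bisection can skip the minimum.

The phase III p-value is the hypergeometric upper tail conditional on the
table margins (one-sided, favoring the experimental arm; the tested
hypotheses are one-sided, so a one-sided 0.05 test is used throughout).
Unconditional power sums Binomial(n, p₁) × Binomial(n, p₀) mass over the
rejection region; the (n+1)×(n+1) rejection matrix depends only on (n, α)
and is cached, making each power evaluation two pmf vectors and a
mat-vec. Sizing finds the smallest per-arm n meeting the target power at
(ÔRR₁, 0.4): a two-proportion normal approximation brackets the answer
and a linear scan from half the bracket confirms exactly (the factor-of-two
margin is far below any n whose exact power could reach the target, and the
result is verified against a full scan in the tests). Totals stay even
(1:1 allocation); at the 400-patient cap the trial still runs, flagged
`capped`. Sizing results are memoized — the phase II estimate takes at
most n₂+1 values per run. A `sizing="normal"` switch exposes the classic
normal-approximation size for sensitivity analysis (exact is the default;
the two differ by roughly 10% in n and materially affect expected
enrollment).

### Segment B: CRM phase I → single-arm phase II

The CRM uses the empiric (power) model p_j(β) = s_j^{exp(β)} with a
N(0, 1.34²) prior on β — the de-facto default parameterization for this
model class. The default skeleton (0.05, 0.12, 0.25, 0.40, 0.55, 0.68)
places the prior MTD at level 3 for the 0.25 target; start dose 3, one
patient per cohort, and no skipping of untried levels upward are
package-chosen defaults, all overridable. Each refit computes the posterior
mean of p_j(β) per dose. Dose assignment targets the estimate closest to
0.25 (ties to the lower dose); the *final* selection is the highest dose
with estimated toxicity ≤ 0.25 — the MTD definition — with the program
stopping when even dose 1 exceeds it. The safety stop is evaluated at the
final analysis only, matching a gate that acts on the completed trial
rather than a mid-trial hard stop.

The gated phase II is the 42-patient exact-binomial design (80% power for
0.4 vs 0.6 at one-sided 0.05), run at the selected dose's true response
and toxicity rates. It is positive when the efficacy test rejects *and*
the observed adverse-event rate is at or below the monitor threshold
(default 0.25, mirroring the phase I target; configurable). Segment-B
power requires, in addition, that the selected dose is truly safe and
effective; the unconditional variant (any selected dose) is reported
alongside as `ddp_power_unconditional`.

An optimal-dose selector (highest estimated ORR among doses with
acceptable toxicity, ties low) is provided as a pure function for
non-monotone dose-response analyses, together with a non-monotone truth
fixture; a full response-adaptive phase I design is out of scope.

### Segment C: adaptive enrichment phase II → subgroup phase III

Patients enroll in three stages (50/25/25%, stage sizes rounded with the
remainder to stage 3) and are randomized 1:1 within consecutive pairs —
the minimal structure supporting a paired (McNemar) analysis. Because both
pair members draw i.i.d. biomarkers and outcomes, the within-pair
randomization is realized by labeling draws directly. The eligibility
cutoff starts fully open (0.0 = no enrichment) and can only rise at the
two interims, over the candidate grid 0.1, …, 0.9.

The interim rule — among candidates at or above the current cutoff with at
least `min_subgroup_pairs` (default 5) complete pairs above them, move to
the one maximizing the observed ORR difference, requiring strict
improvement, ties to the larger population — is one simple, monotone
member of the family of staged enrichment rules; the family is genuinely
under-determined, so the rule is isolated behind `interim_cutoff_update`
and alternatives can be swapped in. The final analysis applies the exact
one-sided sign test to discordant pairs whose members both meet the final
cutoff. Re-using stage-1 data after adaptation can inflate the phase II
type I error above its nominal level in principle; empirically (null
scenario, 10,000 replicates) the discrete sign test's conservatism keeps
the rejection rate near 0.03, and the segment-level false-positive rate
(two sequential tests) near 0.001.

A positive trial triggers a phase III sized from the trial's own subgroup
estimates (not the historical reference — the gate's report is the only
subgroup information available), enrolling biomarkers uniform on
[cutoff, 1) with responses from the true curves.

## Truth scenarios

* **Segment A**: true ORR 0.6 (experimental) vs 0.4 (control/historical);
  a null variant sets both to 0.4.
* **Dose curves**: default truth tox = (0.02, 0.06, 0.12, 0.20, 0.35,
  0.50), ORR = (0.15, 0.30, 0.50, 0.60, 0.65, 0.67) — chosen so that
  exactly doses 3 and 4 are safe (tox ≤ 0.25) and effective (ORR > 0.4),
  doses 1–2 ineffective, doses 5–6 unsafe. The non-monotone variant peaks
  response at dose 3 while dose 4 remains the MTD.
* **Biomarker curve**: ORR₁(x) = expit(logit(0.4) + 4·(x − 0.6)) — a
  logistic curve crossing the flat 0.4 control rate exactly at x = 0.6, so
  patients above 0.6 benefit and patients below do worse; the slope 4 puts
  the mean experimental response in the benefiting subgroup near 0.6,
  matching the effect size used elsewhere in the package. Curve parameters
  are package fixtures constrained by those qualitative requirements, not
  measured values, and are fully configurable.
* **Enrollment model**: 4 patients/month (first trial), 10/month (second),
  6-month between-trial gap, 6-month assessment window per trial —
  planning-grade defaults, configurable.

What the generator does *not* emulate: patient dropout, accrual ramp-up,
non-uniform biomarker distributions, correlation between response and
toxicity within patients, and drift between trial populations. Passing
tests therefore demonstrate the designs' behavior under clean stylized
conditions, not performance guarantees on real trials.

## Numerical choices

* Binomial and hypergeometric tails come from scipy's survival functions;
  p-values exactly at α reject, with a 1e-12 epsilon guarding float
  round-off only.
* The CRM posterior integrals use a fixed 4001-point Simpson rule on
  β ∈ [−10, 10] (≈7.5 prior SDs) with cached per-skeleton dose-probability
  tables, so one refit is two 6×4001 matrix products. Accuracy is checked
  in the tests against an independent 100,001-point trapezoid quadrature
  (agreement < 1e-6 across random data fixtures); an adaptive quadrature
  would be interchangeable but is orders of magnitude slower at
  simulation scale. The log-weight is max-shifted before exponentiation;
  a non-finite or zero normalizer raises a dedicated numeric error.
* Dose/cutoff ties are resolved with a 1e-12 tolerance toward the lower
  dose / larger population.
* Replicate i of a run draws from `SeedSequence(seed, spawn_key=(i,))`:
  estimates are independent of batching or parallelization and runs are
  bit-reproducible. Sweeps reuse the same streams across grid points
  (common random numbers), sharpening between-point contrasts.

## Default problem sizes

Simulation scale defaults to 10,000 replicates (Monte-Carlo SE ≤ 0.5
percentage points on probabilities); the test suite uses 10,000 replicates
for the segment-level checks with analytic cross-checks (semi-analytic
decomposition of Segment A power; closed-form phase II positive rate in
Segment B) and smaller replicate counts (typically 1,000–2,000) for
CRM-heavy regressions, where each trial refits the posterior after every
patient.

## Known limitations

* Segments contain exactly two trials; longer chains are out of scope.
* Second-trial sizing uses point estimates only; interval-based sizing is
  a deliberate non-goal (the config exposes no hook for it yet).
* The enrichment interim rule is one member of a design family; its
  selection probabilities are package regression values, not canonical
  quantities.
* Exact unconditional Fisher power at the default cap costs O(n²) per
  evaluation; caching keeps full runs at seconds-scale, but very large
  caps (≫ 400 total) would need a different strategy.
* With the standard exact-test convention, a 30-patient single-arm phase
  II has 71.5% power for 0.4 vs 0.6 at one-sided 0.05 (critical value
  17); conventions that report 80% at this size correspond to a larger
  rejection region (size ≈ 0.10) and yield materially higher downstream
  enrollment. This package uses the size-controlled convention throughout.
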