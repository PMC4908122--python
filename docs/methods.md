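# Methods

## The paradigm model

The trial schedule generator reproduces a two-day differential
conditioning protocol. Day 1 holds a conditioning phase — two CS+ types
partially reinforced by a US delivered immediately at CS offset (no
delay), and a never-reinforced CS− — followed by an extinction phase
(CS+E and CS− only) after an inter-phase gap; day 2 is a recall phase
with all three CS types and no US. The CS+E trials form a first
contiguous block and the CS+U trials a second one ("the switch"), with
CS− trials spread evenly through both blocks by a Bresenham-style
merge. This makes "the first CS− after the switch" — a trial excluded
from differential conditioning because responses to it are contaminated
by the contingency change — structurally well defined: it is the first
CS− whose onset follows the first CS+U presentation.

Trial counts and timings are configurable; the defaults are 8
presentations of each CS+ with 5 reinforced (exactly 62.5% partial
reinforcement), 16 CS− in conditioning, 16 CS+E / 16 CS− in extinction,
8 of each type at recall, 6 s CS, 0.5 s US, inter-trial intervals
uniform on 12–18 s, and a 60 s gap before extinction. Which CS+
presentations carry the US is a seeded draw that avoids the first
presentation whenever possible (first presentations are excluded from
analysis anyway). Whether CS+E/CS+U order is counterbalanced across
subjects is not modelled; the E-before-U order is fixed.

## Trial scoring

A trial's response amplitude is trough-to-peak: the maximum conductance
over the stimulus interval (closed at both ends at sample resolution;
ties broken by the first sample) minus the mean over the 2 s
immediately preceding onset (`[onset − 2 s, onset)`). For the US the
peak search window is `[US onset, US onset + 6 s]` (configurable).
Scores are floored at 0 by default because the ERI applies a square
root per trial; flooring can be disabled to inspect raw values.

Traces are median-filtered before scoring (0.5 s kernel by default,
rounded up to an odd sample count, reflected edges). The kernel width
is a package choice: it removes single-sample artifacts without
blunting phasic peaks at 10 Hz.

Two numerical properties are asserted in the tests: scores are
invariant to adding any constant to the trace, and a pure linear drift
of d µS/s biases a score by at most `d · (duration + 1 s)` plus half a
sample of window-center discretization.

## Subject quality control

Inclusion requires, at both visits: (a) recorded, undistorted data for
the phases of interest; (b) a US reaction ≥ 0.05 µS; (c) a conditioned
CS+ response ≥ 0.05 µS. Criterion (a) is driven by external
availability flags — the package does not try to detect "obvious
distortions" automatically. Criteria (b) and (c) use the maximum score
across conditioning trials ("exhibited a reaction" read as at least
one supra-threshold response, the most permissive consistent reading).
Failures accumulate: a subject can fail several criteria, each
annotated with the failing visit.

## Endpoints

**ERI.** `100 − 100 · mean(√r1, √r2) / max_j √c_j` with `r1, r2` the
first two CS+E recall trials in presentation order and `c_j` the
conditioning CS+E scores. "The square root of each value" is read as a
per-trial transform before averaging (the denominator is unaffected
since max of √ equals √ of max); the alternative reading
(`√` of the recall mean) is available via `numerator_mode="sqrt_of_mean"`.
No trial exclusions are applied to the conditioning maximum. A zero
conditioning maximum makes the ERI undefined (error at the operation
level; recorded as missing by the pipeline).

**Differential conditioning.** Mean CS+ (E∪U) minus mean CS− over
conditioning, excluding the first presentation of each stimulus type
and the first post-switch CS−. Raw (untransformed, though floored)
scores are used — the square-root transform belongs to the ERI only.

**Weighted tract FA.** `Σ wᵢ FAᵢ / Σ wᵢ` over a precomputed per-voxel
table (FA in [0, 1], likelihood weights ≥ 0, at least one positive).
Tractography itself is out of scope; the operation consumes voxel
tables only.

## Inferential layer

With two occasions, the group × time interaction of a repeated
measures ANCOVA equals the between-group effect in a linear model of
the change score (post − pre) on group plus the between-subject
covariates; `ChangeScoreAncova` implements exactly that and the test
suite verifies the equivalence against a brute-force long-format
cell-means model (subject dummies + time + covariate×time +
group×time) on random datasets. Covariates (age, days between scans by
default) are mean-centered, which leaves the F unchanged. The F
carries (1, n − k) degrees of freedom, k counting model columns;
the effect size is partial η² = SS_effect/(SS_effect + SS_error).
Reported df follow this convention explicitly rather than imitating
any particular software's repeated measures bookkeeping.

Paired t-tests are classical two-sided tests on post − pre (zero
variance of differences is a degenerate-data error, not t = 0).
Baseline group comparisons are one-way ANCOVAs on the pre-visit
endpoint. Partial correlations residualize both variables on the
covariates (plus intercept) and use n − 2 − k df in the t transform;
an x that is an exact linear function of the covariates leaves a zero
residual and is rejected as degenerate. Practice-hour regressions
report the standardized slope; missing daily practice logs are imputed
with the individual's mean over available logs before totalling.
Missing endpoint data are handled by listwise deletion per analysis.
No multiplicity correction is applied anywhere; every summary and the
pipeline report print this caveat.

## The synthetic cohort generator

The generator is the package's test bed: a forward model of tonic
level (lognormal across subjects, median 8 µS), linear drift
(SD 0.03 µS/min), Gaussian sensor noise (0.01 µS), and phasic
responses of canonical shape — a peak-normalized difference of
exponentials with 0.75 s rise, 3 s decay and 1.5 s latency — scaled
per event: US events by the subject's unconditioned-response
amplitude, conditioning CS+ trials by the visit's conditioned
amplitude, extinction CS+E trials by an exponential decay (half-life 4
trials), recall CS+ trials by the visit's retention fraction, CS−
trials by the orienting amplitude. Default sampling rate 10 Hz.

Subject amplitudes are lognormal (positivity and skew typical of SCR),
CS+ median 0.46 µS. The unconditioned amplitude is drawn as the
subject's CS+ amplitude times a lognormal ratio (median 3): responses
scale with individual reactivity, and because the US baseline window
sits on the decaying CS+ response, a ratio comfortably above the
worst-case baseline contamination is what guarantees that every
responder clears the 0.05 µS US criterion — an invariant the QC tests
assert. Non-responders get US and CS+ amplitudes of 0.015 µS, below
threshold even after noise; the default non-responder rate is 0.35,
matching the fraction of recorded subjects that criteria (b) and (c)
remove in studies of this design.

Group × time structure is programmed as differences-in-differences:
controls' conditioned amplitude drops by `effect_cr_interaction`
(default 0.32 µS, floored at 0.08 µS so control subjects remain
scoreable) while the trained group's is maintained, both with
subject-level jitter (SD 0.1 µS); retention fractions start near 0.46
(trained) and 0.074 (control) — i.e. ERIs near 32% and 73% — and move
by +0.03 in controls plus `effect_eri_interaction` (default −0.35) in
the trained group, reproducing a trained-group ERI rise to ~63%
against stable controls. FA changes are drawn bivariate-normally
against the latent CS+ amplitude change to hit a target correlation
(default 0.42) around group mean changes of +0.008 (trained) and
+0.002 (control) on a 0.46 baseline; per-voxel tables (gamma-distributed
likelihood weights, normal FA) are shifted so their weighted mean equals
the subject-visit target. Questionnaire totals (PSS, DERS, MAAS ranges)
are linear in total practice hours at post for trained subjects and
independent of practice at pre. Everything is a pure function of the
spec's seed; identical seeds give bitwise-identical cohorts.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: habituation of the orienting
response, respiration/motion artifacts beyond white noise,
error-driven (trial-by-trial) learning dynamics, non-stationary tonic
activity, and electrode drift beyond a linear term. One emulated
feature deserves note: with closely spaced trials the phasic responses
overlap, so trough-to-peak scores are attenuated by a few percent
relative to programmed amplitudes (and CS− scores can floor at 0 in
the compressed simulation paradigm). This is a property of the scoring
rule applied to overlapping responses, not a scorer defect; scorer
fidelity (2% round-trip tolerance) is therefore assessed on traces
with non-overlapping responses.

## Simulation sizes

Monte-Carlo checks use a compressed paradigm (3 CS+ per type, 2
reinforced, 6 CS−, 4 s CS, 3–5 s ITIs, conditioning phase only) that
preserves the schedule's structure at a fraction of the trace length.
The type-I error of the interaction test is estimated from 1000 null
cohorts of 10 subjects per group (band [0.03, 0.07] at α = 0.05);
power monotonicity uses 40 replicates at 10/25/50/100 subjects per
group with a 0.06 µS programmed effect; correlation and effect
recovery use one 200-per-group cohort at low noise; determinism is
checked on a 2 × 50 cohort written to disk and analysed twice.

## Known limitations

- The ERI numerator reading (mean of roots vs root of the mean) is
  genuinely ambiguous in the field; both are implemented, the default
  is the per-trial reading, and analyses should state which they used.
- The change-score ANCOVA equals the repeated measures interaction
  only for exactly two occasions; more time points are out of scope.
- Criterion (a) depends entirely on external quality flags.
- Generator distributions are stated defaults, not values fitted to
  any dataset; parameter-recovery results certify the pipeline's
  internal consistency, not field validity of the defaults.
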