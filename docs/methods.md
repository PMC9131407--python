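# Methods

## The task and the measurement model

The pipeline analyses a spontaneous visual perspective-taking experiment built
on the classic mental rotation task.  A participant judges whether an
alphanumeric character (4, P, or R), shown on a table at one of eight
orientations θ ∈ {0°, 45°, …, 315°} (0° = upright to the participant, angles
counter-clockwise), is canonical or mirror-inverted.  On two-thirds of trials
another person sits at the table, viewing it from an azimuth of 90°
(person-left) or 270° (person-right); on half the blocks the participant's
head/body movement is restricted with a chinrest.  A session is 4 blocks × 144
trials in ABAB movement order; within each movement condition every
location × character × form × orientation combination appears exactly twice
(once per actor sex), giving 576 trials and 48 distinct stimulus identities.

Recognition time is modelled per participant as additive mental rotation from
two viewpoints:

    RT = γ + β_self · d(θ, 0°) + β_other · d(θ, φ_person) · 1[person present]
           + δ_move · 1[restricted] + ε,

where d(θ, φ) = min(|θ − φ| mod 360, 360 − |θ − φ| mod 360) is the angular
disparity in degrees (so slopes are in ms/degree), and ε is trial noise.
Because the persons sit perpendicular to the participant, d(θ, 0) and
d(θ, φ_person) are *exactly* orthogonal over the 16 person-present design
cells; the dual-viewpoint regression therefore returns the same coefficients
as two simple regressions, which the tests verify to machine tolerance.

## Bias projections

Each participant × condition profile of eight per-orientation mean RTs is
summarised by two orthogonal projections:

* towards/away bias = (1/8) Σ_θ RT(θ) · (−cos θ) — positive when away-facing
  items are slower (the mental rotation effect);
* left/right bias = (1/8) Σ_θ RT(θ) · (−sin θ) — positive when left-facing
  items are faster.

For a profile exactly linear in a viewpoint's disparity, either projection
returns the slope times the gain (1/8) Σ_θ d(θ)(−cos θ) = 38.40990…, the same
constant for the participant's and the 90°/270° viewpoints.  The two verbal
descriptions of the left/right sign convention in the source literature are
mutually inconsistent (they differ by a global sign); we adopt the convention
under which the bias becomes more positive with a person seated on the left,
which matches the reported group results.  The perspective-taking score is
lr_bias(person-left) − lr_bias(person-right), so a positive score indexes
spontaneous adoption of the other's viewpoint, and equals
2 × 38.410 × β_other for noiseless linear data.

Biases are computed from per-orientation *mean* profiles rather than
trial-level projections (equivalent under a balanced design, more robust
after trial exclusions), and pooled-condition biases are means of the two
movement-condition biases rather than recomputed from pooled trials.

## Preprocessing

Participants whose overall error proportion strictly exceeds 20% are excluded
(computed on raw responded trials, before RT trimming).  The RT stream keeps
correct responses with 150 ms ≤ RT ≤ 2000 ms, boundaries inclusive (removal is
of trials strictly *outside* the window); the error stream keeps all responded
trials and is not RT-trimmed.  Incomplete orientation profiles are flagged and
skipped by downstream statistics rather than imputed; under the balanced
design this is rare.

## The synthetic cohort generator

No raw data accompany the study the pipeline emulates, so a generator
reproduces its statistical structure and makes every stage testable.  Defaults
(all configurable in `CohortConfig`):

| parameter | default | why |
|---|---|---|
| n_recruited / n_lapse | 79 / 18 | recruitment arithmetic: 61 retained after the 20% cutoff |
| β_self mean, SD | 1.39, 0.566 ms/deg | group mean as reported; SD = mean·√61/t with t = 19.181 |
| β_other mean, SD | 0.38, 0.412 ms/deg | as above with t = 7.209 |
| γ mean, SD | 750, 80 ms | baseline RT unreported; plausible values for speeded classification, configurable |
| δ_move | +15 ms | small additive restricted-block shift so the movement factor is exercised but negligible, matching the reported near-null movement effect |
| noise | ex-Gaussian σ = 60, τ = 100 ms | standard RT noise family; chosen so the cohort towards/away-bias SD lands near the reported 22.09 ms given the slope SDs |
| response window | clip to [150, 3500] ms | floor truncation and response-deadline censoring |
| p_error | 0.08 (lapse: U(0.25, 0.40)) | 8% average errors; lapse draws are kept above 0.25 so that a lapser's *observed* error rate over 576 trials exceeds the 20% cutoff with near-certainty (at p = 0.21 the binomial observation falls below the cutoff ~29% of the time, which would break the 79 → 61 arithmetic) |
| error model | orientation-independent | reported error-rate biases are small and unreliable; an optional per-degree error slope exists for stress tests |

Questionnaire scores are tied to each participant's *true* β_other (the
generative perspective-taking propensity) through a Gaussian copula: each
trait's latent normal correlates with the standardised propensity at its
target (age +.38, STQ-STA −.26, AQ and IRI 0) and is then mapped to its
marginal — age discrete 18–35 with a geometric (decay 0.72) skew toward young
adults (mean ≈ 20.6), AQ truncated normal (16.64, 6.29) on 0–50, IRI truncated
normal (68.45, 11.34) on 0–112 split into four subscales by largest remainder,
STQ-STA Binomial(37, 0.30).  Because the targets attach to the *latent*
propensity, correlations with the *estimated* perspective-taking score are
attenuated exactly as estimation noise attenuates them in real data; the
attenuation is measured by simulation, never assumed.  Three retained
participants lack questionnaire totals (age, known from recruitment, is always
present), reproducing the 58 complete cases implied by the reported
hierarchical-regression dfs.

What the generator does *not* emulate: sequential/fatigue effects,
speed–accuracy coupling, actor-sex effects, RT nonlinearity in disparity, and
trait–trait correlations beyond those induced through the shared propensity.
Passing recovery tests therefore shows the pipeline is correct and calibrated
under the stated model, not that the model exhausts real data.  One known
consequence: a strictly linear generator cannot jointly reproduce the reported
dual-regression slope (1.39) and the slightly steeper reported *simple*
regression slope (1.5), which reflects real-data nonlinearity; the pipeline
reports whatever the data produce.

## Inference

t-tests and Pearson correlations use scipy; the repeated-measures ANOVA is
delegated to pingouin, with partial η² recomputed as F·df1/(F·df1 + df2) and
Greenhouse–Geisser ε/corrected p attached for factors with ≥ 3 levels
(uncorrected p is primary, as in the emulated analyses).  Bayes factors follow
JASP defaults: the one-sample JZS BF integrates the Cauchy(0, √2/2) prior in
its inverse-gamma g representation by adaptive quadrature (relative tolerance
1e−8; cross-checked in tests against pingouin and a Monte-Carlo
prior-integration oracle); the correlation BF uses the exact stretched-beta
(κ = 1) formulation with the hypergeometric likelihood, integrated in log
space so large-n evidence does not overflow.  ANOVA-level inclusion Bayes
factors (g-prior model averaging) are out of scope and printed as "n/a".

Power: the minimal detectable d inverts the noncentral-t power function by
bisection (the one-tailed α = .05 value at n = 61 is 0.32, the two-tailed
0.36); minimal detectable correlations use the Fisher-z closed form.  The
published correlation power values (.25/.23 at n = 61) are not reproducible
under either Fisher-z or exact noncentral methods (both give ≈ .35/.32) and
are treated as an error in the source; the implemented methods are documented
here instead.

Numerical conventions: disparities stay in degrees everywhere; regressions use
unweighted cell-mean RTs ("item mean RTs"); no-person trials are excluded from
the dual fit (no other-disparity is defined); degenerate inputs (zero
variance, incomplete cells, collinear blocks) raise errors rather than
returning silently wrong numbers, and the pipeline logs and skips the affected
stage.

## Problem sizes used by the test suite and acceptance script

Recovery checks simulate full-size cohorts (79 × 576 trials).  The acceptance
script averages cohort means over 8 independent replicate cohorts (seeds
derived from the command-line seed) to reduce the Monte-Carlo error of the
estimated expectation — a single 61-participant cohort mean has SE ≈ 0.053 on
β_other, comparable to the quantity itself.  Null calibration of the
perspective-taking test uses 500 replicate cohorts through a vectorised
harness that exploits the exact annihilation of all deterministic RT
components by the sine projection, so only trial noise and error thinning are
simulated; biases and t-tests still go through the package's own functions.

## Known limitations

* The AQ/IRI scoring keys shipped as defaults are synthetic stand-ins with the
  published keys' structure (26 agree-keyed AQ items, 9 reverse-keyed IRI
  items, 7-item subscales); real data need the published keys passed in.
* The generator's lapse mechanism is a uniform elevated error rate, not a
  mixture of attention states within a session.
* Greenhouse–Geisser correction is the only sphericity handling; no
  multivariate alternatives.
* Error-rate biases are computed and tabulated but, matching their small
  reported magnitudes, no acceptance-level claims attach to them.
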