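# Methods

## The estimation model

Paired-comparison valuation data are modelled under Thurstone's law of
comparative judgment (Case V).  Each health state *i* has a latent severity
β<sub>i</sub>; a respondent shown the ordered pair (first, second) judges the
first person healthier with probability

    P(first healthier) = Φ(β_second − β_first).

Responses are pooled across respondents and tasks with no respondent random
effect, which matches how such studies analyse the data.  The likelihood is
that of a probit regression with a signed incidence design: one row per
response with +1 in the first-listed state's column and −1 in the second's,
outcome 1 iff the first state was chosen.  Only contrasts of β are
identified, so one reference state is fixed at 0; the reference defaults to
the most frequently compared state, and anchored weights are invariant to
the choice (tested by refitting with a different reference).  Larger β means
more severe, aligning the latent scale with the disability-weight scale.

Estimation is exact Newton iteration with step halving on the probit
log-likelihood, restricted to the comparison-graph component containing the
reference; states outside it are reported as disconnected rather than
fitted.  Convergence: |ΔlogL| < 1e−8 or gradient norm < 1e−6, at most 100
iterations.  Standard errors come from the observed information (verified
against an independent discrete-probit implementation in the tests).
Complete separation — a state judged healthier in all or none of its
comparisons, which small simulations do produce for extreme states — makes
the MLE diverge; when detected, a weakly informative ridge penalty of
strength 1e−4 is added and recorded in the fit metadata.

## Anchoring and uncertainty

The latent coefficients are located on the 0-to-1 scale by a loess of
logit(reference weight) on β over the anchor states (states carrying a
published reference weight), then predicting logit-weights for all states
and back-transforming with the inverse logit.  The regression direction —
logit-weight as response, β as predictor — is the one that yields
predictions on the weight scale.  Loess uses the conventional
parameterization: tricube weights over a nearest-neighbour window covering
a `span` fraction of the anchors (default 0.75) and local polynomial degree
1 (default; exact on collinear data) or 2.  At least 10 anchors are
required; reference weights of exactly 0 or 1 are clipped by 1e−6 before
the logit; predictions outside the anchor β range use the boundary local
polynomial and are flagged as extrapolated rather than clamped.

Uncertainty propagates by a parametric bootstrap (default 1000 replicates):
each replicate redraws every state's coefficient from Normal(β̂, SE), refits
the loess on the anchor states' redrawn coefficients, and predicts all
states at their redrawn coefficients.  This interprets "means defined by the
predicted coefficients and variance by their standard deviation" as
per-state normal sampling on the coefficient scale — the only per-state
spread the pipeline produces; bootstrapping respondents with a full probit
refit would be a possible extension but is not what the procedure describes.
The point estimate is the inverse logit of the mean logit-scale replicate
prediction; averaging the back-transformed weights instead is available as
a sensitivity switch.  The 95% uncertainty interval is the 2.5th–97.5th
percentile of the replicate weights; percentile construction does not
guarantee the point estimate falls inside the interval, and refitting on
redrawn anchors carries a small smoothing bias, so interval coverage is
checked in the tests only against a loose 80% bound.

## Test-retest reliability

The survey repeats the pair of one early task at a later task, in the same
or reversed presentation order.  Consistency probabilities are computed
from raw counts of respondents choosing the same health state twice.
Cohen's κ uses the 0.5 chance level of a binary forced choice, so
κ = 2·p<sub>o</sub> − 1.  For reverse-order repeats κ is computed on
*positional* agreement (choosing the same state in reversed order counts as
positional disagreement); this is the convention that gives a strongly
state-consistent cohort a negative reverse-order κ, as reported in such
studies.  Published figures for the reverse pair (0.727, κ = −0.453) differ
by 0.001 from the value implied by the rounded consistency
(1 − 0.727 → κ = −0.454), presumably because unrounded inputs were used;
this implementation always computes from raw counts.  Verbal agreement
bands follow the usual scale (0.41–0.60 moderate, etc.).

## The synthetic survey

The real survey data is access-restricted, so the simulator emulates the
study design end to end: 3994 respondents by default, 18 tasks each, pairs
drawn uniformly from all unordered state pairs with uniformly random
presentation order, the 2nd pair repeated at the 15th task (same order with
probability 0.481, the observed share), and demographics drawn
independently per attribute from the study sample's marginal distributions
(including the 0.2% "other" gender category).  Ground-truth latent
severities are logit(true weight), so the simulated pipeline is
self-consistent with the anchoring model's logit link.

Choice noise is a single discrimination scale σ:
P(first healthier) = Φ(Δlatent/σ).  By default σ is **calibrated** so that
the expected same-order repeat consistency over all unordered catalog pairs,
E[p² + (1−p)²] with p = Φ(Δ/σ), equals the observed 0.741 (κ = 0.482); for
the packaged 203-state catalog this gives σ ≈ 1.431, and simulated surveys
reproduce κ ≈ 0.48 without further tuning.  A `subgroup_shift` parameter
perturbs one demographic level's latents by a fixed per-state normal draw
(0 = exchangeable population, the null under which subgroup correlations
approach 1); an optional per-respondent lognormal noise multiplier exists
but defaults off, matching the pooled estimation model.

What the simulator does *not* emulate: panel attrition, response times,
straight-lining, order effects within a session, or any balancing of how
often each state appears (real pair assignment may have balanced appearance
counts; uniform sampling is an assumption).  Passing recovery tests
therefore show the estimation machinery is correct under the stated choice
law, not that the law captures every feature of human panels.

## Subgroup and cross-set analyses

Subgroup homogeneity refits the probit separately per level of a respondent
attribute (shared reference state) and reports pairwise Spearman
correlations of the coefficient vectors over the states estimated in every
level (the intersection size is reported).  Levels with fewer than
`min_cell` respondents (default 30) are excluded with a warning —
`min_cell` counts respondents, not responses, because a handful of
respondents cannot support a 200-state fit no matter how many rows they
contribute; this removes the sub-percent "other" gender level at study
scale.  Spearman uses midranks for ties.

Two weight sets are compared over matched state ids by Spearman correlation,
a two-sided Wilcoxon signed-rank test (zero differences dropped; exact null
for n ≤ 25 without ties, continuity-corrected normal approximation
otherwise), medians/IQRs, and the count of set-A point estimates outside
set-B's 95% interval, split into below/above and tallied per disease
category.  The European weight table needed to reproduce the published
cross-study headline numbers is external data and is not packaged; the
comparison accepts any estimates CSV in the documented schema.

## The packaged weight table

The fixture `data/table2.csv` is a transcription of the published Dutch
disability-weight table: 203 rows with point estimates and 95% uncertainty
intervals, from 0.007 (mild distance vision impairment) to 0.741 (intensive
care unit admission), with disease-category labels and slug ids assigned by
this package (the table names states only in prose; the CSV documents the
name → id mapping).  The study valued 210 states, seven of which were
experimental and not part of the published weight set.  Note the study's
prose reports 57 states below 0.05 while the printed table contains 61;
the package computes all such counts from the table itself.  When used as a
simulation catalog, the published point estimates serve as both ground
truth and anchor values, and all rows carry origin `prior_study` because
the per-state prior/new split is not printed.

## Problem sizes used by the tests

Module tests run on catalogs of 2–51 states and surveys of up to ~1500
respondents; the end-to-end recovery and subgroup-homogeneity checks run
one shared full-scale survey (3994 × 18 over the 203-state catalog,
calibrated σ, fixed seed) and assert rank correlation ≥ 0.95 with the
generating weights and ≥ 0.95 between gender levels (both observed ≈ 0.99).
Interval-coverage sanity uses 50 seeded surveys of 120 respondents over a
20-state catalog spanning the severity range, with 300 bootstrap
replicates.  The whole suite completes in well under a minute.
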