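# Methods

## Disproportionality model

Each drug–ADR pair is reduced to a 2×2 table of distinct report counts
(a drug or ADR repeated within one report counts once). The expected
count under independence is

    E = (n00 + n01)(n00 + n10) / n++ ,

the product of the with-drug and with-ADR margins over the grand total —
the baseline of the relative reporting ratio. A `strict_margins` switch
instead uses the without-ADR column (n01 + n11) for the second margin;
it exists purely for auditability, since that convention makes E the
expectation of a drug-without-ADR cell and is not a sensible baseline.

The observed count is modelled as Poisson with mean λE and λ carries the
5-parameter two-gamma mixture prior (shape/rate parametrisation)

    λ ~ w·Ga(α₁, β₁) + (1 − w)·Ga(α₂, β₂).

The marginal distribution of the count under one component is negative
binomial; we implement it through log-gamma functions with n! generalised
to Γ(n + 1), so the same density scores the fractional counts produced by
cumulative Monte-Carlo averaging. The posterior of λ given n00 is the
two-gamma mixture with updated parameters (αᵢ + n00, βᵢ + E) and
posterior weight

    Qₙ = w f₁ / (w f₁ + (1 − w) f₂),

and all posterior summaries use Qₙ (not the prior weight w) on the
components. EBlog2 = E[log₂ λ | n00] has the closed digamma form; EBGM =
2^EBlog2; EB05/EB95 are mixture quantiles found by vectorised bisection
between the two component quantiles (interval shrinks by 2⁻ᵏ per step,
far below the 1e-9 relative target). All densities and weights are
computed in log space with log-sum-exp; no ratio can hit 0/0.

### Prior estimation

The paper-stated prior is the mixture; how it is estimated is not
specified, so the package maximises the marginal likelihood
Σ log[w f₁ + (1 − w) f₂] with L-BFGS-B on transformed coordinates
(logit w, log α₁, log β₁, log α₂, log β₂). Defaults: the canonical
starting point (w = 1/3, α₁ = 0.2, β₁ = 0.1, α₂ = 2, β₂ = 4) plus two
jittered restarts under a fixed seed to dodge local optima; an explicit
`init` makes the fit a single deterministic run from that point. The log
coordinates are bounded at ±12: the likelihood can be flat in the
direction (α, β) → ∞ at fixed α/β (a component degenerating to a point
mass), and the bound keeps the log-gamma terms well conditioned while
changing the attained likelihood only in the flat tail. On data whose
true λ distribution is nearly discrete — including the synthetic
generator's worlds, where λ takes a few planted values — the fitted
components legitimately become near-point-masses; ranking quality is
unaffected because EBlog2 still varies smoothly through Qₙ.

## MCEM confounder filtering

Iteration 0 fits and scores plain co-occurrence counts. Each subsequent
iteration:

1. samples, for every (report, ADR) occurrence, one major drug with
   probability proportional to max(score, floor) over the drugs in that
   report (floor 1e-6, so a pair absent from the score table or driven
   to zero can still be drawn — no lock-in);
2. rebuilds n00 from the assignments — either the current draw
   (`last_sample`, textbook MCEM with Monte-Carlo sample size 1) or the
   running mean of all post-burn-in draws (`cumulative_mean`, the
   default with burn_in = 1), which damps Monte-Carlo noise at the cost
   of fractional counts;
3. refits the prior, initialised at the previous optimum, and rescores.

Margins and E never change — only n00 is redistributed among the drugs
of each report, so per-ADR count mass is conserved exactly at every
iteration. The stopping rule compares consecutive attained marginal
log-likelihoods against `tol` (default 1e-3, matching the usual
heuristic range 1e-3…1e-5). Under `cumulative_mean` the counts move
O(1/t) per iteration, so the objective plateaus slowly and `max_iter`
(default 30) is the practical stop on large databases; non-convergence
is reported in the trace, never fatal. The drug sampled is scored by
EBGM by default; a switch allows EB05. If an iteration reproduces the
previous counts exactly (e.g. every report has one drug, so assignments
are forced), the prior is reused and the loop terminates — making the
degenerate case bit-identical to plain MGPS.

## Signal combination

Scores enter on the log₂ relative-risk scale: SRS signals as EBlog2 with
variance equal to the posterior variance of log₂ λ under the mixture
(trigamma component variances plus the between-component spread of the
log means), claims-like sources as log₂ RR with the variance they
declare. The Gaussian hierarchy needs an unbounded, roughly symmetric
scale, which λ itself is not.

The per-pair summary first pools a pair's scores within each source by
inverse-variance weighting, then across sources with weights equal to
the reciprocal of each source's mean score variance, normalised to sum
to one over the sources that actually observed the pair; σ_l² follows by
variance propagation through the convex combination. A literal
(unnormalised) variant of the across-source formula is available behind
`strict_eq10` for audit; as printed it is not a convex combination and
its inner summation indices do not evaluate, so the prose description is
the implemented form. θ and τ² are estimated by EM on the summaries
(E-step: posterior moments of each φ_l; M-step: their means), tolerance
1e-8, τ² floored at 1e-12 so shrinkage weights stay defined when the
summaries carry no spread.

The population matters: `combine_sources(pairs="union")` keeps every
pair any source scored (weights renormalised over observed sources),
while `pairs="intersection"` — what the pipeline uses — restricts to
pairs scored by every source. When one source covers only a small
curated pair list, fitting τ² on the union lets tens of thousands of
single-source background pairs dominate, drives τ² toward zero, and
shrinks exactly the high-evidence pairs (whose posterior variance is
largest) into the grand mean; the intersection estimates the hierarchy
on the population actually being combined.

## Evaluation

AUC is the Mann–Whitney rank statistic with ties counted ½ (computed via
scikit-learn; tests verify it against exhaustive concordant-pair
counting). Reference pairs that never co-occurred and so have no score
are assigned the minimum observed score minus a small epsilon — absence
of evidence ranks last for every method symmetrically — or excluded via
a flag. Signal calls use strict inequality (EB05 > 2); precision is
reported over called pairs present in the reference and flagged
undefined when none are. Per-ADR AUCs and their mean are emitted
alongside the pooled AUC; the detection timeline reports the first year
a rule fires for a pair.

## Synthetic study conditions

The generator emulates the statistical structure of spontaneous
reporting that the method targets, at desk scale. Defaults: 20 000
reports over 200 drugs and 50 ADRs; 48% of reports mention 2–4 drugs;
with probability 0.9 a report's drugs come from one of 50 co-prescription
clusters of 4 (the confounding mechanism — cluster-mates of a causal
drug inherit its association), otherwise uniformly from the vocabulary.
Every ADR occurs spontaneously in any report at rate 0.004; each of the
25 planted causal pairs (distinct drugs, distinct ADRs, so every ADR
occurrence has at most one causal drug) adds excess probability
rate × (RR − 1) when its drug is present, making the pair's total
occurrence rate ≈ rate × RR and RR = 1 exactly the null model. Planted
RR defaults to 5. Caused events are dropped with probability 0.25
(under-reporting) before being recorded; reports with no remaining ADR
are discarded and regenerated, as a report only exists because something
was reported. Reporters record a primary suspect for half of the caused
events, correct 70% of the time. These rates put per-pair counts in the
low single digits — the sparse regime where shrinkage and confounding
actually bite and where the filtering has something to fix; with denser
rates every method saturates and comparisons are uninformative.

The per-outcome reference standard mirrors curated standards: each
planted pair is a positive for its ADR, and the `negative_ratio` (3)
most co-reported non-causal drugs for the same ADR are the negatives —
plausible suspects, dominated by the cluster confounders. Source-score
tables for the combination stage are the true log₂ RR plus Gaussian
noise with per-source standard deviations (1.0, 1.5), the declared
variance being the noise variance, so source reliabilities differ by
construction.

What the generator does **not** emulate: FAERS marginal frequencies and
vocabulary sizes, MedDRA term hierarchies, duplicate case versions,
longitudinal claims structure, drug–drug-interaction ADRs, or
cohort-specific reporting. Passing tests therefore demonstrate the
machinery's correctness and the direction of its benefits under the
stated generative assumptions, not performance on any real database.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full conditions above
(20 000 reports; the confounder-suppression check averages 20 replicate
worlds with MCEM capped at 10 iterations; the prior-fit check uses 5 000
pairs; hyperparameter recovery uses 2 000 summaries). Quadrature oracles
integrate with relative tolerance 1e-11 because posterior normalising
constants at large counts are ~1e-11 in magnitude. All randomness flows
from explicit seeds; the pipeline expands one global seed into
independent per-stage substreams so adding a stage never perturbs
another stage's draws.

## Known limitations

- Classic MGPS stratifies E by age/sex/report-year and scores
  higher-order drug itemsets; this package computes one table per pair
  and two-way associations only.
- The MCEM stopping rule is heuristic; under `cumulative_mean` the
  objective plateaus as O(1/t) and the loop usually ends on `max_iter`.
- The combination model treats pair summaries as exchangeable draws from
  one Gaussian hierarchy; there is no per-outcome or per-source random
  effect.
- Under-reporting is modelled as independent thinning of caused events;
  real reporting propensity varies by drug, event severity and year.
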