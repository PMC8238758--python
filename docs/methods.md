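# Methods

## Response models

Both ROC models describe an observer who places a latent memory-strength
draw against `B − 1` strictly ordered criteria to produce a confidence
response on a `B`-point scale (1 = sure new … B = sure old; responses
above the scale midpoint are "old" decisions).

**DPSD.** New items draw strength from `N(0, 1)`. Old items are
recollected with probability `Ro ∈ [0, 1]`; a recollection is all-or-none
and is mapped to the most-confident "old" bin. Non-recollected old items
draw from `N(d', 1)` with `d' ≥ 0` (familiarity is a positive-evidence
process in this model). Cumulative response probabilities:

    P(resp > c_j | old) = Ro + (1 − Ro)(1 − Φ(c_j − d'))
    P(resp > c_j | new) = 1 − Φ(c_j)

**UVSD.** A single strength dimension: old items draw from `N(d', Vo²)`
with `Vo > 0` and unconstrained `d'`; new items from `N(0, 1)`.

Setting `Ro = 0` in DPSD and `Vo = 1` in UVSD gives the same equal-variance
model; this equivalence is verified to 1e-8 in the tests and holds by
construction in the likelihood code.

## Likelihood, fitting, and model comparison

The sufficient statistic is the 2×B rating-count table. The likelihood is
product-multinomial: old and new rows are independent multinomials given
the parameters. Reported `logL` is the multinomial kernel
`Σ O·log p` (the combinatorial coefficients cancel in every comparison the
package makes — G, BIC differences, likelihood-ratio tests).

Optimisation works on an unconstrained reparameterisation — `logit(Ro)`,
`log(d')` (DPSD), `log(Vo)`, and first-criterion plus log-gaps for the
ordered thresholds — with L-BFGS-B. Starting values are moment-based:
criteria from the inverse-normal of the new-item cumulative proportions,
`d'` from the mean zROC gap, `Vo` from the inverse zROC slope, `Ro`
starting at 0.1. Because ordered-threshold likelihoods can be multimodal,
up to 10 restarts are run from randomly jittered starts (SD 0.25 on the
transformed scale); restarting stops early once three starts reproduce the
best log-likelihood within 1e-4, which in practice keeps a fit under
~0.1 s without trusting any single start. `converged` is honest: it is
false for degenerate tables (all mass in one bin in both rows, which are
non-identifiable) or when no optimiser run succeeded.

Goodness of fit is `G = 2 Σ O ln(O/E)` over cells with positive observed
counts, with expected counts not floored, referred to a chi-square with
`df = 2(B − 1) − n_params`. Free parameters are counted identically for
both models — `B − 1` criteria plus two model parameters, so
`n_params = B + 1` and `df = B − 3` (3 at B = 6). `BIC = −2 logL +
n_params·ln(N)` with `N` the total of old and new trials; `N` is recorded
on the fit so alternative conventions are auditable. G-test calibration
(fit to correctly specified data, 1000 replicates at 360 trials) rejects
at 5–6% at the nominal 5% level.

The winning-model rule requires the lower BIC in at least 80% of subjects
*and* G-test acceptance (p ≥ .05) in more than 80%; anything else is
"inconclusive". BIC ties count for neither model.

## Descriptive statistics

Hit and false-alarm rates use the Snodgrass–Corwin correction — add 0.5
to the hit and false-alarm counts and 1 to the old and new totals — before
any inverse-normal transform. The correction is applied uniformly wherever
rates are formed (per subject, per bin, per image); per-image statistics
pool trials across subjects first and correct after pooling.
`d' = z(hit) − z(fa)`. Empirical ROC points are cumulative proportions
from the most-confident "old" bin downward; zROC drops points at 0 or 1
where the transform diverges; AUC is trapezoidal with (0,0)/(1,1) anchors
and needs no model.

Memorability bins: score > .75 high, (.55, .75] mid, ≤ .55 low. The
thresholds in the source procedure are strict inequalities on the high
side, leaving the boundary open; boundary scores go to the lower bin so
binning is deterministic.

Subject exclusion uses a one-sided exact binomial test of overall old/new
accuracy against 0.5 (default α = .05): at-chance performers are excluded,
which is deliberately strict — accuracy exactly at 0.5 is always excluded
regardless of trial count.

An "Exp-1 style" table (separate old/new decision plus 3-point
confidence) is collapsed onto the 6-point scale as `("new", c) → 4 − c`,
`("old", c) → 3 + c`.

## Scaled differences and Bayes factors

`Y = (a − b)/(a + b)` is antisymmetric and scale-invariant, and undefined
at `a + b = 0`; undefined subject×bin cells are dropped listwise within
each contrast (there is no defensible imputation at 0/0). Group summaries
report both the mean of per-subject scaled differences and the scaled
difference of mean proportions, because the two conventions differ and
reported tables elsewhere do not always say which was used.

The JZS Bayes factor integrates the noncentral-t likelihood of the
observed t statistic against a Cauchy prior on the standardised effect
size δ (scale √2/2 by default, exposed as a parameter), truncated to the
hypothesised direction for one-sided tests and renormalised. The
integration substitutes `δ = r·tan(u)` so the prior becomes uniform on a
finite interval — numerically robust at large df where the noncentral-t
tails misbehave. The implementation agrees with pingouin's independent
JZS implementation to four significant figures on two-sided cases (tested).
Cohen's d is reported as `d_z` (mean difference / SD of differences),
flagged as such since paired designs admit more than one convention.

## Quantile regression

Items are sorted by memorability (stable on a pre-sort by image id, so
tied scores are order-free) and packed into Q quantiles by cumulative
trial mass: an item joins the quantile containing the midpoint of its
trial span, keeping quantile totals within one item's trial count of each
other. Rating counts are pooled over subjects within quantile — the
pooling is what makes per-quantile ROC fits feasible at ordinary sample
sizes — and both models are fitted per quantile.

The regression of quantile rank (ordered categories 1..Q with Q − 1
thresholds) on each model's two signal parameters — (Ro, d') for DPSD,
(d', Vo) for UVSD; criteria are deliberately excluded — is a
proportional-odds cumulative-logit ML fit (statsmodels `OrderedModel`).
The intercept-only log-likelihood has a closed form (thresholds can match
the marginal rank frequencies exactly), giving the LR chi-square without
a second optimisation. Variance explained is Nagelkerke pseudo-R²,
reported raw and with a small-sample adjustment analogous to adjusted R²
(`1 − (1 − R²)(n − 1)/(n − k − 1)`); both are emitted because "adjusted
R²" is not uniquely defined for ordinal models. Standardised coefficients
are raw coefficients × predictor SD (latent-scale standardisation). With
few quantiles and strong signals the fit can sit near separation;
`converged` reports the optimiser's verdict and near-separation warnings
are expected rather than fatal.

## The synthetic observer

The generator emulates a scene-recognition study with separate encoding
and test phases: a pool of `n_old + n_new` images with memorability scores
drawn from a configurable distribution (default uniform(0.3, 0.95),
matching the spread of curated image sets whose low/mid/high bin means
fall near .45/.66/.87); each image is a target for half of the subjects
and a foil for the other half (alternating halves across subjects); each
subject runs on an RNG stream spawned from the master seed, so tables are
reproducible independent of execution order and byte-identical on rerun.

Observer parameters are linked to item memorability: `Ro(m) =
expit(−4.0 + 4.5·m)`, `d'(m) = 0.75 + 0.5·m`, `P(D | "new" response, m) =
expit(−2.6 + 2.8·m)`, criteria (−0.5, 0.2, 0.85, 1.5, 2.2). These defaults
place the memorability effect mainly on recollection with only a weak
familiarity gradient — the pattern observed with facilitated encoding —
and yield hit rates ≈ .58 (low) to .77 (high) with false-alarm rates
≈ .20, matching the rates typical of that regime. Recollection events
always produce the most-confident "old" response with statement R
(the classical high-confidence-recollection assumption, which reproduces
the hockey-stick ROC); non-recollected "old" responses get K. UVSD
observers have no recollection event, so R is assigned by the convention
"R iff response = B" — a stated stand-in that keeps statement data
available under both generative models, not a claim about mechanism.
D/U statements come from the single logistic link above for both models;
there is no recollect-to-reject mechanism, in line with the doubts about
that account for simple item recognition. Random draws are consumed in
fixed blocks (strength noise, recollection uniforms, statement uniforms)
so a DPSD observer with Ro = 0 and a UVSD observer with Vo = 1 produce
identical response columns under the same seed; their statement columns
necessarily differ by the conventions above.

What the generator does **not** emulate: encoding-phase dynamics
(presentation time, concurrent tasks, feedback), semantic image-category
structure, response times, between-subject parameter heterogeneity beyond
independent noise, criterion drift, or any generative account of K-
statement confidence. Passing tests therefore show that the analysis
chain recovers what this family of observers puts in — not that human
data obey these models.

## Problem sizes and determinism

The validation suite uses: 10⁵–10⁶ draws for Monte-Carlo agreement with
the closed-form probabilities (tolerances 0.01 and 0.005); 200 simulated
subjects × 360 trials for parameter recovery (mean |Ro error| ≤ 0.08,
|d' error| ≤ 0.15 observed ≈ 0.05 / 0.13); 24 subjects per arm at 360 and
3600 trials for model-selection recovery; 1000 replicates for G
calibration; and a 42-subject, 360-trial, Q = 30 pipeline for the
directional recovery (one-sided BF10 > 10 for the high-vs-low Yold
contrast, Spearman ρ > 0.5 between quantile rank and fitted Ro, and a
standardised recollection coefficient exceeding the familiarity
coefficient). Hypothesis-based property tests run derandomised; all
simulations are seeded.

## Known limitations

- The G-based acceptance threshold relies on the chi-square approximation;
  with very sparse extreme bins (expected counts ≪ 1) the test can drift
  from its nominal level.
- BIC compares models of equal parameter count here, so it reduces to a
  likelihood comparison; it cannot reflect the UVSD model's greater
  functional-form flexibility.
- The ordinal regression treats per-quantile parameter *estimates* as
  error-free predictors; estimation noise attenuates coefficients.
- Per-image scores pool few trials per image, so image-level correlations
  are noisier than subject-level contrasts.
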