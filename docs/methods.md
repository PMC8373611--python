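# Methods

## The model family

`pragmalex` implements a family of probabilistic models of how young children
(ages 2–5) decide what a novel word refers to when two objects are present:
one familiar object whose conventional label they may or may not know, and
one novel object without a label. Three information sources bear on the
choice:

* **Speaker informativeness** (`α ≥ 0`): the listener assumes the speaker
  picks the more informative of the two available utterances (the novel word
  or the familiar word). Formally a rational-speech-act recursion: a literal
  listener `L0` interprets words by their lexical semantics; the speaker `S1`
  chooses utterances soft-max-proportionally to how well `L0` would identify
  the intended referent, with exponent `α`; the pragmatic listener `L1`
  combines the speaker likelihood with a referent prior by Bayes' rule.
* **Semantic knowledge** (`θ ∈ [0,1]`, per familiar object): the probability
  that the listener knows the familiar word. The lexicon is a mixture: with
  probability `θ` the familiar word denotes the familiar object exclusively;
  with probability `1−θ` it is unknown and applies to either referent. The
  novel word always applies uniformly. This yields the exact limits the
  family needs: `θ = 0` or `α = 0` collapse the posterior onto the prior,
  and `θ = 1` gives the classic mutual-exclusivity inference.
* **Common ground** (`ρ ∈ [0,1]`): a conversational prior that the referent
  is the object that is new to the speaker in context. In the congruent
  condition the novel object carries prior `ρ`; in the incongruent condition
  it carries `1−ρ`.

For the two-referent scene the recursion closes to

```
p_novel ∝ ρ′ · 1/(1 + (1−θ)^α),     p_familiar ∝ (1−ρ′) · 1/(1 + (1+θ)^α)
```

with `ρ′` the condition-specific prior on the novel object.

Six variants are compared. The **rational-integration** model uses all three
sources. Three **lesions** each remove one: no-word-knowledge (object-blind,
pooled `θ`), no-common-ground (uniform prior, hence condition-blind), and
no-speaker-informativeness (`α = 0`, posterior = prior). Two **biased**
models compute the mutual-exclusivity inference `P_ME(α, θ)` (uniform prior)
and the common-ground prior separately and mix them with a weight
`φ ∈ [0,1]`: constant `φ` (biased integration) or age-varying `φ_i`
(developmental bias). Being convex mixtures, the biased predictions are
always bounded by their two components — the integration model, by
multiplying evidence, can exceed both.

The printed equation for the developmental-bias variant we follow ends its
second term without a prior factor; we implement it as
`φ_i·P_ME + (1−φ_i)·P(r|ρ_i)`, structurally identical to the constant-bias
model, since the variant is defined as that model with an age-varying weight.

## Age trajectories

Every sensitivity is a regression on age centred at 3.0 years (`AGE_CENTER`,
configurable): `α` linear with the predictor floored at 0 (a log link is
available via `alpha_link="log"`), `ρ`, `θ` and `φ` logistic. Semantic
knowledge is hierarchical: a population intercept/slope plus per-object
offsets (one familiar object per trial, 12 objects ordered by rated age of
acquisition), which is what makes the no-word-knowledge lesion meaningful —
it uses the population trajectory and ignores the offsets.

## Likelihood and estimation

Each trial is a Bernoulli draw of the model's predicted probability of the
"correct" choice at the child's age, object and condition. By design of the
experiments: Experiment 1 rows (no common-ground manipulation) are evaluated
under the mutual-exclusivity adaptation (uniform prior) for every variant;
Experiment 2 rows measure `ρ(age)` directly; the variants differ on
Experiment 3 rows and in all predictions. Parameter estimation for the
prediction stage uses Experiments 1–2 only — the package *enforces* that
prediction-stage fits never see Experiment 3 rows, so Experiment-3
trajectories are genuine out-of-sample predictions. Explanation-stage fits
use all experiments; the bias weight `φ` is only identifiable there.

Priors are weakly informative and configurable (`PriorSpec`): Normal(1, 1)
on the `α` intercept, Normal(0, 1) on its slope, Normal(0, 2.5) on
logit-scale intercepts and slopes, half-Normal(1) hyperpriors on the
object-offset scales. Object offsets are parametrized non-centred
(`offset = z·σ`, `z ~ N(0,1)`, `σ` sampled on the log scale): with twelve
objects and one trial per child-object pair the offsets are at most
moderately identified, and the non-centred form keeps the geometry benign
across the whole range from prior-dominated to data-dominated fits. A fully
centred parametrization was tried and collapses into the `σ → 0` density
spike whenever the data leave an offset scale weakly constrained.

Sampling is preconditioned static Hamiltonian Monte Carlo, written for this
model because the likelihood and its gradient close in a few lines per
trial: analytic trial-level gradients (numba kernels; the `θ`-derivative is
taken with respect to the logit so the `(1−θ)^{α−1}` factor cancels at
saturation), an L-BFGS posterior mode plus exact finite-difference Hessian
as the preconditioner, chains advanced in lock-step so each leapfrog step
costs one batched gradient call, dual-averaging step-size adaptation toward
0.8 acceptance, a diagonal mass-matrix update from a mid-warmup window, and
jittered trajectory lengths. Defaults: 4 chains × 250 warmup + 550 retained
draws, 12 leapfrog steps (reduced preset: 150 + 250, 10 steps); at least
1,000 retained draws are always kept. Diagnostics are attached to every fit:
minimum bulk ESS and maximum split-R-hat across chains (arviz), acceptance
rate and divergence count; if R-hat exceeds 1.15 the fit automatically
re-runs once with a doubled budget, and a fit that still misses ESS ≥ 400 /
R-hat ≤ 1.05 is returned flagged (`converged = 0`) with a logged warning
rather than rejected.

The exp-1 likelihood `p_j = ME(α, θ_j)` is pointwise under-identified (one
`α` against twelve `θ_j` per age), so the posterior has a genuinely wide,
curved `α`–`θ` ridge; the Laplace preconditioner plus mass adaptation is
what makes HMC traverse it. Affine-invariant ensemble sampling was tried
first and could not converge on this ridge at any feasible budget.

## Model evidence and comparison

Marginal likelihoods are estimated by simple Monte Carlo: average the
Experiment-3 data likelihood over parameter draws, computed in log space
with log-sum-exp, with a delta-method standard error. For the prediction
models the draws come from the Experiment-1/2 posterior (out-of-sample
evidence); for explanation-stage comparisons of the biased variants the
shared coefficients likewise come from that posterior while `φ`, which
Experiments 1–2 cannot inform, is drawn from its prior. Naive Monte Carlo
from the full ~30-dimensional prior would be astronomically high-variance
and is not offered as a default. Bayes factors are evidence ratios, also
reported on the log10 scale. Model fit is additionally summarised by the
Pearson correlation (and `r²`) between predicted and observed correct-choice
rates binned by age year × condition × object (72 Experiment-3 cells),
equally weighted by default with an n-weighted option.

## Synthetic data

The generator reproduces the structure of the three child experiments:
Experiment 1, 12 mutual-exclusivity trials per child (each familiar object
once); Experiment 2, 10 discourse-novelty trials (no familiar object;
the observable is `ρ(age)` itself); Experiment 3, 12 trials, six congruent
and six incongruent, object-to-alignment assignment randomised per child
(24 cells). Ages are uniform within each year bin {2, 3, 4}; default
children per bin mirror the study samples (30/30/30, 18/19/21, 76/72/72).
Responses are Bernoulli draws from the chosen generating model's predicted
probability, so downstream estimates can be checked against known truth.
Dropout, side/speaker counterbalancing, training trials and exclusion
criteria are not simulated; real data would also bring child-level
heterogeneity beyond age that the generator (like the models) omits, so
passing recovery tests here demonstrates correctness of the inference
machinery, not adequacy of the model for any particular dataset.

`default_truth()` fixes a documented fixture with all three sensitivities
increasing in age (α ≈ 0.6→1.8, ρ ≈ 0.55→0.85, population θ ≈ 0.43→0.89
over ages 2→4), object intercept offsets spanning ±2.2 logits (mean zero)
and small slope offsets, a constant bias weight of 0.65 — the published
estimate, used as the generating condition for bias-recovery checks — and a
developmental-bias trajectory crossing 0.5 shortly before age 3.

## Calibration and known limitations

* Parameter recovery is validated by simulation-based calibration: the
  generating coefficients are drawn from the fitting prior each replicate,
  so 95% credible intervals must cover at their nominal rate. With a fixed
  generating truth this guarantee does not hold for the under-identified
  `α`/`θ` intercepts — along the likelihood-flat ridge the offset-shrinkage
  prior legitimately pulls the posterior away from any particular truth —
  and that behaviour is a property of the model, not a fault of the sampler.
* Bayes factors computed here are not comparable in magnitude to any
  particular published analysis: they depend on priors, sample sizes and the
  evidence estimator.
* The HDI is the shortest contiguous window of sorted samples; for
  multimodal samples a warning is logged and the contiguous interval is
  still reported.
* Probabilities are clipped at `1e-12` in the likelihood; exact 0/1 priors
  propagate exactly through the listener recursion.
* Test-suite and acceptance-script problem sizes (60 children per year for
  calibration and model-selection replicates; the study's own sizes for the
  headline pipeline) were chosen as the package's standard demonstration
  scale.
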