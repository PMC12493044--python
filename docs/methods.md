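# Methods

This note documents the models, algorithms, numerical choices and
limitations of the package in enough detail to reproduce or audit any
number it computes.

## Task model

The task is a block-structured two-armed bandit. Each block introduces two
novel symbols; one rewards (100 points) with probability 0.75, the other
with 0.25; trials end with 0 or 100 points. Blocks belong to one of three
recipient conditions (self, other, no one). The schedule holds three
16-trial blocks per recipient — 48 trials per recipient, 144 in total —
arranged as one of the six orderings of (self, other, noone) repeated three
times, which guarantees the same recipient never appears in consecutive
blocks. The left/right placement of the high-probability symbol is
uniform-random per trial and recorded, but no model term uses it.

Two published descriptions of the block layout are arithmetically
incompatible ("three blocks of 16 trials per recipient" vs "six blocks" for
144 trials); the package fixes the explicit totals (48/48/48 = 144) with
nine 16-trial blocks and exposes `n_blocks_per_recipient` in
`build_schedule` so other layouts can be constructed.

Missed trials are representable (a `MISSED` sentinel and flag column) and
are excluded from likelihoods, value updates and accuracy denominators, but
the simulator never generates them: response-time mechanics are out of
scope.

## The 13-model space

The space is built iteratively. Step 1 fixes the recipient granularity of
the learning rate — one shared α or three (self/other/noone) — and adds a
value-free win-stay/lose-shift (WSLS) control. Step 2 optionally splits
each α by prediction-error valence or by chosen/unchosen stimulus. Every
value-based structure is crossed with one softmax temperature or three
(by recipient), giving 12 value models (ids i–xii) plus WSLS (xiii). Model
ix — six learning rates (recipient × valence) and a single temperature —
is the winning specification in the study population this package emulates.

Conventions, all exposed and unit-tested:

* Rewards are normalised to {0, 1} internally (file I/O keeps the task's
  {0, 100} points). Likelihoods are invariant to this convention when β is
  rescaled accordingly.
* Values start at Q = 0.5 per block (unbiased between the two outcomes).
* δ = 0 counts as a **positive** prediction error: an outcome as good as
  expected routes through the positive-PE learning rate.
* In chosen/unchosen-split models the unchosen value moves toward the
  counterfactual outcome 1 − r with its own rate, motivated by the
  complementary 0.75/0.25 contingencies. This (and the WSLS form below) is
  a provisional stand-in for an unpublished supplementary definition and is
  isolated behind `ModelSpec` so it can be swapped.
* WSLS has a single consistency parameter c: stay after a win with
  probability c, shift after a loss with probability c, chance on each
  block's first trial.

## Hierarchical MAP fitting

Parameters are fit in transformed space (logit for α and the WSLS
consistency, log for β) under a diagonal Gaussian group prior, by
expectation-maximization:

* **E-step**: per subject, minimise the negative log posterior with
  L-BFGS-B from `n_restarts` starts (first at the prior mean, the rest
  drawn from the prior; draws are keyed to the subject id so fits are
  invariant to subject ordering and adding restarts only extends the start
  set). The Hessian of the negative log posterior at the optimum is
  computed by central finite differences (step 1e-3).
* **M-step**: prior mean ← mean of MAP estimates; prior variance ← mean of
  squared deviations plus inverse-Hessian diagonals, floored at 1e-4 to
  prevent collapse.
* Convergence: max |Δ prior mean| < `tol` (default 1e-3) or
  `max_em_iter` (default 50). Defaults for the initial prior are mean 0
  (α = 0.5, β = 1) and variance 3 — weakly informative on both scales.

Log model evidence per subject is the Laplace approximation
log p(D|M) ≈ log posterior(MAP) + (k/2)·log 2π − ½·log det H; with no free
parameters this is exactly the log-likelihood; if H is not positive
definite the fit falls back to a BIC-style penalty
(LL − (k/2)·log n_trials) and carries an `evidence_fallback` flag.

The heavily-called likelihood loop is JIT-compiled with numba when
available; a pure-Python fallback with identical semantics is kept and the
test suite verifies both against a per-trial recomposition of the public
single-trial operations to 1e-10.

## Model comparison

* **iBIC** = −2·Σ_subjects log evidence + h·ln N, with h = 2k group-level
  hyperparameters (a mean and variance per model parameter) and N the total
  non-missed trials. Lower is better.
* **Exceedance probabilities** use the standard random-effects scheme: a
  variational Dirichlet update (uniform Dirichlet(1) prior) over per-subject
  model responsibilities, then Monte-Carlo sampling of the fitted Dirichlet
  (default 1e5 samples, seeded; ≈ ±0.003 precision) to estimate the
  probability that each model is the most frequent generating model.
* The winner per group is the exceedance argmax; a report flags any
  disagreement among the three metrics (at small n the iBIC's
  hyperparameter penalty can prefer a simpler model even when exceedance is
  decisive).

## Behavioural metrics

Accuracy is the frequency of choosing the high-probability symbol per
recipient over non-missed trials, regardless of outcome. The six
learning-rate difference scores — other−noone, other−self, self−noone for
each valence, on the native (0, 1) scale — are the lesion-mapping
regressors. Group summaries include simple paired t/Wilcoxon contrasts
labelled descriptive; the mixed-model inference a full analysis would run
on real data is deliberately out of scope, and the tidy per-subject table
is the hand-off point.

## Lesion-symptom mapping

Masks are binary grids sharing one shape. Mirroring ORs each mask with its
reflection across the laterality axis (symmetric output, idempotent).
Voxels damaged in fewer than 5 patients are excluded. The voxel statistic
is a pooled-variance two-sample t comparing scores of damaged vs spared
patients, signed damaged-minus-spared (binary masks make "degree of
damage" a two-group comparison); degenerate voxels (a group empty, zero
pooled variance) are set to 0.

TFCE integrates extent^E · height^H · dh over cluster-forming thresholds
(defaults E = 0.5, H = 2, dh = max|t|/100, 6-connected clusters, positive
and negative tails enhanced separately). Inference permutes scores across
patients and compares each voxel's |TFCE| to the permutation distribution
of the map-wise maximum: p = (1 + #{null ≥ observed}) / (n_perm + 1),
giving exact family-wise control under exchangeability. The per-map alpha
defaults to 0.05/3 for the three recipient-contrast regressors (Bonferroni
applied to the alpha, matching a printed threshold of P < 0.0167);
uncorrected exploratory thresholds are available by passing
`alpha_corrected=0.05`. Lesion volume is not modelled as a covariate.

Numerical notes: the threshold ladder is computed as k·dh (integer k) to
avoid float accumulation; permutation maps are computed on the inclusion
bounding box; the number of ladder steps (`n_steps`) trades accuracy for
speed and is reduced in the repeated-null validation runs.

## Synthetic cohorts

Choice cohorts draw each subject's transformed parameters from group
Gaussians and simulate them on fresh schedules. The default three groups
match the study sizes (124 healthy-control-like, 28 vmPFC-like, 21
lesion-control-like) and impose the observed qualitative orderings —
controls: α_self_pos and α_other_pos above α_noone_pos; vmPFC-like:
α_other_pos below α_noone_pos, α_other_neg above α_self_neg, no self
advantage. The magnitudes (rates around 0.3–0.55, β = 3, logit-SD 0.5) are
repository choices: no group-level native parameter values are published,
so only the orderings are meaningful. Everything is reproducible
bit-for-bit from the spec plus a master seed (per-subject seeds are spawned
from a `SeedSequence`).

Lesion cohorts place one spherical blob per patient (radius 2–5), centred
near a fixed hotspot with probability 0.7 (Gaussian jitter, SD 2 voxels)
and uniformly otherwise, on a 32³ synthetic grid — no anatomical
registration; the mapping machinery is exercised structurally, not
anatomically. The behavioural score is baseline + coupling · (damaged
fraction of a radius-3 effect ball at the hotspot) + N(0, noise_sd); with
noise SD 1, the coupling is the planted effect size in SD units at full
damage.

What a green test does and does not establish: synthetic agents always
respond, parameters are Gaussian in transformed space with no
cross-parameter correlation, and lesions are independent spheres — real
lesions follow vascular territories with strong spatial covariance, and
real missingness/response-time structure is absent. Recovery results here
validate the estimation machinery on data satisfying its assumptions, not
performance on clinical data.

## Known limitations

* Parameter identifiability at 144 trials is intrinsically modest: each
  recipient-by-valence learning-rate cell receives roughly 12–36 effective
  updates, capping truth-estimate correlations near 0.4–0.7 per rate (a
  split-session reliability analysis in the test suite quantifies this
  ceiling). The temperature recovers best.
* With all rate means equal and β near 1 (near-chance behaviour), the
  valence split is essentially unidentifiable at this trial count and
  random-effects model selection spreads mass across the value models;
  decisive selection of the six-rate model requires genuinely distinct rate
  cells and/or lower decision noise.
* The M-step uses the common empirical-Bayes variance update (squared
  deviations + inverse-Hessian diagonals); with identical subjects the
  prior variance converges to the per-subject curvature term, not the
  floor.
* No full-covariance priors, MCMC, protected exceedance probabilities,
  forgetting/decay parameters, or multivariate lesion mapping.
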