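# prolearn

Computational modelling of **prosocial reinforcement learning** and
**voxel-based lesion-symptom mapping (VLSM)**, built for studies that ask
whether damage to ventromedial prefrontal cortex (vmPFC) and its
subregions disrupts the ability to learn rewards *for other people*.

The package covers the full analysis path for a probabilistic
reward-learning task played in three recipient conditions — **self**,
**other** (prosocial) and **no one** (control) — and for binary lesion
masks on a common grid:

1. **Task simulation** (`prolearn.task`) — nine 16-trial blocks (three per
   recipient, never the same recipient twice in a row; 48 trials per
   recipient, 144 in total), two novel symbols per block paying 100 points
   with probability 0.75 / 0.25.
2. **Model space** (`prolearn.models`) — 13 candidate models built
   iteratively: learning rates shared or split by recipient, by
   prediction-error valence, or by chosen/unchosen stimulus; one or three
   softmax temperatures; plus a value-free win-stay/lose-shift control.
3. **Hierarchical fitting** (`prolearn.fitting`) — iterative MAP with
   empirical-Bayes group priors (EM), Laplace log model evidence.
4. **Model selection** (`prolearn.selection`) — summed log evidence, iBIC,
   and random-effects exceedance probabilities.
5. **Behavioural metrics** (`prolearn.metrics`) — per-recipient accuracy and
   the six learning-rate difference scores used as lesion-mapping regressors.
6. **Lesion mapping** (`prolearn.vlsm`) — mask mirroring, ≥5-patient
   coverage filter, voxelwise t maps, threshold-free cluster enhancement
   (TFCE), max-statistic permutation inference, Bonferroni-corrected alpha.
7. **Synthetic cohorts** (`prolearn.cohort`) — choice and lesion cohorts
   with known ground truth for parameter, model and lesion-effect recovery.

## The model

Behaviour is modelled with Rescorla–Wagner learning and softmax choice. On
each trial the value of the chosen stimulus is updated by the prediction
error δ = r − Q_chosen (rewards normalised to r ∈ {0, 1}):

    Q_chosen ← Q_chosen + α_cell · δ

The winning specification (model ix, "6α1β") carves the learning rate into
six cells — α_recipient,valence for recipient ∈ {self, other, no one} and
valence ∈ {positive PE (δ ≥ 0), negative PE (δ < 0)} — with one inverse
temperature β in the softmax

    p(a) = exp(β · Q_a) / Σ_b exp(β · Q_b).

Models are fit per subject by MAP under a group-level Gaussian prior on
transformed parameters (logit for rates, log for β), with the prior itself
estimated by EM. Model evidence is the Laplace approximation at the MAP;
group-level comparison uses summed evidence, the integrated BIC
(−2·Σ evidence + h·ln N with h = 2 hyperparameters per parameter) and
random-effects exceedance probabilities (variational Dirichlet scheme with
Monte-Carlo exceedance).

For lesion inference, each behavioural regressor (e.g. the other − no one
difference in positive-PE learning rates) is compared between damaged and
spared patients at every voxel covered by ≥5 patients (pooled-variance t,
negative when damage lowers the score), enhanced with TFCE
(Σ extent^0.5 · height² · dh over thresholds, 6-connected clusters), and
tested against the permutation distribution of the map-wise max |TFCE| at
α = 0.05/3.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/03_fit_and_compare.py` simulates 12 agents from the
six-learning-rate model and compares a ladder of four candidates:

```
model_id group   sum_lme     ibic  dirichlet_alpha  model_frequency  exceedance
       i   sim  -828.500 1686.820            2.360            0.148       0.008
     iii   sim  -827.749 1715.136            2.532            0.158       0.011
      ix   sim  -809.885 1724.136           10.108            0.632       0.980
    xiii   sim -1031.139 2077.188            1.000            0.063       0.001

winner: ix (all three metrics agree: False)
```

The generating model wins with exceedance 0.98 — the probability that it is
the most frequent generating model in the population. (At this small n the
iBIC's hyperparameter penalty favours the simplest model, which the
disagreement flag surfaces.) `python examples/05_lesion_mapping.py` runs
the full VLSM on a synthetic 49-patient lesion cohort and reports the
significant cluster and its Dice overlap (≈0.35) with the planted effect
region.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: (t5) the empirical reward frequency of the
high-probability symbol over 100,000 sampled outcomes, and (t7) the
exceedance probability of the generating six-learning-rate model when a
28-agent synthetic group (transformed parameter means 0, SD 0.5) is run
through the full 13-model hierarchical fit and random-effects comparison.
Values are written as JSON percentages. See `docs/methods.md` for the
modelling details, the synthetic-data assumptions and known limitations.
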