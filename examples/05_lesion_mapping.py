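"""Voxel-based lesion-symptom mapping on a synthetic lesion cohort.

Generates 49 blob lesions on a 32^3 grid with a behavioural score coupled
to damage in a planted effect region (slope 1.5 noise-SD units at full
damage), mirrors the masks, and runs the max-|TFCE| permutation test at the
Bonferroni-corrected alpha (0.05/3). Prints the significant clusters and
the Dice overlap with the planted region. Takes ~10 s.
"""

import numpy as np

from prolearn.cohort import LesionCohortSpec, generate_lesion_cohort
from prolearn.vlsm import (
    bonferroni_alpha,
    cluster_summary,
    mirror_and_binarize,
    permutation_vlsm,
)

masks, scores, truth = generate_lesion_cohort(LesionCohortSpec(master_seed=1))
masks = [mirror_and_binarize(m) for m in masks]

result = permutation_vlsm(
    masks,
    scores,
    n_permutations=2000,
    seed=1,
    n_steps=50,
    alpha_corrected=bonferroni_alpha(),  # 0.05 / 3 regressors
    regressor="synthetic_difference_score",
)

print(f"included voxels (damage in >=5 patients): {result.inclusion.sum()}")
print(f"significant voxels at p < {result.alpha_corrected:.4f}: "
      f"{result.significant.sum()}")
print(cluster_summary(result).to_string(index=False))

dice = (2.0 * (result.significant & truth.effect_region).sum()
        / (result.significant.sum() + truth.effect_region.sum()))
print(f"\nDice overlap with the planted effect region: {dice:.3f}")
print("Dice > 0.3 means the mapping localises the true damage-behaviour"
      "\ncoupling rather than flagging arbitrary well-covered voxels.")
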