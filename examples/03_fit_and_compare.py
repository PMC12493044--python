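"""Hierarchical fitting and model comparison on a small simulated group.

Simulates 12 agents from the winning six-learning-rate model (distinct
valence/recipient means so the structure is identifiable), fits a nested
ladder of four candidate models with the empirical-Bayes EM procedure, and
prints summed log evidence, iBIC and exceedance probabilities.
Takes ~1 minute.
"""

from prolearn import enumerate_models, get_model
from prolearn.cohort import CohortSpec, GroupSpec, generate_choice_cohort
from prolearn.fitting import FitConfig, em_fit_group
from prolearn.selection import compare_models, select_winning_model

group = GroupSpec(
    name="sim",
    n_subjects=12,
    model_id="ix",
    mean_native={
        "alpha_self_pos": 0.55, "alpha_self_neg": 0.25,
        "alpha_other_pos": 0.45, "alpha_other_neg": 0.30,
        "alpha_noone_pos": 0.35, "alpha_noone_neg": 0.20,
        "beta": 4.0,
    },
    sd_transformed={n: 0.4 for n in get_model("ix").param_names},
)
datasets, _truth = generate_choice_cohort(CohortSpec(groups=[group], master_seed=2))

candidates = [get_model(mid) for mid in ("i", "iii", "ix", "xiii")]
config = FitConfig(n_restarts=2, max_em_iter=12, tol=2e-3, seed=0)
results = [em_fit_group(datasets["sim"], spec, config) for spec in candidates]

comparison = compare_models(results, candidates, group="sim", seed=0)
print(comparison.to_frame().round(3).to_string(index=False))
report = select_winning_model({"sim": comparison})
print(f"\nwinner: {report.winners['sim']} "
      f"(all three metrics agree: {report.agreement['sim']})")
print("The generating six-rate model should win: its exceedance probability"
      "\nis the chance it is the most frequent generating model in the group.")
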