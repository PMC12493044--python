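"""Parameter recovery for the winning model at a small desk scale.

Simulates 20 agents with range-spanning learning rates, refits the
generating model hierarchically, and prints the truth-vs-estimate Pearson
correlation per parameter. Takes ~30 s.
"""

from prolearn import get_model
from prolearn.cohort import CohortSpec, GroupSpec, generate_choice_cohort, run_recovery
from prolearn.fitting import FitConfig

spec = get_model("ix")
group = GroupSpec(
    name="rec",
    n_subjects=20,
    model_id="ix",
    mean_native={
        "alpha_self_pos": 0.55, "alpha_other_pos": 0.50, "alpha_noone_pos": 0.40,
        "alpha_self_neg": 0.35, "alpha_other_neg": 0.36, "alpha_noone_neg": 0.35,
        "beta": 3.0,
    },
    sd_transformed={n: (0.3 if n == "beta" else 1.0) for n in spec.param_names},
)
datasets, truth = generate_choice_cohort(CohortSpec(groups=[group], master_seed=1))
report = run_recovery(
    datasets["rec"], truth, fit_config=FitConfig(n_restarts=2, max_em_iter=15, seed=0)
)
print(report["table"].round(3).to_string(index=False))
print("\nWith 144 trials each valence-by-recipient cell only sees ~12-36"
      "\nupdates, so correlations of 0.4-0.7 per learning rate are the"
      "\nrealistic ceiling at this scale; the temperature recovers best.")
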