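"""Walk the 13-model space and evaluate one likelihood by hand.

Prints the roster (which learning-rate/temperature cells each model
carves), then scores a 2-trial toy sequence under the simplest model to
show how softmax choice probabilities and Rescorla-Wagner updates compose
into the log-likelihood.
"""

import math

import numpy as np

import prolearn as pl
from prolearn.models import ChoiceDataset

for spec in pl.enumerate_models():
    kind = "WSLS" if spec.is_wsls else f"{len(spec.alpha_names)}a{len(spec.beta_names)}b"
    print(f"model {spec.model_id:>4}: {kind:5} params = {', '.join(spec.param_names)}")

# toy: choose the high symbol, win, choose it again (alpha=0.5, beta=1)
toy = ChoiceDataset(
    subject_id="toy",
    block=np.array([0, 0]),
    recipient=np.array([0, 0]),
    chose_high=np.array([True, True]),
    outcome01=np.array([1.0, 1.0]),
    missed=np.array([False, False]),
)
ll = pl.log_likelihood(toy, {"alpha_all": 0.5, "beta": 1.0}, pl.get_model("i"))
print(f"\ntoy log-likelihood: {ll:.4f}")
print("= ln(0.5) for the first trial (values start equal) plus "
      f"ln(1/(1+e^-0.25)) = {math.log(1/(1+math.exp(-0.25))):.4f} for the second,")
print("because the win pushed the chosen value from 0.50 to 0.75.")
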