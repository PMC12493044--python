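"""The 13-model reinforcement-learning model space.

The model space is built iteratively. The first step asks how many learning
rates are needed across recipient conditions (one shared rate, or one per
recipient), alongside a value-free win-stay/lose-shift (WSLS) control model.
The second step asks whether learning rates should additionally split by
prediction-error valence (positive vs negative PE) or by chosen vs unchosen
stimulus. Every value-based variant is crossed with either a single softmax
temperature or one temperature per recipient:

========  =================================  ========
model id  learning rates                     betas
========  =================================  ========
i         1 (shared)                         1
ii        1 (shared)                         3
iii       3 (recipient)                      1
iv        3 (recipient)                      3
v         2 (valence)                        1
vi        2 (valence)                        3
vii       2 (chosen/unchosen)                1
viii      2 (chosen/unchosen)                3
ix        6 (recipient x valence)            1
x         6 (recipient x valence)            3
xi        6 (recipient x chosen/unchosen)    1
xii       6 (recipient x chosen/unchosen)    3
xiii      WSLS (consistency only)            --
========  =================================  ========

Model ix — six learning rates (positive/negative PE for self, other and
no one) plus a single temperature — is the winning model for every group.

Value updating is Rescorla-Wagner on a normalised reward scale: after
choosing stimulus *c* and observing outcome *r* in {0, 1},

    Q_c <- Q_c + alpha_cell * (r - Q_c)

where the learning-rate cell depends on the model: on the recipient, on the
sign of the prediction error delta = r - Q_c (delta >= 0 counts as a
positive PE — an outcome as good as or better than expected), and for
chosen/unchosen-split models the unchosen stimulus value is also updated
toward the counterfactual outcome 1 - r with its own rate (the two reward
contingencies, 0.75 and 0.25, are complementary).

Choices follow a softmax in the stimulus values:

    p(a) = exp(beta * Q_a) / sum_b exp(beta * Q_b)

WSLS ignores values entirely: with consistency c in (0, 1) it repeats the
previous choice with probability c after a win and switches with
probability c after a loss; the first trial of each block is at chance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .task import (
    MISSED,
    POINTS_WIN,
    Recipient,
    Schedule,
    TrialRecord,
    sample_outcome,
    trials_frame,
)

__all__ = [
    "ModelSpec",
    "ValueState",
    "ChoiceDataset",
    "enumerate_models",
    "get_model",
    "WINNING_MODEL_ID",
    "update_values",
    "choice_probability",
    "log_likelihood",
    "simulate_agent",
    "model_roster_json",
]

RECIPIENT_CODES = {"self": 0, "other": 1, "noone": 2}
RECIPIENT_NAMES = ("self", "other", "noone")

#: id of the winning specification: six learning rates, one temperature.
WINNING_MODEL_ID = "ix"

Q_INIT = 0.5  # unbiased value prior on the normalised [0, 1] reward scale

_INDEX_CACHE: dict[str, tuple] = {}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which learning-rate/temperature cells it carves."""

    model_id: str
    alpha_by_recipient: bool = False
    alpha_split: str = "none"  # "none" | "valence" | "chosen"
    beta_by_recipient: bool = False
    is_wsls: bool = False

    def __post_init__(self):
        if self.alpha_split not in ("none", "valence", "chosen"):
            raise ValueError(f"unknown alpha_split {self.alpha_split!r}")

    @property
    def alpha_names(self) -> tuple[str, ...]:
        if self.is_wsls:
            return ()
        recips = RECIPIENT_NAMES if self.alpha_by_recipient else ("all",)
        if self.alpha_split == "valence":
            suffixes = ("pos", "neg")
        elif self.alpha_split == "chosen":
            suffixes = ("chosen", "unchosen")
        else:
            suffixes = ("",)
        names = []
        for r in recips:
            for s in suffixes:
                names.append(f"alpha_{r}_{s}" if s else f"alpha_{r}")
        return tuple(names)

    @property
    def beta_names(self) -> tuple[str, ...]:
        if self.is_wsls:
            return ()
        if self.beta_by_recipient:
            return tuple(f"beta_{r}" for r in RECIPIENT_NAMES)
        return ("beta",)

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.is_wsls:
            return ("consistency",)
        return self.alpha_names + self.beta_names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # --- parameter-vector indexing used by the likelihood kernels ---------

    def _index_arrays(self):
        """Per-recipient parameter indices: (a_pos, a_neg, a_unchosen, b)."""
        cached = _INDEX_CACHE.get(self.model_id)
        if cached is not None:
            return cached
        names = list(self.param_names)

        def idx(name):
            return names.index(name)

        a_pos = np.empty(3, dtype=np.int64)
        a_neg = np.empty(3, dtype=np.int64)
        a_un = np.full(3, -1, dtype=np.int64)
        b_ix = np.empty(3, dtype=np.int64)
        for r, rname in enumerate(RECIPIENT_NAMES):
            tag = rname if self.alpha_by_recipient else "all"
            if self.alpha_split == "valence":
                a_pos[r] = idx(f"alpha_{tag}_pos")
                a_neg[r] = idx(f"alpha_{tag}_neg")
            elif self.alpha_split == "chosen":
                a_pos[r] = a_neg[r] = idx(f"alpha_{tag}_chosen")
                a_un[r] = idx(f"alpha_{tag}_unchosen")
            else:
                a_pos[r] = a_neg[r] = idx(f"alpha_{tag}")
            b_ix[r] = idx(f"beta_{rname}" if self.beta_by_recipient else "beta")
        _INDEX_CACHE[self.model_id] = (a_pos, a_neg, a_un, b_ix)
        return a_pos, a_neg, a_un, b_ix

    def alpha_cell(self, recipient: str, positive_pe: bool) -> str | None:
        """Name of the learning rate applied to the chosen stimulus."""
        if self.is_wsls:
            return None
        tag = recipient if self.alpha_by_recipient else "all"
        if self.alpha_split == "valence":
            return f"alpha_{tag}_pos" if positive_pe else f"alpha_{tag}_neg"
        if self.alpha_split == "chosen":
            return f"alpha_{tag}_chosen"
        return f"alpha_{tag}"

    def unchosen_cell(self, recipient: str) -> str | None:
        if self.is_wsls or self.alpha_split != "chosen":
            return None
        tag = recipient if self.alpha_by_recipient else "all"
        return f"alpha_{tag}_unchosen"

    def beta_cell(self, recipient: str) -> str | None:
        if self.is_wsls:
            return None
        return f"beta_{recipient}" if self.beta_by_recipient else "beta"


def enumerate_models() -> list[ModelSpec]:
    """The full 13-model roster, ids i..xiii (see module docstring)."""
    ids = iter(
        ["i", "ii", "iii", "iv", "v", "vi", "vii", "viii", "ix", "x", "xi", "xii"]
    )
    specs = []
    for by_recip, split in [
        (False, "none"),
        (True, "none"),
        (False, "valence"),
        (False, "chosen"),
        (True, "valence"),
        (True, "chosen"),
    ]:
        for beta_by_recip in (False, True):
            specs.append(
                ModelSpec(
                    model_id=next(ids),
                    alpha_by_recipient=by_recip,
                    alpha_split=split,
                    beta_by_recipient=beta_by_recip,
                )
            )
    specs.append(ModelSpec(model_id="xiii", is_wsls=True))
    return specs


def get_model(model_id: str) -> ModelSpec:
    for spec in enumerate_models():
        if spec.model_id == model_id:
            return spec
    raise KeyError(f"unknown model id {model_id!r}")


def model_roster_json() -> str:
    """Model roster (model_id -> parameter names) for audit."""
    return json.dumps(
        {m.model_id: list(m.param_names) for m in enumerate_models()}, indent=2
    )


# ---------------------------------------------------------------------------
# single-trial operations (reference semantics; the kernels inline these)


@dataclass
class ValueState:
    """Per-block value estimates for the two stimuli, on the [0, 1] scale."""

    q_high: float = Q_INIT
    q_low: float = Q_INIT

    def q(self, chose_high: bool) -> float:
        return self.q_high if chose_high else self.q_low


def update_values(
    state: ValueState,
    chose_high: bool,
    outcome: float,
    params: dict[str, float],
    spec: ModelSpec,
    recipient: str,
) -> ValueState:
    """Rescorla-Wagner update; returns a new state.

    The learning-rate cell is selected by recipient and PE sign
    (delta = outcome - Q_chosen; delta >= 0 is a positive PE). For
    chosen/unchosen-split models the unchosen value moves toward the
    counterfactual outcome ``1 - outcome``. WSLS models keep no values.
    """
    if outcome not in (0, 1, 0.0, 1.0):
        raise ValueError(f"outcome must be 0 or 1 on the normalised scale, got {outcome}")
    if spec.is_wsls:
        return replace(state)
    qc = state.q(chose_high)
    delta = outcome - qc
    alpha = params[spec.alpha_cell(recipient, positive_pe=delta >= 0)]
    qc_new = qc + alpha * delta
    un_cell = spec.unchosen_cell(recipient)
    qu = state.q(not chose_high)
    if un_cell is not None:
        qu = qu + params[un_cell] * ((1.0 - outcome) - qu)
    if chose_high:
        return ValueState(q_high=qc_new, q_low=qu)
    return ValueState(q_high=qu, q_low=qc_new)


def choice_probability(
    state: ValueState,
    params: dict[str, float],
    spec: ModelSpec,
    recipient: str,
    previous_trial: tuple[bool, float] | None = None,
) -> tuple[float, float]:
    """(p_high, p_low) for the current trial.

    Value models use the softmax with the recipient's temperature. WSLS uses
    ``previous_trial = (chose_high, outcome01)`` of the preceding trial in
    the same block (None on the first trial -> chance).
    """
    if spec.is_wsls:
        c = params["consistency"]
        if previous_trial is None:
            return (0.5, 0.5)
        prev_high, prev_out = previous_trial
        stay = c if prev_out >= 0.5 else 1.0 - c
        p_high = stay if prev_high else 1.0 - stay
        return (p_high, 1.0 - p_high)
    beta = params[spec.beta_cell(recipient)]
    p_high = 1.0 / (1.0 + math.exp(-beta * (state.q_high - state.q_low)))
    return (p_high, 1.0 - p_high)


# ---------------------------------------------------------------------------
# trial data container


@dataclass
class ChoiceDataset:
    """Trial sequence for one subject, in kernel-ready arrays.

    Missed trials are retained (``missed`` flag) but contribute no
    log-likelihood and trigger no value update. ``outcome01`` holds outcomes
    on the normalised {0, 1} scale; file I/O uses the task's {0, 100} points.
    """

    subject_id: str
    block: np.ndarray  # int, block index per trial
    recipient: np.ndarray  # int codes 0=self 1=other 2=noone
    chose_high: np.ndarray  # bool
    outcome01: np.ndarray  # float {0,1}
    missed: np.ndarray  # bool
    group: str = "sim"
    side_of_high: np.ndarray | None = None  # recorded but ignored by all models

    def __post_init__(self):
        n = len(self.block)
        for name in ("recipient", "chose_high", "outcome01", "missed"):
            if len(getattr(self, name)) != n:
                raise ValueError("trial arrays have inconsistent lengths")

    @property
    def n_trials(self) -> int:
        return int(len(self.block))

    @property
    def n_valid_trials(self) -> int:
        return int((~self.missed).sum())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, subject_id=None) -> "ChoiceDataset":
        if subject_id is not None:
            frame = frame[frame["subject_id"] == subject_id]
        sids = frame["subject_id"].unique()
        if len(sids) != 1:
            raise ValueError("frame must contain exactly one subject")
        unknown = set(frame["recipient"]) - set(RECIPIENT_CODES)
        if unknown:
            raise ValueError(f"unknown recipient labels: {sorted(unknown)}")
        frame = frame.sort_values(["block", "trial"])
        group = str(frame["group"].iloc[0]) if "group" in frame else "sim"
        return cls(
            subject_id=str(sids[0]),
            block=frame["block"].to_numpy(dtype=np.int64),
            recipient=frame["recipient"].map(RECIPIENT_CODES).to_numpy(dtype=np.int64),
            chose_high=frame["chosen_is_high"].to_numpy(dtype=bool),
            outcome01=frame["outcome"].to_numpy(dtype=float) / POINTS_WIN,
            missed=frame["missed"].to_numpy(dtype=bool),
            group=group,
            side_of_high=frame["side_of_high"].to_numpy(dtype=object)
            if "side_of_high" in frame
            else None,
        )

    def to_frame(self) -> pd.DataFrame:
        trial_in_block = np.zeros(self.n_trials, dtype=np.int64)
        counts: dict[int, int] = {}
        for i, b in enumerate(self.block):
            counts[b] = counts.get(b, -1) + 1
            trial_in_block[i] = counts[b]
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "block": self.block,
                "trial": trial_in_block,
                "recipient": [RECIPIENT_NAMES[r] for r in self.recipient],
                "side_of_high": self.side_of_high
                if self.side_of_high is not None
                else "left",
                "chosen_is_high": self.chose_high.astype(int),
                "outcome": (self.outcome01 * POINTS_WIN).astype(int),
                "missed": self.missed.astype(int),
            }
        )

    def _kernel_arrays(self):
        """Valid-trial arrays: (chosen_low, outcome, new_block, recipient)."""
        cached = getattr(self, "_kernel_cache", None)
        if cached is not None:
            return cached
        valid = ~self.missed
        block = self.block[valid]
        new_block = np.empty(len(block), dtype=np.bool_)
        if len(block):
            new_block[0] = True
            new_block[1:] = block[1:] != block[:-1]
        arrays = (
            (~self.chose_high[valid]).astype(np.int64),
            self.outcome01[valid].astype(np.float64),
            new_block,
            self.recipient[valid].astype(np.int64),
        )
        object.__setattr__(self, "_kernel_cache", arrays)
        return arrays


# ---------------------------------------------------------------------------
# likelihood and simulation


def log_likelihood(
    dataset: ChoiceDataset, params: dict[str, float], spec: ModelSpec
) -> float:
    """Summed log choice probability over non-missed trials.

    Values are re-initialised to 0.5 at each block start (new stimuli) and
    updated trial by trial; missed trials contribute nothing and do not
    update values.
    """
    theta = np.array([params[name] for name in spec.param_names], dtype=np.float64)
    chosen_low, outcome, new_block, recip = dataset._kernel_arrays()
    if spec.is_wsls:
        return float(_kernels.ll_wsls(chosen_low, outcome, new_block, theta[0]))
    a_pos, a_neg, a_un, b_ix = spec._index_arrays()
    return float(
        _kernels.ll_value(
            chosen_low, outcome, new_block, recip, a_pos, a_neg, a_un, b_ix, theta
        )
    )


def simulate_agent(
    params: dict[str, float],
    spec: ModelSpec,
    schedule: Schedule,
    seed: int,
    *,
    subject_id: str | None = None,
    group: str = "sim",
) -> ChoiceDataset:
    """Simulate one agent playing the schedule under the given model.

    Choices are sampled from :func:`choice_probability`, outcomes from the
    block's 0.75/0.25 contingencies. Synthetic agents always respond (no
    missed trials). Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sid = subject_id if subject_id is not None else f"sim_{seed}"
    block_ix, recip, chose_high, out01, sides = [], [], [], [], []
    for b, blockobj in enumerate(schedule.blocks):
        state = ValueState()
        prev: tuple[bool, float] | None = None
        rname = blockobj.recipient.value
        for trial in blockobj.trials:
            p_high, _ = choice_probability(state, params, spec, rname, prev)
            high = rng.random() < p_high
            prob = blockobj.reward_prob_high if high else blockobj.reward_prob_low
            points = sample_outcome(prob, rng)
            r01 = points / POINTS_WIN
            state = update_values(state, high, r01, params, spec, rname)
            prev = (high, r01)
            block_ix.append(b)
            recip.append(RECIPIENT_CODES[rname])
            chose_high.append(high)
            out01.append(r01)
            sides.append(trial.side_of_high)
    n = len(block_ix)
    return ChoiceDataset(
        subject_id=sid,
        block=np.array(block_ix, dtype=np.int64),
        recipient=np.array(recip, dtype=np.int64),
        chose_high=np.array(chose_high, dtype=bool),
        outcome01=np.array(out01, dtype=float),
        missed=np.zeros(n, dtype=bool),
        group=group,
        side_of_high=np.array(sides, dtype=object),
    )


def simulate_trials_frame(
    params: dict[str, float], spec: ModelSpec, schedule: Schedule, seed: int, **kw
) -> pd.DataFrame:
    """Convenience: simulate an agent and return the long-format trial table."""
    return simulate_agent(params, spec, schedule, seed, **kw).to_frame()
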