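"""Model space: roster, value updates, choice rule, likelihood, simulation.

The likelihood oracle here recomposes the trial loop from the public
single-trial operations (`update_values` + `choice_probability`), which the
production kernel never calls — the two routes must agree to 1e-10.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import prolearn as pl
from conftest import draw_params
from prolearn.models import (
    RECIPIENT_NAMES,
    ChoiceDataset,
    ValueState,
    choice_probability,
    update_values,
)

ALL_MODELS = pl.enumerate_models()


# ---------------------------------------------------------------------------
# roster


def test_thirteen_distinct_models():
    assert len(ALL_MODELS) == 13
    assert len({m.model_id for m in ALL_MODELS}) == 13
    assert len({m.param_names for m in ALL_MODELS}) == 13


def test_winning_model_structure():
    spec = pl.get_model("ix")
    assert len(spec.alpha_names) == 6
    assert len(spec.beta_names) == 1
    assert spec.n_params == 7
    assert {f"alpha_{r}_{v}" for r in RECIPIENT_NAMES for v in ("pos", "neg")} == set(
        spec.alpha_names
    )


def test_wsls_has_no_learning_rates():
    spec = pl.get_model("xiii")
    assert spec.is_wsls
    assert spec.alpha_names == ()
    assert spec.param_names == ("consistency",)
    assert spec.n_params == 1


def test_model_roster_json():
    import json

    roster = json.loads(pl.model_roster_json())
    assert set(roster) == {m.model_id for m in ALL_MODELS}
    assert roster["ix"] == list(pl.get_model("ix").param_names)


# ---------------------------------------------------------------------------
# update_values


def test_update_values_examples():
    spec = pl.get_model("i")
    s = ValueState(0.5, 0.5)
    # zero learning rate: unchanged
    out = update_values(s, True, 1.0, {"alpha_all": 0.0, "beta": 1.0}, spec, "self")
    assert out.q_high == 0.5
    # full update to the outcome
    out = update_values(s, True, 1.0, {"alpha_all": 1.0, "beta": 1.0}, spec, "self")
    assert out.q_high == 1.0
    # hand arithmetic: 0.5 + 0.5 * (1 - 0.5)
    out = update_values(s, True, 1.0, {"alpha_all": 0.5, "beta": 1.0}, spec, "self")
    assert out.q_high == pytest.approx(0.75)
    with pytest.raises(ValueError):
        update_values(s, True, 0.7, {"alpha_all": 0.5, "beta": 1.0}, spec, "self")


def test_update_values_valence_cells():
    """delta >= 0 routes to the positive-PE rate, delta < 0 to the negative."""
    spec = pl.get_model("v")  # 2 alphas by valence
    params = {"alpha_all_pos": 0.8, "alpha_all_neg": 0.2, "beta": 1.0}
    up = update_values(ValueState(0.5, 0.5), True, 1.0, params, spec, "other")
    assert up.q_high == pytest.approx(0.5 + 0.8 * 0.5)
    down = update_values(ValueState(0.5, 0.5), True, 0.0, params, spec, "other")
    assert down.q_high == pytest.approx(0.5 - 0.2 * 0.5)
    # delta == 0 counts as a positive PE (outcome as good as expected)
    flat = update_values(ValueState(1.0, 0.5), True, 1.0, params, spec, "other")
    assert flat.q_high == 1.0


def test_update_values_unchosen_counterfactual():
    """Chosen/unchosen-split models push the unchosen value toward 1 - r."""
    spec = pl.get_model("vii")
    params = {"alpha_all_chosen": 0.5, "alpha_all_unchosen": 0.4, "beta": 1.0}
    out = update_values(ValueState(0.5, 0.5), True, 1.0, params, spec, "self")
    assert out.q_high == pytest.approx(0.75)
    assert out.q_low == pytest.approx(0.5 + 0.4 * (0.0 - 0.5))


def test_wsls_keeps_no_values():
    spec = pl.get_model("xiii")
    s = ValueState(0.3, 0.9)
    out = update_values(s, True, 1.0, {"consistency": 0.8}, spec, "self")
    assert (out.q_high, out.q_low) == (0.3, 0.9)


# ---------------------------------------------------------------------------
# choice_probability


def test_choice_probability_examples():
    spec = pl.get_model("i")
    assert choice_probability(
        ValueState(0.9, 0.1), {"alpha_all": 0.5, "beta": 0.0}, spec, "self"
    ) == (0.5, 0.5)
    assert choice_probability(
        ValueState(0.6, 0.6), {"alpha_all": 0.5, "beta": 7.0}, spec, "self"
    )[0] == pytest.approx(0.5)
    # hand-computed softmax: Q=(0.75, 0.50), beta=1 -> 1/(1+e^-0.25)
    p_high, p_low = choice_probability(
        ValueState(0.75, 0.50), {"alpha_all": 0.5, "beta": 1.0}, spec, "self"
    )
    assert p_high == pytest.approx(1.0 / (1.0 + math.exp(-0.25)), abs=1e-12)
    assert p_high == pytest.approx(0.5622, abs=1e-4)


def test_wsls_choice_probability():
    spec = pl.get_model("xiii")
    params = {"consistency": 0.8}
    assert choice_probability(ValueState(), params, spec, "self", None) == (0.5, 0.5)
    # stay after a win with p = c
    assert choice_probability(ValueState(), params, spec, "self", (True, 1.0))[0] == 0.8
    # shift after a loss with p = c
    assert choice_probability(ValueState(), params, spec, "self", (True, 0.0))[0] == pytest.approx(0.2)
    assert choice_probability(ValueState(), params, spec, "self", (False, 0.0))[0] == pytest.approx(0.8)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    model_index=st.integers(0, 12),
    qh=st.floats(0, 1),
    ql=st.floats(0, 1),
    seed=st.integers(0, 10_000),
)
def test_choice_probabilities_sum_to_one(model_index, qh, ql, seed):
    spec = ALL_MODELS[model_index]
    params = draw_params(spec, np.random.default_rng(seed))
    prev = (seed % 2 == 0, float(seed % 3 == 0))
    p = choice_probability(ValueState(qh, ql), params, spec, "other", prev)
    assert p[0] + p[1] == pytest.approx(1.0, abs=1e-12)
    assert 0.0 <= p[0] <= 1.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), model_index=st.integers(0, 11))
def test_values_stay_in_unit_interval(seed, model_index):
    """Q remains in [0,1] for any alpha in [0,1] and outcomes in {0,1}."""
    rng = np.random.default_rng(seed)
    spec = ALL_MODELS[model_index]
    params = draw_params(spec, rng)
    state = ValueState()
    for _ in range(60):
        state = update_values(
            state, bool(rng.integers(2)), float(rng.integers(2)), params, spec, "self"
        )
        assert 0.0 <= state.q_high <= 1.0
        assert 0.0 <= state.q_low <= 1.0


# ---------------------------------------------------------------------------
# log_likelihood


def loop_oracle(dataset, params, spec):
    """Naive per-trial recomposition from the public single-trial ops."""
    ll = 0.0
    by_block: dict[int, list[int]] = {}
    for i, b in enumerate(dataset.block):
        by_block.setdefault(int(b), []).append(i)
    for _b, idx in sorted(by_block.items()):
        state = ValueState()
        prev = None
        for i in idx:
            if dataset.missed[i]:
                continue
            rname = RECIPIENT_NAMES[dataset.recipient[i]]
            p = choice_probability(state, params, spec, rname, prev)
            chose_high = bool(dataset.chose_high[i])
            ll += math.log(p[0] if chose_high else p[1])
            out = float(dataset.outcome01[i])
            state = update_values(state, chose_high, out, params, spec, rname)
            prev = (chose_high, out)
    return ll


def test_loglik_uniform_policy(standard_schedule):
    spec = pl.get_model("i")
    ds = pl.simulate_agent({"alpha_all": 0.3, "beta": 2.0}, spec, standard_schedule, seed=1)
    ll = pl.log_likelihood(ds, {"alpha_all": 0.3, "beta": 0.0}, spec)
    assert ll == pytest.approx(144 * math.log(0.5), abs=1e-9)


def test_loglik_two_trial_hand_oracle():
    """Choose high, win, repeat: ln(0.5) + ln(0.5622) with alpha=0.5, beta=1."""
    ds = ChoiceDataset(
        subject_id="toy",
        block=np.array([0, 0]),
        recipient=np.array([0, 0]),
        chose_high=np.array([True, True]),
        outcome01=np.array([1.0, 1.0]),
        missed=np.array([False, False]),
    )
    spec = pl.get_model("i")
    ll = pl.log_likelihood(ds, {"alpha_all": 0.5, "beta": 1.0}, spec)
    expected = math.log(0.5) + math.log(1.0 / (1.0 + math.exp(-0.25)))
    assert ll == pytest.approx(expected, abs=1e-10)
    assert ll == pytest.approx(-1.269, abs=1e-3)


def test_loglik_matches_loop_oracle_all_models(random_param_draw):
    """Kernel likelihood equals the naive per-trial loop to 1e-10."""
    rng = np.random.default_rng(123)
    for rep in range(50):
        spec = ALL_MODELS[rep % 13]
        gen_params = random_param_draw(spec, rng)
        sch = pl.build_schedule(int(rng.integers(6)), seed=int(rng.integers(2**31)))
        ds = pl.simulate_agent(gen_params, spec, sch, seed=int(rng.integers(2**31)))
        eval_params = random_param_draw(spec, rng)
        fast = pl.log_likelihood(ds, eval_params, spec)
        slow = loop_oracle(ds, eval_params, spec)
        assert fast == pytest.approx(slow, abs=1e-10)


def test_loglik_missed_trials_ignored(standard_schedule):
    spec = pl.get_model("ix")
    params = {n: 0.4 for n in spec.alpha_names} | {"beta": 2.5}
    ds = pl.simulate_agent(params, spec, standard_schedule, seed=9)
    ll_full = pl.log_likelihood(ds, params, spec)
    # marking trials missed removes their contribution and their update
    missed = ds.missed.copy()
    missed[5] = True
    ds_miss = ChoiceDataset(
        subject_id=ds.subject_id,
        block=ds.block,
        recipient=ds.recipient,
        chose_high=ds.chose_high,
        outcome01=ds.outcome01,
        missed=missed,
    )
    ll_miss = pl.log_likelihood(ds_miss, params, spec)
    assert ll_miss != pytest.approx(ll_full)
    assert ll_miss == pytest.approx(loop_oracle(ds_miss, params, spec), abs=1e-10)


def test_unknown_recipient_label_rejected():
    import pandas as pd

    frame = pd.DataFrame(
        {
            "subject_id": ["a"],
            "group": ["g"],
            "block": [0],
            "trial": [0],
            "recipient": ["stranger"],
            "side_of_high": ["left"],
            "chosen_is_high": [1],
            "outcome": [100],
            "missed": [0],
        }
    )
    with pytest.raises(ValueError, match="recipient"):
        ChoiceDataset.from_frame(frame)


def test_nesting_ix_reduces_to_iii(standard_schedule):
    """Model ix with alpha_pos = alpha_neg per recipient equals model iii."""
    spec_ix, spec_iii = pl.get_model("ix"), pl.get_model("iii")
    rates = {"self": 0.3, "other": 0.55, "noone": 0.2}
    p_ix = {f"alpha_{r}_{v}": rates[r] for r in rates for v in ("pos", "neg")}
    p_ix["beta"] = 2.0
    p_iii = {f"alpha_{r}": rates[r] for r in rates} | {"beta": 2.0}
    ds = pl.simulate_agent(p_iii, spec_iii, standard_schedule, seed=21)
    assert pl.log_likelihood(ds, p_ix, spec_ix) == pytest.approx(
        pl.log_likelihood(ds, p_iii, spec_iii), abs=1e-10
    )


def test_outcome_scale_invariance(standard_schedule):
    """{0,100} points with Q0=50 and beta/100 match the normalised scale."""
    spec = pl.get_model("i")
    params = {"alpha_all": 0.35, "beta": 2.4}
    ds = pl.simulate_agent(params, spec, standard_schedule, seed=31)

    def points_scale_loop(alpha, beta_points):
        ll = 0.0
        q = {}
        for b in np.unique(ds.block):
            idx = np.where(ds.block == b)[0]
            qh, ql = 50.0, 50.0
            for i in idx:
                p_high = 1.0 / (1.0 + math.exp(-beta_points * (qh - ql)))
                ll += math.log(p_high if ds.chose_high[i] else 1 - p_high)
                r = ds.outcome01[i] * 100.0
                if ds.chose_high[i]:
                    qh += alpha * (r - qh)
                else:
                    ql += alpha * (r - ql)
        return ll

    assert pl.log_likelihood(ds, params, spec) == pytest.approx(
        points_scale_loop(0.35, 2.4 / 100.0), abs=1e-9
    )


# ---------------------------------------------------------------------------
# simulate_agent


def test_simulate_agent_deterministic(standard_schedule, winning_spec):
    params = {n: 0.4 for n in winning_spec.alpha_names} | {"beta": 3.0}
    a = pl.simulate_agent(params, winning_spec, standard_schedule, seed=77)
    b = pl.simulate_agent(params, winning_spec, standard_schedule, seed=77)
    np.testing.assert_array_equal(a.chose_high, b.chose_high)
    np.testing.assert_array_equal(a.outcome01, b.outcome01)


def test_greedy_limit():
    """Huge beta with one value forced high: the agent picks it nearly always."""
    spec = pl.get_model("i")
    p_high, _ = choice_probability(
        ValueState(0.9, 0.1), {"alpha_all": 0.5, "beta": 80.0}, spec, "self"
    )
    assert p_high > 1.0 - 1e-12


def test_simulate_agent_chance_at_beta_zero(standard_schedule):
    spec = pl.get_model("i")
    accs = []
    from prolearn.metrics import accuracy

    for seed in range(60):
        ds = pl.simulate_agent({"alpha_all": 0.4, "beta": 0.0}, spec, standard_schedule, seed=seed)
        accs.append(np.mean(list(accuracy(ds).values())))
    assert np.mean(accs) == pytest.approx(0.5, abs=0.03)


def test_simulated_accuracy_above_chance():
    """Agents at alpha_pos=0.4, alpha_neg=0.3, beta=3 beat chance clearly."""
    spec = pl.get_model("v")
    params = {"alpha_all_pos": 0.4, "alpha_all_neg": 0.3, "beta": 3.0}
    from prolearn.metrics import accuracy

    accs = []
    for seed in range(200):
        sch = pl.build_schedule(seed % 6, seed=seed)
        ds = pl.simulate_agent(params, spec, sch, seed=10_000 + seed)
        accs.append(np.mean(list(accuracy(ds).values())))
    assert np.mean(accs) > 0.6


def test_simulated_accuracy_monotone_in_beta():
    """Mean accuracy is non-decreasing in beta at fixed alpha (CRN seeds)."""
    spec = pl.get_model("i")
    from prolearn.metrics import accuracy

    means = []
    for beta in [0.0, 1.0, 3.0, 8.0]:
        accs = []
        for seed in range(80):
            sch = pl.build_schedule(seed % 6, seed=seed)
            ds = pl.simulate_agent(
                {"alpha_all": 0.4, "beta": beta}, spec, sch, seed=5_000 + seed
            )
            accs.append(np.mean(list(accuracy(ds).values())))
        means.append(np.mean(accs))
    assert all(b >= a - 0.01 for a, b in zip(means, means[1:]))
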