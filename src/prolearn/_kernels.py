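"""Inner likelihood loops, JIT-compiled with numba when available.

The trial loop is inherently sequential (each value update feeds the next
choice probability), so the hot path is a scalar loop over trials. With
numba this costs a few microseconds per 144-trial dataset; the pure-Python
fallback is ~30x slower but semantically identical and exercised by the
same tests.
"""

from __future__ import annotations

import math

Q_INIT = 0.5
_P_FLOOR = 1e-300


def _ll_value(chosen_low, outcome, new_block, recip, a_pos, a_neg, a_un, b_ix, theta):
    ll = 0.0
    q0 = Q_INIT  # high-probability symbol
    q1 = Q_INIT  # low-probability symbol
    for t in range(len(chosen_low)):
        if new_block[t]:
            q0 = Q_INIT
            q1 = Q_INIT
        r = recip[t]
        beta = theta[b_ix[r]]
        x = beta * (q0 - q1)
        if x > 700.0:
            p_high = 1.0
        elif x < -700.0:
            p_high = 0.0
        else:
            p_high = 1.0 / (1.0 + math.exp(-x))
        c = chosen_low[t]
        p = (1.0 - p_high) if c == 1 else p_high
        if p < _P_FLOOR:
            p = _P_FLOOR
        ll += math.log(p)
        out = outcome[t]
        qc = q1 if c == 1 else q0
        delta = out - qc
        if delta >= 0.0:
            a = theta[a_pos[r]]
        else:
            a = theta[a_neg[r]]
        qc = qc + a * delta
        if a_un[r] >= 0:
            au = theta[a_un[r]]
            if c == 1:
                q1 = qc
                q0 = q0 + au * ((1.0 - out) - q0)
            else:
                q0 = qc
                q1 = q1 + au * ((1.0 - out) - q1)
        else:
            if c == 1:
                q1 = qc
            else:
                q0 = qc
    return ll


def _ll_wsls(chosen_low, outcome, new_block, consistency):
    ll = 0.0
    prev_low = -1  # -1: no previous trial in block
    prev_win = False
    for t in range(len(chosen_low)):
        if new_block[t]:
            prev_low = -1
        c = chosen_low[t]
        if prev_low < 0:
            p = 0.5
        else:
            stayed = c == prev_low
            if prev_win:
                p = consistency if stayed else 1.0 - consistency
            else:
                p = 1.0 - consistency if stayed else consistency
        if p < _P_FLOOR:
            p = _P_FLOOR
        ll += math.log(p)
        prev_low = c
        prev_win = outcome[t] >= 0.5
    return ll


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    ll_value = njit(cache=False)(_ll_value)
    ll_wsls = njit(cache=False)(_ll_wsls)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    ll_value = _ll_value
    ll_wsls = _ll_wsls
    HAVE_NUMBA = False
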