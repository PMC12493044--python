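"""Behavioural metrics: accuracy and learning-rate difference scores.

Accuracy is the frequency of choosing the high-probability symbol,
regardless of the outcome actually received, computed per recipient over
non-missed trials. The learning-rate difference scores — other-no one,
other-self and self-no one, separately for positive- and negative-PE rates
from the winning six-learning-rate model — are the behavioural regressors
the lesion-symptom mapping consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import SubjectFit
from .models import RECIPIENT_NAMES, WINNING_MODEL_ID, ChoiceDataset

__all__ = [
    "accuracy",
    "learning_rate_differences",
    "behavioural_scores",
    "group_summary",
    "DIFFERENCE_NAMES",
]

#: the six VLSM regressor columns (three recipient contrasts x two valences)
DIFFERENCE_NAMES = tuple(
    f"diff_{pair}_{val}"
    for val in ("pos", "neg")
    for pair in ("other_noone", "other_self", "self_noone")
)


def accuracy(dataset: ChoiceDataset) -> dict[str, float]:
    """Per-recipient proportion of high-probability choices.

    Missed trials are excluded from the denominator; a recipient with no
    valid trials gets NaN (flagged by being NaN rather than raising).
    """
    out: dict[str, float] = {}
    valid = ~dataset.missed
    for code, name in enumerate(RECIPIENT_NAMES):
        sel = valid & (dataset.recipient == code)
        n = int(sel.sum())
        out[name] = float(dataset.chose_high[sel].mean()) if n else float("nan")
    return out


def learning_rate_differences(fit: SubjectFit) -> dict[str, float]:
    """The six recipient-contrast scores on the native (0, 1) rate scale.

    For each valence v in {pos, neg}: alpha_other_v - alpha_noone_v,
    alpha_other_v - alpha_self_v, alpha_self_v - alpha_noone_v. Requires a
    fit of the winning six-learning-rate model.
    """
    if fit.model_id != WINNING_MODEL_ID:
        raise ValueError(
            f"difference scores are defined for model {WINNING_MODEL_ID!r}, "
            f"got {fit.model_id!r}"
        )
    p = fit.params
    out = {}
    for val in ("pos", "neg"):
        out[f"diff_other_noone_{val}"] = p[f"alpha_other_{val}"] - p[f"alpha_noone_{val}"]
        out[f"diff_other_self_{val}"] = p[f"alpha_other_{val}"] - p[f"alpha_self_{val}"]
        out[f"diff_self_noone_{val}"] = p[f"alpha_self_{val}"] - p[f"alpha_noone_{val}"]
    return out


def behavioural_scores(
    datasets: list[ChoiceDataset], fits: list[SubjectFit]
) -> pd.DataFrame:
    """Tidy per-subject score table: accuracy, native rates, differences.

    One row per subject; column layout matches the ``scores.csv`` interface
    (accuracy_self/other/noone, alpha_{recipient}_{valence}, diff_* columns)
    and is ready for external mixed-model software.
    """
    by_id = {f.subject_id: f for f in fits}
    rows = []
    for ds in datasets:
        fit = by_id[ds.subject_id]
        row = {"subject_id": ds.subject_id, "group": ds.group}
        for name, value in accuracy(ds).items():
            row[f"accuracy_{name}"] = value
        for pname, value in fit.params.items():
            row[pname] = value
        row.update(learning_rate_differences(fit))
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary(scores: pd.DataFrame, value_columns: list[str] | None = None) -> pd.DataFrame:
    """Descriptive per-group summary with simple paired recipient contrasts.

    For each group and each value column: mean, SEM (NaN-flagged for single
    subjects), n. For accuracy columns the within-group self-vs-noone and
    other-vs-noone paired comparisons (two-sided t and Wilcoxon) are
    appended as descriptive statistics — not the mixed-model inference the
    full analysis would run on real data.
    """
    if value_columns is None:
        value_columns = [
            c
            for c in scores.columns
            if c.startswith(("accuracy_", "alpha_", "diff_")) or c == "beta"
        ]
    rows = []
    for group, sub in scores.groupby("group"):
        for col in value_columns:
            vals = sub[col].dropna().to_numpy()
            n = len(vals)
            rows.append(
                {
                    "group": group,
                    "measure": col,
                    "mean": float(np.mean(vals)) if n else float("nan"),
                    "sem": float(stats.sem(vals)) if n > 1 else float("nan"),
                    "n": n,
                }
            )
        for a, b in [
            ("accuracy_self", "accuracy_noone"),
            ("accuracy_other", "accuracy_noone"),
            ("accuracy_other", "accuracy_self"),
        ]:
            if a not in sub.columns or b not in sub.columns:
                continue
            x = sub[a].to_numpy()
            y = sub[b].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if len(x) < 2:
                continue
            t_res = stats.ttest_rel(x, y)
            d = x - y
            if np.allclose(d, 0):
                w_p = 1.0
            else:
                w_p = float(stats.wilcoxon(x, y, zero_method="wilcox").pvalue)
            rows.append(
                {
                    "group": group,
                    "measure": f"paired:{a}-{b}",
                    "mean": float(np.mean(d)),
                    "sem": float(stats.sem(d)),
                    "n": len(d),
                    "t_stat": float(t_res.statistic),
                    "t_p": float(t_res.pvalue),
                    "wilcoxon_p": w_p,
                }
            )
    return pd.DataFrame(rows)
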