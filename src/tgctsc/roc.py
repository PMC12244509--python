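"""Two-marker recurrence classifier: cutoff-pair grid, ROC envelope, Youden.

Given per-patient positivity rates for two markers and a binary recurrence
outcome, every pair of observed cutoff values (plus -inf) is evaluated: a
patient is predicted positive when both rates strictly exceed their cutoffs
(AND rule; OR and mean-score rules available for sensitivity analysis).
A single ROC curve is obtained as the Pareto-dominant (FPR, TPR) staircase
over the grid, closed at (0,0) and (1,1); its staircase area is the AUC. The
optimal cutoff pair maximizes the Youden index J = sensitivity +
specificity - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ValidationError

__all__ = ["RocResult", "validate_biomarker_table", "grid_roc", "youden_optimal"]

RULES = ("and", "or", "mean")


@dataclass
class RocResult:
    grid: pd.DataFrame  # c1, c2, sensitivity, specificity, youden_j
    envelope: pd.DataFrame  # fpr, tpr staircase, monotone nondecreasing
    auc: float
    best: tuple  # (c1, c2, J)
    rule: str = "and"


def validate_biomarker_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"marker1_rate", "marker2_rate", "outcome"}
    if not required.issubset(table.columns):
        raise ValidationError(f"biomarker table needs columns {sorted(required)}")
    rates = table[["marker1_rate", "marker2_rate"]].values
    if ((rates < 0) | (rates > 1)).any():
        raise ValidationError("positivity rates must lie in [0, 1]")
    outcomes = set(table["outcome"].astype(int))
    if outcomes - {0, 1}:
        raise ValidationError("outcome must be binary 0/1")
    if len(outcomes) < 2:
        raise ValidationError("both outcome classes must be present")
    if (table["outcome"] == 1).sum() < 2 or (table["outcome"] == 0).sum() < 2:
        raise ValidationError("need >= 2 patients per outcome class")
    return table


def _staircase_auc(fpr: np.ndarray, tpr: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Pareto envelope and its staircase area from raw (FPR, TPR) points."""
    pts = np.column_stack([fpr, tpr])
    pts = np.vstack([pts, [0.0, 0.0], [1.0, 1.0]])
    order = np.lexsort((-pts[:, 1], pts[:, 0]))
    pts = pts[order]
    env_x = [0.0]
    env_y = [0.0]
    best_tpr = 0.0
    for x, y in pts:
        if y > best_tpr:
            best_tpr = y
            if x == env_x[-1]:
                env_y[-1] = y
            else:
                env_x.append(x)
                env_y.append(y)
    if env_x[-1] < 1.0:
        env_x.append(1.0)
        env_y.append(best_tpr)
    env = pd.DataFrame({"fpr": env_x, "tpr": env_y})
    x = env["fpr"].to_numpy()
    y = env["tpr"].to_numpy()
    auc = float(np.sum((x[1:] - x[:-1]) * y[:-1]))
    return env, auc


def grid_roc(table: pd.DataFrame, rule: str = "and") -> RocResult:
    """Sensitivity/specificity over the full cutoff-pair grid plus the
    Pareto-envelope ROC and its AUC."""
    if rule not in RULES:
        raise ValidationError(f"rule must be one of {RULES}")
    table = validate_biomarker_table(table)
    m1 = table["marker1_rate"].to_numpy(dtype=float)
    m2 = table["marker2_rate"].to_numpy(dtype=float)
    pos = table["outcome"].to_numpy(dtype=int) == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())

    c1 = np.concatenate([[-np.inf], np.unique(m1)])
    c2 = np.concatenate([[-np.inf], np.unique(m2)])
    P1 = m1[None, :] > c1[:, None]  # len(c1) x patients
    P2 = m2[None, :] > c2[:, None]

    if rule == "and":
        # entry (i, k) = number of patients with m1 > c1[i] and m2 > c2[k]
        tp = (P1 * pos).astype(float) @ P2.T.astype(float)
        fp = (P1 * ~pos).astype(float) @ P2.T.astype(float)
    elif rule == "or":
        both_neg_pos = ((~P1) * pos).astype(float) @ (~P2).T.astype(float)
        both_neg_neg = ((~P1) * ~pos).astype(float) @ (~P2).T.astype(float)
        tp = n_pos - both_neg_pos
        fp = n_neg - both_neg_neg
    else:  # mean-score rule: (m1 + m2)/2 > (c1 + c2)/2
        s = (m1 + m2) / 2.0
        cut = (c1[:, None] + c2[None, :]) / 2.0
        pred = s[None, None, :] > cut[:, :, None]
        tp = (pred & pos[None, None, :]).sum(axis=2).astype(float)
        fp = (pred & ~pos[None, None, :]).sum(axis=2).astype(float)

    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    youden = sens + spec - 1.0

    g1, g2 = np.meshgrid(c1, c2, indexing="ij")
    grid = pd.DataFrame(
        {
            "c1": g1.ravel(),
            "c2": g2.ravel(),
            "sensitivity": sens.ravel(),
            "specificity": spec.ravel(),
            "youden_j": youden.ravel(),
        }
    )
    env, auc = _staircase_auc(1.0 - spec.ravel(), sens.ravel())
    result = RocResult(grid=grid, envelope=env, auc=auc, best=(np.nan, np.nan, np.nan), rule=rule)
    result.best = youden_optimal(result)
    return result


def youden_optimal(r: RocResult) -> tuple[float, float, float]:
    """Grid point maximizing J; ties broken by higher specificity, then lower
    c1, then lower c2."""
    if len(r.grid) == 0:
        raise ValidationError("empty cutoff grid")
    g = r.grid
    order = np.lexsort(
        (g["c2"].to_numpy(), g["c1"].to_numpy(), -g["specificity"].to_numpy(), -g["youden_j"].to_numpy())
    )
    row = g.iloc[order[0]]
    return (float(row["c1"]), float(row["c2"]), float(row["youden_j"]))
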