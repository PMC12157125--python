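"""Evaluation metrics: censoring-aware concordance index and ROC AUC.

The concordance index treats a pair (i, j) as evaluable when T*_i > T*_j and
subject j's event was observed (δ_j = 1); the pair is concordant when the
longer-lived subject carries the smaller predicted log relative hazard,
f_i < f_j.  Censored-versus-censored pairs are never evaluable.  Tied scores
are worth 0.5 under the default ``half`` policy (so uninformative constant
scores give exactly 0.5) or 0 under the literal ``strict`` counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

from .data import SurvivalDataset

__all__ = ["MetricReport", "concordance_index", "roc_auc"]


@dataclass(frozen=True)
class MetricReport:
    """C-index over all samples (C1), optional subgroup C-index (C2), AUC."""

    c_index_all: float
    c_index_subgroup: Optional[float] = None
    auc: Optional[float] = None
    n_pairs_evaluable: int = 0

    def __post_init__(self) -> None:
        for v in (self.c_index_all, self.c_index_subgroup, self.auc):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"index out of [0, 1]: {v}")
        if self.n_pairs_evaluable < 0:
            raise ValueError("n_pairs_evaluable must be non-negative")


def concordance_index(
    dataset: SurvivalDataset,
    scores,
    tie_policy: str = "half",
    return_pairs: bool = False,
):
    """Concordance index with explicit handling of tied scores.

    Parameters
    ----------
    tie_policy
        ``"half"`` counts score ties as 0.5 concordant (the convention that
        makes constant predictions score exactly 0.5); ``"strict"`` counts
        them as 0.
    return_pairs
        Also return the number of evaluable pairs.
    """
    if tie_policy not in ("half", "strict"):
        raise ValueError("tie_policy must be 'half' or 'strict'")
    f = np.asarray(scores, dtype=float)
    if f.shape != dataset.times.shape:
        raise ValueError("one score per record required")
    t, d = dataset.times, dataset.events

    concordant = 0.0
    evaluable = 0
    # j ranges over observed events; pairs are (i, j) with T_i > T_j
    for j in np.flatnonzero(d == 1):
        longer = t > t[j]
        evaluable += int(longer.sum())
        concordant += float((f[longer] < f[j]).sum())
        if tie_policy == "half":
            concordant += 0.5 * float((f[longer] == f[j]).sum())
    if evaluable == 0:
        raise ValueError("no evaluable pairs (need T*_i > T*_j with δ_j = 1)")
    c = concordant / evaluable
    return (c, evaluable) if return_pairs else c


def roc_auc(probabilities, labels) -> float:
    """Rank-statistic area under the ROC curve for the disease labels."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("roc_auc needs both label classes present")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))
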