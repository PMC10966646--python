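"""Evaluation metrics for active-learning campaigns.

Acquisition is scored as a retrieval task over the true potency ranking: the
"active" set is the top r fraction (r = 2% or 5% by default) of the pool by
true potency, and an acquired compound counts as a true positive if it falls
in that set. With N_acq acquired compounds and k actives,

    Recall = TP / k            (TP + FN = k)
    F1     = 2 TP / (N_acq + k)   (TP + FP = N_acq)

The expected TP under uniform random acquisition is r * N_acq, which gives the
random baseline Recall r * N_acq / k.

k is the round-half-up integer of r * n_total, so Recall can reach exactly 1.
Ties in true potency at the top-k boundary are broken by ascending compound id
for determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


def top_k_count(n_total: int, r: float) -> int:
    """Number of compounds in the top-r fraction: round-half-up of r*n_total, >= 1."""
    if not 0 < r < 1:
        raise ValueError(f"r must be in (0, 1), got {r}")
    if n_total < 1:
        raise ValueError(f"n_total must be >= 1, got {n_total}")
    return max(1, math.floor(r * n_total + 0.5))


@dataclass(frozen=True)
class TopKSpec:
    """The active set: ids of the k most potent compounds in a pool of n_total."""

    r: float
    n_total: int
    active_ids: frozenset = field(default_factory=frozenset)

    @property
    def k(self) -> int:
        return top_k_count(self.n_total, self.r)

    def __post_init__(self) -> None:
        if self.active_ids and len(self.active_ids) != self.k:
            raise ValueError(
                f"|active_ids| = {len(self.active_ids)} != k = {self.k}"
            )


def make_topk_spec(ids: Sequence, potency: np.ndarray, r: float) -> TopKSpec:
    """Build a TopKSpec from a pool's true potencies.

    Ranks by descending potency, ties broken by ascending id.
    """
    potency = np.asarray(potency, dtype=float)
    if len(ids) != len(potency):
        raise ValueError("ids and potency must have equal length")
    order = sorted(range(len(ids)), key=lambda i: (-potency[i], ids[i]))
    k = top_k_count(len(ids), r)
    return TopKSpec(r=r, n_total=len(ids), active_ids=frozenset(ids[i] for i in order[:k]))


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int


def confusion_counts(acquired_ids, spec: TopKSpec) -> ConfusionCounts:
    acquired = set(acquired_ids)
    tp = len(acquired & spec.active_ids)
    return ConfusionCounts(TP=tp, FP=len(acquired) - tp, FN=spec.k - tp)


def recall_topk(acquired_ids, spec: TopKSpec) -> float:
    """Fraction of the true top-k compounds contained in the acquired set."""
    if not spec.active_ids:
        raise ValueError("empty active set")
    c = confusion_counts(acquired_ids, spec)
    return c.TP / spec.k


def f1_topk(acquired_ids, spec: TopKSpec) -> float:
    """F1 of acquisition-as-classification: 2*TP / (N_acq + k)."""
    if not spec.active_ids:
        raise ValueError("empty active set")
    c = confusion_counts(acquired_ids, spec)
    denom = (c.TP + c.FP) + spec.k
    if denom == 0:
        raise ValueError("N_acq + k = 0")
    return 2 * c.TP / denom


def random_baseline_tp(r: float, n_acq: int) -> float:
    """Expected true positives when n_acq compounds are drawn uniformly: r * n_acq."""
    if n_acq < 0:
        raise ValueError(f"n_acq must be >= 0, got {n_acq}")
    return r * n_acq


def regression_metrics(
    predicted: np.ndarray, observed: np.ndarray
) -> Mapping[str, float]:
    """R2, Spearman rho and RMSE of predictions against observations.

    Observed values that are constant make R2 and rho undefined; those entries
    are returned as NaN while RMSE is still computed.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-D arrays")
    if len(predicted) < 2:
        raise ValueError("need at least 2 points")
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return {"r2": float("nan"), "spearman_rho": float("nan"), "rmse": rmse}
    ss_res = float(np.sum((observed - predicted) ** 2))
    rho = stats.spearmanr(predicted, observed).statistic
    return {"r2": 1.0 - ss_res / ss_tot, "spearman_rho": float(rho), "rmse": rmse}
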