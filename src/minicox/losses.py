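"""Training losses for neural Cox models.

Four losses share one convention: they are pure functions of a survival
table, a vector of per-record log relative hazards ``f`` (the scores), and a
batch index set Ω.  Each has a ``*_with_grad`` companion returning the
analytic gradient with respect to the scores, so any differentiable scoring
model can be trained by back-propagating that gradient.

* full-batched loss — averaged negative log partial likelihood over the
  whole dataset, risk sets over the whole dataset;
* mini-batched loss — the same expression restricted to a batch Ω, with
  risk sets intersected with Ω (valid down to |Ω| = 2);
* oracle loss — the negative full log-likelihood with the simulation
  ground-truth baseline λ0 ≡ 1 plugged in, usable only when that baseline
  is known;
* two-task loss — mini-batched loss plus binary cross-entropy on disease
  labels, with the cancer probability P = sigmoid(f) read off the same
  scalar output.

Risk sets use the inclusive convention (T*_j ≥ t) and tied event times share
a Breslow denominator.  A batch without events contributes zero survival
loss rather than an error; occurrences are tallied in ``EVENT_FREE_BATCHES``
so a training loop can report them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .data import SurvivalDataset

__all__ = [
    "Batch",
    "EVENT_FREE_BATCHES",
    "full_batched_loss",
    "full_batched_loss_with_grad",
    "mini_batched_loss",
    "mini_batched_loss_with_grad",
    "oracle_loss",
    "oracle_loss_with_grad",
    "true_loss",
    "binary_cross_entropy",
    "binary_cross_entropy_with_grad",
    "two_task_loss",
    "two_task_loss_with_grad",
    "partition_batches",
]

_CLAMP = 1e-12


class _Counter:
    """Tally of survival-loss evaluations that saw an event-free batch."""

    def __init__(self) -> None:
        self.count = 0

    def reset(self) -> None:
        self.count = 0


EVENT_FREE_BATCHES = _Counter()


@dataclass(frozen=True)
class Batch:
    """An index set Ω into a dataset; sizes down to 2 are meaningful."""

    member_indices: np.ndarray

    @staticmethod
    def of(indices) -> "Batch":
        idx = np.asarray(indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("batch indices must be one-dimensional")
        if len(np.unique(idx)) != idx.size:
            raise ValueError("batch indices must be unique")
        return Batch(idx)

    @property
    def size(self) -> int:
        return int(self.member_indices.size)


def _check_scores(dataset: SurvivalDataset, scores) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.shape != dataset.times.shape:
        raise ValueError("one score per record required")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return scores


def _cox_value_and_grad(times, events, scores):
    """Negative log partial likelihood (sum over events, unnormalised) and
    its gradient w.r.t. the scores, with inclusive tie-sharing risk sets.

    For each event i:  term = f_i − log Σ_{j: T_j ≥ T_i} exp(f_j).
    Gradient:  ∂/∂f_k = −[δ_k − e^{f_k} Σ_{events i: T_i ≤ T_k} 1/S_i].
    """
    n = times.size
    order = np.argsort(times, kind="stable")
    t_s, d_s, f_s = times[order], events[order], scores[order]

    # log S at each sorted position: logsumexp of scores with time ≥ t_pos,
    # computed tie-aware so equal times share the same denominator.
    shift = f_s.max()
    rev_cum = np.cumsum(np.exp(f_s - shift)[::-1])[::-1]  # Σ_{j≥pos} e^{f−shift}
    # first index of each tie group
    first_of_group = np.zeros(n, dtype=int)
    for i in range(1, n):
        first_of_group[i] = first_of_group[i - 1] if t_s[i] == t_s[i - 1] else i
    log_S = shift + np.log(rev_cum[first_of_group])

    ev = d_s == 1
    value = -np.sum(f_s[ev] - log_S[ev])

    # G_k = Σ over events i with T_i ≤ T_k of 1/S_i  (own event included)
    inv_S_event = np.where(ev, np.exp(-(log_S - shift)), 0.0)
    cum = np.cumsum(inv_S_event)
    # tie-aware: all events at T_k's own time are included; take the last
    # index of each tie group
    last_of_group = np.empty(n, dtype=int)
    last = n - 1
    for i in range(n - 1, -1, -1):
        if i < n - 1 and t_s[i] != t_s[i + 1]:
            last = i
        last_of_group[i] = last
    G = cum[last_of_group] * np.exp(-shift)
    grad_sorted = -(ev.astype(float) - np.exp(f_s) * G)

    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return float(value), grad


def full_batched_loss(dataset: SurvivalDataset, scores) -> float:
    """Averaged negative log partial likelihood over the full dataset."""
    return full_batched_loss_with_grad(dataset, scores)[0]


def full_batched_loss_with_grad(dataset: SurvivalDataset, scores):
    scores = _check_scores(dataset, scores)
    if not (dataset.events == 1).any():
        EVENT_FREE_BATCHES.count += 1
        return 0.0, np.zeros_like(scores)
    value, grad = _cox_value_and_grad(dataset.times, dataset.events, scores)
    n = dataset.n
    return value / n, grad / n


def mini_batched_loss(dataset: SurvivalDataset, scores, batch: Batch) -> float:
    """Batched negative log partial likelihood with within-batch risk sets."""
    return mini_batched_loss_with_grad(dataset, scores, batch)[0]


def mini_batched_loss_with_grad(dataset: SurvivalDataset, scores, batch: Batch):
    scores = _check_scores(dataset, scores)
    idx = batch.member_indices
    if batch.size < 2:
        raise ValueError("batch size must be at least 2")
    if idx.min() < 0 or idx.max() >= dataset.n:
        raise ValueError("batch indices out of range")
    t, d, f = dataset.times[idx], dataset.events[idx], scores[idx]
    grad = np.zeros_like(scores)
    if not (d == 1).any():
        EVENT_FREE_BATCHES.count += 1
        return 0.0, grad
    value, g = _cox_value_and_grad(t, d, f)
    grad[idx] = g / batch.size
    return value / batch.size, grad


def oracle_loss(dataset: SurvivalDataset, scores, batch: Batch | None = None) -> float:
    """Batched negative full log-likelihood with the known baseline λ0 ≡ 1."""
    return oracle_loss_with_grad(dataset, scores, batch)[0]


def oracle_loss_with_grad(dataset: SurvivalDataset, scores, batch: Batch | None = None):
    scores = _check_scores(dataset, scores)
    idx = batch.member_indices if batch is not None else np.arange(dataset.n)
    t, d, f = dataset.times[idx], dataset.events[idx], scores[idx]
    m = idx.size
    value = -np.sum(d * f - np.exp(f) * t) / m
    grad = np.zeros_like(scores)
    grad[idx] = -(d - np.exp(f) * t) / m
    return float(value), grad


def true_loss(dataset: SurvivalDataset, spec, class_assignments) -> float:
    """Benchmark loss: the full likelihood evaluated at the generative truth.

    Each record's score is set to the true log relative hazard φ of its
    generating class and the baseline is the known λ0 ≡ baseline_rate; this
    equals the oracle loss evaluated at the true scores.
    """
    classes = np.asarray(class_assignments)
    if classes.shape != dataset.times.shape:
        raise ValueError("one class per record required")
    phis = np.asarray(spec.class_log_hazards, dtype=float)
    if classes.min() < 0 or classes.max() >= phis.size:
        raise ValueError("record with unknown generating class")
    from .survival import ConstantBaseline, full_negative_log_likelihood

    return full_negative_log_likelihood(
        dataset, phis[classes], ConstantBaseline(spec.baseline_rate)
    )


def binary_cross_entropy(probabilities, labels) -> float:
    """−mean[y log P + (1−y) log(1−P)], probabilities clamped away from 0/1."""
    p = np.clip(np.asarray(probabilities, dtype=float), _CLAMP, 1 - _CLAMP)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must align")
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def binary_cross_entropy_with_grad(scores, labels):
    """BCE evaluated from logits (P = sigmoid(f)); gradient w.r.t. scores."""
    f = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    p = expit(f)
    value = binary_cross_entropy(p, y)
    grad = (p - y) / f.size
    return value, grad


def two_task_loss(dataset: SurvivalDataset, scores, labels, batch: Batch) -> float:
    """Mini-batched loss plus binary cross-entropy over the same batch."""
    return two_task_loss_with_grad(dataset, scores, labels, batch)[0]


def two_task_loss_with_grad(dataset: SurvivalDataset, scores, labels, batch: Batch):
    if labels is None:
        raise ValueError("two-task loss requires disease labels")
    labels = np.asarray(labels)
    if labels.shape != dataset.times.shape:
        raise ValueError("one label per record required")
    surv_value, surv_grad = mini_batched_loss_with_grad(dataset, scores, batch)
    idx = batch.member_indices
    scores = np.asarray(scores, dtype=float)
    bce_value, bce_grad_batch = binary_cross_entropy_with_grad(scores[idx], labels[idx])
    grad = surv_grad.copy()
    grad[idx] += bce_grad_batch
    return surv_value + bce_value, grad


def partition_batches(n: int, batch_size: int, rng: np.random.Generator):
    """Random disjoint batches covering all ``n`` indices once.

    Sampling is without replacement; a trailing batch of size 1 is merged
    into its predecessor so every batch is valid for the batched losses.
    """
    if batch_size < 2:
        raise ValueError("batch size must be at least 2")
    perm = rng.permutation(n)
    batches = [perm[i : i + batch_size] for i in range(0, n, batch_size)]
    if len(batches) > 1 and batches[-1].size == 1:
        batches[-2] = np.concatenate([batches[-2], batches[-1]])
        batches.pop()
    return [Batch.of(b) for b in batches]
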