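"""Training loop and simulation experiment drivers.

``train`` runs seeded SGD over random batch partitions of the data.  The
loss kind decides both the objective and the batching regime:

* ``oracle`` — batched negative full log-likelihood with the known unit
  baseline (simulation ground truth only);
* ``mini_batched`` — batched partial likelihood with within-batch risk sets;
* ``full_batched`` — one full-dataset gradient step per epoch, risk sets
  over the whole training set;
* ``two_task`` / ``two_task_full`` — mini-batched (resp. full-batched)
  partial likelihood plus binary cross-entropy on disease labels through
  the shared sigmoid output.

Test-set evaluation uses the full test set: the full-batched loss value
(plus BCE for the two-task kinds; the oracle loss for the oracle kind), the
concordance index over all samples (C1), a subgroup concordance (C2 — the
cancer group when labels exist, otherwise the event cases when censoring is
present), and ROC AUC when labels exist.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import losses as L
from .data import SurvivalDataset
from .metrics import MetricReport, concordance_index, roc_auc
from .models import NetworkSpec, build_sim_net_ab, build_sim_net_c
from .simdata import (
    NoduleParams,
    SimulationSpec,
    apply_median_censoring,
    ledger_frame,
    make_nodule_images,
    make_two_class_images,
    simulate_survival_times,
    stack_pixels,
)

__all__ = [
    "TrainConfig",
    "History",
    "train",
    "evaluate",
    "run_simulation_a",
    "run_simulation_b",
    "run_simulation_c",
    "SimulationResult",
]

LOSS_KINDS = ("oracle", "full_batched", "mini_batched", "two_task", "two_task_full")


@dataclass(frozen=True)
class TrainConfig:
    loss_kind: str = "mini_batched"
    batch_size: int = 64
    epochs: int = 30
    learning_rate: float = 0.01
    momentum: float = 0.9
    grad_clip: float = 5.0
    lr_decay: float = 1.0  # multiplicative per-epoch decay (1 = constant)
    seed: int = 0
    eval_every: int = 1

    def __post_init__(self) -> None:
        if self.loss_kind not in LOSS_KINDS:
            raise ValueError(f"loss_kind must be one of {LOSS_KINDS}")
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs must be ≥ 1 and learning_rate positive")


class History:
    """Per-epoch training log: losses and test metrics."""

    COLUMNS = ["epoch", "train_loss", "test_loss", "auc", "c1", "c2"]

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def append(self, **row) -> None:
        self.rows.append({k: row.get(k, np.nan) for k in self.COLUMNS})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def last(self, column: str):
        frame = self.to_frame()
        series = frame[column].dropna()
        return float(series.iloc[-1]) if len(series) else np.nan

    def __len__(self) -> int:
        return len(self.rows)


def _forward_chunks(net, images, chunk: int = 256) -> np.ndarray:
    scores = np.empty(images.shape[0])
    for start in range(0, images.shape[0], chunk):
        out = net.forward(images[start : start + chunk])
        scores[start : start + chunk] = out[:, 0]
    return scores


def _loss_and_score_grad(kind: str, dataset: SurvivalDataset, scores, batch):
    """Dispatch to the loss for this kind; returns (value, dL/dscores)."""
    if kind == "oracle":
        return L.oracle_loss_with_grad(dataset, scores, batch)
    if kind in ("mini_batched", "full_batched"):
        return L.mini_batched_loss_with_grad(dataset, scores, batch)
    if kind in ("two_task", "two_task_full"):
        return L.two_task_loss_with_grad(dataset, scores, dataset.labels, batch)
    raise ValueError(kind)


def _test_loss(kind: str, dataset: SurvivalDataset, scores) -> float:
    if kind == "oracle":
        return L.oracle_loss(dataset, scores)
    value = L.full_batched_loss(dataset, scores)
    if kind in ("two_task", "two_task_full"):
        value += L.binary_cross_entropy(expit(scores), dataset.labels)
    return value


def _metric_report(dataset: SurvivalDataset, scores) -> MetricReport:
    c1, n_pairs = concordance_index(dataset, scores, return_pairs=True)
    c2 = None
    auc = None
    if dataset.labels is not None:
        subgroup = np.flatnonzero(dataset.labels == 1)
        if subgroup.size >= 2 and (dataset.events[subgroup] == 1).any():
            c2 = concordance_index(dataset.subset(subgroup), scores[subgroup])
        auc = roc_auc(expit(scores), dataset.labels)
    elif (dataset.events == 0).any():
        subgroup = np.flatnonzero(dataset.events == 1)
        if subgroup.size >= 2:
            c2 = concordance_index(dataset.subset(subgroup), scores[subgroup])
    return MetricReport(c_index_all=c1, c_index_subgroup=c2, auc=auc,
                        n_pairs_evaluable=n_pairs)


def train(
    model: NetworkSpec,
    images: np.ndarray,
    dataset: SurvivalDataset,
    config: TrainConfig,
    test_images: Optional[np.ndarray] = None,
    test_dataset: Optional[SurvivalDataset] = None,
    image_ids=None,
    chunk: int = 600,
) -> History:
    """Seeded SGD training of a runnable scoring network.

    ``images`` must be aligned with ``dataset`` row-for-row; when
    ``image_ids`` is given it is checked against the dataset's sample ids
    before training starts.
    """
    if model.network is None:
        raise ValueError(f"{model.name} is not runnable (structural spec only)")
    images = np.asarray(images, dtype=np.float32)
    if test_images is not None:
        test_images = np.asarray(test_images, dtype=np.float32)
    if images.shape[0] != dataset.n:
        raise ValueError("images and survival records are misaligned")
    if image_ids is not None and list(map(str, image_ids)) != list(
        map(str, dataset.sample_ids)
    ):
        raise ValueError("image sample_ids do not match the survival table")
    if config.loss_kind in ("two_task", "two_task_full") and dataset.labels is None:
        raise ValueError("two-task training requires disease labels")

    from .nn import SGD

    net = model.network
    opt = SGD(net.parameters(), lr=config.learning_rate, momentum=config.momentum,
              clip_norm=config.grad_clip)
    history = History()
    full_batch = config.loss_kind in ("full_batched", "two_task_full")

    for epoch in range(1, config.epochs + 1):
        opt.lr = config.learning_rate * config.lr_decay ** (epoch - 1)
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 100 + epoch)))
        if full_batch:
            batches = [L.Batch.of(np.arange(dataset.n))]
        else:
            batches = L.partition_batches(dataset.n, config.batch_size, rng)
        epoch_loss = 0.0
        for batch in batches:
            idx = batch.member_indices
            sub = dataset.subset(idx)
            local = L.Batch.of(np.arange(idx.size))
            if idx.size > chunk:
                # memory-bounded full-batch step: score pass, then
                # chunked re-forward + backward accumulating grads
                scores = _forward_chunks(net, images[idx], chunk)
                value, gscores = _loss_and_score_grad(config.loss_kind, sub, scores, local)
                opt.zero_grad()
                for start in range(0, idx.size, chunk):
                    sl = slice(start, start + chunk)
                    net.forward(images[idx[sl]])
                    net.backward(gscores[sl][:, None])
            else:
                out = net.forward(images[idx])
                value, gscores = _loss_and_score_grad(
                    config.loss_kind, sub, out[:, 0], local
                )
                opt.zero_grad()
                net.backward(gscores[:, None])
            opt.step()
            epoch_loss += value * idx.size
        epoch_loss /= dataset.n

        row = {"epoch": epoch, "train_loss": epoch_loss}
        if (
            test_dataset is not None
            and (epoch % config.eval_every == 0 or epoch == config.epochs)
        ):
            scores = _forward_chunks(net, test_images, chunk)
            row["test_loss"] = _test_loss(config.loss_kind, test_dataset, scores)
            report = _metric_report(test_dataset, scores)
            row["c1"] = report.c_index_all
            if report.c_index_subgroup is not None:
                row["c2"] = report.c_index_subgroup
            if report.auc is not None:
                row["auc"] = report.auc
        history.append(**row)
    return history


def evaluate(model: NetworkSpec, images, dataset: SurvivalDataset,
             chunk: int = 256) -> MetricReport:
    """Score a dataset with a trained network and report C-index/AUC."""
    if model.network is None:
        raise ValueError(f"{model.name} is not runnable")
    scores = _forward_chunks(model.network, images, chunk)
    return _metric_report(dataset, scores)


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    reports: dict
    histories: dict
    train_dataset: SurvivalDataset
    test_dataset: SurvivalDataset
    ledger: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for kind, history in self.histories.items():
            history.to_csv(out / f"metrics_{kind}.csv")
        self.ledger.to_csv(out / "ledger.csv", index=False)


def _two_class_data(spec: SimulationSpec, censor: bool):
    samples = make_two_class_images(spec)
    classes = np.array([s.class_id for s in samples])
    times = simulate_survival_times(spec, classes)
    dataset = SurvivalDataset(
        times, np.ones(len(samples), dtype=int),
        sample_ids=[s.sample_id for s in samples],
    )
    if censor:
        dataset = apply_median_censoring(dataset, classes, seed=spec.seed + 17)
    ledger = ledger_frame(samples, dataset, spec=spec)
    pixels = stack_pixels(samples)
    n_tr = spec.n_train
    split = dict(
        train_images=pixels[:n_tr],
        train_dataset=dataset.subset(np.arange(n_tr)),
        test_images=pixels[n_tr:],
        test_dataset=dataset.subset(np.arange(n_tr, dataset.n)),
        classes=classes,
    )
    return split, ledger


def _run_two_class(spec, losses, config: TrainConfig, censor: bool,
                   out_dir=None) -> SimulationResult:
    split, ledger = _two_class_data(spec, censor)
    reports, histories = {}, {}
    for kind in losses:
        model = build_sim_net_ab(seed=config.seed + LOSS_KINDS.index(kind))
        cfg = replace(config, loss_kind=kind)
        history = train(
            model, split["train_images"], split["train_dataset"], cfg,
            test_images=split["test_images"], test_dataset=split["test_dataset"],
        )
        reports[kind] = evaluate(model, split["test_images"], split["test_dataset"])
        histories[kind] = history
    result = SimulationResult(reports, histories, split["train_dataset"],
                              split["test_dataset"], ledger)
    if out_dir is not None:
        result.write(out_dir)
    return result


def run_simulation_a(
    spec: Optional[SimulationSpec] = None,
    config: Optional[TrainConfig] = None,
    losses=("oracle", "full_batched", "mini_batched"),
    out_dir=None,
) -> SimulationResult:
    """Two-class design, events only: compare oracle/full/mini losses."""
    spec = spec or SimulationSpec(censoring_scheme="none")
    config = config or TrainConfig()
    return _run_two_class(spec, losses, config, censor=False, out_dir=out_dir)


def run_simulation_b(
    spec: Optional[SimulationSpec] = None,
    config: Optional[TrainConfig] = None,
    losses=("oracle", "full_batched", "mini_batched"),
    out_dir=None,
) -> SimulationResult:
    """Two-class design with median censoring: reports C1 (all pairs) and
    C2 (event cases only)."""
    spec = spec or SimulationSpec(censoring_scheme="median_half")
    config = config or TrainConfig()
    return _run_two_class(spec, losses, config, censor=True, out_dir=out_dir)


def run_simulation_c(
    spec: Optional[SimulationSpec] = None,
    config: Optional[TrainConfig] = None,
    params: NoduleParams = NoduleParams(),
    losses=("two_task_full", "two_task"),
    out_dir=None,
    configs: Optional[dict] = None,
) -> SimulationResult:
    """Nodule design with the two-task loss in both batch regimes; reports
    AUC, C1 (all samples) and C2 (cancer group).

    ``configs`` optionally maps a loss kind to its own TrainConfig (the
    full-batch regime usually wants a different schedule); kinds not in
    the mapping fall back to ``config``.
    """
    spec = spec or SimulationSpec(censoring_scheme="nodule_cifar")
    config = config or TrainConfig(loss_kind="two_task")
    configs = configs or {}
    samples, dataset = make_nodule_images(spec, params)
    ledger = ledger_frame(samples, dataset, hazard_scale=params.hazard_scale)
    pixels = stack_pixels(samples)
    n_tr = spec.n_train
    train_images, test_images = pixels[:n_tr], pixels[n_tr:]
    train_ds = dataset.subset(np.arange(n_tr))
    test_ds = dataset.subset(np.arange(n_tr, dataset.n))
    reports, histories = {}, {}
    for kind in losses:
        base = configs.get(kind, config)
        model = build_sim_net_c(seed=base.seed + LOSS_KINDS.index(kind))
        cfg = replace(base, loss_kind=kind)
        history = train(model, train_images, train_ds, cfg,
                        test_images=test_images, test_dataset=test_ds)
        reports[kind] = evaluate(model, test_images, test_ds)
        histories[kind] = history
    result = SimulationResult(reports, histories, train_ds, test_ds, ledger)
    if out_dir is not None:
        result.write(out_dir)
    return result
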