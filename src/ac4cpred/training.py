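"""Training protocol and cross-validation driver.

The protocol: Adam at learning rate 1e-4, batch size 64, binary cross-entropy
loss, at most 300 epochs, early stopping when 0.5*MCC + AUC on the validation
set fails to improve for 20 consecutive epochs; the best-epoch weights are
restored on exit. Cross-validation carves an inner validation split from the
training folds for the early-stopping monitor, so the held-out fold is never
seen before scoring (``monitor="heldout"`` reproduces the literal protocol
that monitors the held-out fold itself).
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .encoding import stack_features
from .metrics import METRIC_NAMES, MetricsReport, evaluate, format_percent
from .network import Ac4cNet, ModelConfig, build_model, predict
from .seqdata import SeqDataset, kfold_indices, stratified_split

__all__ = ["TrainConfig", "TrainHistory", "EpochRecord", "CVReport",
           "Adam", "train", "run_cv", "evaluate_model", "selection_metric"]


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 300
    patience: int = 20
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.patience < self.max_epochs):
            raise ValueError("need 0 < patience < max_epochs")
        if not (0.0 < self.validation_fraction < 0.5):
            raise ValueError("validation_fraction must be in (0, 0.5)")
        if self.learning_rate < 0 or self.batch_size < 1:
            raise ValueError("invalid learning_rate or batch_size")


@dataclasses.dataclass
class EpochRecord:
    epoch: int  # 1-based
    train_loss: float
    val_report: MetricsReport
    selection: float


@dataclasses.dataclass
class TrainHistory:
    epochs: list[EpochRecord]
    best_epoch: int
    stopped_early: bool

    @property
    def best_selection(self) -> float:
        return self.epochs[self.best_epoch - 1].selection


def selection_metric(report: MetricsReport) -> float:
    """The early-stopping criterion 0.5*MCC + AUC (MCC on [-1,1], AUC on [0,1])."""
    return 0.5 * report.MCC + report.AUC


class Adam:
    """Adam optimiser over a parameter list."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _bce_loss(scores: Tensor, y: np.ndarray, eps: float = 1e-7) -> Tensor:
    yt = Tensor(y.astype(np.float32))
    return -(yt * (scores + eps).log()
             + (1.0 - yt) * (1.0 - scores + eps).log()).mean()


def train(model: Ac4cNet, train_ds: SeqDataset, val_ds: SeqDataset,
          cfg: TrainConfig) -> tuple[Ac4cNet, TrainHistory]:
    """Fit the model in place and return it with the epoch-by-epoch history.

    Deterministic given ``cfg.seed`` (epoch shuffles are derived from it) and
    the model's own construction seed.
    """
    if train_ds.window_length != model.cfg.window_length:
        raise ValueError(
            f"model expects windows of {model.cfg.window_length} nt, "
            f"data has {train_ds.window_length}")
    if val_ds.window_length != train_ds.window_length:
        raise ValueError("train and validation window lengths differ")
    if len(set(val_ds.labels.tolist())) < 2:
        raise ValueError("validation set must contain both classes "
                         "(MCC/AUC are undefined otherwise)")

    X, y = stack_features(train_ds, model.cfg.encoder)
    Xval, yval = stack_features(val_ds, model.cfg.encoder)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    history: list[EpochRecord] = []
    best_sel = -np.inf
    best_epoch = 0
    best_state: dict[str, np.ndarray] | None = None
    stopped_early = False

    for epoch in range(1, cfg.max_epochs + 1):
        model.train(True)
        order = rng.permutation(len(X))
        losses = []
        for lo in range(0, len(X), cfg.batch_size):
            idx = order[lo: lo + cfg.batch_size]
            model.zero_grad()
            scores = model(X[idx])
            loss = _bce_loss(scores, y[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        val_scores = predict(model, Xval)
        report = evaluate(yval.astype(int), val_scores)
        sel = selection_metric(report)
        history.append(EpochRecord(epoch, float(np.mean(losses)), report, sel))

        if sel > best_sel:  # strict improvement; earliest best epoch wins ties
            best_sel = sel
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        elif epoch - best_epoch >= cfg.patience:
            stopped_early = True
            break

    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model, TrainHistory(history, best_epoch, stopped_early)


def evaluate_model(model: Ac4cNet, ds: SeqDataset, threshold: float = 0.5
                   ) -> MetricsReport:
    """Score a dataset with a trained model and compute the metric report."""
    X, y = stack_features(ds, model.cfg.encoder)
    return evaluate(y.astype(int), predict(model, X), threshold)


@dataclasses.dataclass
class CVReport:
    """Per-fold metric reports plus mean +/- sd summaries."""

    fold_reports: list[MetricsReport]
    fold_histories: list[TrainHistory]

    def metric_matrix(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.fold_reports]
        return pd.DataFrame(rows, index=range(len(rows)))

    def mean_sd(self) -> dict[str, tuple[float, float]]:
        df = self.metric_matrix()
        return {m: (float(df[m].mean()), float(df[m].std(ddof=1)))
                for m in METRIC_NAMES}

    def summary(self) -> str:
        """Per-fold table on the percent scale, with a mean +/- sd footer."""
        lines = ["Fold\t" + "\t".join(f"{m} (%)" for m in METRIC_NAMES)]
        for i, r in enumerate(self.fold_reports):
            vals = r.as_dict()
            lines.append(f"{i}\t" + "\t".join(format_percent(vals[m])
                                              for m in METRIC_NAMES))
        ms = self.mean_sd()
        lines.append("mean\t" + "\t".join(
            f"{100 * ms[m][0]:.2f} ± {100 * ms[m][1]:.2f}" for m in METRIC_NAMES))
        return "\n".join(lines)


def run_cv(ds: SeqDataset, model_cfg: ModelConfig, train_cfg: TrainConfig,
           k: int = 10, monitor: Literal["inner", "heldout"] = "inner"
           ) -> CVReport:
    """Stratified k-fold cross-validation of the full training protocol.

    Each fold trains a fresh model on the k-1 training folds (with an inner
    early-stopping split of ``validation_fraction``) and is scored on the
    untouched held-out fold. Fold membership is keyed on record ids and
    derived from ``train_cfg.seed``.
    """
    folds = kfold_indices(ds, k, train_cfg.seed)
    reports: list[MetricsReport] = []
    histories: list[TrainHistory] = []
    for fold_no, (train_ids, held_ids) in enumerate(folds):
        fold_train = ds.subset_by_ids(train_ids)
        held = ds.subset_by_ids(held_ids)
        if monitor == "heldout":
            fit_ds, val_ds = fold_train, held
        else:
            fit_ds, val_ds = stratified_split(
                fold_train, train_cfg.validation_fraction,
                seed=train_cfg.seed + 1000 + fold_no)
        cfg = dataclasses.replace(model_cfg, window_length=ds.window_length,
                                  seed=model_cfg.seed + fold_no)
        fold_tcfg = dataclasses.replace(train_cfg, seed=train_cfg.seed + fold_no)
        model = build_model(cfg)
        model, hist = train(model, fit_ds, val_ds, fold_tcfg)
        # leakage guard: the monitor never sees the held-out fold
        if monitor == "inner":
            assert not (set(val_ds.ids) & set(held.ids))
        reports.append(evaluate_model(model, held))
        histories.append(hist)
    return CVReport(reports, histories)
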