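"""Training loop, optimizer and the two-architecture comparison harness.

Defaults follow the experiment's stated hyper-parameters: Adam with
learning rate 0.001 and per-step decay 1e-6, batch size 16, binary
cross-entropy, 40 epochs with the best-validation-loss checkpoint kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor, bce_with_logits
from .layers import Module, count_parameters, encode_image
from .metrics import MetricsReport, compute_metrics
from .network import ModelConfig, QcsaNetwork, build_qcsa_network, predict

__all__ = ["TrainConfig", "TrainHistory", "Adam", "train",
           "compare_architectures", "TABLE_COLUMNS"]

TABLE_COLUMNS = ["Architecture", "Epoch", "Total parameters",
                 "Trainable parameters", "Test accuracy", "Precision",
                 "Recall", "F1-score", "AUC", "Cohens kappa"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters (defaults as in the experiment)."""

    optimizer: str = "adam"
    lr: float = 0.001
    decay: float = 1e-6
    batch_size: int = 16
    epochs: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("lr must be non-negative")
        if min(self.batch_size, self.epochs) < 1 or self.decay < 0:
            raise ValueError("batch_size/epochs must be positive, decay >= 0")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


@dataclass
class TrainHistory:
    """Per-epoch curves; one entry per completed epoch."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    train_precision: list[float] = field(default_factory=list)
    train_recall: list[float] = field(default_factory=list)
    train_f1: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_precision: list[float] = field(default_factory=list)
    val_recall: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self) + 1),
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "train_precision": self.train_precision,
            "train_recall": self.train_recall,
            "train_f1": self.train_f1,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
            "val_precision": self.val_precision,
            "val_recall": self.val_recall,
            "val_f1": self.val_f1,
        })


class Adam(object):
    """Adam with the classical per-step learning-rate decay
    ``lr_t = lr / (1 + decay * t)``."""

    def __init__(self, params, lr: float = 0.001, decay: float = 1e-6,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.decay = lr, decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * self.t)
        b1, b2 = self.beta1, self.beta2
        corr = lr_t * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data = p.data - corr * m / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _bce_loss_value(model: Module, x: np.ndarray, y: np.ndarray,
                    batch_size: int = 64) -> float:
    losses, counts = [], []
    for lo in range(0, len(x), batch_size):
        logits = model(Tensor(x[lo:lo + batch_size]))
        losses.append(float(bce_with_logits(logits, y[lo:lo + batch_size]).data))
        counts.append(len(y[lo:lo + batch_size]))
    return float(np.average(losses, weights=counts))


def train(model: QcsaNetwork, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
          cfg: TrainConfig = TrainConfig(),
          class_weights: dict[int, float] | None = None,
          encode_mode: str = "gray-replicate",
          verbose: int = 0) -> tuple[QcsaNetwork, TrainHistory]:
    """Train in place on images in [0, 1]; returns (model, history).

    Mini-batches are reshuffled every epoch from ``cfg.seed``; the
    parameters with the best validation loss are restored at the end (the
    final epoch count still honours ``cfg.epochs``).  ``class_weights``
    maps label -> weight for the weighted cross-entropy.
    """
    if len(x_train) == 0:
        raise ValueError("empty training split")
    x_train = _ensure_encoded(x_train, encode_mode)
    y_train = np.asarray(y_train, dtype=np.float32)
    has_val = x_val is not None and len(x_val) > 0
    if has_val:
        x_val = _ensure_encoded(x_val, encode_mode)
        y_val = np.asarray(y_val, dtype=np.float32)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, decay=cfg.decay)
    history = TrainHistory()
    sample_w = None
    if class_weights is not None:
        sample_w = np.array([class_weights[int(t)] for t in y_train],
                            dtype=np.float32)
    best_loss, best_state = np.inf, None
    n = len(x_train)
    for epoch in range(cfg.epochs):
        model.train(True)
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_pred, epoch_true = [], []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            wb = sample_w[idx] if sample_w is not None else None
            logits = model(Tensor(xb))
            loss = bce_with_logits(logits, yb, weights=wb)
            opt.zero_grad()
            loss.backward()
            if cfg.lr > 0:
                opt.step()
            epoch_loss += float(loss.data) * len(idx)
            epoch_pred.append((logits.data >= 0).astype(int))
            epoch_true.append((yb >= 0.5).astype(int))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            train_rep = compute_metrics(np.concatenate(epoch_true),
                                        np.concatenate(epoch_pred))
        history.train_loss.append(epoch_loss / n)
        history.train_accuracy.append(train_rep.accuracy)
        history.train_precision.append(train_rep.precision)
        history.train_recall.append(train_rep.recall)
        history.train_f1.append(train_rep.f1)
        if has_val:
            model.eval()
            val_scores = predict(model, x_val)
            val_pred = (val_scores >= 0.5).astype(int)
            rep = compute_metrics(y_val.astype(int), val_pred, val_scores)
            vloss = _bce_loss_value(model, x_val, y_val)
            history.val_loss.append(vloss)
            history.val_accuracy.append(rep.accuracy)
            history.val_precision.append(rep.precision)
            history.val_recall.append(rep.recall)
            history.val_f1.append(rep.f1)
            if vloss < best_loss:
                best_loss = vloss
                best_state = model.state_arrays()
                history.best_epoch = epoch + 1
        else:
            history.val_loss.append(float("nan"))
            history.val_accuracy.append(float("nan"))
            history.val_precision.append(float("nan"))
            history.val_recall.append(float("nan"))
            history.val_f1.append(float("nan"))
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs} "
                  f"loss={history.train_loss[-1]:.4f} "
                  f"acc={history.train_accuracy[-1]:.4f} "
                  f"val_loss={history.val_loss[-1]:.4f} "
                  f"val_acc={history.val_accuracy[-1]:.4f}")
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model, history


def _ensure_encoded(x: np.ndarray, encode_mode: str) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim == 4 and x.shape[1] == 4:
        return x.astype(np.float32)
    return encode_image(x, mode=encode_mode)


def evaluate(model: QcsaNetwork, x: np.ndarray, y: np.ndarray,
             encode_mode: str = "gray-replicate") -> MetricsReport:
    """Metrics of ``model`` on a labeled set (threshold 0.5)."""
    scores = predict(model, _ensure_encoded(x, encode_mode))
    return compute_metrics(np.asarray(y).astype(int),
                           (scores >= 0.5).astype(int), scores)


def compare_architectures(x_train, y_train, x_test, y_test,
                          model_cfg: ModelConfig | None = None,
                          train_cfg: TrainConfig = TrainConfig(),
                          x_val=None, y_val=None,
                          class_weights: dict[int, float] | None = None,
                          verbose: int = 0
                          ) -> tuple[MetricsReport, MetricsReport, pd.DataFrame]:
    """Train the attention-free twin and the attention model identically.

    Both networks share hyper-parameters, initial seed and data order; the
    returned table has one row per architecture in the canonical column
    order (architecture, epochs, parameter counts, then the test metrics).
    """
    from dataclasses import replace

    model_cfg = model_cfg or ModelConfig.miniature()
    reports, rows = [], []
    for name, use_attention in [("Quaternion residual network", False),
                                ("Quaternion residual attention network", True)]:
        cfg = replace(model_cfg, use_attention=use_attention)
        net = build_qcsa_network(cfg)
        net, _ = train(net, x_train, y_train, x_val, y_val, cfg=train_cfg,
                       class_weights=class_weights, verbose=verbose)
        rep = evaluate(net, x_test, y_test)
        total, trainable = count_parameters(net)
        reports.append(rep)
        rows.append([name, train_cfg.epochs, total, trainable,
                     rep.accuracy, rep.precision, rep.recall, rep.f1,
                     rep.auc, rep.kappa])
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return reports[0], reports[1], table
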