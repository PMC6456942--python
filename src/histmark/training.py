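"""Loss, optimizer, early stopping, and the 5-fold cross-validation protocol.

The objective is binary cross entropy averaged over all examples and all 7
sigmoid outputs. Optimization uses Adam with default moment parameters and
an initial learning rate of 0.001. Training on each fold holds out a small
internal validation split; when its loss stops improving for ``patience``
consecutive epochs, training stops and the parameters from the best holdout
epoch are restored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger("histmark")

from .dataset import EncodedBatch, SiteTable, build_batch
from .network import ModelHandle, NetworkSpec, build_network

__all__ = [
    "TrainConfig",
    "FoldAssignment",
    "multi_label_loss",
    "multi_label_loss_grad",
    "make_folds",
    "Adam",
    "train_fold",
    "run_cv",
    "CVResult",
]

LOSS_EPS = 1e-7


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 20
    patience: int = 5
    folds: int = 5
    seed: int = 0
    holdout_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0 < self.holdout_fraction < 1):
            raise ValueError("holdout_fraction must be in (0, 1)")


@dataclass
class FoldAssignment:
    """fold_of[i] is the fold index of example i."""

    fold_of: np.ndarray
    n_folds: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_of == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_of != fold)[0]


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def multi_label_loss(pred: np.ndarray, labels: np.ndarray, eps: float = LOSS_EPS) -> float:
    """Mean binary cross entropy over every (example, marker) entry.

    ``-[p log q + (1-p) log(1-q)]`` with predictions clipped to
    ``[eps, 1-eps]`` so the loss stays finite at saturated outputs.
    """
    pred = np.asarray(pred, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if pred.shape != labels.shape:
        raise ValueError(f"pred shape {pred.shape} != labels shape {labels.shape}")
    q = np.clip(pred, eps, 1.0 - eps)
    return float(-np.mean(labels * np.log(q) + (1.0 - labels) * np.log1p(-q)))


def multi_label_loss_grad(pred: np.ndarray, labels: np.ndarray,
                          eps: float = LOSS_EPS) -> np.ndarray:
    """Analytic gradient of :func:`multi_label_loss` w.r.t. the predictions."""
    pred = np.asarray(pred, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    q = np.clip(pred, eps, 1.0 - eps)
    grad = (-labels / q + (1.0 - labels) / (1.0 - q)) / pred.size
    grad[(pred < eps) | (pred > 1.0 - eps)] = 0.0  # clipped region is flat
    return grad


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def make_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Randomly partition n examples into k folds whose sizes differ by at
    most one; deterministic for a fixed seed."""
    if n < k:
        raise ValueError(f"cannot split {n} examples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    fold_of[perm] = np.arange(n) % k
    return FoldAssignment(fold_of, k)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)


# ---------------------------------------------------------------------------
# Per-fold training
# ---------------------------------------------------------------------------

def _eval_loss(model: ModelHandle, seq, openness, labels, batch_size: int) -> float:
    total, count = 0.0, 0
    for lo in range(0, labels.shape[0], batch_size):
        hi = min(lo + batch_size, labels.shape[0])
        probs = model.forward(
            seq[lo:hi] if seq is not None else None,
            openness[lo:hi] if openness is not None else None,
            train=False,
        )
        total += multi_label_loss(probs, labels[lo:hi]) * (hi - lo)
        count += hi - lo
    return total / max(count, 1)


def predict_in_batches(model: ModelHandle, seq, openness, batch_size: int = 128) -> np.ndarray:
    n = (seq if seq is not None else openness).shape[0]
    out = []
    for lo in range(0, n, batch_size):
        hi = min(lo + batch_size, n)
        out.append(
            model.forward(
                seq[lo:hi] if seq is not None else None,
                openness[lo:hi] if openness is not None else None,
                train=False,
            )
        )
    return np.concatenate(out, axis=0)


def train_fold(
    model: ModelHandle,
    train_data: EncodedBatch,
    config: TrainConfig,
    log: Optional[list] = None,
) -> Tuple[ModelHandle, List[Dict[str, float]]]:
    """Train one model on one fold's training rows.

    A ``holdout_fraction`` split of the rows monitors generalization; the
    parameters from the epoch with the best holdout loss are restored at the
    end. History records per-epoch train and holdout loss.
    """
    n = len(train_data)
    if n == 0:
        raise ValueError("train_fold requires a non-empty training set")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_hold = max(1, int(round(config.holdout_fraction * n))) if n > 1 else 0
    hold_idx, fit_idx = perm[:n_hold], perm[n_hold:]
    if fit_idx.size == 0:
        fit_idx, hold_idx = perm, perm

    use_seq = model.dna_branch is not None
    use_open = model.dnase_branch is not None
    seq = train_data.seq if use_seq else None
    openness = train_data.openness if use_open else None
    labels = train_data.labels

    fit_seq = seq[fit_idx] if use_seq else None
    fit_open = openness[fit_idx] if use_open else None
    fit_labels = labels[fit_idx]
    hold_seq = seq[hold_idx] if use_seq else None
    hold_open = openness[hold_idx] if use_open else None
    hold_labels = labels[hold_idx]

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history: List[Dict[str, float]] = []
    best_loss = math.inf
    best_state = model.state_dict()
    epochs_since_improve = 0
    n_fit = fit_idx.size
    denom = model.spec.n_markers

    for epoch in range(config.max_epochs):
        order = rng.permutation(n_fit)
        epoch_loss, seen = 0.0, 0
        for lo in range(0, n_fit, config.batch_size):
            rows = order[lo : lo + config.batch_size]
            b_seq = fit_seq[rows] if use_seq else None
            b_open = fit_open[rows] if use_open else None
            b_labels = fit_labels[rows]
            model.zero_grad()
            logits = model.forward_logits(b_seq, b_open, train=True)
            probs = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
            loss = multi_label_loss(probs, b_labels)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            # d(BCE)/d(logit) = (q - p) / count, numerically exact through
            # the sigmoid so saturated outputs still receive gradient
            dlogits = (probs - b_labels) / probs.size
            model.backward_logits(dlogits)
            optimizer.step()
            epoch_loss += loss * rows.size
            seen += rows.size
        hold_loss = _eval_loss(model, hold_seq, hold_open, hold_labels, 256)
        entry = {
            "epoch": epoch,
            "train_loss": epoch_loss / max(seen, 1),
            "holdout_loss": hold_loss,
            "learning_rate": config.learning_rate,
        }
        history.append(entry)
        if log is not None:
            log.append(entry)
        logger.info(
            "epoch=%d train_loss=%.5f holdout_loss=%.5f lr=%g",
            epoch, entry["train_loss"], hold_loss, config.learning_rate,
        )
        if hold_loss < best_loss - 1e-6:
            best_loss = hold_loss
            best_state = model.state_dict()
            epochs_since_improve = 0
        else:
            epochs_since_improve += 1
            if epochs_since_improve > config.patience:
                break
    model.load_state_dict(best_state)
    model.training_log = history
    return model, history


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    models: List[ModelHandle]
    oof_predictions: np.ndarray  # (n, n_markers)
    folds: FoldAssignment
    histories: List[List[Dict[str, float]]]


def run_cv_encoded(
    batch: EncodedBatch,
    spec: NetworkSpec,
    config: TrainConfig,
) -> CVResult:
    """K-fold cross-validation on a pre-encoded dataset.

    Each fold trains a fresh model on the other folds' rows and predicts its
    own rows, so every example gets exactly one out-of-fold prediction. The
    trained per-fold models are retained (they form the within-epigenome
    ensemble for collective scoring).
    """
    n = len(batch)
    folds = make_folds(n, config.folds, config.seed)
    oof = np.full((n, spec.n_markers), np.nan)
    models: List[ModelHandle] = []
    histories = []
    for fold in range(config.folds):
        tr = folds.train_indices(fold)
        te = folds.test_indices(fold)
        logger.info("fold=%d n_train=%d n_test=%d mode=%s",
                    fold, tr.size, te.size, spec.mode)
        model = build_network(spec, seed=(config.seed * 1009 + fold) % 2**31)
        fold_cfg = replace(config, seed=(config.seed * 9176 + fold) % 2**31)
        train_batch = EncodedBatch(batch.seq[tr], batch.openness[tr], batch.labels[tr])
        model, history = train_fold(model, train_batch, fold_cfg)
        use_seq = model.dna_branch is not None
        use_open = model.dnase_branch is not None
        oof[te] = predict_in_batches(
            model,
            batch.seq[te] if use_seq else None,
            batch.openness[te] if use_open else None,
        )
        models.append(model)
        histories.append(history)
    assert not np.isnan(oof).any(), "out-of-fold coverage must be complete"
    return CVResult(models, oof, folds, histories)


def run_cv(
    site_table: SiteTable,
    genome,
    track,
    spec: NetworkSpec,
    config: TrainConfig,
) -> CVResult:
    """Encode the site table and run K-fold cross-validation."""
    batch = build_batch(genome, track, site_table, region_bp=spec.seq_len)
    return run_cv_encoded(batch, spec, config)
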