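"""Training loop for the recurrent classifiers.

Binary cross-entropy on the final-day logit, adaptive moment estimation
(lr 1e-3, batch 64), and early stopping when the validation loss has not
decreased for 20 consecutive epochs; 10% of the training stays are split
off (stratified) for that model selection.  Everything is deterministic
given the config seed: fixed initialization, fixed batch order, and the
returned parameters are those of the epoch with minimal validation loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..preprocess import NormStats, StayTensor
from .core import (Batch, DECAYED, bce_loss_and_grads, final_logits, forward,
                   init_params, sigmoid, tensors_to_batch)

__all__ = ["TrainConfig", "EarlyStopper", "train", "predict",
           "predict_trajectories", "fine_tune", "stratified_split"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 20
    val_fraction: float = 0.10
    seed: int = 0
    hidden: int = 32
    pos_weight: float | None = None  # off by default; plain BCE

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")


class EarlyStopper:
    """Stop when the monitored loss has not strictly decreased for
    ``patience`` consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record one epoch; returns True when training should stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk ** 2
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def stratified_split(labels: np.ndarray, frac: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(main_idx, held_out_idx) with the held-out fraction stratified by label."""
    labels = np.asarray(labels)
    held = []
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        idx = rng.permutation(idx)
        k = max(1, int(round(frac * len(idx)))) if len(idx) > 1 else 0
        held.extend(idx[:k])
    held = np.sort(np.array(held, dtype=int))
    main = np.setdiff1d(np.arange(len(labels)), held)
    return main, held


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def _batch_loss(params, batch, variant, xbar, pos_weight=None):
    loss, _ = bce_loss_and_grads(params, batch, variant, xbar,
                                 pos_weight=pos_weight, want_grads=False)
    return loss


def train(variant: str, tensors: Sequence[StayTensor], config: TrainConfig,
          stats: NormStats | None = None,
          init: dict[str, np.ndarray] | None = None,
          val_tensors: Sequence[StayTensor] | None = None,
          ) -> tuple[dict[str, np.ndarray], TrainLog]:
    """Train one recurrent classifier.

    ``init`` warm-starts from existing parameters (fine-tuning).  When
    ``val_tensors`` is not given, a stratified ``val_fraction`` of
    ``tensors`` is split off for early stopping / model selection.
    """
    labels = np.array([t.label for t in tensors])
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    D = len(tensors[0].channels)
    xbar = stats.fill_values(normalized=True) if stats is not None else np.zeros(D)

    if val_tensors is None:
        tr_idx, va_idx = stratified_split(labels, config.val_fraction, rng)
        train_list = [tensors[i] for i in tr_idx]
        val_list = [tensors[i] for i in va_idx]
    else:
        train_list = list(tensors)
        val_list = list(val_tensors)

    full = tensors_to_batch(train_list, variant, stats)
    val = tensors_to_batch(val_list, variant, stats)
    n = len(train_list)

    if init is not None:
        params = copy.deepcopy(init)
    else:
        params = init_params(variant, D, n_static=len(tensors[0].static),
                             hidden=config.hidden, seed=config.seed)
        # prior initialization: start the head at the base-rate log-odds so
        # the first epochs learn discrimination, not calibration — without
        # it the tiny selection split can hand its loss minimum to a barely
        # trained model
        base_rate = float(np.clip(np.mean([t.label for t in train_list]),
                                  1e-3, 1 - 1e-3))
        params["b_out"][...] = np.log(base_rate / (1.0 - base_rate))
    opt = _Adam(params, config.learning_rate)
    stopper = EarlyStopper(config.patience)
    log = TrainLog()
    best_params = copy.deepcopy(params)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            sub = full.take(idx)
            loss, grads = bce_loss_and_grads(params, sub, variant, xbar,
                                             pos_weight=config.pos_weight)
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        log.train_loss.append(epoch_loss / n)
        vloss = _batch_loss(params, val, variant, xbar, config.pos_weight)
        log.val_loss.append(vloss)
        if vloss < stopper.best:
            best_params = copy.deepcopy(params)
        stop = stopper.update(epoch, vloss)
        if stop:
            break
    log.best_epoch = stopper.best_epoch
    log.stopped_epoch = len(log.val_loss) - 1
    return best_params, log


def predict(params: dict[str, np.ndarray], variant: str,
            tensors: Sequence[StayTensor],
            stats: NormStats | None = None) -> np.ndarray:
    """Per-stay deterioration risk (probability at the final day)."""
    batch = tensors_to_batch(tensors, variant, stats)
    D = len(tensors[0].channels)
    xbar = stats.fill_values(normalized=True) if stats is not None else np.zeros(D)
    logits, _ = forward(params, batch, variant, xbar)
    return sigmoid(final_logits(logits, batch.lengths))


def predict_trajectories(params: dict[str, np.ndarray], variant: str,
                         tensors: Sequence[StayTensor],
                         stats: NormStats | None = None) -> list[np.ndarray]:
    """Per-day risk trajectory for each stay (prefix predictions)."""
    batch = tensors_to_batch(tensors, variant, stats)
    D = len(tensors[0].channels)
    xbar = stats.fill_values(normalized=True) if stats is not None else np.zeros(D)
    logits, _ = forward(params, batch, variant, xbar)
    return [sigmoid(logits[i, :t.n_days]) for i, t in enumerate(tensors)]


def fine_tune(pretrained: dict[str, np.ndarray], variant: str,
              site_tensors: Sequence[StayTensor], fractions: Sequence[float],
              config: TrainConfig, stats: NormStats | None = None,
              test_frac: float = 0.40, selection_frac: float = 0.10,
              ) -> dict[float, dict]:
    """Warm-started adaptation to a new site with nested training subsets.

    The site data is split (stratified, seeded) into a fixed test set, a
    fixed model-selection set, and a training pool; the training set at
    fraction f is the first ``f * n`` stays of the pool, so smaller
    fractions are subsets of larger ones and the learning curve is monotone
    in data rather than split noise.  Fraction 0 reports the pretrained
    model's zero-shot scores.
    """
    if max(fractions, default=0) + test_frac + selection_frac > 1 + 1e-9:
        raise ValueError("fractions + test + selection exceed the site data")
    labels = np.array([t.label for t in site_tensors])
    rng = np.random.default_rng(config.seed)
    rest, test_idx = stratified_split(labels, test_frac, rng)
    rest_labels = labels[rest]
    pool_rel, sel_rel = stratified_split(
        rest_labels, selection_frac / (1.0 - test_frac), rng)
    pool_idx = rest[rng.permutation(pool_rel)]
    sel_idx = rest[sel_rel]
    test = [site_tensors[i] for i in test_idx]
    sel = [site_tensors[i] for i in sel_idx]
    n = len(site_tensors)

    from ..evaluation import auroc, aupr  # local import avoids a cycle
    y_test = labels[test_idx]
    out: dict[float, dict] = {}
    for f in fractions:
        if f == 0:
            scores = predict(pretrained, variant, test, stats)
            params = pretrained
            train_ids: list[str] = []
        else:
            k = int(round(f * n))
            sub_idx = pool_idx[:k]
            sub = [site_tensors[i] for i in sub_idx]
            if len(np.unique(labels[sub_idx])) < 2:
                raise ValueError(f"fraction {f}: training subset lacks both classes")
            params, _ = train(variant, sub, config, stats, init=pretrained,
                              val_tensors=sel)
            scores = predict(params, variant, test, stats)
            train_ids = [site_tensors[i].stay_id for i in sub_idx]
        out[f] = {"auroc": auroc(scores, y_test), "aupr": aupr(scores, y_test),
                  "scores": scores, "train_ids": train_ids, "params": params}
    return out
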