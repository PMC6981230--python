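"""Maximum-likelihood training loop.

Networks are trained by minimising the class-weighted log loss with Adam
(default batch size 128, learning rate 0.001), dropout applied inside the
encoders, and a fixed epoch budget (default 80, no early stopping —
validation average precision is logged per epoch but not used to stop).
Class imbalance is handled by weighting positive stays by N_neg / N_pos
computed on the training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor
from .data import StayRecord, pad_batch

__all__ = ["TrainConfig", "class_weights", "train"]


@dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 0.001
    epochs: int = 80
    dropout: float = 0.5  # applied inside encoders; kept here for the record
    class_weighting: bool = True
    valid_fraction: float = 1.0 / 9.0  # of train_valid, by patient
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate < 0:
            raise ValueError("batch size, epochs and learning rate must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def class_weights(labels) -> tuple[float, float]:
    """(negative, positive) misclassification weights: (1, N_neg / N_pos)."""
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("class weights need both classes in the training labels")
    return 1.0, n_neg / n_pos


def weighted_log_loss(logits: Tensor, labels: np.ndarray, w_pos: float) -> Tensor:
    """Mean class-weighted binary cross-entropy from logits (stable form)."""
    y = np.asarray(labels, dtype=float)
    w = 1.0 + (w_pos - 1.0) * y
    bce = logits.softplus() - logits * Tensor(y)
    return (Tensor(w) * bce).mean()


def split_train_valid(stays: list[StayRecord], valid_fraction: float,
                      seed: int) -> tuple[list[StayRecord], list[StayRecord]]:
    """Patient-level sub-split of the pooled training/validation stays."""
    patients = sorted({s.patient_id for s in stays})
    rng = np.random.default_rng(seed)
    valid_set = set(np.array(patients)[rng.random(len(patients)) < valid_fraction])
    train = [s for s in stays if s.patient_id not in valid_set]
    valid = [s for s in stays if s.patient_id in valid_set]
    return train, valid


def train(network, stays: list[StayRecord], config: TrainConfig | None = None,
          valid_stays: list[StayRecord] | None = None) -> list[dict]:
    """Fit ``network`` in place; returns the per-epoch history.

    If ``valid_stays`` is None, a patient-level validation subset is carved
    out of ``stays`` (its average precision is recorded, not acted upon).
    """
    from .metrics import average_precision

    config = config or TrainConfig()
    if valid_stays is None and config.valid_fraction > 0 and len(stays) > 20:
        stays, valid_stays = split_train_valid(stays, config.valid_fraction,
                                               config.seed + 1)
    labels = np.array([s.label for s in stays], dtype=float)
    w_pos = class_weights(labels)[1] if config.class_weighting else 1.0
    params = network.parameters()
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    n = len(stays)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = pad_batch([stays[i] for i in idx])
            logits = network.logits(batch, rng=rng, training=True)
            loss = weighted_log_loss(logits, batch["label"], w_pos)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        record = {"train_loss": float(np.mean(losses))}
        if valid_stays:
            v_labels = np.array([s.label for s in valid_stays])
            if v_labels.sum() > 0:
                record["valid_ap"] = average_precision(
                    v_labels, network.predict(valid_stays))
        history.append(record)
    return history
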