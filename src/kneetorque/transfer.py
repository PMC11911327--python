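"""Subject-to-subject transfer learning.

A model pre-trained on a pool of subjects is adapted to a new subject by
reinitializing the final (output) dense layer and continuing training on the
new subject's data with Adam at a reduced learning rate (1e-4 by default,
one tenth of the pre-training rate).  All other layers keep their
pre-trained values at initialization and are fine-tuned jointly.  An
optional two-phase schedule (head-only warmup before full fine-tuning) is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkConfig, TrainConfig, WeightSet, init_weights, train_model


class TransferProtocolError(ValueError):
    """Raised when fine-tuning data violates the transfer protocol."""


@dataclass
class TransferConfig:
    fine_tune_lr: float = 1e-4
    max_epochs: int = 1000
    patience: int = 30
    seed: int = 0
    head_warmup_epochs: int = 0  # optional two-phase variant; 0 = single phase

    def __post_init__(self) -> None:
        if self.fine_tune_lr <= 0:
            raise ValueError("fine_tune_lr must be positive")


def init_transfer_model(pretrained: WeightSet, seed: int = 0) -> WeightSet:
    """Copy the pre-trained weights, reinitializing only the output layer.

    Every tensor outside the final dense layer is bitwise-equal to its
    pre-trained value; the final layer is freshly seeded-initialized.  The
    pre-trained set is never modified.
    """
    fresh = init_weights(pretrained.config, seed=seed)
    out = pretrained.copy()
    for key in WeightSet.FINAL_DENSE_KEYS:
        out.tensors[key] = fresh.tensors[key].copy()
    out.meta["transfer_seed"] = seed
    return out


def fine_tune(
    pretrained: WeightSet,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    target_subject: str,
    transfer_config: TransferConfig | None = None,
    batch_size: int = 512,
) -> tuple[WeightSet, dict[str, list[float]]]:
    """Adapt a pre-trained model to one target subject.

    The target subject must be disjoint from the pre-training subjects
    (recorded in ``pretrained.meta['train_subjects']``); violating this is a
    protocol error, not a warning.  Early stopping uses the held-out target
    windows passed as the validation set.
    """
    cfg = transfer_config or TransferConfig()
    pretrain_subjects = set(pretrained.meta.get("train_subjects", []))
    if target_subject in pretrain_subjects:
        raise TransferProtocolError(
            f"target subject {target_subject!r} was part of pre-training"
        )
    if cfg.fine_tune_lr >= pretrained.meta.get("pretrain_lr", np.inf):
        raise TransferProtocolError("fine-tune lr must be below the pre-training lr")

    weights = init_transfer_model(pretrained, seed=cfg.seed)
    if cfg.max_epochs == 0 and cfg.head_warmup_epochs == 0:
        return weights, {"train_mse": [], "val_mse": []}

    history: dict[str, list[float]] = {"train_mse": [], "val_mse": []}
    if cfg.head_warmup_epochs > 0:
        # optional warmup: brief head-only training before full fine-tuning
        frozen = {
            k: v.copy() for k, v in weights.tensors.items()
            if k not in WeightSet.FINAL_DENSE_KEYS
        }
        warm_cfg = TrainConfig(
            batch_size=batch_size, lr=cfg.fine_tune_lr, seed=cfg.seed,
            max_epochs=cfg.head_warmup_epochs, patience=cfg.head_warmup_epochs - 1,
        )
        weights, hist0 = train_model(
            X, y, weights.config, warm_cfg, X_val, y_val, initial_weights=weights
        )
        for k, v in frozen.items():
            weights.tensors[k] = v
        for key in history:
            history[key].extend(hist0[key])
    adapted = weights
    if cfg.max_epochs > 0:
        train_cfg = TrainConfig(
            batch_size=batch_size, lr=cfg.fine_tune_lr, seed=cfg.seed,
            max_epochs=cfg.max_epochs, patience=min(cfg.patience, cfg.max_epochs - 1),
        )
        adapted, hist = train_model(
            X, y, weights.config, train_cfg, X_val, y_val, initial_weights=weights
        )
        for key in history:
            history[key].extend(hist[key])
    adapted.meta["fine_tuned_on"] = target_subject
    return adapted, history
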