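"""Learning-rate schedule: linear warmup by epoch, then cosine annealing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScheduleConfig", "lr_at"]


@dataclass
class ScheduleConfig:
    base_lr: float = 6.25e-5
    warmup_epochs: int = 20
    total_epochs: int = 400
    weight_decay: float = 5e-4
    min_lr: float = 0.0

    def __post_init__(self):
        if self.base_lr <= 0 or self.total_epochs <= 0 or self.warmup_epochs < 0:
            raise ValueError("schedule parameters must be positive")
        if self.warmup_epochs >= self.total_epochs:
            raise ValueError("warmup must end before total_epochs")


def lr_at(epoch: int, cfg: ScheduleConfig) -> float:
    """Learning rate for a 0-indexed epoch.

    Warmup ramps linearly from base_lr/warmup to base_lr over the first
    ``warmup_epochs`` epochs; the cosine phase then decays base_lr to
    ``min_lr`` over the remaining epochs.  Continuous at the boundary
    (epoch == warmup_epochs gives exactly base_lr) and non-increasing after
    it.
    """
    if not 0 <= epoch < cfg.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.total_epochs})")
    if epoch < cfg.warmup_epochs:
        return cfg.base_lr * (epoch + 1) / cfg.warmup_epochs
    t = (epoch - cfg.warmup_epochs) / max(1, cfg.total_epochs - 1 - cfg.warmup_epochs)
    return cfg.min_lr + 0.5 * (cfg.base_lr - cfg.min_lr) * (1.0 + np.cos(np.pi * t))
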