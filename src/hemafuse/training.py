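"""Training loops: MAE pre-training, classifier fine-tuning, embedding export.

These are the procedural engines behind the sklearn-style estimators in
:mod:`hemafuse.estimators`; they can also be driven directly or through the
CLI.  All randomness (shuffling, augmentation, masking, weight init) derives
from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .arcface import LossConfig, MarginTable, compute_margins
from .autodiff import Tensor
from .backbone import BackboneConfig, ViTClassifier
from .evaluation import EvalReport, evaluate_predictions
from .mae import (MAEConfig, MaskedAutoencoder, random_mask,
                  reconstruction_loss, transfer_weights)
from .optim import AdamW
from .preprocessing import AugmentConfig, preprocess_eval, preprocess_train
from .schedule import ScheduleConfig, lr_at
from .synthetic import ImageRecord

__all__ = [
    "LOSS_CHOICES",
    "TrainResult",
    "pretrain_mae",
    "train_classifier",
    "evaluate_model",
    "export_embeddings",
]

LOSS_CHOICES = ("ce", "arcface", "subcenter", "dynamic-subcenter")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def _stack_eval(images, target_size: int) -> np.ndarray:
    return np.stack([preprocess_eval(im, target_size) for im in images])


@dataclass
class TrainResult:
    state: dict[str, np.ndarray]  # best-validation parameters
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_acc: float = float("nan")
    margins: MarginTable | None = None


def pretrain_mae(images: list[np.ndarray], cfg: BackboneConfig,
                 mae_cfg: MAEConfig | None = None, steps: int = 200,
                 batch_size: int = 16, lr: float = 1.5e-3,
                 weight_decay: float = 5e-4, seed: int = 0
                 ) -> tuple[MaskedAutoencoder, list[float]]:
    """Self-supervised pre-training on raw images (labels unused).

    Images are resized/standardized deterministically, patchified, and each
    step draws a fresh random mask (shared across the batch) at
    ``mae_cfg.mask_ratio``.  Returns the trained model and the per-step
    masked-patch MSE trace.
    """
    mae_cfg = mae_cfg or MAEConfig()
    model = MaskedAutoencoder(cfg, mae_cfg, _rng(seed, 0))
    data = _stack_eval(images, cfg.image_size)
    from .backbone import patchify

    patches = patchify(data, cfg.patch_size)  # (M, N, P)
    n_tokens = patches.shape[1]
    opt = AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
    draw = _rng(seed, 1)
    losses: list[float] = []
    for _ in range(steps):
        idx = draw.choice(len(patches), size=min(batch_size, len(patches)),
                          replace=False)
        plan = random_mask(n_tokens, mae_cfg.mask_ratio, draw)
        pred = model(patches[idx], plan)
        loss = reconstruction_loss(pred, patches[idx], plan,
                                   mae_cfg.norm_pixel_targets)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    return model, losses


def _classifier_loss(model: ViTClassifier, feats: Tensor, labels: np.ndarray,
                     margins: np.ndarray, s: float) -> Tensor:
    if model.head_type == "linear":
        logits = model.head(feats)
        logp = ad.log_softmax(logits, axis=1)
        onehot = np.zeros(logp.shape)
        onehot[np.arange(len(labels)), labels] = 1.0
        return -(logp * onehot).sum(axis=1).mean()
    return model.arcface.loss(model.center_embeddings(feats), labels,
                              margins, s=s)


def _margins_for(loss_type: str, counts: np.ndarray, loss_cfg: LossConfig
                 ) -> MarginTable:
    if loss_type == "dynamic-subcenter":
        return compute_margins(counts, loss_cfg.a, loss_cfg.b, loss_cfg.lam)
    # fixed-margin variants use the upper bound for every class
    fixed = np.full(len(counts), loss_cfg.a)
    return MarginTable(margins=fixed, class_counts=counts,
                       a=loss_cfg.a, b=loss_cfg.b, lam=loss_cfg.lam)


def train_classifier(train_records: list[ImageRecord],
                     val_records: list[ImageRecord],
                     backbone_cfg: BackboneConfig,
                     n_classes: int,
                     loss_type: str = "dynamic-subcenter",
                     loss_cfg: LossConfig | None = None,
                     aug_cfg: AugmentConfig | None = None,
                     sched_cfg: ScheduleConfig | None = None,
                     fusion: bool = True,
                     batch_size: int = 64,
                     seed: int = 0,
                     init_state: dict[str, np.ndarray] | None = None
                     ) -> tuple[ViTClassifier, TrainResult]:
    """Supervised training with the warmup+cosine schedule and AdamW.

    ``loss_type`` selects the objective/head: plain softmax cross-entropy on
    a linear head (``ce``), single-center fixed-margin ArcFace (``arcface``),
    K sub-centers with a fixed margin (``subcenter``), or K sub-centers with
    count-derived per-class margins (``dynamic-subcenter``).  Margins are
    computed once from the training-split class counts.  ``init_state`` is an
    MAE checkpoint whose encoder weights seed the backbone.

    The best-validation-accuracy parameters are retained (ties resolved to
    the earlier epoch); with an empty validation split the final parameters
    are kept and a warning is issued.
    """
    if loss_type not in LOSS_CHOICES:
        raise ValueError(f"loss_type must be one of {LOSS_CHOICES}")
    labels_all = np.array([r.label for r in train_records])
    if len(np.unique(labels_all)) < 2:
        raise ValueError("training split must contain at least 2 classes")
    loss_cfg = loss_cfg or LossConfig()
    aug_cfg = aug_cfg or AugmentConfig(target_size=backbone_cfg.image_size)
    sched_cfg = sched_cfg or ScheduleConfig()

    counts = np.bincount(labels_all, minlength=n_classes)
    margins = _margins_for(loss_type, np.maximum(counts, 1), loss_cfg)

    head = "linear" if loss_type == "ce" else "arcface"
    k = 1 if loss_type in ("ce", "arcface") else loss_cfg.sub_centers
    model = ViTClassifier(backbone_cfg, n_classes, _rng(seed, 0),
                          fusion=fusion, head=head, sub_centers=k)
    if init_state is not None:
        transfer_weights(init_state, model)

    opt = AdamW(model.parameters(), lr=sched_cfg.base_lr,
                weight_decay=sched_cfg.weight_decay)
    shuffle_rng = _rng(seed, 1)
    aug_rng = _rng(seed, 2)

    val_images = None
    val_labels = None
    if val_records:
        val_images = _stack_eval([r.pixels for r in val_records],
                                 backbone_cfg.image_size)
        val_labels = np.array([r.label for r in val_records])
    else:
        warnings.warn("validation split is empty; keeping the final "
                      "checkpoint", stacklevel=2)

    result = TrainResult(state={}, margins=margins)
    best_acc = -1.0
    for epoch in range(sched_cfg.total_epochs):
        opt.lr = lr_at(epoch, sched_cfg)
        order = shuffle_rng.permutation(len(train_records))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            batch = np.stack([
                preprocess_train(train_records[i].pixels, aug_cfg, aug_rng)
                for i in idx])
            labels = labels_all[idx]
            feats = model.features(batch)
            loss = _classifier_loss(model, feats, labels, margins.margins,
                                    loss_cfg.s)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        row = {"epoch": epoch, "lr": opt.lr,
               "train_loss": epoch_loss / max(1, n_batches)}
        if val_images is not None:
            preds = _predict_batched(model, val_images, batch_size)
            acc = 100.0 * np.mean(preds == val_labels)
            row["val_acc"] = acc
            if acc > best_acc:
                best_acc = acc
                result.best_epoch = epoch
                result.best_val_acc = acc
                result.state = model.state_dict()
        result.history.append(row)
    if val_images is None:
        result.state = model.state_dict()
        result.best_epoch = sched_cfg.total_epochs - 1
    else:
        model.load_state_dict(result.state)
    return model, result


def _predict_batched(model: ViTClassifier, images: np.ndarray,
                     batch_size: int) -> np.ndarray:
    preds = []
    with ad.no_grad():
        for start in range(0, len(images), batch_size):
            preds.append(model.predict(images[start:start + batch_size]))
    return np.concatenate(preds)


def evaluate_model(model: ViTClassifier, records: list[ImageRecord],
                   batch_size: int = 64) -> EvalReport:
    """Run the deterministic evaluation path and compute the metric report."""
    images = _stack_eval([r.pixels for r in records], model.cfg.image_size)
    labels = np.array([r.label for r in records])
    preds = _predict_batched(model, images, batch_size)
    return evaluate_predictions(labels, preds, n_classes=model.n_classes)


def export_embeddings(model: ViTClassifier, records: list[ImageRecord],
                      batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Fused features for each record: (N, D) array plus the label vector."""
    images = _stack_eval([r.pixels for r in records], model.cfg.image_size)
    labels = np.array([r.label for r in records])
    feats = []
    with ad.no_grad():
        for start in range(0, len(images), batch_size):
            feats.append(model.features(images[start:start + batch_size]).data)
    return np.concatenate(feats), labels


def write_embeddings(path, features: np.ndarray, labels: np.ndarray) -> None:
    """Plain-text TSV with a header row: feat_0 ... feat_{D-1}, label."""
    d = features.shape[1]
    header = "\t".join([f"feat_{i}" for i in range(d)] + ["label"])
    body = np.column_stack([features, labels])
    np.savetxt(path, body, delimiter="\t", header=header, comments="")
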