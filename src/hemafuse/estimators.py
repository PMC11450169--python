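"""Scikit-learn-style estimators wrapping the training engines.

:class:`ViTFusionClassifier` is a classifier (``fit`` / ``predict`` /
``score``) and :class:`MAEPretrainer` a transformer (``fit`` / ``transform``)
in the sklearn sense: plain-attribute hyperparameters handled by
``get_params`` / ``set_params``, fitted state in trailing-underscore
attributes, so both compose with ``clone``, pipelines and model selection.

Input ``X`` is a sequence of (H, W, 3) uint8 RGB images — variable sizes are
allowed (the preprocessing stage resizes) — or a 4-D array.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .arcface import LossConfig
from .backbone import BackboneConfig
from .mae import MAEConfig
from .preprocessing import AugmentConfig
from .schedule import ScheduleConfig
from .synthetic import ImageRecord
from .training import (evaluate_model, export_embeddings, pretrain_mae,
                       train_classifier)

__all__ = ["ViTFusionClassifier", "MAEPretrainer"]


def _validate_images(X) -> list[np.ndarray]:
    if isinstance(X, np.ndarray) and X.ndim == 4:
        X = list(X)
    images = []
    for i, im in enumerate(X):
        arr = np.asarray(im)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"image {i} is not (H, W, 3)")
        if min(arr.shape[:2]) < 8:
            raise ValueError(f"image {i} smaller than 8x8")
        images.append(arr.astype(np.uint8))
    if not images:
        raise ValueError("X is empty")
    return images


class ViTFusionClassifier(ClassifierMixin, BaseEstimator):
    """Fine-grained image classifier: ViT encoder, SE layer fusion, and a
    dynamic-margin sub-center angular head.

    Parameters
    ----------
    image_size, patch_size, depth, dim, heads, mlp_ratio, use_cls_token,
    pos_embed : backbone architecture (defaults are a small CPU-friendly
        configuration; pass the ViT-base values for the full model).
    fusion : fuse all encoder layers through the SE gate (otherwise the
        vanilla last-layer readout).
    loss : one of ``ce``, ``arcface``, ``subcenter``, ``dynamic-subcenter``.
    sub_centers, scale_s, margin_a, margin_b, margin_lam : loss-head
        geometry; per-class margins are m_c = (a-b) n_c**lam + b.
    epochs, warmup_epochs, base_lr, min_lr, weight_decay, batch_size :
        AdamW + linear-warmup/cosine-annealing schedule.
    n_rand_ops, magnitude, erase_prob : training augmentation.
    init_state : optional MAE checkpoint (flat key->array dict) transferred
        into the encoder before training.
    validation_fraction : carved from (X, y) when no explicit validation set
        is passed to ``fit``.
    seed : single source for all randomness.

    Attributes
    ----------
    classes_ : label values seen in fit.
    model_ : the underlying network with best-validation weights.
    history_ : per-epoch log (loss, lr, validation accuracy).
    margins_ : per-class margin table used by the loss.
    """

    def __init__(self, image_size: int = 32, patch_size: int = 8,
                 depth: int = 2, dim: int = 32, heads: int = 4,
                 mlp_ratio: float = 4.0, use_cls_token: bool = False,
                 pos_embed: str = "learned", fusion: bool = True,
                 loss: str = "dynamic-subcenter", sub_centers: int = 3,
                 scale_s: float = 64.0, margin_a: float = 0.5,
                 margin_b: float = 0.05, margin_lam: float = -0.5,
                 epochs: int = 30, warmup_epochs: int = 3,
                 base_lr: float = 1e-3, min_lr: float = 0.0,
                 weight_decay: float = 5e-4, batch_size: int = 32,
                 n_rand_ops: int = 2, magnitude: int = 9,
                 erase_prob: float = 0.25, init_state=None,
                 validation_fraction: float = 0.2, seed: int = 0):
        self.image_size = image_size
        self.patch_size = patch_size
        self.depth = depth
        self.dim = dim
        self.heads = heads
        self.mlp_ratio = mlp_ratio
        self.use_cls_token = use_cls_token
        self.pos_embed = pos_embed
        self.fusion = fusion
        self.loss = loss
        self.sub_centers = sub_centers
        self.scale_s = scale_s
        self.margin_a = margin_a
        self.margin_b = margin_b
        self.margin_lam = margin_lam
        self.epochs = epochs
        self.warmup_epochs = warmup_epochs
        self.base_lr = base_lr
        self.min_lr = min_lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.n_rand_ops = n_rand_ops
        self.magnitude = magnitude
        self.erase_prob = erase_prob
        self.init_state = init_state
        self.validation_fraction = validation_fraction
        self.seed = seed

    # -- config assembly ------------------------------------------------------

    def _backbone_cfg(self) -> BackboneConfig:
        return BackboneConfig(
            image_size=self.image_size, patch_size=self.patch_size,
            depth=self.depth, dim=self.dim, heads=self.heads,
            mlp_ratio=self.mlp_ratio, use_cls_token=self.use_cls_token,
            pos_embed=self.pos_embed)

    def _loss_cfg(self) -> LossConfig:
        return LossConfig(s=self.scale_s, sub_centers=self.sub_centers,
                          a=self.margin_a, b=self.margin_b,
                          lam=self.margin_lam)

    def fit(self, X, y, X_val=None, y_val=None):
        images = _validate_images(X)
        y = np.asarray(y)
        if len(y) != len(images):
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")

        records = [ImageRecord(pixels=im, label=int(lbl))
                   for im, lbl in zip(images, y_idx)]
        if X_val is not None:
            val_images = _validate_images(X_val)
            y_val_idx = np.searchsorted(self.classes_, np.asarray(y_val))
            val_records = [ImageRecord(pixels=im, label=int(lbl), split="val")
                           for im, lbl in zip(val_images, y_val_idx)]
            train_records = records
        else:
            rng = np.random.default_rng([int(self.seed) % (2**31), 99])
            n_val = int(round(self.validation_fraction * len(records)))
            order = rng.permutation(len(records))
            val_records = [records[i] for i in order[:n_val]]
            train_records = [records[i] for i in order[n_val:]]

        sched = ScheduleConfig(base_lr=self.base_lr,
                               warmup_epochs=self.warmup_epochs,
                               total_epochs=self.epochs,
                               weight_decay=self.weight_decay,
                               min_lr=self.min_lr)
        aug = AugmentConfig(target_size=self.image_size,
                            n_rand_ops=self.n_rand_ops,
                            magnitude=self.magnitude,
                            erase_prob=self.erase_prob)
        self.model_, result = train_classifier(
            train_records, val_records, self._backbone_cfg(),
            n_classes=len(self.classes_), loss_type=self.loss,
            loss_cfg=self._loss_cfg(), aug_cfg=aug, sched_cfg=sched,
            fusion=self.fusion, batch_size=self.batch_size, seed=self.seed,
            init_state=self.init_state)
        self.history_ = result.history
        self.margins_ = result.margins
        self.best_epoch_ = result.best_epoch
        self.best_val_acc_ = result.best_val_acc
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        records = [ImageRecord(pixels=im, label=0)
                   for im in _validate_images(X)]
        feats, _ = export_embeddings(self.model_, records, self.batch_size)
        from . import autodiff as ad
        from .autodiff import Tensor
        with ad.no_grad():
            centered = self.model_.center_embeddings(Tensor(feats))
            if self.model_.head_type == "arcface":
                scores = self.model_.arcface.cosines(centered).data
            else:
                scores = self.model_.head(centered).data
        return self.classes_[np.argmax(scores, axis=1)]

    def transform(self, X):
        """Fused D-dimensional features (for embedding export / t-SNE)."""
        check_is_fitted(self, "model_")
        records = [ImageRecord(pixels=im, label=0)
                   for im in _validate_images(X)]
        feats, _ = export_embeddings(self.model_, records, self.batch_size)
        return feats

    def evaluate(self, X, y):
        """Full metric report (accuracy, per-class P/R/F1, confusion)."""
        check_is_fitted(self, "model_")
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        records = [ImageRecord(pixels=im, label=int(lbl))
                   for im, lbl in zip(_validate_images(X), y_idx)]
        return evaluate_model(self.model_, records, self.batch_size)


class MAEPretrainer(TransformerMixin, BaseEstimator):
    """Masked-autoencoder self-supervised pre-trainer.

    ``fit(X)`` pre-trains an encoder on unlabeled images (75% of patches
    masked by default); ``transform(X)`` returns mean-pooled encoder
    features; ``checkpoint_`` holds the named-parameter map whose
    ``encoder.*`` keys seed :class:`ViTFusionClassifier` via ``init_state``.
    """

    def __init__(self, image_size: int = 32, patch_size: int = 8,
                 depth: int = 2, dim: int = 32, heads: int = 4,
                 mlp_ratio: float = 4.0, decoder_dim: int = 32,
                 decoder_depth: int = 1, decoder_heads: int = 4,
                 mask_ratio: float = 0.75, norm_pixel_targets: bool = False,
                 steps: int = 200, batch_size: int = 16, lr: float = 1.5e-3,
                 weight_decay: float = 5e-4, seed: int = 0):
        self.image_size = image_size
        self.patch_size = patch_size
        self.depth = depth
        self.dim = dim
        self.heads = heads
        self.mlp_ratio = mlp_ratio
        self.decoder_dim = decoder_dim
        self.decoder_depth = decoder_depth
        self.decoder_heads = decoder_heads
        self.mask_ratio = mask_ratio
        self.norm_pixel_targets = norm_pixel_targets
        self.steps = steps
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.seed = seed

    def fit(self, X, y=None):
        images = _validate_images(X)
        cfg = BackboneConfig(
            image_size=self.image_size, patch_size=self.patch_size,
            depth=self.depth, dim=self.dim, heads=self.heads,
            mlp_ratio=self.mlp_ratio, use_cls_token=False, pos_embed="sincos")
        mae_cfg = MAEConfig(decoder_dim=self.decoder_dim,
                            decoder_depth=self.decoder_depth,
                            decoder_heads=self.decoder_heads,
                            mask_ratio=self.mask_ratio,
                            norm_pixel_targets=self.norm_pixel_targets)
        self.model_, self.loss_history_ = pretrain_mae(
            images, cfg, mae_cfg, steps=self.steps,
            batch_size=self.batch_size, lr=self.lr,
            weight_decay=self.weight_decay, seed=self.seed)
        self.checkpoint_ = self.model_.state_dict()
        return self

    def transform(self, X):
        check_is_fitted(self, "model_")
        from . import autodiff as ad
        from .preprocessing import preprocess_eval

        images = _validate_images(X)
        data = np.stack([preprocess_eval(im, self.image_size)
                         for im in images])
        feats = []
        with ad.no_grad():
            for start in range(0, len(data), self.batch_size):
                feats.append(
                    self.model_.encode_images(data[start:start + self.batch_size]).data)
        return np.concatenate(feats)
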