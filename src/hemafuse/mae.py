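"""Masked-autoencoder self-supervised pre-training.

A large fraction (default 75%) of image patches is masked; the encoder sees
only the visible patches (plus their fixed sine-cosine positions); a light
decoder receives the encoded visible tokens re-interleaved with a shared
learned mask token at the masked positions and regresses the pixel values of
every patch.  The reconstruction loss is mean-squared error over the *masked*
patches only, so visible positions carry no training signal.  After
pre-training, the encoder weights are transferred into the classifier and the
decoder is discarded.

Pre-training runs without a class token so the encoder matches the
class-token-free fusion classifier key-for-key.

Checkpoint key schema (stable; transfer matches by name):

    encoder.patch_embed.{weight,bias}
    encoder.pos_embed                       (only if learned positions)
    encoder.blocks.<i>.norm1.{weight,bias}
    encoder.blocks.<i>.attn.qkv.{weight,bias}
    encoder.blocks.<i>.attn.proj.{weight,bias}
    encoder.blocks.<i>.norm2.{weight,bias}
    encoder.blocks.<i>.mlp.fc1.{weight,bias}
    encoder.blocks.<i>.mlp.fc2.{weight,bias}
    encoder.norm.{weight,bias}
    decoder.* , mask_token                  (pre-training only, never transferred)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import (BackboneConfig, Block, LayerNorm, Linear, ModuleList,
                       patchify, sincos_positions, unpatchify, ViTEncoder)
from .nn import Module, Parameter

__all__ = [
    "MaskPlan",
    "random_mask",
    "MAEConfig",
    "MaskedAutoencoder",
    "reconstruction_loss",
    "TransferReport",
    "transfer_weights",
    "render_reconstruction",
]


@dataclass
class MaskPlan:
    """Partition of the N patch indices into visible and masked sets."""

    visible_idx: np.ndarray
    masked_idx: np.ndarray
    ratio: float

    @property
    def n_tokens(self) -> int:
        return self.visible_idx.size + self.masked_idx.size


def random_mask(n_tokens: int, ratio: float, rng: np.random.Generator) -> MaskPlan:
    """Draw a uniformly random mask over ``n_tokens`` patches.

    ``round(ratio * n_tokens)`` indices are masked (147 of 196 at the default
    75%).  Deterministic given the generator state.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"mask ratio must be in (0, 1), got {ratio}")
    if n_tokens < 2:
        raise ValueError("need at least 2 tokens to mask")
    n_masked = int(round(ratio * n_tokens))
    perm = rng.permutation(n_tokens)
    return MaskPlan(
        visible_idx=np.sort(perm[n_masked:]),
        masked_idx=np.sort(perm[:n_masked]),
        ratio=ratio,
    )


@dataclass
class MAEConfig:
    """Decoder shape; the encoder comes from a :class:`BackboneConfig`.

    The decoder is deliberately narrower and shallower than the encoder (it is
    a throwaway training aid): 8 blocks of width 512 for the base preset,
    1 block for toy configurations.
    """

    decoder_dim: int = 512
    decoder_depth: int = 8
    decoder_heads: int = 16
    mask_ratio: float = 0.75
    norm_pixel_targets: bool = False  # per-patch-normalized regression targets

    @classmethod
    def for_backbone(cls, cfg: "BackboneConfig", **overrides) -> "MAEConfig":
        """Decoder scaled to the encoder: ~2/3 of its width (rounded to a
        multiple of the head count) and ~2/3 of its depth — 512x8 for the
        ViT-base preset, a single narrow block for toy encoders."""
        raw = int(cfg.dim * 2 / 3)
        heads = 16 if raw >= 256 else cfg.heads
        dim = max(heads, raw // heads * heads)
        depth = max(1, round(cfg.depth * 2 / 3))
        params = dict(decoder_dim=dim, decoder_depth=depth,
                      decoder_heads=heads)
        params.update(overrides)
        return cls(**params)


class MaskedAutoencoder(Module):
    def __init__(self, cfg: BackboneConfig, mae_cfg: MAEConfig,
                 rng: np.random.Generator):
        if cfg.use_cls_token:
            raise ValueError("MAE pre-training runs without a class token")
        enc_cfg = BackboneConfig(
            image_size=cfg.image_size, patch_size=cfg.patch_size,
            depth=cfg.depth, dim=cfg.dim, heads=cfg.heads,
            mlp_ratio=cfg.mlp_ratio, use_cls_token=False, pos_embed="sincos",
        )
        self.cfg = enc_cfg
        self.mae_cfg = mae_cfg
        self.encoder = ViTEncoder(enc_cfg, rng)
        dd = mae_cfg.decoder_dim
        self.decoder_embed = Linear(enc_cfg.dim, dd, rng)
        self.mask_token = Parameter(rng.normal(0.0, 0.02, size=(dd,)))
        self.decoder_blocks = ModuleList(
            Block(dd, mae_cfg.decoder_heads, 4.0, rng)
            for _ in range(mae_cfg.decoder_depth)
        )
        self.decoder_norm = LayerNorm(dd)
        self.decoder_head = Linear(dd, enc_cfg.patch_dim, rng)
        self._decoder_pos = sincos_positions((enc_cfg.grid, enc_cfg.grid), dd)

    def forward(self, patches: np.ndarray, plan: MaskPlan) -> Tensor:
        """Patches (B, N, P) -> per-patch pixel predictions (B, N, P).

        The encoder consumes only the visible patches; the decoder rebuilds
        the full-length sequence with the shared mask token at masked slots.
        """
        patches = np.asarray(patches, dtype=np.float64)
        if patches.ndim == 2:
            patches = patches[None]
        b, n, p = patches.shape
        if plan.n_tokens != n or p != self.cfg.patch_dim:
            raise ValueError(
                f"mask plan for {plan.n_tokens} tokens does not match "
                f"{n} patches of dim {p} (expected {self.cfg.patch_dim})"
            )
        vis = plan.visible_idx
        enc_pos = self.encoder.positions()
        tokens = self.encoder.patch_embed(Tensor(patches[:, vis, :]))
        tokens = tokens + enc_pos[vis]
        x = tokens
        for block in self.encoder.blocks:
            x = block(x)
        x = self.encoder.norm(x)

        latent = self.decoder_embed(x)  # (B, V, dd)
        n_masked = plan.masked_idx.size
        mask_tok = self.mask_token.reshape(1, 1, -1) + Tensor(
            np.zeros((b, n_masked, self.mae_cfg.decoder_dim))
        )
        full = ad.concatenate([latent, mask_tok], axis=1)  # visible-first order
        order = np.concatenate([vis, plan.masked_idx])
        inverse = np.argsort(order)  # position i <- slot inverse[i]
        full = full[:, inverse, :]
        full = full + self._decoder_pos
        for block in self.decoder_blocks:
            full = block(full)
        full = self.decoder_norm(full)
        return self.decoder_head(full)

    def encode_images(self, images: np.ndarray) -> Tensor:
        """Full (unmasked) encoder pass; mean-pooled (B, D) features."""
        outs = self.encoder(images)
        return outs[-1].mean(axis=-2)


def reconstruction_loss(pred, target: np.ndarray, plan: MaskPlan,
                        norm_pixel_targets: bool = False) -> Tensor:
    """Mean-squared error over masked patches only.

    ``pred`` may be a :class:`Tensor` (training) or ndarray; ``target`` is the
    raw patch array of the same shape.  With ``norm_pixel_targets`` each
    target patch is standardized to zero mean / unit variance first.
    """
    if plan.masked_idx.size == 0:
        raise ValueError("mask plan has no masked patches; loss undefined")
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    if target.ndim == 2:
        target = target[None]
    if pred.ndim == 2:
        pred = pred.reshape(1, *pred.shape)
    if norm_pixel_targets:
        mu = target.mean(axis=-1, keepdims=True)
        sd = target.std(axis=-1, keepdims=True)
        target = (target - mu) / (sd + 1e-6)
    diff = pred[:, plan.masked_idx, :] - target[:, plan.masked_idx, :]
    return (diff * diff).mean()


@dataclass
class TransferReport:
    copied: list[str]
    ignored: list[str]
    initialized: list[str]


def transfer_weights(mae_ckpt: dict[str, np.ndarray], classifier) -> TransferReport:
    """Copy MAE encoder weights into a classifier, in place.

    Every ``encoder.*`` key of the checkpoint must exist in the classifier
    with a matching shape (a depth or width mismatch raises, naming the key).
    ``decoder.*`` and ``mask_token`` are ignored; classifier parameters absent
    from the checkpoint (positional table if learned, class token, SE gate,
    head) keep their fresh initialisation and are listed in the report.
    """
    own = dict(classifier.named_parameters())
    copied, ignored = [], []
    for key, value in mae_ckpt.items():
        if key.startswith("decoder") or key == "mask_token" or key.startswith(
                "mask_token"):
            ignored.append(key)
            continue
        if not key.startswith("encoder."):
            ignored.append(key)
            continue
        if key not in own:
            raise KeyError(
                f"checkpoint key '{key}' has no counterpart in the classifier "
                "(encoder configuration mismatch)"
            )
        if own[key].data.shape != value.shape:
            raise ValueError(
                f"shape mismatch for '{key}': checkpoint {value.shape} vs "
                f"classifier {own[key].data.shape}"
            )
        own[key].data = np.asarray(value, dtype=np.float64).copy()
        copied.append(key)
    initialized = sorted(set(own) - set(copied))
    return TransferReport(copied=sorted(copied), ignored=sorted(ignored),
                          initialized=initialized)


def render_reconstruction(image: np.ndarray, plan: MaskPlan,
                          pred: np.ndarray, patch_size: int,
                          fill: int = 127) -> np.ndarray:
    """Four-panel composite: original | masked | reconstruction | paste.

    Panel 4 overlays the true visible patches on the reconstruction, so it
    equals the original exactly at visible positions.  Returns (H, 4W, 3)
    uint8.
    """
    image = np.asarray(image)
    h, w, _ = image.shape
    grid = (h // patch_size, w // patch_size)
    patches = patchify(image, patch_size)[0]
    pred = np.asarray(pred)
    if pred.ndim == 3:
        pred = pred[0]

    masked_patches = patches.copy()
    masked_patches[plan.masked_idx] = fill
    recon = np.clip(pred, 0, 255)
    paste = recon.copy()
    paste[plan.visible_idx] = patches[plan.visible_idx]

    panels = [patches, masked_patches, recon, paste]
    imgs = [unpatchify(p, grid, patch_size) for p in panels]
    return np.concatenate(imgs, axis=1).astype(np.uint8)
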