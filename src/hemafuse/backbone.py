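"""Class-token-free vision transformer with squeeze-and-excitation layer fusion.

The classifier used for fine-grained blood-cell recognition is a standard
pre-norm ViT encoder with one twist: instead of reading a single class token,
the token-pooled output of *every* encoder layer is kept (an L x D stack of
per-layer features), a squeeze-and-excitation (SE) gate scores the L layers,
and the gated stack is summed over the layer axis into one D-dimensional
feature.  Early layers carry colour/contour/texture information that a
class-token readout discards; the gate learns how much each depth contributes.

Positional information can be supplied either as a trainable embedding table
(``pos_embed="learned"``) or as fixed 2-D sine-cosine encodings
(``pos_embed="sincos"``, the choice used during masked-autoencoder
pre-training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Buffer, LayerNorm, Linear, Module, ModuleList, Parameter

__all__ = [
    "BackboneConfig",
    "sincos_positions",
    "patchify",
    "unpatchify",
    "ViTEncoder",
    "SEGate",
    "pool_layers",
    "se_fuse",
    "ViTClassifier",
    "vit_base_p16_vanilla",
    "vit_base_p16_fusion",
    "toy_backbone_config",
]


@dataclass
class BackboneConfig:
    """Architecture hyperparameters.  Defaults are the ViT-base/16 preset."""

    image_size: int = 224
    patch_size: int = 16
    depth: int = 12
    dim: int = 768
    heads: int = 12
    mlp_ratio: float = 4.0
    use_cls_token: bool = False
    pos_embed: str = "learned"  # "learned" | "sincos"

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by patch_size "
                f"{self.patch_size}"
            )
        if self.dim % self.heads != 0:
            raise ValueError("dim must be divisible by heads")
        if self.pos_embed not in ("learned", "sincos"):
            raise ValueError(f"unknown pos_embed mode {self.pos_embed!r}")
        if self.pos_embed == "sincos" and self.dim % 4 != 0:
            raise ValueError("sincos positions require dim divisible by 4")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid * self.grid

    @property
    def num_tokens(self) -> int:
        return self.num_patches + (1 if self.use_cls_token else 0)

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * 3


def sincos_positions(grid: tuple[int, int], dim: int) -> np.ndarray:
    """Fixed 2-D sine-cosine positional encodings.

    Half the channels encode the row coordinate and half the column, each half
    split between sines and cosines over a geometric frequency ladder.  All
    values lie in [-1, 1]; the (0, 0) position has all sines 0 and cosines 1.

    Parameters
    ----------
    grid : (h, w) token-grid shape.
    dim : embedding width, must be divisible by 4.
    """
    h, w = grid
    if dim % 4 != 0:
        raise ValueError("dim must be divisible by 4 for 2-D sincos positions")
    quarter = dim // 4
    omega = 1.0 / (10000.0 ** (np.arange(quarter) / quarter))
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")

    def axis_encoding(pos):
        angles = pos.reshape(-1, 1) * omega  # (N, dim/4)
        return np.concatenate([np.sin(angles), np.cos(angles)], axis=1)

    return np.concatenate([axis_encoding(ys), axis_encoding(xs)], axis=1)


def patchify(images: np.ndarray, patch_size: int) -> np.ndarray:
    """Rearrange (B, H, W, 3) images into (B, N, patch_size**2 * 3) patches.

    A single (H, W, 3) image is promoted to a batch of one and returned as
    (1, N, P).  Raises if H or W is not divisible by the patch size.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    b, h, w, c = images.shape
    p = patch_size
    if h % p or w % p:
        raise ValueError(f"image size {(h, w)} not divisible by patch size {p}")
    gh, gw = h // p, w // p
    x = images.reshape(b, gh, p, gw, p, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, gh * gw, p * p * c)


def unpatchify(patches: np.ndarray, grid: tuple[int, int], patch_size: int) -> np.ndarray:
    """Inverse of :func:`patchify` for a single image: (N, P) -> (H, W, 3)."""
    gh, gw = grid
    p = patch_size
    x = np.asarray(patches).reshape(gh, gw, p, p, 3)
    x = x.transpose(0, 2, 1, 3, 4)
    return x.reshape(gh * p, gw * p, 3)


class Attention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = self.head_dim**-0.5
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        qkv = self.qkv(x).reshape(b, n, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, H, N, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        att = ad.softmax(att, axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.proj(out)


class MLP(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class Block(Module):
    """Pre-norm transformer block: x + MSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = Attention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, int(dim * mlp_ratio), rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))


class ViTEncoder(Module):
    """Patch embedding + positions + L pre-norm blocks + final LayerNorm."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.patch_embed = Linear(cfg.patch_dim, cfg.dim, rng)
        if cfg.use_cls_token:
            self.cls_token = Parameter(rng.normal(0.0, 0.02, size=(cfg.dim,)))
        if cfg.pos_embed == "learned":
            self.pos_embed = Parameter(
                rng.normal(0.0, 0.02, size=(cfg.num_tokens, cfg.dim))
            )
        else:
            pos = sincos_positions((cfg.grid, cfg.grid), cfg.dim)
            if cfg.use_cls_token:
                pos = np.vstack([np.zeros((1, cfg.dim)), pos])
            self._pos_const = pos
        self.blocks = ModuleList(
            Block(cfg.dim, cfg.heads, cfg.mlp_ratio, rng) for _ in range(cfg.depth)
        )
        self.norm = LayerNorm(cfg.dim)

    # -- pieces (also used by the masked autoencoder) -------------------------

    def positions(self) -> Tensor | np.ndarray:
        return self.pos_embed if self.cfg.pos_embed == "learned" else self._pos_const

    def embed(self, images: np.ndarray) -> Tensor:
        """Images (B, H, W, 3) -> positioned token sequence (B, N[, +1], D)."""
        patches = patchify(images, self.cfg.patch_size)
        tokens = self.patch_embed(Tensor(patches))
        if self.cfg.use_cls_token:
            b = tokens.shape[0]
            cls = self.cls_token.reshape(1, 1, self.cfg.dim)
            cls = cls + Tensor(np.zeros((b, 1, self.cfg.dim)))  # broadcast copy
            tokens = ad.concatenate([cls, tokens], axis=1)
        return tokens + self.positions()

    def forward_layers(self, tokens: Tensor) -> list[Tensor]:
        """Run all blocks, returning every layer's output.

        The final LayerNorm is applied to the last element only; intermediate
        taps are raw block outputs.
        """
        outs = []
        x = tokens
        for block in self.blocks:
            x = block(x)
            outs.append(x)
        outs[-1] = self.norm(outs[-1])
        return outs

    def forward(self, images: np.ndarray) -> list[Tensor]:
        return self.forward_layers(self.embed(images))


class SEGate(Module):
    """Squeeze-and-excitation over the layer axis of an (L, D) feature stack.

    Squeeze: mean over the feature axis, one scalar per layer.  Excitation:
    bottleneck MLP L -> r_h -> L with ReLU, then a sigmoid producing per-layer
    weights strictly inside (0, 1).  The second map is zero-initialised so the
    initial gates are exactly 0.5 (an even blend of all layers).
    """

    def __init__(self, n_layers: int, rng: np.random.Generator,
                 reduction: int = 4):
        self.n_layers = n_layers
        hidden = max(1, n_layers // reduction)
        self.fc1 = Linear(n_layers, hidden, rng, std=1.0 / np.sqrt(n_layers))
        self.fc2 = Linear(hidden, n_layers, rng, zero_init=True)

    def forward(self, stack: Tensor) -> Tensor:
        squeezed = stack.mean(axis=-1)  # (..., L)
        return self.fc2(self.fc1(squeezed).relu()).sigmoid()


def pool_layers(layer_outputs: list[Tensor]) -> Tensor:
    """Mean-pool tokens per layer: L sequences of (..., N, D) -> (..., L, D)."""
    return ad.stack([o.mean(axis=-2) for o in layer_outputs], axis=-2)


def se_fuse(stack: Tensor, gate) -> Tensor:
    """Gate an (..., L, D) layer stack and sum over the layer axis.

    ``gate`` is either an :class:`SEGate` (applied to the stack) or a
    precomputed per-layer weight tensor/array of shape (..., L).  Output is
    ``sum_l w_l * stack[..., l, :]`` with shape (..., D).
    """
    if isinstance(gate, SEGate):
        weights = gate(stack)
    elif isinstance(gate, Tensor):
        weights = gate
    else:
        weights = Tensor(np.asarray(gate, dtype=np.float64))
    w = weights.reshape(*weights.shape, 1)
    return (stack * w).sum(axis=-2)


class ViTClassifier(Module):
    """ViT encoder + (optional) SE layer fusion + classification head.

    head:
      * ``"arcface"`` — a sub-center prototype bank scored by max-sub-center
        cosine (metric-learning head used with the dynamic-margin loss);
      * ``"linear"`` — plain affine logits (softmax cross-entropy head).

    With ``fusion=False`` the feature is the class token (if present) or the
    token mean of the final layer — the vanilla ViT readout.
    """

    def __init__(self, cfg: BackboneConfig, n_classes: int,
                 rng: np.random.Generator, fusion: bool = True,
                 head: str = "arcface", sub_centers: int = 3):
        from .arcface import SubcenterArcFace  # local import to avoid a cycle

        if head not in ("arcface", "linear"):
            raise ValueError(f"unknown head {head!r}")
        self.cfg = cfg
        self.n_classes = n_classes
        self.fusion = fusion
        self.encoder = ViTEncoder(cfg, rng)
        if fusion:
            self.se = SEGate(cfg.depth, rng)
        if head == "arcface":
            self.arcface = SubcenterArcFace(n_classes, sub_centers, cfg.dim, rng)
            # running mean of the fused embedding; the angular head sees
            # centered features (the standard embedding-normalization block
            # of margin heads; removes the common component all images share)
            self.embed_center = Buffer(np.zeros(cfg.dim))
            self._center_momentum = 0.9
        else:
            self.head = Linear(cfg.dim, n_classes, rng)
        self.head_type = head

    def features(self, images: np.ndarray) -> Tensor:
        """Fused D-dimensional feature per image, shape (B, D)."""
        outs = self.encoder(images)
        if self.fusion:
            if self.cfg.use_cls_token:
                outs = [o[:, 1:, :] for o in outs]  # drop cls before fusion
            stack = pool_layers(outs)
            return se_fuse(stack, self.se)
        last = outs[-1]
        if self.cfg.use_cls_token:
            return last[:, 0, :]
        return last.mean(axis=-2)

    def center_embeddings(self, feats: Tensor) -> Tensor:
        """Subtract the embedding mean before the angular head.

        In training mode (autodiff enabled) the batch mean is used and folded
        into the running estimate; in inference mode the running mean is
        subtracted.  Linear heads learn their own bias and skip this.
        """
        if self.head_type != "arcface":
            return feats
        if ad.is_grad_enabled() and feats.shape[0] >= 2:
            mu = feats.data.mean(axis=0)
            mom = self._center_momentum
            self.embed_center.data = mom * self.embed_center.data + (1 - mom) * mu
            return feats - Tensor(mu)
        # inference, or a degenerate single-sample batch (whose own mean
        # would annihilate the embedding): use the running estimate
        return feats - Tensor(self.embed_center.data)

    def scores(self, images: np.ndarray) -> Tensor:
        """Per-class scores: cosines for the arcface head, logits otherwise."""
        feats = self.center_embeddings(self.features(images))
        if self.head_type == "arcface":
            return self.arcface.cosines(feats)
        return self.head(feats)

    def predict(self, images: np.ndarray) -> np.ndarray:
        with ad.no_grad():
            return np.argmax(self.scores(images).data, axis=-1)


def vit_base_p16_vanilla(n_classes: int = 10, seed: int = 0) -> ViTClassifier:
    """Standard ViT-base/16 classifier: class token, learned positions
    (197 tokens), linear head.  The Table-style comparison baseline."""
    cfg = BackboneConfig(use_cls_token=True)
    rng = np.random.default_rng(seed)
    return ViTClassifier(cfg, n_classes, rng, fusion=False, head="linear")


def vit_base_p16_fusion(n_classes: int = 10, sub_centers: int = 3,
                        seed: int = 0) -> ViTClassifier:
    """The fusion model: no class token (196 tokens), learned positions,
    SE layer gate, sub-center prototype head."""
    cfg = BackboneConfig(use_cls_token=False)
    rng = np.random.default_rng(seed)
    return ViTClassifier(cfg, n_classes, rng, fusion=True, head="arcface",
                         sub_centers=sub_centers)


def toy_backbone_config(image_size: int = 32, patch_size: int = 8,
                        depth: int = 2, dim: int = 32, heads: int = 4,
                        **kwargs) -> BackboneConfig:
    """Small configuration for tests and CPU-scale experiments."""
    return BackboneConfig(image_size=image_size, patch_size=patch_size,
                          depth=depth, dim=dim, heads=heads, **kwargs)
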