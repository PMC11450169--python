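"""Dynamic-margin sub-center ArcFace loss.

Metric-learning head for imbalanced fine-grained classification.  Each class
owns K unit-norm prototype vectors (sub-centers); the class score for an
embedding x is the *maximum* cosine over its K sub-centers,

    cos(theta_j) = max_k  <W_jk / ||W_jk||,  x / ||x||>.

Training minimises the additive-angular-margin softmax cross-entropy

    L = -log  exp(s * cos(theta_y + m_y)) /
              (exp(s * cos(theta_y + m_y)) + sum_{j != y} exp(s * cos(theta_j)))

where the per-class margin shrinks with the class's training-set size n_c:

    m_c = (a - b) * n_c**lam + b,    lam = -0.5 by default,

so the rarest classes (n_c = 1) get the full margin a and abundant classes
approach the floor b.  Rare classes are intrinsically harder to learn; a
larger margin forces tighter angular clustering exactly where data is scarce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Module, Parameter

__all__ = [
    "MarginTable",
    "LossConfig",
    "compute_margins",
    "subcenter_cosines",
    "margin_logits",
    "SubcenterArcFace",
]

COS_EPS = 1e-7  # clamp for cosines before any arccos/sqrt(1-c^2)


@dataclass
class MarginTable:
    """Per-class angular margins (radians) derived from class counts."""

    margins: np.ndarray
    class_counts: np.ndarray
    a: float = 0.5
    b: float = 0.05
    lam: float = -0.5


@dataclass
class LossConfig:
    s: float = 64.0  # feature re-scale
    sub_centers: int = 3
    a: float = 0.5
    b: float = 0.05
    lam: float = -0.5

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("scale s must be positive")
        if self.sub_centers < 1:
            raise ValueError("need at least one sub-center per class")


def compute_margins(class_counts, a: float = 0.5, b: float = 0.05,
                    lam: float = -0.5) -> MarginTable:
    """Margin schedule m_c = (a - b) * n_c**lam + b.

    With the default lam = -0.5 the margin is a at n_c = 1, decays as
    1/sqrt(n_c) and approaches b from above, so b <= m_c <= a and m is
    non-increasing in the class count.
    """
    counts = np.asarray(class_counts)
    if counts.size == 0:
        raise ValueError("class_counts is empty")
    if np.any(counts < 1):
        raise ValueError("every class count must be >= 1")
    if not b < a:
        raise ValueError("need lower bound b < upper bound a")
    margins = (a - b) * counts.astype(np.float64) ** lam + b
    return MarginTable(margins=margins, class_counts=counts, a=a, b=b, lam=lam)


def _normalize_rows(x: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError(f"zero-norm {what} cannot be normalized")
    return x / norms


def subcenter_cosines(embedding: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Class cosine scores by the max-over-sub-centers rule (pure numpy).

    Parameters
    ----------
    embedding : (D,) or (B, D) array, non-zero rows.
    weights : (N_classes, K, D) prototype bank (need not be pre-normalized).

    Returns
    -------
    (N_classes,) or (B, N_classes) cosines, clamped to [-1+eps, 1-eps].
    """
    emb = np.asarray(embedding, dtype=np.float64)
    single = emb.ndim == 1
    if single:
        emb = emb[None]
    emb = _normalize_rows(emb, "embedding")
    w = _normalize_rows(np.asarray(weights, dtype=np.float64), "sub-center")
    n, k, d = w.shape
    cos = emb @ w.reshape(n * k, d).T  # (B, N*K)
    cos = cos.reshape(-1, n, k).max(axis=2)
    cos = np.clip(cos, -1.0 + COS_EPS, 1.0 - COS_EPS)
    return cos[0] if single else cos


def margin_logits(cosines: np.ndarray, target: int, m: float,
                  s: float = 64.0) -> np.ndarray:
    """Apply the additive angular margin to the target class and scale.

    The target entry becomes s*cos(theta_y + m), computed through the angle
    addition identity s*(cos t * cos m - sin t * sin m) (no arccos round
    trip); other entries are s*cos(theta_j).
    """
    cos = np.asarray(cosines, dtype=np.float64)
    out = s * cos.copy()
    ct = cos[..., target]
    st = np.sqrt(np.clip(1.0 - ct**2, 0.0, None))
    out[..., target] = s * (ct * np.cos(m) - st * np.sin(m))
    return out


class SubcenterArcFace(Module):
    """Trainable sub-center prototype bank with the margin loss.

    The bank ``subcenters`` has shape (N_classes, K, D); it is drawn from a
    zero-mean Gaussian and re-normalized on every forward pass (the stored
    parameter is free, the cosine geometry sees unit vectors).
    """

    def __init__(self, n_classes: int, sub_centers: int, dim: int,
                 rng: np.random.Generator):
        if sub_centers < 1:
            raise ValueError("need at least one sub-center per class")
        w = rng.normal(0.0, 1.0, size=(n_classes, sub_centers, dim))
        w /= np.linalg.norm(w, axis=-1, keepdims=True)
        self.subcenters = Parameter(w)
        self.n_classes = n_classes
        self.k = sub_centers
        self.dim = dim

    def cosines(self, embeddings: Tensor) -> Tensor:
        """Differentiable (B, N_classes) max-sub-center cosines."""
        if np.any(np.linalg.norm(embeddings.data, axis=-1) == 0):
            raise ValueError("zero-norm embedding cannot be normalized")
        emb = embeddings / (embeddings * embeddings).sum(
            axis=-1, keepdims=True).sqrt()
        w = self.subcenters.reshape(self.n_classes * self.k, self.dim)
        w = w / (w * w).sum(axis=-1, keepdims=True).sqrt()
        cos = emb @ w.transpose(1, 0)  # (B, N*K)
        b = cos.shape[0]
        cos = cos.reshape(b, self.n_classes, self.k).max(axis=2)
        return cos.clamp(-1.0 + COS_EPS, 1.0 - COS_EPS)

    def loss(self, embeddings: Tensor, labels: np.ndarray,
             margins: MarginTable | np.ndarray, s: float = 64.0) -> Tensor:
        """Mean margin cross-entropy over a batch."""
        labels = np.asarray(labels)
        if np.any(labels < 0) or np.any(labels >= self.n_classes):
            raise IndexError("label out of range")
        m_vec = margins.margins if isinstance(margins, MarginTable) else margins
        m = np.asarray(m_vec)[labels]  # (B,)
        cos = self.cosines(embeddings)  # (B, N)
        batch = cos.shape[0]
        onehot = np.zeros((batch, self.n_classes))
        onehot[np.arange(batch), labels] = 1.0
        ct = (cos * onehot).sum(axis=1)  # target cosines
        st = (1.0 - ct * ct).clamp(0.0, 1.0).sqrt()
        margined = ct * np.cos(m) - st * np.sin(m)  # cos(theta_y + m)
        logits = s * (cos + Tensor(onehot) * (margined - ct).reshape(batch, 1))
        logp = ad.log_softmax(logits, axis=1)
        nll = -(logp * onehot).sum(axis=1)
        return nll.mean()
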