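"""Independent reference implementations used as test oracles.

Deliberately naive transcriptions — explicit loops, arccos round trips and
raw exponentials — kept free of the stable rewrites the package uses, so the
two routes are genuinely independent.
"""

import numpy as np


def naive_subcenter_cosines(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Brute-force max-over-sub-centers cosine, one dot product at a time."""
    x = x / np.linalg.norm(x)
    n, k, _ = w.shape
    out = np.empty(n)
    for j in range(n):
        best = -np.inf
        for kk in range(k):
            wv = w[j, kk] / np.linalg.norm(w[j, kk])
            best = max(best, float(np.dot(wv, x)))
        out[j] = best
    return out


def naive_margin_loss(embeddings: np.ndarray, labels: np.ndarray,
                      weights: np.ndarray, margins: np.ndarray,
                      s: float) -> float:
    """Direct transcription of the margin softmax: theta by arccos, margin
    added in angle space, raw exponential ratio, mean over the batch."""
    total = 0.0
    for x, y in zip(embeddings, labels):
        cos = np.clip(naive_subcenter_cosines(x, weights), -1 + 1e-7, 1 - 1e-7)
        theta = np.arccos(cos)
        num = np.exp(s * np.cos(theta[y] + margins[y]))
        den = num + sum(np.exp(s * cos[j]) for j in range(len(cos)) if j != y)
        total += -np.log(num / den)
    return total / len(labels)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Plain softmax cross-entropy, stable form, mean over batch."""
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(labels)), labels].mean())
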