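"""Checkpoint files: a named parameter collection with a stable key schema.

A checkpoint is a flat ``{dotted.key: ndarray}`` mapping (see
:mod:`hemafuse.mae` for the encoder/decoder schema) plus a JSON metadata
blob, stored as an ``.npz`` archive.  Keys are matched by name, never by
position, which is what makes MAE-to-classifier transfer robust.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["save_checkpoint", "load_checkpoint"]

_META_KEY = "__meta__"


def save_checkpoint(path: str | Path, state: dict[str, np.ndarray],
                    meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = dict(state)
    if _META_KEY in arrays:
        raise ValueError(f"reserved key {_META_KEY!r} in state dict")
    arrays[_META_KEY] = np.frombuffer(
        json.dumps(meta or {}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data[_META_KEY]).decode()) if _META_KEY in data else {}
        state = {k: data[k] for k in data.files if k != _META_KEY}
    return state, meta
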