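"""Serial feature fusion and train-split standardization.

Fusion is plain ordered concatenation — the dual-deep representation joins
two reduced deep vectors, and the DL+ML representation joins a reduced deep
vector with the 25 GLCM and 3 Hu values — with per-part provenance kept so
every fused coordinate remains traceable to its source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureVector

__all__ = ["FusedVector", "fuse", "standardize"]


@dataclass
class FusedVector(FeatureVector):
    parts: list[tuple[str, int]] = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.parts is None:
            self.parts = [(self.source, self.dim)]


def fuse(vectors: list[FeatureVector]) -> FusedVector:
    """Serially concatenate feature vectors, preserving order and names."""
    if not vectors:
        raise ValueError("need at least one vector to fuse")
    names: list[str] = []
    parts: list[tuple[str, int]] = []
    for v in vectors:
        names.extend(v.names)
        if isinstance(v, FusedVector):
            parts.extend(v.parts)
        else:
            parts.append((v.source, v.dim))
    if len(set(names)) != len(names):
        dupes = {n for n in names if names.count(n) > 1}
        raise ValueError(f"duplicate feature names in fusion: {sorted(dupes)[:5]}")
    values = np.concatenate([v.values for v in vectors])
    return FusedVector(values, names, "fused", parts=parts)


def standardize(train_matrix: np.ndarray, *apply_matrices: np.ndarray
                ) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Column z-scoring with parameters fitted on the training rows only.

    Returns ``([train_std, *applied_std], mean, scale)``.  Zero-variance
    training columns pass through centered (scale forced to 1).
    """
    train = np.asarray(train_matrix, dtype=float)
    if train.size == 0:
        raise ValueError("empty training matrix")
    mean = train.mean(axis=0)
    scale = train.std(axis=0)
    scale[scale == 0] = 1.0
    out = [(train - mean) / scale]
    for m in apply_matrices:
        out.append((np.asarray(m, dtype=float) - mean) / scale)
    return out, mean, scale
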