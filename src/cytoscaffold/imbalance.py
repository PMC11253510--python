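"""SMOTE class rebalancing to an exact minority:majority target ratio.

Synthetic minority samples are linear interpolations between a minority
point and one of its k nearest minority neighbours:

    s = a + u * (b - a),   u ~ Uniform(0, 1),

so every synthetic point lies on a segment inside the minority convex hull.
The interface is stated in terms of the *target ratio* (1:1, 1:2, 1:3 ...)
rather than oversampling percentages: the caller says what class balance
the training set should have and the module derives how many synthetic
minority points to create and how many majority points to draw.

Final counts: minority is raised to max(original, ceil(a/b * majority))
for ratio a:b, all original minority points retained; the majority is then
drawn to make the ratio exact — without replacement when enough majority
samples exist (undersampling), with replacement otherwise (the target
ratio is more majority-heavy than the data can supply).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError, DataError

__all__ = ["SmoteConfig", "smote_resample"]


@dataclass(frozen=True)
class SmoteConfig:
    """Target class balance and neighbourhood size for SMOTE."""

    target_ratio: tuple[int, int] = (1, 1)  # minority : majority
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.target_ratio
        if a < 1 or b < 1:
            raise ConfigError("ratio components must be positive integers")
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")

    @classmethod
    def from_ratio_string(cls, text: str, k_neighbors: int = 5, seed: int = 0) -> "SmoteConfig":
        """Parse ``"1:2"`` style ratio strings."""
        try:
            a, b = (int(p) for p in text.split(":"))
        except Exception as exc:
            raise ConfigError(f"cannot parse ratio {text!r}; expected 'a:b'") from exc
        return cls(target_ratio=(a, b), k_neighbors=k_neighbors, seed=seed)


def smote_resample(
    X: np.ndarray, y: np.ndarray, cfg: SmoteConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Rebalance a binary dataset to ``cfg.target_ratio`` exactly.

    Returns ``(X', y')`` with all original minority rows first, then the
    synthetic minority rows, then the drawn majority rows. Deterministic
    given ``cfg.seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DataError("X must be 2-D with one label per row")
    if not np.isfinite(X).all():
        raise DataError("features must be finite")
    classes, counts = np.unique(y.astype(str), return_counts=True)
    if classes.size != 2:
        raise DataError(f"SMOTE requires exactly 2 classes, got {classes.size}")
    min_label = classes[np.argmin(counts)]
    is_min = y.astype(str) == min_label
    n_min, n_maj = int(is_min.sum()), int((~is_min).sum())
    if n_min < 2:
        raise DataError("minority class has fewer than 2 points; cannot interpolate")
    if n_min <= cfg.k_neighbors:
        raise DataError(
            f"minority size {n_min} <= k_neighbors {cfg.k_neighbors}; use smaller k"
        )

    a, b = cfg.target_ratio
    m_min = max(n_min, math.ceil(a * n_maj / b))
    m_maj = round(m_min * b / a)

    rng = np.random.default_rng(cfg.seed)
    X_min = X[is_min]
    y_min = y[is_min]
    n_synth = m_min - n_min
    synth = np.empty((n_synth, X.shape[1]))
    if n_synth > 0:
        nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(X_min)
        _, nbr = nn.kneighbors(X_min)
        nbr = nbr[:, 1:]  # drop self
        parents = rng.integers(0, n_min, size=n_synth)
        picks = rng.integers(0, cfg.k_neighbors, size=n_synth)
        u = rng.uniform(0.0, 1.0, size=n_synth)
        pa = X_min[parents]
        pb = X_min[nbr[parents, picks]]
        synth = pa + u[:, None] * (pb - pa)

    maj_idx = np.flatnonzero(~is_min)
    if m_maj <= n_maj:
        drawn = rng.choice(maj_idx, size=m_maj, replace=False)
    else:
        drawn = np.concatenate(
            [maj_idx, rng.choice(maj_idx, size=m_maj - n_maj, replace=True)]
        )
    X_out = np.vstack([X_min, synth, X[drawn]])
    y_out = np.concatenate(
        [y_min, np.full(n_synth, y_min[0], dtype=object), y[drawn]]
    )
    return X_out, y_out
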