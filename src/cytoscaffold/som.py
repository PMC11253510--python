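"""Online self-organizing map on a rectangular grid.

A small, deterministic SOM in the FlowSOM mould: cells are presented one at
a time, the best-matching unit (BMU, nearest codebook vector in Euclidean
distance) and its grid neighbours are pulled toward the cell under a
Gaussian neighbourhood whose radius and learning rate decay linearly over a
fixed number of passes. The 10x10 default grid gives 100 micro-clusters,
comfortably more than the number of true populations in typical panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError, DataError

__all__ = ["SOMModel", "train_som", "assign_to_nodes"]


@dataclass
class SOMModel:
    grid_rows: int
    grid_cols: int
    codebook: np.ndarray  # (grid_rows * grid_cols) x n_features
    training_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codebook = np.asarray(self.codebook, dtype=np.float64)
        if self.codebook.shape[0] != self.grid_rows * self.grid_cols:
            raise ConfigError("codebook row count must equal grid size")
        if not np.isfinite(self.codebook).all():
            raise DataError("codebook contains non-finite entries")

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)


def train_som(
    X: np.ndarray,
    rows: int = 10,
    cols: int = 10,
    n_epochs: int = 10,
    learning_rate: float = 0.05,
    final_learning_rate: float = 0.01,
    initial_radius: float | None = None,
    seed: int = 0,
) -> SOMModel:
    """Train an online SOM; deterministic given ``seed``.

    The codebook is initialized from a random sample of cells (with
    replacement when there are fewer cells than nodes). The initial
    neighbourhood radius defaults to half the larger grid dimension and
    decays linearly to ~0 over all presentations, as does the learning
    rate down to ``final_learning_rate``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise DataError("SOM training requires a non-empty 2-D matrix")
    if not np.isfinite(X).all():
        raise DataError("SOM training input contains non-finite values")
    if rows < 1 or cols < 1 or n_epochs < 1:
        raise ConfigError("grid dimensions and epochs must be positive")
    n_nodes = rows * cols
    if X.shape[0] < n_nodes:
        warnings.warn(
            f"fewer cells ({X.shape[0]}) than SOM nodes ({n_nodes}); "
            "clusters will be sparse",
            stacklevel=2,
        )
    if initial_radius is None:
        initial_radius = max(rows, cols) / 2.0

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(X.shape[0], size=n_nodes, replace=X.shape[0] < n_nodes)
    codebook = X[init_idx].copy()
    grid = _grid_coords(rows, cols)
    grid_d2 = cdist(grid, grid, metric="sqeuclidean")  # node-to-node grid distances

    n_steps = n_epochs * X.shape[0]
    step = 0
    for _ in range(n_epochs):
        order = rng.permutation(X.shape[0])
        for i in order:
            frac = step / n_steps
            lr = learning_rate + (final_learning_rate - learning_rate) * frac
            sigma = max(initial_radius * (1.0 - frac), 0.3)
            x = X[i]
            diff = codebook - x
            bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))
            codebook -= (lr * h)[:, None] * diff
            step += 1

    return SOMModel(
        grid_rows=rows,
        grid_cols=cols,
        codebook=codebook,
        training_params={
            "n_epochs": n_epochs,
            "learning_rate": learning_rate,
            "final_learning_rate": final_learning_rate,
            "initial_radius": initial_radius,
            "seed": seed,
        },
    )


def assign_to_nodes(som: SOMModel, X: np.ndarray) -> np.ndarray:
    """BMU index per cell (Euclidean); ties go to the lowest node index."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != som.codebook.shape[1]:
        raise DataError(
            f"input dimension {X.shape} does not match codebook "
            f"dimension {som.codebook.shape[1]}"
        )
    d2 = cdist(X, som.codebook, metric="sqeuclidean")
    return np.argmin(d2, axis=1)  # argmin returns the first (lowest) index on ties
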