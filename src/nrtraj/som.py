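"""Self-organizing map with a Gaussian neighborhood on a square grid.

Batch training: every epoch assigns all rows to their best-matching unit
(BMU), then blends each neuron toward the neighborhood-weighted mean of the
data, with both the neighborhood radius (initial value = half the grid
diagonal) and the blending rate (0.5 -> 0.01) decaying exponentially over
epochs.  Training is fully reproducible given the seed, which controls only
the weight initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NrtrajError
from .stats import FeatureTable

DEFAULT_GRID = (10, 10)
INITIAL_RATE, FINAL_RATE = 0.5, 0.01
FINAL_RADIUS = 0.5


@dataclass
class SOMResult:
    grid_shape: tuple
    weights: np.ndarray          # (rows, cols, n_features)
    assignments: np.ndarray      # (n_samples, 2) BMU grid coordinates
    quantization_error: float
    qe_history: np.ndarray       # per-epoch quantization error
    seed: int

    def bmu_distance(self, i: int, j: int) -> int:
        """Chebyshev grid distance between the BMUs of samples i and j."""
        return int(np.max(np.abs(self.assignments[i] - self.assignments[j])))


def _bmus(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    flat = W.reshape(-1, X.shape[1])
    d = np.linalg.norm(X[:, None, :] - flat[None, :, :], axis=2)
    return np.argmin(d, axis=1)


def som_fit(table: FeatureTable, grid: tuple = DEFAULT_GRID,
            epochs: int = 50, seed: int = 0) -> SOMResult:
    """Train a Gaussian-neighborhood SOM on an autoscaled feature table.

    Weights are initialised from a seeded standard normal scaled to the data
    spread; identical seeds give identical maps and assignments.
    """
    X = table.data.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise NrtrajError("SOM training needs at least 2 rows")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rows, cols = grid
    n_feat = X.shape[1]
    rng = np.random.default_rng(seed)
    W = rng.normal(loc=X.mean(axis=0), scale=X.std(axis=0) + 1e-12,
                   size=(rows * cols, n_feat)).reshape(rows, cols, n_feat)

    gy, gx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    grid_pos = np.stack([gy.ravel(), gx.ravel()], axis=1).astype(float)
    sq_grid_dist = ((grid_pos[:, None, :] - grid_pos[None, :, :]) ** 2).sum(axis=2)

    sigma0 = 0.5 * np.hypot(rows - 1, cols - 1)
    sigma0 = max(sigma0, FINAL_RADIUS)
    qe_history = np.empty(epochs)
    for t in range(epochs):
        frac = t / max(epochs - 1, 1)
        sigma = sigma0 * (FINAL_RADIUS / sigma0) ** frac
        rate = INITIAL_RATE * (FINAL_RATE / INITIAL_RATE) ** frac
        flat = W.reshape(-1, n_feat)
        bmu = _bmus(X, W)
        qe_history[t] = float(np.mean(np.linalg.norm(X - flat[bmu], axis=1)))
        h = np.exp(-sq_grid_dist[:, bmu] / (2 * sigma ** 2))  # (units, samples)
        denom = h.sum(axis=1, keepdims=True)
        target = np.where(denom > 1e-300, (h @ X) / np.maximum(denom, 1e-300), flat)
        W = ((1 - rate) * flat + rate * target).reshape(rows, cols, n_feat)

    bmu = _bmus(X, W)
    assignments = np.stack([bmu // cols, bmu % cols], axis=1)
    qe = float(np.mean(np.linalg.norm(X - W.reshape(-1, n_feat)[bmu], axis=1)))
    return SOMResult(grid_shape=(rows, cols), weights=W, assignments=assignments,
                     quantization_error=qe, qe_history=qe_history, seed=seed)
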