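"""Self-organizing map clustering of interaction-effect expression profiles.

A classic online Kohonen SOM on a small rectangular grid (default 2x3 = 6
units, one per expected expression archetype). Each gene's profile is the
vector of its four design-cell means of log2 expression, z-scored per gene so
that clustering reflects profile shape rather than absolute level. Training
is competitive: at each step the best-matching unit (BMU) and its grid
neighbours move toward the presented profile, with a Gaussian neighbourhood
whose radius and a learning rate that both decay linearly to zero over the
schedule. Fully deterministic given a seed (random-row initialization and
presentation order are drawn from one generator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class ClusterAssignment:
    """Gene -> SOM unit id, plus the trained unit centroids."""

    labels: pd.Series            # gene -> cluster id (int, row-major grid order)
    centroids: pd.DataFrame      # cluster id x profile columns
    grid: tuple[int, int]


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row; rows with zero variance become all-zero vectors."""
    arr = profiles.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return pd.DataFrame((arr - mean) / sd, index=profiles.index, columns=profiles.columns)


def som_cluster(
    profiles: pd.DataFrame,
    grid: tuple[int, int] = (2, 3),
    epochs: int = 500,
    learning_rate: float = 0.5,
    radius: float = 1.5,
    seed: int = 0,
    zscore: bool = True,
) -> ClusterAssignment:
    """Cluster expression profiles on a ``grid[0] x grid[1]`` Kohonen map.

    Parameters follow the conventional online SOM: ``learning_rate`` and
    ``radius`` are the initial values of linearly decaying schedules; the
    neighbourhood kernel is Gaussian in grid (Chebyshev-free Euclidean)
    distance. Unit ids are row-major grid positions. Requires at least as
    many genes as units.
    """
    n_units = grid[0] * grid[1]
    if profiles.shape[0] < n_units:
        raise DataError(
            f"SOM needs >= {n_units} genes for a {grid[0]}x{grid[1]} grid; got "
            f"{profiles.shape[0]} — configure a smaller grid"
        )
    data = zscore_profiles(profiles) if zscore else profiles
    X = data.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise DataError("non-finite values in SOM profiles")

    rng = np.random.default_rng(seed)
    coords = np.array([(i, j) for i in range(grid[0]) for j in range(grid[1])], dtype=float)
    # random-sample initialization from the data rows
    weights = X[rng.choice(len(X), size=n_units, replace=False)].copy()

    total_steps = epochs * len(X)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(X))
        for idx in order:
            frac = 1.0 - step / total_steps
            lr = learning_rate * frac
            rad = max(radius * frac, 1e-3)
            x = X[idx]
            bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
            grid_d2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
            h = np.exp(-grid_d2 / (2.0 * rad * rad))
            weights += lr * h[:, None] * (x - weights)
            step += 1

    d2 = ((X[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
    labels = pd.Series(np.argmin(d2, axis=1), index=data.index, name="cluster")
    centroids = pd.DataFrame(
        weights, index=pd.RangeIndex(n_units, name="cluster"), columns=data.columns
    )
    return ClusterAssignment(labels=labels, centroids=centroids, grid=grid)
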