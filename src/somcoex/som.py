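"""Online Kohonen self-organizing map on a rectangular lattice.

Genes are presented as vectors of log2-normalized expression over all
samples (20 dimensions in the two-substrate, five-growth-point duplicate
design) and compete for nodes on a rows x cols rectangular grid
(4-neighbour topology).  Defaults follow the convention of classic
co-expression SOM pipelines: a 24 x 20 grid (480 nodes), a training
budget of 1000 presentations per node (480,000 steps), an initial
neighbourhood radius taken from the quantile of pairwise node lattice
distances, a bubble neighbourhood, and linear learning-rate and radius
decays.  Input vectors are trained as-is (no feature scaling): nodes
therefore separate genes both by profile shape and by expression level.

Training is online and strictly sequential -- one observation updates the
best-matching unit (BMU) and every node within the current radius -- and
is reproducible given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .io import SomcoexError, ValidationError

__all__ = [
    "SOMGrid",
    "NodeAssignment",
    "init_grid",
    "epoch_count",
    "initial_radius",
    "bmu",
    "train",
    "assign",
    "quantization_error",
]


@dataclass
class SOMGrid:
    """Rectangular SOM: lattice geometry plus the codebook.

    Node IDs run 1..rows*cols in row-major order; node ``i`` sits at
    lattice coordinate ``((i-1) // cols, (i-1) % cols)``.  ``codebook``
    has one weight vector per node (dimension = number of samples).
    """

    rows: int
    cols: int
    codebook: np.ndarray  # (n_nodes, dim)
    trained: bool = False
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValidationError("grid dimensions must be positive")
        self.codebook = np.asarray(self.codebook, dtype=float)
        if self.codebook.shape[0] != self.n_nodes:
            raise ValidationError(
                f"codebook has {self.codebook.shape[0]} rows, expected {self.n_nodes}"
            )

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    @property
    def node_ids(self) -> np.ndarray:
        return np.arange(1, self.n_nodes + 1)

    @property
    def coordinates(self) -> np.ndarray:
        """Integer lattice (row, col) per node, row-major."""
        ids = np.arange(self.n_nodes)
        return np.column_stack([ids // self.cols, ids % self.cols]).astype(float)

    def lattice_distance_matrix(self) -> np.ndarray:
        c = self.coordinates
        return cdist(c, c)


@dataclass
class NodeAssignment:
    """Gene -> best-matching node, and the members of every node."""

    gene_to_node: pd.Series  # gene_id -> node_id (1-based)
    n_nodes: int

    def members(self, node_id: int) -> list[str]:
        return list(self.gene_to_node.index[self.gene_to_node == node_id])

    @property
    def member_lists(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {i: [] for i in range(1, self.n_nodes + 1)}
        for g, n in self.gene_to_node.items():
            out[int(n)].append(g)
        return out


def _as_array(data) -> np.ndarray:
    x = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    if x.ndim != 2:
        raise ValidationError("data must be 2-dimensional (observations x features)")
    return x


def init_grid(rows: int = 24, cols: int = 20, data=None, seed: int = 0) -> SOMGrid:
    """Construct a grid with codebooks sampled from the data rows.

    Sampling is without replacement (seeded); if there are fewer
    observations than nodes a warning is emitted and sampling falls back
    to with-replacement.
    """
    if rows <= 0 or cols <= 0:
        raise ValidationError("grid dimensions must be positive")
    if data is None:
        raise ValidationError("data is required to initialize the codebook")
    x = _as_array(data)
    n_nodes = rows * cols
    rng = np.random.default_rng(seed)
    if x.shape[0] < n_nodes:
        warnings.warn(
            f"fewer observations ({x.shape[0]}) than nodes ({n_nodes}); "
            "sampling initial codebooks with replacement",
            stacklevel=2,
        )
        idx = rng.integers(0, x.shape[0], size=n_nodes)
    else:
        idx = rng.choice(x.shape[0], size=n_nodes, replace=False)
    return SOMGrid(rows, cols, x[idx].copy(), trained=False, config={"seed": seed})


def epoch_count(grid: SOMGrid, factor: int = 1000) -> int:
    """Training budget: ``factor`` presentations per node (map size x factor)."""
    return grid.n_nodes * factor


def initial_radius(grid: SOMGrid, quantile: float = 0.67) -> float:
    """Neighbour-distance initial radius.

    The given quantile (linear interpolation) of all pairwise Euclidean
    distances between node lattice coordinates.
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValidationError("quantile must lie in [0, 1]")
    d = pdist(grid.coordinates)
    return float(np.quantile(d, quantile))


def bmu(grid: SOMGrid, vector: np.ndarray) -> int:
    """Best-matching unit: node ID minimizing Euclidean distance.

    Ties break to the lowest node ID (row-major order).
    """
    v = np.asarray(vector, dtype=float)
    if v.shape != (grid.codebook.shape[1],):
        raise ValidationError(
            f"vector dimension {v.shape} does not match codebook dimension "
            f"({grid.codebook.shape[1]},)"
        )
    d2 = np.square(grid.codebook - v).sum(axis=1)
    return int(np.argmin(d2)) + 1


def train(
    grid: SOMGrid,
    data,
    epochs: int | None = None,
    lr_start: float = 0.05,
    lr_end: float = 0.01,
    radius_start: float | None = None,
    radius_end: float = 1.0,
    radius_quantile: float = 0.67,
    seed: int = 0,
    steps_mode: str = "presentations",
) -> SOMGrid:
    """Online SOM training; returns the grid with an updated codebook.

    One step presents a single observation (seeded random order, cycling
    through the data each pass): the BMU and every node strictly within
    the current lattice radius move toward it by ``lr * (x - w)`` (bubble
    neighbourhood; a final radius of 1 therefore means BMU-only updates).  Learning rate decays linearly lr_start -> lr_end and
    the radius linearly from the neighbour-distance initial radius down
    to ``radius_end`` over the step budget.  ``steps_mode`` sets whether
    ``epochs`` counts observation presentations (default, matching the
    map-size x 1000 budget) or full passes over the data.
    """
    x = _as_array(data)
    if np.isnan(x).any():
        bad = np.where(np.isnan(x).any(axis=1))[0]
        names = list(data.index[bad]) if isinstance(data, pd.DataFrame) else bad.tolist()
        raise SomcoexError(f"NaN values in data rows: {names[:10]}")
    if x.shape[1] != grid.codebook.shape[1]:
        raise ValidationError("data dimension does not match codebook")
    if steps_mode not in {"presentations", "passes"}:
        raise ValidationError("steps_mode must be 'presentations' or 'passes'")

    n_obs = x.shape[0]
    if epochs is None:
        epochs = epoch_count(grid)
    total_steps = int(epochs) * (n_obs if steps_mode == "passes" else 1)
    if total_steps <= 0:
        raise ValidationError("epochs must be positive")
    r0 = initial_radius(grid, radius_quantile) if radius_start is None else float(radius_start)

    rng = np.random.default_rng(seed)
    cb = grid.codebook.copy()
    lattice = grid.lattice_distance_matrix()
    # precompute per-node neighbour lists sorted by lattice distance, so the
    # bubble membership at radius r is a prefix of each list
    sort_idx = np.argsort(lattice, axis=1, kind="stable")
    sorted_dist = np.take_along_axis(lattice, sort_idx, axis=1)

    denom = max(total_steps - 1, 1)
    order = rng.permutation(n_obs)
    pos = 0
    for step in range(total_steps):
        if pos == n_obs:
            order = rng.permutation(n_obs)
            pos = 0
        v = x[order[pos]]
        pos += 1
        frac = step / denom
        lr = lr_start + (lr_end - lr_start) * frac
        radius = r0 + (radius_end - r0) * frac
        diff = v - cb
        b = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
        k = max(1, int(np.searchsorted(sorted_dist[b], radius, side="left")))
        nbrs = sort_idx[b, :k]
        cb[nbrs] += lr * diff[nbrs]

    grid.codebook = cb
    grid.trained = True
    grid.config.update(
        {
            "epochs": int(epochs),
            "steps": total_steps,
            "lr_start": lr_start,
            "lr_end": lr_end,
            "radius_start": r0,
            "radius_end": radius_end,
            "train_seed": seed,
            "steps_mode": steps_mode,
        }
    )
    return grid


def _bmu_all(grid: SOMGrid, x: np.ndarray, chunk: int = 2048) -> np.ndarray:
    out = np.empty(x.shape[0], dtype=np.int64)
    for i in range(0, x.shape[0], chunk):
        d = cdist(x[i : i + chunk], grid.codebook)
        out[i : i + chunk] = np.argmin(d, axis=1)
    return out


def assign(grid: SOMGrid, data) -> NodeAssignment:
    """Map every gene to its best-matching unit."""
    x = _as_array(data)
    idx = _bmu_all(grid, x)
    genes = (
        pd.Index(data.index)
        if isinstance(data, pd.DataFrame)
        else pd.RangeIndex(x.shape[0])
    )
    return NodeAssignment(pd.Series(idx + 1, index=genes, name="node_id"), grid.n_nodes)


def quantization_error(grid: SOMGrid, data) -> float:
    """Mean Euclidean distance of observations to their BMU codebooks."""
    x = _as_array(data)
    idx = _bmu_all(grid, x)
    return float(np.linalg.norm(x - grid.codebook[idx], axis=1).mean())
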