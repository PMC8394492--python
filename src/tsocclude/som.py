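"""Self-Organizing-Map clustering of influential sub-signals.

A SOM arranges neurons on a small 2-D lattice and pulls each neuron's
weight vector toward the inputs it (and its lattice neighbours) respond to,
so that nearby neurons end up representing morphologically similar
sub-signals.  Projecting the mean influence score of the sub-signals mapped
to each neuron onto the lattice — the E-matrix — highlights the prototypical
signal shapes the model is most sensitive to.

The trainer is the classic online algorithm: at each step a random input is
drawn, its best matching unit (BMU) found by Euclidean distance, and all
weights updated with a Gaussian neighbourhood kernel centred on the BMU.
Learning rate and neighbourhood width decay asymptotically over the run.
Default hyperparameters: a 12 x 17 hexagonal grid, sigma = 2.05,
learning rate 0.7, 1e5 steps.

Sub-signals from a clipped trailing window are zero-padded to the window
duration before mapping; they stay flagged ``truncated`` in their records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np

from .core import ShapeError, SubSignal

__all__ = [
    "SOMConfig",
    "SOMGrid",
    "EMatrix",
    "train_som",
    "bmu",
    "build_e_matrix",
    "unit_members",
    "subsignal_matrix",
    "save_som",
    "load_som",
]


@dataclass(frozen=True)
class SOMConfig:
    """SOM hyperparameters with the package defaults."""

    rows: int = 12
    cols: int = 17
    sigma: float = 2.05
    learning_rate: float = 0.7
    steps: int = 100_000
    topology: str = "hexagonal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.sigma <= 0 or self.learning_rate <= 0 or self.steps < 1:
            raise ValueError("sigma, learning_rate and steps must be positive")
        if self.topology not in ("hexagonal", "rectangular"):
            raise ValueError(f"topology must be hexagonal or rectangular, got {self.topology!r}")


def _grid_coordinates(rows: int, cols: int, topology: str) -> np.ndarray:
    """Planar (x, y) position of every neuron, shape (rows, cols, 2).

    Hexagonal lattices offset odd rows by half a unit and compress row
    spacing to sqrt(3)/2, giving equidistant nearest neighbours.
    """
    jj, ii = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    if topology == "hexagonal":
        x = jj + 0.5 * (ii % 2)
        y = ii * (np.sqrt(3.0) / 2.0)
    else:
        x, y = jj, ii
    return np.stack([x, y], axis=-1)


@dataclass(frozen=True)
class SOMGrid:
    """A trained map: weight vectors on a rows x cols lattice."""

    weights: np.ndarray  # (rows, cols, w)
    config: SOMConfig

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 3:
            raise ShapeError("weights must be 3-D (rows, cols, length)")
        if w.shape[:2] != (self.config.rows, self.config.cols):
            raise ShapeError(
                f"weights shape {w.shape[:2]} != grid ({self.config.rows}, {self.config.cols})"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "weights", w)

    @property
    def input_length(self) -> int:
        return self.weights.shape[2]

    def grid_coordinates(self) -> np.ndarray:
        return _grid_coordinates(self.config.rows, self.config.cols, self.config.topology)


def subsignal_matrix(G: Sequence[SubSignal], length: Optional[int] = None) -> np.ndarray:
    """Stack sub-signal values into a (len(G), length) matrix.

    ``length`` defaults to the longest entry; shorter entries (clipped
    trailing windows) are zero-padded on the right.
    """
    if not G:
        raise ValueError("G must be nonempty")
    if length is None:
        length = max(s.length for s in G)
    out = np.zeros((len(G), length))
    for i, s in enumerate(G):
        if s.length > length:
            raise ShapeError(f"sub-signal length {s.length} exceeds map length {length}")
        out[i, : s.length] = s.values
    return out


def train_som(
    G: Sequence[SubSignal] | np.ndarray,
    config: SOMConfig = SOMConfig(),
) -> SOMGrid:
    """Train a map on sub-signals (or a raw (m, w) matrix) of equal length.

    Reproducible: the initial weights and the step-wise sampling both flow
    from ``config.seed``.
    """
    if isinstance(G, np.ndarray):
        data = np.asarray(G, dtype=float)
        if data.ndim != 2:
            raise ShapeError("training data must be 2-D (inputs, length)")
    else:
        data = subsignal_matrix(G)
    m, w = data.shape
    rng = np.random.default_rng(config.seed)
    weights = rng.uniform(-1.0, 1.0, size=(config.rows, config.cols, w))
    # scale the random init to the data range so early neighbourhoods are sane
    lo, hi = data.min(), data.max()
    if hi > lo:
        weights = lo + (weights + 1.0) * 0.5 * (hi - lo)

    coords = _grid_coordinates(config.rows, config.cols, config.topology)
    flat_w = weights.reshape(-1, w)
    flat_xy = coords.reshape(-1, 2)
    half_life = config.steps / 2.0
    picks = rng.integers(0, m, size=config.steps)
    for t in range(config.steps):
        x = data[picks[t]]
        decay = 1.0 + t / half_life
        sig = config.sigma / decay
        lr = config.learning_rate / decay
        best = int(np.argmin(np.einsum("ij,ij->i", flat_w - x, flat_w - x)))
        d2 = np.sum((flat_xy - flat_xy[best]) ** 2, axis=1)
        g = lr * np.exp(-d2 / (2.0 * sig * sig))
        flat_w += g[:, None] * (x - flat_w)
    return SOMGrid(weights=flat_w.reshape(config.rows, config.cols, w), config=config)


def bmu(som: SOMGrid, s: np.ndarray) -> Tuple[int, int]:
    """Best matching unit: coordinates of the weight vector nearest to ``s``.

    Euclidean distance; ties broken row-major (first minimal unit).
    """
    x = np.asarray(s, dtype=float).ravel()
    if x.size != som.input_length:
        raise ShapeError(f"query length {x.size} != map length {som.input_length}")
    diff = som.weights.reshape(-1, som.input_length) - x
    idx = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
    return idx // som.config.cols, idx % som.config.cols


@dataclass(frozen=True)
class EMatrix:
    """Per-neuron mean influence score of the sub-signals mapped to it.

    ``values[u, v]`` is the mean score over the sub-signals whose BMU is
    ``(u, v)`` (0 where none map); ``counts`` is the occupancy.  When
    ``normalized``, values are min-max scaled over occupied cells into
    [0, 1] (unoccupied cells stay 0; if all occupied cells tie, they map
    to 1.0).
    """

    values: np.ndarray
    counts: np.ndarray
    normalized: bool

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.17g")


def _bmu_assignments(som: SOMGrid, G: Sequence[SubSignal]) -> List[Tuple[int, int]]:
    length = som.input_length
    return [bmu(som, np.pad(s.values, (0, length - s.length))) for s in G]


def build_e_matrix(som: SOMGrid, G: Sequence[SubSignal], normalize: bool = False) -> EMatrix:
    """Map every sub-signal to its BMU and accumulate mean scores per unit."""
    rows, cols = som.config.rows, som.config.cols
    values = np.zeros((rows, cols))
    counts = np.zeros((rows, cols), dtype=int)
    if not G:
        warnings.warn("empty sub-signal set: E-matrix is all zeros")
        return EMatrix(values=values, counts=counts, normalized=normalize)
    for s, (u, v) in zip(G, _bmu_assignments(som, G)):
        values[u, v] += s.score
        counts[u, v] += 1
    occupied = counts > 0
    values[occupied] /= counts[occupied]
    if normalize:
        occ_vals = values[occupied]
        lo, hi = occ_vals.min(), occ_vals.max()
        # spreads below float accumulation noise are treated as exact ties
        if hi - lo > 1e-12 * max(abs(hi), 1.0):
            values[occupied] = (occ_vals - lo) / (hi - lo)
        else:
            values[occupied] = 1.0
    return EMatrix(values=values, counts=counts, normalized=normalize)


def unit_members(som: SOMGrid, G: Sequence[SubSignal], cell: Tuple[int, int]) -> List[SubSignal]:
    """All sub-signals of G whose BMU is ``cell`` (empty list if none)."""
    u, v = cell
    return [s for s, c in zip(G, _bmu_assignments(som, G)) if c == (u, v)]


def save_som(path, som: SOMGrid) -> None:
    """Persist a trained map (weights + hyperparameters) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=som.weights)
        cfg = som.config
        f.attrs["rows"] = cfg.rows
        f.attrs["cols"] = cfg.cols
        f.attrs["sigma"] = cfg.sigma
        f.attrs["learning_rate"] = cfg.learning_rate
        f.attrs["steps"] = cfg.steps
        f.attrs["topology"] = cfg.topology
        f.attrs["seed"] = cfg.seed


def load_som(path) -> SOMGrid:
    with h5py.File(path, "r") as f:
        weights = f["weights"][...]
        cfg = SOMConfig(
            rows=int(f.attrs["rows"]),
            cols=int(f.attrs["cols"]),
            sigma=float(f.attrs["sigma"]),
            learning_rate=float(f.attrs["learning_rate"]),
            steps=int(f.attrs["steps"]),
            topology=str(f.attrs["topology"]),
            seed=int(f.attrs["seed"]),
        )
    return SOMGrid(weights=weights, config=cfg)
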