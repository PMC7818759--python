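"""Functional and structural connectome construction.

A functional connectome is the zero-lagged Pearson correlation matrix of the
preprocessed ROI time series; a structural connectome is the undirected
streamline-based connection-probability matrix from probabilistic
tractography.  Both are symmetric 90 x 90 matrices with zeros assigned to the
diagonal, and both serve directly as weighted adjacency matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import RoiTimeSeriesSet

__all__ = [
    "FunctionalConnectome",
    "StructuralConnectome",
    "StreamlineCountSet",
    "build_correlation_matrix",
    "directed_connection_probabilities",
    "symmetrize_connection_matrix",
]


def _validate_square_symmetric(matrix: np.ndarray, what: str) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{what} must be square, got shape {matrix.shape}")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError(f"{what} must be symmetric")
    if np.any(np.diag(matrix) != 0.0):
        raise ValueError(f"{what} must have a zero diagonal")
    return matrix


def _default_labels(n: int, labels: list[str] | None) -> list[str]:
    if labels is None:
        return [f"region_{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise ValueError(f"{n} regions but {len(labels)} labels")
    return list(labels)


@dataclass
class FunctionalConnectome:
    """Region x region Pearson correlation matrix, zero diagonal."""

    matrix: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = _validate_square_symmetric(self.matrix, "correlation matrix")
        if np.any(np.abs(self.matrix) > 1.0 + 1e-12):
            raise ValueError("correlation values must lie in [-1, 1]")
        self.region_labels = _default_labels(self.matrix.shape[0], self.region_labels)


@dataclass
class StructuralConnectome:
    """Region x region undirected connection probabilities, zero diagonal."""

    matrix: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = _validate_square_symmetric(self.matrix, "connection matrix")
        if np.any(self.matrix < 0.0) or np.any(self.matrix > 1.0):
            raise ValueError("connection probabilities must lie in [0, 1]")
        self.region_labels = _default_labels(self.matrix.shape[0], self.region_labels)


@dataclass
class StreamlineCountSet:
    """Raw tractography tallies: streamlines from each seed region to each target.

    ``counts[i, j]`` is the number of streamlines seeded in region *i* that
    reached region *j*; ``voxels_per_region[i] * samples_per_voxel`` is the
    number of streamlines launched from region *i*.
    """

    counts: np.ndarray
    voxels_per_region: np.ndarray
    samples_per_voxel: int = 5000
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.voxels_per_region = np.asarray(self.voxels_per_region)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"counts must be square, got shape {self.counts.shape}")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValueError("streamline counts must be non-negative integers")
        if self.voxels_per_region.shape != (self.counts.shape[0],):
            raise ValueError("voxels_per_region must have one entry per region")
        if np.any(self.voxels_per_region < 1):
            raise ValueError("every region must contain at least one voxel")
        if self.samples_per_voxel < 1:
            raise ValueError("samples_per_voxel must be a positive integer")
        launched = self.voxels_per_region[:, None] * self.samples_per_voxel
        if np.any(self.counts > launched):
            raise ValueError("counts exceed the number of streamlines launched")
        self.region_labels = _default_labels(self.counts.shape[0], self.region_labels)


def build_correlation_matrix(ts: RoiTimeSeriesSet) -> FunctionalConnectome:
    """Zero-lagged Pearson correlation between all region pairs, zero diagonal."""
    data = ts.data
    if data.shape[0] < 3:
        raise ValueError("at least 3 time points are required for a correlation matrix")
    constant = np.flatnonzero(np.ptp(data, axis=0) == 0.0)
    if constant.size:
        names = [ts.region_labels[i] for i in constant]
        raise ValueError(f"constant time series for region(s): {names}")
    corr = np.corrcoef(data, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 0.0)
    return FunctionalConnectome(corr, list(ts.region_labels))


def directed_connection_probabilities(sc: StreamlineCountSet) -> np.ndarray:
    """Seed->target probability: counts[i, j] / (voxels_i * samples_per_voxel)."""
    launched = sc.voxels_per_region.astype(float) * sc.samples_per_voxel
    probs = sc.counts.astype(float) / launched[:, None]
    np.fill_diagonal(probs, 0.0)
    return probs


def symmetrize_connection_matrix(
    directed: np.ndarray, region_labels: list[str] | None = None
) -> StructuralConnectome:
    """Undirected probability: the average of the two directed probabilities."""
    directed = np.asarray(directed, dtype=float)
    if directed.ndim != 2 or directed.shape[0] != directed.shape[1]:
        raise ValueError(f"directed matrix must be square, got shape {directed.shape}")
    if np.any(directed < 0.0) or np.any(directed > 1.0):
        raise ValueError("directed probabilities must lie in [0, 1]")
    undirected = (directed + directed.T) / 2.0
    np.fill_diagonal(undirected, 0.0)
    return StructuralConnectome(undirected, region_labels)
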