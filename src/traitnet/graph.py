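"""Weighted network metrics on unthresholded connectomes.

Six measures on a symmetric weighted graph with zero diagonal:

* nodal strength            s_i = sum_j w_ij
* characteristic path length L   = mean of shortest-path distances d_ij,
                                   with edge length 1/w_ij
* global efficiency         E    = mean of 1/d_ij (0 for disconnected pairs)
* nodal clustering          C_i  = sum_{j,m} (w_ij w_im w_jm)^(1/3) / (k_i (k_i - 1))
* global clustering         C    = mean_i C_i
* local efficiency          E_i  = (1/2) sum_{j,m in N(i), j != m}
                                   (w_ij w_im / d_jm(N_i))^(1/3) / (k_i (k_i - 1))

where d_jm(N_i) is the shortest path between neighbours j and m restricted to
node i's neighbourhood subgraph.  Because functional correlations can be
negative while the distance transform 1/w requires non-negative weights, a
:class:`WeightPolicy` makes every such choice explicit: how negatives are
resolved, whether the degree k_i in the clustering denominators is the binary
neighbour count (the convention of the usual connectivity toolboxes) or the
weighted degree (the definition as commonly printed), and whether weights are
rescaled by their maximum before the clustering-family measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "WeightedGraph",
    "WeightPolicy",
    "PreparedWeights",
    "DistanceMatrix",
    "prepare_weights",
    "nodal_strength",
    "shortest_path_distances",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_clustering",
    "global_clustering",
    "local_efficiency",
    "compute_metric_table",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
]

GLOBAL_METRICS = ("characteristic_path_length", "global_clustering", "global_efficiency")
NODAL_METRICS = ("strength", "clustering", "local_efficiency")


@dataclass
class WeightedGraph:
    """Symmetric N x N weighted adjacency with zero diagonal, N >= 2."""

    weights: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {w.shape}")
        if w.shape[0] < 2:
            raise ValueError("a graph needs at least 2 nodes")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.node_labels is None:
            self.node_labels = [f"node_{i + 1}" for i in range(w.shape[0])]
        elif len(self.node_labels) != w.shape[0]:
            raise ValueError("node_labels length does not match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class WeightPolicy:
    """Resolution of everything the unthresholded-weights convention leaves open."""

    negative_mode: Literal["absolute", "clip_to_zero", "keep"] = "absolute"
    normalize_for_clustering: bool = True
    degree_mode: Literal["binary", "weighted"] = "binary"

    def __post_init__(self) -> None:
        if self.negative_mode not in ("absolute", "clip_to_zero", "keep"):
            raise ValueError(f"unknown negative_mode {self.negative_mode!r}")
        if self.degree_mode not in ("binary", "weighted"):
            raise ValueError(f"unknown degree_mode {self.degree_mode!r}")


@dataclass
class PreparedWeights:
    """Policy-resolved weights plus the companion copy used for clustering."""

    graph: WeightedGraph
    clustering_weights: np.ndarray
    policy: WeightPolicy


@dataclass
class DistanceMatrix:
    """All-pairs shortest-path lengths; ``inf`` marks disconnected pairs."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        self.distances = d

    @property
    def n_nodes(self) -> int:
        return self.distances.shape[0]


def prepare_weights(g: WeightedGraph, policy: WeightPolicy | None = None) -> PreparedWeights:
    """Apply the negative-weight rule and build the clustering companion copy.

    The companion is the policy-resolved matrix divided by its maximum
    off-diagonal magnitude when ``normalize_for_clustering`` is on, so the
    clustering-family measures are scale-free per subject.
    """
    policy = policy or WeightPolicy()
    w = g.weights.copy()
    if policy.negative_mode == "absolute":
        w = np.abs(w)
    elif policy.negative_mode == "clip_to_zero":
        w = np.maximum(w, 0.0)
    max_off = np.max(np.abs(w))
    if max_off == 0.0:
        raise ValueError("all off-diagonal weights are zero after applying the policy")
    cw = w / max_off if policy.normalize_for_clustering else w.copy()
    return PreparedWeights(WeightedGraph(w, list(g.node_labels)), cw, policy)


def nodal_strength(g: WeightedGraph) -> np.ndarray:
    """Strength s_i: the sum of the edge weights incident to node i."""
    return g.weights.sum(axis=1)


def shortest_path_distances(g: WeightedGraph) -> DistanceMatrix:
    """All-pairs shortest paths with edge length the reciprocal of the weight.

    Zero weight means "no edge"; disconnected pairs get ``inf``.  Negative
    weights are rejected — resolve them first with a :class:`WeightPolicy`
    via :func:`prepare_weights`.
    """
    w = g.weights
    if np.any(w < 0.0):
        raise ValueError(
            "negative weights have no distance interpretation; apply "
            "prepare_weights with a WeightPolicy (absolute or clip_to_zero) first"
        )
    lengths = np.zeros_like(w)
    nz = w > 0.0
    lengths[nz] = 1.0 / w[nz]
    # dense csgraph input: zero entries are interpreted as absent edges
    dist = _csgraph_shortest_path(lengths, method="D", directed=False)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(dist)


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def characteristic_path_length(
    d: DistanceMatrix, infinite: Literal["exclude", "strict"] = "exclude"
) -> float:
    """Mean shortest-path distance over all ordered node pairs.

    Disconnected pairs: ``strict`` raises, ``exclude`` (default) averages the
    finite pairs and emits a warning — on unthresholded connectomes
    disconnection is rare but possible in structural data.
    """
    off = d.distances[_offdiag_mask(d.n_nodes)]
    infinite_pairs = np.isinf(off)
    if infinite_pairs.any():
        if infinite == "strict":
            raise ValueError(
                f"{int(infinite_pairs.sum())} disconnected node pairs; "
                "characteristic path length is undefined under the strict policy"
            )
        warnings.warn(
            f"excluding {int(infinite_pairs.sum())} disconnected pairs from "
            "the characteristic path length",
            RuntimeWarning,
            stacklevel=2,
        )
        off = off[~infinite_pairs]
        if off.size == 0:
            raise ValueError("no finite node pairs: the graph is fully disconnected")
    return float(off.mean())


def global_efficiency(d: DistanceMatrix) -> float:
    """Mean reciprocal shortest-path distance; disconnected pairs contribute 0."""
    off = d.distances[_offdiag_mask(d.n_nodes)]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(off), 0.0, 1.0 / np.where(off > 0, off, np.inf))
    return float(inv.mean())


def _degrees(cw: np.ndarray, policy: WeightPolicy) -> np.ndarray:
    if policy.degree_mode == "binary":
        return (cw != 0.0).sum(axis=1).astype(float)
    return cw.sum(axis=1)


def nodal_clustering(g: WeightedGraph, policy: WeightPolicy | None = None) -> np.ndarray:
    """Weighted clustering coefficient of every node.

    Geometric-mean triangle intensity around node i, normalized by
    k_i (k_i - 1).  Nodes with fewer than two neighbours (binary degree mode)
    or a degenerate denominator (weighted mode) are assigned zero.
    """
    prepared = prepare_weights(g, policy)
    cw = prepared.clustering_weights
    cr = np.cbrt(cw)  # signed cube root: negative triangles stay negative
    cyc3 = np.diagonal(cr @ cr @ cr)  # sum over ordered pairs (j, m)
    k = _degrees(cw, prepared.policy)
    denom = k * (k - 1.0)
    out = np.zeros(g.n_nodes)
    ok = denom > 1e-12
    out[ok] = cyc3[ok] / denom[ok]
    return out


def global_clustering(nodal: np.ndarray) -> float:
    """Arithmetic mean of the nodal clustering coefficients."""
    nodal = np.asarray(nodal, dtype=float)
    if nodal.size == 0:
        raise ValueError("cannot average an empty clustering vector")
    return float(nodal.mean())


def local_efficiency(g: WeightedGraph, policy: WeightPolicy | None = None) -> np.ndarray:
    """Efficiency of each node's neighbourhood subgraph.

    For node i with neighbours N(i), shortest paths d_jm(N_i) are computed on
    the subgraph induced by N(i) (edge length = reciprocal weight), and

        E_i = (1/2) sum_{j != m in N(i)} (w_ij w_im / d_jm(N_i))^(1/3)
              / (k_i (k_i - 1)).

    Nodes with fewer than two neighbours score zero.
    """
    prepared = prepare_weights(g, policy)
    cw = prepared.clustering_weights
    if np.any(cw < 0.0):
        raise ValueError(
            "negative weights reached local_efficiency; use a WeightPolicy "
            "with negative_mode 'absolute' or 'clip_to_zero'"
        )
    n = g.n_nodes
    k = _degrees(cw, prepared.policy)
    out = np.zeros(n)
    for i in range(n):
        neigh = np.flatnonzero(cw[i] > 0.0)
        if neigh.size < 2:
            continue
        sub = cw[np.ix_(neigh, neigh)]
        lengths = np.zeros_like(sub)
        nz = sub > 0.0
        lengths[nz] = 1.0 / sub[nz]
        d_sub = _csgraph_shortest_path(lengths, method="D", directed=False)
        np.fill_diagonal(d_sub, np.inf)  # exclude j == m
        with np.errstate(divide="ignore"):
            dinv = np.where(np.isinf(d_sub), 0.0, 1.0 / d_sub)
        sw = cw[i, neigh]
        triple = np.cbrt(np.outer(sw, sw) * dinv)
        denom = k[i] * (k[i] - 1.0)
        if denom <= 1e-12:
            continue
        out[i] = 0.5 * triple.sum() / denom
    return out


def compute_metric_table(
    graphs: dict[str, WeightedGraph] | list[WeightedGraph],
    policy: WeightPolicy | None = None,
    infinite: Literal["exclude", "strict"] = "exclude",
    scopes: tuple[str, ...] = ("global", "nodal"),
) -> pd.DataFrame:
    """All six measures for a set of subjects, in tidy long format.

    Returns columns ``subject, scope, metric, region, value`` with global
    rows (L, C, E_glob; region = NA) and nodal rows (strength, clustering,
    local efficiency; one row per region).  Restricting ``scopes`` to
    ``("global",)`` skips the nodal sweep (local efficiency in particular
    costs one shortest-path problem per node).
    """
    if isinstance(graphs, list):
        graphs = {f"sub-{i + 1:02d}": g for i, g in enumerate(graphs)}
    unknown = set(scopes) - {"global", "nodal"}
    if unknown:
        raise ValueError(f"unknown scope(s) {sorted(unknown)}")
    policy = policy or WeightPolicy()
    records: list[dict] = []
    for subject, g in graphs.items():
        prepared = prepare_weights(g, policy)
        pg = prepared.graph
        d = shortest_path_distances(pg)
        nodal_c = nodal_clustering(g, policy)
        if "global" in scopes:
            values_global = {
                "characteristic_path_length": characteristic_path_length(d, infinite),
                "global_clustering": global_clustering(nodal_c),
                "global_efficiency": global_efficiency(d),
            }
            for metric, value in values_global.items():
                records.append(
                    {"subject": subject, "scope": "global", "metric": metric,
                     "region": pd.NA, "value": value}
                )
        if "nodal" in scopes:
            values_nodal = {
                "strength": nodal_strength(pg),
                "clustering": nodal_c,
                "local_efficiency": local_efficiency(g, policy),
            }
            for metric, vec in values_nodal.items():
                for label, value in zip(g.node_labels, vec):
                    records.append(
                        {"subject": subject, "scope": "nodal", "metric": metric,
                         "region": label, "value": float(value)}
                    )
    return pd.DataFrame.from_records(records)
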