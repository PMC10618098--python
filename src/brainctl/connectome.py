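"""Weighted structural brain networks and their linear dynamics.

A structural network is a symmetric, non-negative, zero-diagonal weighted
adjacency matrix over labeled parcels (edge weights play the role of
diffusion-derived connection strengths such as quantitative anisotropy).
The network is turned into a stable continuous-time linear system

    x'(t) = A x(t) + B u(t),    A = W / (lambda_max(W) + c) - I,

so that the largest eigenvalue of ``A`` is ``-c / (lambda_max(W) + c) < 0``
and free dynamics decay toward the origin. Degree-preserving rewired null
networks provide a topological reference against which control-energy
results can be compared.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SYM_ATOL = 1e-10

__all__ = [
    "StructuralNetwork",
    "DynamicsMatrix",
    "load_network",
    "save_network",
    "group_average",
    "normalize_dynamics",
    "rewire_null",
]


@dataclass(frozen=True)
class StructuralNetwork:
    """Symmetric weighted connectome over labeled parcels.

    Parameters
    ----------
    labels : tuple of str
        Ordered, unique parcel identifiers; this order is canonical for all
        downstream vectors.
    weights : ndarray of shape (n, n)
        Symmetric, non-negative connection strengths with zero diagonal.
    """

    labels: tuple
    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weights must be square, got shape {W.shape}")
        n = W.shape[0]
        if len(labels) != n:
            raise ValueError(f"{len(labels)} labels for {n}x{n} weight matrix")
        if len(set(labels)) != n:
            raise ValueError("duplicate parcel labels")
        if not np.all(np.isfinite(W)):
            bad = np.argwhere(~np.isfinite(W))[0]
            raise ValueError(f"non-finite weight at ({bad[0]}, {bad[1]})")
        if np.any(W < 0):
            bad = np.argwhere(W < 0)[0]
            raise ValueError(f"negative weight at ({bad[0]}, {bad[1]})")
        asym = np.abs(W - W.T)
        if asym.max(initial=0.0) > _SYM_ATOL:
            i, j = np.unravel_index(np.argmax(asym), W.shape)
            raise ValueError(
                f"asymmetric weights: W[{i},{j}]={W[i, j]!r} != W[{j},{i}]={W[j, i]!r}"
            )
        if np.any(np.diag(W) != 0):
            i = int(np.flatnonzero(np.diag(W))[0])
            raise ValueError(f"nonzero diagonal at node {i} ({labels[i]})")
        W = W.copy()
        W.flags.writeable = False
        object.__setattr__(self, "weights", W)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class DynamicsMatrix:
    """Stabilized system matrix ``A`` with its normalization record."""

    A: np.ndarray = field(repr=False)
    c: float = 1.0
    source_lambda_max: float = 0.0

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got shape {A.shape}")
        A = A.copy()
        A.flags.writeable = False
        object.__setattr__(self, "A", A)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


def load_network(path, fmt: str = "matrix_tsv") -> StructuralNetwork:
    """Read a structural network from a TSV matrix or an edge list.

    ``matrix_tsv``: first row is the tab-separated parcel labels, each
    subsequent row is a label followed by ``n`` floats.  ``edge_list``:
    header ``source<TAB>target<TAB>weight``; the graph is undirected, so a
    pair given twice must carry the same weight.
    """
    if fmt == "matrix_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[0] != df.shape[1]:
            raise ValueError(
                f"{path}: non-square matrix ({df.shape[0]} rows x {df.shape[1]} columns)"
            )
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError(f"{path}: row labels do not match column labels")
        return StructuralNetwork(tuple(df.columns.astype(str)), df.to_numpy(float))
    if fmt == "edge_list":
        df = pd.read_csv(path, sep="\t")
        required = {"source", "target", "weight"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: edge list needs columns {sorted(required)}")
        labels = sorted(set(df["source"].astype(str)) | set(df["target"].astype(str)))
        idx = {l: i for i, l in enumerate(labels)}
        W = np.zeros((len(labels), len(labels)))
        seen: dict = {}
        for s, t, w in df[["source", "target", "weight"]].itertuples(index=False):
            s, t, w = str(s), str(t), float(w)
            key = (min(s, t), max(s, t))
            if key in seen and seen[key] != w:
                raise ValueError(
                    f"{path}: conflicting duplicate edge {key}: {seen[key]} vs {w}"
                )
            seen[key] = w
            W[idx[s], idx[t]] = w
            W[idx[t], idx[s]] = w
        return StructuralNetwork(tuple(labels), W)
    raise ValueError(f"unknown format {fmt!r}")


def save_network(network: StructuralNetwork, path) -> None:
    """Write the matrix-TSV dialect (labels header, 12 significant digits)."""
    df = pd.DataFrame(network.weights, index=network.labels, columns=network.labels)
    df.to_csv(path, sep="\t", float_format="%.12g")


def group_average(networks) -> StructuralNetwork:
    """Element-wise mean of connectomes sharing one label order."""
    networks = list(networks)
    if not networks:
        raise ValueError("need at least one network to average")
    ref = networks[0].labels
    for k, net in enumerate(networks[1:], start=1):
        if net.labels != ref:
            pos = next(
                i for i, (a, b) in enumerate(zip(ref, net.labels)) if a != b
            ) if len(net.labels) == len(ref) else min(len(ref), len(net.labels))
            raise ValueError(
                f"network {k} label mismatch at position {pos}"
            )
    mean = np.mean([net.weights for net in networks], axis=0)
    return StructuralNetwork(ref, mean)


def normalize_dynamics(network: StructuralNetwork, c: float = 1.0) -> DynamicsMatrix:
    """Map weights to the stable system matrix A = W/(lambda_max + c) - I.

    ``c > 0`` sets the decay margin: the slowest mode of ``A`` has rate
    ``-c / (lambda_max(W) + c)``.
    """
    if c <= 0:
        raise ValueError(f"stabilization constant c must be > 0, got {c}")
    W = network.weights
    lam_max = float(np.linalg.eigvalsh(W)[-1]) if W.size else 0.0
    A = W / (lam_max + c) - np.eye(network.n_nodes)
    return DynamicsMatrix(A=A, c=float(c), source_lambda_max=lam_max)


def rewire_null(
    network: StructuralNetwork,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
    preserve: str = "degree",
) -> StructuralNetwork:
    """Topological null: degree-preserving double-edge swaps, weights reshuffled.

    The binary topology is rewired with ``n_swaps_per_edge * n_edges``
    double-edge swaps (degree sequence preserved exactly), then the original
    weight multiset is reassigned to the surviving edges.  With
    ``preserve="strength"`` weights are instead assigned greedily so that
    high-weight edges attach to high-degree nodes, approximately preserving
    the strength sequence as well.
    """
    if n_swaps_per_edge < 0:
        raise ValueError("n_swaps_per_edge must be >= 0")
    if n_swaps_per_edge == 0:
        return network
    rng = np.random.default_rng(seed)
    W = network.weights
    iu = np.triu_indices(network.n_nodes, k=1)
    edge_mask = W[iu] > 0
    weights_multiset = W[iu][edge_mask]
    n_edges = int(edge_mask.sum())
    if n_edges < 2:
        raise ValueError("need at least 2 edges to swap")
    G = nx.from_numpy_array((W > 0).astype(int))
    try:
        nx.double_edge_swap(
            G,
            nswap=n_swaps_per_edge * n_edges,
            max_tries=100 * n_swaps_per_edge * n_edges,
            seed=int(rng.integers(2**31)),
        )
    except nx.NetworkXAlgorithmError as exc:  # disjoint-edge shortage
        raise ValueError(f"too few disjoint edges to swap: {exc}") from exc
    edges = sorted(G.edges())
    Wnull = np.zeros_like(W)
    if preserve == "degree":
        assigned = rng.permutation(weights_multiset)
    elif preserve == "strength":
        # attach large weights to edges whose endpoints have large degree
        deg = dict(G.degree())
        score = np.array([deg[a] + deg[b] for a, b in edges], dtype=float)
        order = np.argsort(-score, kind="stable")
        assigned = np.empty_like(weights_multiset)
        assigned[order] = np.sort(weights_multiset)[::-1]
    else:
        raise ValueError(f"unknown preserve mode {preserve!r}")
    for (a, b), w in zip(edges, assigned):
        Wnull[a, b] = w
        Wnull[b, a] = w
    null = StructuralNetwork(network.labels, Wnull)
    if not nx.is_connected(G):
        msg = "rewired null network is disconnected"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
    return null
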