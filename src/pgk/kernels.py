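"""Graph kernels over perceptual trait graphs.

The central object is the interaction embedding Phi(G): the 15 edge
weights of a trait graph read off in the canonical pair order, with
zeros at pruned coordinates (optionally extended by the 6 node
intensities).  Because every graph shares the same node set, Phi places
all graphs in one fixed-dimensional space, and the perceptual graph
kernel is simply

    PGK(G_i, G_j) = exp(-||Phi(G_i) - Phi(G_j)||^2 / (2 sigma^2))   (rbf)
    PGK(G_i, G_j) = <Phi(G_i), Phi(G_j)>                            (linear)

Both are Mercer kernels: the linear form is an explicit inner product
and the rbf form is a Gaussian on a finite-dimensional embedding, so
every Gram matrix is symmetric positive semi-definite, as is the
normalised kernel K_ij / sqrt(K_ii K_jj).

Two classical baselines are provided on the same graphs: the
Weisfeiler-Lehman subtree kernel on the perceptual state labels and the
pruned topology, and a shortest-path kernel on binned weighted
distances.  Both are explicit feature-count inner products and hence
also PSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse.csgraph import floyd_warshall
from scipy.spatial.distance import pdist

from .graphs import CANONICAL_PAIRS, PerceptualTraitGraph

__all__ = [
    "InteractionVector",
    "KernelMatrix",
    "embed",
    "embedding_matrix",
    "pgk_pair",
    "median_sigma",
    "gram_matrix",
    "pgk_cross",
    "wl_kernel",
    "sp_kernel",
    "check_psd",
]


@dataclass
class InteractionVector:
    """Phi(G): edge weights in canonical pair order (+ intensities if
    augmented)."""

    owner_id: str
    coordinates: np.ndarray
    augmented: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)


def embed(graph: PerceptualTraitGraph, augmented: bool = False) -> InteractionVector:
    """Extract the interaction vector of a graph.

    Coordinates follow the canonical pair enumeration (LC-LA, LC-TU,
    ..., ES-WI); pruned pairs contribute exactly 0.  In augmented mode
    the 6 node intensities are appended.
    """
    index = {c: i for i, c in enumerate(graph.traits)}
    pairs = tuple((a, b) for a, b in CANONICAL_PAIRS)
    for a, b in graph.edges:
        if a not in index or b not in index:
            raise ValueError(f"unknown trait code in edge ({a}, {b})")
    coords = np.array([graph.edges.get(p, 0.0) for p in pairs])
    if augmented:
        coords = np.concatenate([coords, graph.intensities])
    return InteractionVector(owner_id=graph.owner_id, coordinates=coords, augmented=augmented)


def embedding_matrix(
    graphs: Sequence[PerceptualTraitGraph], augmented: bool = False
) -> np.ndarray:
    """Stack interaction vectors into an (n_graphs, dim) matrix."""
    return np.stack([embed(g, augmented=augmented).coordinates for g in graphs])


def pgk_pair(
    a: InteractionVector | np.ndarray,
    b: InteractionVector | np.ndarray,
    sigma: float = 1.0,
    variant: str = "rbf",
) -> float:
    """PGK similarity between two interaction vectors."""
    va = a.coordinates if isinstance(a, InteractionVector) else np.asarray(a, dtype=float)
    vb = b.coordinates if isinstance(b, InteractionVector) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError(f"embedding shapes differ: {va.shape} vs {vb.shape}")
    if variant == "rbf":
        if sigma <= 0:
            raise ValueError(f"sigma must be > 0 for the rbf variant, got {sigma}")
        d2 = float(np.sum((va - vb) ** 2))
        return float(np.exp(-d2 / (2.0 * sigma**2)))
    if variant == "linear":
        return float(va @ vb)
    raise ValueError(f"unknown PGK variant {variant!r}")


def median_sigma(embeddings: np.ndarray) -> float:
    """Median heuristic: median pairwise ||Phi_i - Phi_j|| over a cohort.

    Falls back to 1.0 when the median is zero (all embeddings equal).
    """
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(embeddings)))
    return med if med > 0 else 1.0


def _rbf_matrix(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * sigma**2))


@dataclass
class KernelMatrix:
    """Symmetric similarity matrix with its PSD certificate."""

    values: np.ndarray
    owner_ids: tuple[str, ...]
    spec: dict
    smallest_eigenvalue: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def normalised(self) -> "KernelMatrix":
        """K_ij / sqrt(K_ii K_jj); rows with zero self-similarity stay 0."""
        d = np.diag(self.values).copy()
        scale = np.sqrt(np.where(d > 0, d, 1.0))
        K = self.values / np.outer(scale, scale)
        K[d == 0, :] = 0.0
        K[:, d == 0] = 0.0
        spec = dict(self.spec, normalised=True)
        return KernelMatrix(
            values=K,
            owner_ids=self.owner_ids,
            spec=spec,
            smallest_eigenvalue=float(np.linalg.eigvalsh((K + K.T) / 2)[0]),
        )

    def save(self, path) -> None:
        """Write the matrix as delimited text with an owner-ID header."""
        import pandas as pd

        pd.DataFrame(self.values, index=self.owner_ids, columns=self.owner_ids).to_csv(path)


def _finish(K: np.ndarray, owners: Sequence[str], spec: dict) -> KernelMatrix:
    K = (K + K.T) / 2.0  # remove float asymmetry from BLAS order
    lam = float(np.linalg.eigvalsh(K)[0]) if K.size else 0.0
    return KernelMatrix(
        values=K, owner_ids=tuple(owners), spec=spec, smallest_eigenvalue=lam
    )


def gram_matrix(
    graphs: Sequence[PerceptualTraitGraph],
    variant: str = "rbf",
    sigma: float | str = "median",
    augmented: bool = False,
    normalised: bool = False,
) -> KernelMatrix:
    """PGK Gram matrix over a collection of graphs.

    ``sigma`` may be a positive float or ``"median"`` for the median
    heuristic over this collection (rbf variant only).
    """
    if not graphs:
        raise ValueError("need at least one graph")
    traits = graphs[0].traits
    if any(g.traits != traits for g in graphs):
        raise ValueError("all graphs must share the same trait set")
    X = embedding_matrix(graphs, augmented=augmented)
    owners = [g.owner_id for g in graphs]
    if variant == "rbf":
        sig = median_sigma(X) if sigma == "median" else float(sigma)
        if sig <= 0:
            raise ValueError(f"sigma must be > 0, got {sig}")
        K = _rbf_matrix(X, X, sig)
        spec = {"type": "pgk", "variant": "rbf", "sigma": sig, "augmented": augmented}
    elif variant == "linear":
        K = X @ X.T
        spec = {"type": "pgk", "variant": "linear", "augmented": augmented}
    else:
        raise ValueError(f"unknown PGK variant {variant!r}")
    km = _finish(K, owners, spec)
    return km.normalised() if normalised else km


def pgk_cross(
    X: np.ndarray, Y: np.ndarray, sigma: float = 1.0, variant: str = "rbf"
) -> np.ndarray:
    """Rectangular PGK kernel between two embedding matrices."""
    if variant == "rbf":
        if sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {sigma}")
        return _rbf_matrix(np.atleast_2d(X), np.atleast_2d(Y), sigma)
    if variant == "linear":
        return np.atleast_2d(X) @ np.atleast_2d(Y).T
    raise ValueError(f"unknown PGK variant {variant!r}")


# ---------------------------------------------------------------------------
# Weisfeiler-Lehman subtree kernel


def _wl_feature_maps(
    labels_list: Sequence[Sequence[str]],
    adjacency_list: Sequence[Sequence[Sequence[int]]],
    h: int,
) -> list[dict]:
    """WL refinement over a set of labelled graphs.

    ``labels_list[g][v]`` is the initial label of node v in graph g;
    ``adjacency_list[g][v]`` its neighbour indices.  Returns one sparse
    feature counter per graph, counting compressed labels from all
    iterations 0..h under a shared compression dictionary.
    """
    if h < 0:
        raise ValueError(f"WL iteration count must be >= 0, got {h}")
    n_graphs = len(labels_list)
    # shared label compression across graphs, per iteration
    features: list[dict] = [dict() for _ in range(n_graphs)]
    current = [list(labels) for labels in labels_list]
    compress: dict = {}

    def code_of(key) -> int:
        if key not in compress:
            compress[key] = len(compress)
        return compress[key]

    for it in range(h + 1):
        if it > 0:
            new = []
            for g in range(n_graphs):
                labels = current[g]
                adj = adjacency_list[g]
                new.append(
                    [
                        code_of((labels[v], tuple(sorted(labels[u] for u in adj[v]))))
                        for v in range(len(labels))
                    ]
                )
            current = new
        for g in range(n_graphs):
            for lab in current[g]:
                key = (it, lab)
                features[g][key] = features[g].get(key, 0) + 1
    return features


def _feature_gram(features: Sequence[dict]) -> np.ndarray:
    n = len(features)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            small, big = (features[i], features[j])
            if len(small) > len(big):
                small, big = big, small
            v = sum(c * big.get(k, 0) for k, c in small.items())
            K[i, j] = K[j, i] = v
    return K


def _graph_adjacency(g: PerceptualTraitGraph) -> list[list[int]]:
    index = {c: i for i, c in enumerate(g.traits)}
    adj: list[list[int]] = [[] for _ in g.traits]
    for a, b in g.edges:
        adj[index[a]].append(index[b])
        adj[index[b]].append(index[a])
    return adj


def wl_kernel(
    graphs: Sequence[PerceptualTraitGraph],
    h: int = 2,
    normalised: bool = False,
) -> KernelMatrix:
    """Weisfeiler-Lehman subtree kernel on perceptual state labels.

    Runs on the pruned topology: on an unpruned complete graph every
    node sees every other node, neighbourhood multisets coincide up to
    the centre label, and WL adds nothing over the plain state-label
    histogram.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    labels = [list(g.states) for g in graphs]
    adjacency = [_graph_adjacency(g) for g in graphs]
    features = _wl_feature_maps(labels, adjacency, h)
    K = _feature_gram(features)
    km = _finish(K, [g.owner_id for g in graphs], {"type": "wl", "h": h})
    return km.normalised() if normalised else km


# ---------------------------------------------------------------------------
# Shortest-path kernel


def _sp_features(
    labels: Sequence[str],
    weighted_edges: Iterable[tuple[int, int, float]],
    bin_width: float,
) -> dict:
    """Counts of (unordered endpoint-label pair, distance bin) over all
    reachable node pairs, distances by Floyd-Warshall on edge weights."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    n = len(labels)
    W = np.full((n, n), np.inf)
    np.fill_diagonal(W, 0.0)
    for i, j, w in weighted_edges:
        W[i, j] = W[j, i] = min(W[i, j], w)
    D = floyd_warshall(W)
    feats: dict = {}
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isfinite(D[i, j]):
                continue
            pair = tuple(sorted((labels[i], labels[j])))
            key = (pair, int(np.floor(D[i, j] / bin_width + 1e-12)))
            feats[key] = feats.get(key, 0) + 1
    return feats


def sp_kernel(
    graphs: Sequence[PerceptualTraitGraph],
    bin_width: float = 0.1,
    normalised: bool = False,
) -> KernelMatrix:
    """Shortest-path kernel: inner product of binned labelled-distance
    counts; unreachable pairs are skipped."""
    if not graphs:
        raise ValueError("need at least one graph")
    features = []
    for g in graphs:
        index = {c: i for i, c in enumerate(g.traits)}
        edges = [(index[a], index[b], w) for (a, b), w in g.edges.items()]
        features.append(_sp_features(list(g.states), edges, bin_width))
    K = _feature_gram(features)
    km = _finish(
        K, [g.owner_id for g in graphs], {"type": "sp", "bin_width": bin_width}
    )
    return km.normalised() if normalised else km


# ---------------------------------------------------------------------------


def check_psd(
    matrix: KernelMatrix | np.ndarray, tolerance: float = 1e-8
) -> tuple[float, bool]:
    """Smallest eigenvalue of a symmetric kernel matrix and the PSD
    verdict (eigenvalue >= -tolerance)."""
    K = matrix.values if isinstance(matrix, KernelMatrix) else np.asarray(matrix, float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"kernel matrix must be square, got shape {K.shape}")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kernel matrix is asymmetric beyond 1e-10")
    lam = float(np.linalg.eigvalsh((K + K.T) / 2)[0])
    return lam, lam >= -tolerance
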