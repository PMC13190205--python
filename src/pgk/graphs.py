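"""Perceptual trait interaction graphs.

A graph has one node per trait, carrying the perceptual intensity and
state, and undirected edges between trait pairs.  In the default
*deviation* mode the edge weight is the perceptual deviation

    w_ij = |p_i - p_j|

computed on the complete graph and then pruned: edges with w_ij < epsilon
are dropped.  Large deviations mark trait pairs thrown out of balance by
stress (e.g. wilting rising while greenness falls), so stressed plants
produce denser, heavier graphs.

An alternative *correlation* mode wires edges by absolute Pearson
correlation of trait pairs over a training cohort, a construction closer
to classical trait-trait correlation networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .encoding import (
    DEFAULT_THRESHOLDS,
    TRAIT_CODES,
    PerceptualTraitVector,
    discretize,
)

__all__ = [
    "CANONICAL_PAIRS",
    "DEFAULT_EPSILON",
    "PerceptualTraitGraph",
    "CorrelationTemplate",
    "build_deviation_graph",
    "fit_correlation_template",
    "build_correlation_graph",
    "write_graph",
    "read_graph",
]

#: Canonical enumeration of the 15 unordered trait pairs; fixes the
#: coordinate order of the interaction embedding.
CANONICAL_PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(TRAIT_CODES, 2))

#: Default pruning threshold.
DEFAULT_EPSILON: float = 0.05


class GraphFormatError(ValueError):
    """Raised when a serialised graph file cannot be parsed."""


@dataclass
class PerceptualTraitGraph:
    """Undirected trait graph with intensities, states and edge weights.

    ``edges`` maps canonical (code_i, code_j) pairs to non-negative
    weights; pruned pairs are absent (not stored as zero weights).
    """

    owner_id: str
    traits: tuple[str, ...]
    intensities: np.ndarray
    states: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    epsilon: float
    mode: str = "deviation"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, a: str, b: str) -> float:
        """Edge weight between traits a and b; 0.0 if the edge is pruned."""
        key = (a, b) if self.traits.index(a) < self.traits.index(b) else (b, a)
        return self.edges.get(key, 0.0)

    def intensity(self, code: str) -> float:
        return float(self.intensities[self.traits.index(code)])

    def state(self, code: str) -> str:
        return self.states[self.traits.index(code)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(owner_id=self.owner_id, epsilon=self.epsilon, mode=self.mode)
        for i, code in enumerate(self.traits):
            g.add_node(
                code,
                code=code,
                intensity=float(self.intensities[i]),
                state=self.states[i],
                order=i,
            )
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=float(w))
        return g

    def equals(self, other: "PerceptualTraitGraph", tol: float = 1e-12) -> bool:
        return (
            self.owner_id == other.owner_id
            and self.traits == other.traits
            and self.states == other.states
            and self.mode == other.mode
            and abs(self.epsilon - other.epsilon) <= tol
            and np.allclose(self.intensities, other.intensities, atol=tol)
            and set(self.edges) == set(other.edges)
            and all(abs(self.edges[k] - other.edges[k]) <= tol for k in self.edges)
        )


def build_deviation_graph(
    vector: PerceptualTraitVector,
    epsilon: float = DEFAULT_EPSILON,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> PerceptualTraitGraph:
    """Build the deviation-weighted graph of one plant or zone.

    All pairwise deviations |p_i - p_j| are computed on the complete
    graph; edges with weight < epsilon are pruned.  epsilon = 0
    reproduces the fully connected graph.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    p = vector.intensities
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("perceptual intensities must lie in [0, 1]")
    traits = vector.traits
    states = discretize(vector, thresholds).states
    edges: dict[tuple[str, str], float] = {}
    for i, j in combinations(range(len(traits)), 2):
        w = abs(float(p[i]) - float(p[j]))
        if w >= epsilon:
            edges[(traits[i], traits[j])] = w
    return PerceptualTraitGraph(
        owner_id=vector.owner_id,
        traits=traits,
        intensities=p.copy(),
        states=states,
        edges=edges,
        epsilon=float(epsilon),
        mode="deviation",
    )


@dataclass
class CorrelationTemplate:
    """Cohort-level edge template: |Pearson r| per retained trait pair."""

    traits: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    r_min: float
    n: int
    use_pvalue: bool = False
    alpha: float = 0.05


def fit_correlation_template(
    vectors: Sequence[PerceptualTraitVector],
    r_min: float = 0.3,
    use_pvalue: bool = False,
    alpha: float = 0.05,
) -> CorrelationTemplate:
    """Estimate the correlation edge template over a training cohort.

    Keeps pairs with |r| >= r_min (weight |r|); with ``use_pvalue`` the
    screen is a two-sided test at level ``alpha`` instead.  Pairs where
    either trait has zero variance are excluded outright.
    """
    vectors = list(vectors)
    if len(vectors) < 3:
        raise ValueError(
            f"need at least 3 training vectors to estimate correlations, got {len(vectors)}"
        )
    traits = vectors[0].traits
    mat = np.stack([v.intensities for v in vectors])
    edges: dict[tuple[str, str], float] = {}
    for i, j in combinations(range(len(traits)), 2):
        xi, xj = mat[:, i], mat[:, j]
        if np.std(xi) == 0 or np.std(xj) == 0:
            continue
        r, p = stats.pearsonr(xi, xj)
        keep = (p <= alpha) if use_pvalue else (abs(r) >= r_min)
        if keep:
            edges[(traits[i], traits[j])] = abs(float(r))
    return CorrelationTemplate(
        traits=traits,
        edges=edges,
        r_min=r_min,
        n=len(vectors),
        use_pvalue=use_pvalue,
        alpha=alpha,
    )


def build_correlation_graph(
    vector: PerceptualTraitVector,
    template: CorrelationTemplate,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> PerceptualTraitGraph:
    """Attach a plant's intensities/states to the cohort edge template."""
    if vector.traits != template.traits:
        raise ValueError("vector and template trait sets differ")
    states = discretize(vector, thresholds).states
    return PerceptualTraitGraph(
        owner_id=vector.owner_id,
        traits=vector.traits,
        intensities=vector.intensities.copy(),
        states=states,
        edges=dict(template.edges),
        epsilon=template.r_min,
        mode="correlation",
    )


# ---------------------------------------------------------------------------
# Serialisation: GraphML (via networkx) and a JSON dialect.


def write_graph(graph: PerceptualTraitGraph, path: str | Path) -> None:
    """Write a graph to ``path``; format chosen by extension
    (.graphml or .json)."""
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(graph.to_networkx(), path)
    elif path.suffix == ".json":
        payload = {
            "owner_id": graph.owner_id,
            "epsilon": graph.epsilon,
            "mode": graph.mode,
            "traits": list(graph.traits),
            "nodes": [
                {
                    "code": code,
                    "intensity": float(graph.intensities[i]),
                    "state": graph.states[i],
                }
                for i, code in enumerate(graph.traits)
            ],
            "edges": [
                {"source": a, "target": b, "weight": w}
                for (a, b), w in graph.edges.items()
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unsupported graph format: {path.suffix!r}")


def _from_networkx(g: nx.Graph) -> PerceptualTraitGraph:
    try:
        owner = g.graph["owner_id"]
        epsilon = float(g.graph["epsilon"])
        mode = g.graph["mode"]
    except KeyError as e:
        raise GraphFormatError(f"graph file is missing graph attribute {e}") from e
    nodes = sorted(g.nodes(data=True), key=lambda kv: kv[1].get("order", 0))
    traits = tuple(d["code"] for _, d in nodes)
    intensities = np.array([float(d["intensity"]) for _, d in nodes])
    states = tuple(d["state"] for _, d in nodes)
    index = {c: i for i, c in enumerate(traits)}
    edges: dict[tuple[str, str], float] = {}
    for a, b, d in g.edges(data=True):
        key = (a, b) if index[a] < index[b] else (b, a)
        edges[key] = float(d["weight"])
    return PerceptualTraitGraph(
        owner_id=owner,
        traits=traits,
        intensities=intensities,
        states=states,
        edges=edges,
        epsilon=epsilon,
        mode=mode,
    )


def read_graph(path: str | Path) -> PerceptualTraitGraph:
    """Read a graph written by :func:`write_graph`."""
    path = Path(path)
    if path.suffix == ".graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as e:  # malformed XML or missing attributes
            raise GraphFormatError(f"cannot parse GraphML file {path}: {e}") from e
        return _from_networkx(g)
    if path.suffix == ".json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise GraphFormatError(
                f"cannot parse JSON graph {path}: line {e.lineno}, column {e.colno}: {e.msg}"
            ) from e
        try:
            traits = tuple(payload["traits"])
            by_code = {n["code"]: n for n in payload["nodes"]}
            for code in traits:
                if code not in by_code:
                    raise GraphFormatError(
                        f"graph file {path} is missing the node entry for trait {code!r}"
                    )
            intensities = np.array([float(by_code[c]["intensity"]) for c in traits])
            states = tuple(by_code[c]["state"] for c in traits)
            index = {c: i for i, c in enumerate(traits)}
            edges: dict[tuple[str, str], float] = {}
            for e in payload["edges"]:
                a, b = e["source"], e["target"]
                key = (a, b) if index[a] < index[b] else (b, a)
                edges[key] = float(e["weight"])
            return PerceptualTraitGraph(
                owner_id=payload["owner_id"],
                traits=traits,
                intensities=intensities,
                states=states,
                edges=edges,
                epsilon=float(payload["epsilon"]),
                mode=payload["mode"],
            )
        except KeyError as e:
            raise GraphFormatError(f"graph file {path} is missing field {e}") from e
    raise ValueError(f"unsupported graph format: {path.suffix!r}")
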