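"""Epsilon-network clustering and partition comparison.

Stimulus conditions are vertices of a graph with an edge whenever their
Euclidean feature distance is <= epsilon; clusters are connected components,
so two conditions farther than epsilon apart still share a cluster when an
intermediate condition links them. Non-responders are removed before graph
construction and form a designated non-responder cluster.

Two partitions are compared by the misclustering rate: the fraction of
elements left unmatched under the one-to-one cluster alignment that
maximizes total overlap (an assignment problem on the overlap-count matrix).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform


@dataclass(frozen=True)
class Partition:
    """Cluster assignment of labeled elements.

    ``clusters`` is a tuple of frozensets of element labels; at most one of
    them may be designated the non-responder cluster via its index.
    """

    elements: tuple[str, ...]
    clusters: tuple[frozenset[str], ...]
    nonresponder_cluster: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("clusters must be non-empty")
            if c & seen:
                raise ValueError(f"elements {sorted(c & seen)} appear in two clusters")
            seen |= c
        if seen != set(self.elements):
            raise ValueError("clusters must cover exactly the element set")
        if self.nonresponder_cluster is not None and not (
            0 <= self.nonresponder_cluster < len(self.clusters)
        ):
            raise ValueError("nonresponder_cluster index out of range")

    @classmethod
    def from_lists(
        cls,
        clusters: Sequence[Sequence[str]],
        nonresponder_cluster: int | None = None,
    ) -> "Partition":
        elems = tuple(e for c in clusters for e in c)
        return cls(
            elements=elems,
            clusters=tuple(frozenset(c) for c in clusters),
            nonresponder_cluster=nonresponder_cluster,
        )

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def responder_clusters(self) -> tuple[frozenset[str], ...]:
        return tuple(
            c for i, c in enumerate(self.clusters) if i != self.nonresponder_cluster
        )

    @property
    def nonresponders(self) -> frozenset[str]:
        if self.nonresponder_cluster is None:
            return frozenset()
        return self.clusters[self.nonresponder_cluster]

    def labels(self) -> dict[str, int]:
        """Element -> cluster-index map."""
        return {e: i for i, c in enumerate(self.clusters) for e in c}

    def to_json_dict(self) -> dict:
        return {
            "elements": list(self.elements),
            "clusters": [sorted(c) for c in self.clusters],
            "nonresponder_cluster": self.nonresponder_cluster,
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "Partition":
        return cls(
            elements=tuple(d["elements"]),
            clusters=tuple(frozenset(c) for c in d["clusters"]),
            nonresponder_cluster=d.get("nonresponder_cluster"),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "Partition":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass
class EpsilonCalibration:
    space: str
    epsilon: float
    grid: np.ndarray
    mean_mr_curve: np.ndarray
    per_regime_mr: dict[str, float] = field(default_factory=dict)

    @property
    def mean_mr(self) -> float:
        return float(np.mean(list(self.per_regime_mr.values())))

    def to_json_dict(self) -> dict:
        return {
            "space": self.space,
            "epsilon": self.epsilon,
            "grid": list(map(float, self.grid)),
            "mean_mr_curve": list(map(float, self.mean_mr_curve)),
            "per_regime_mr": self.per_regime_mr,
            "mean_mr": self.mean_mr,
        }


def pairwise_distances(features: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix between feature rows."""
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    return squareform(pdist(features, metric="euclidean"))


def epsilon_cluster(
    distances: np.ndarray,
    eps: float,
    labels: Sequence[str],
    nonresponders: Iterable[str] = (),
) -> Partition:
    """Connected components of the distance-threshold graph (d <= eps).

    Non-responder elements are removed before graph construction and appended
    as the designated non-responder cluster.
    """
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    distances = np.asarray(distances, dtype=float)
    labels = list(labels)
    nonresp = set(nonresponders)
    responders = [i for i, lab in enumerate(labels) if lab not in nonresp]

    graph = nx.Graph()
    graph.add_nodes_from(responders)
    for a_pos, i in enumerate(responders):
        for j in responders[a_pos + 1:]:
            if distances[i, j] <= eps:
                graph.add_edge(i, j)
    comps = [frozenset(labels[i] for i in comp)
             for comp in nx.connected_components(graph)]
    comps.sort(key=lambda c: min(labels.index(e) for e in c))

    nonresp_idx = None
    if nonresp:
        comps.append(frozenset(nonresp))
        nonresp_idx = len(comps) - 1
    return Partition(
        elements=tuple(labels),
        clusters=tuple(comps),
        nonresponder_cluster=nonresp_idx,
    )


def misclustering_rate(a: Partition, b: Partition) -> float:
    """Fraction of elements mismatched under the best one-to-one cluster
    alignment (maximum total overlap, Hungarian assignment)."""
    if set(a.elements) != set(b.elements):
        raise ValueError("partitions must cover the same element set")
    n = a.n_elements
    overlap = np.zeros((len(a.clusters), len(b.clusters)))
    for i, ca in enumerate(a.clusters):
        for j, cb in enumerate(b.clusters):
            overlap[i, j] = len(ca & cb)
    row, col = linear_sum_assignment(-overlap)
    matched = overlap[row, col].sum()
    return float((n - matched) / n)


def optimize_epsilon(
    feature_sets: Mapping[str, np.ndarray],
    expert: Mapping[str, Partition],
    eps_grid: Sequence[float] | None = None,
    labels: Sequence[str] | None = None,
    nonresponders: Mapping[str, Iterable[str]] | None = None,
    space: str = "codon",
) -> EpsilonCalibration:
    """Grid-search the epsilon minimizing mean MR against expert partitions.

    MR is averaged jointly over all calibration regimes at each candidate
    epsilon; ties resolve to the smallest epsilon. When no grid is given,
    200 log-spaced values between the 1st and 99th percentile of observed
    pairwise distances are used.
    """
    if not feature_sets:
        raise ValueError("at least one calibration regime is required")
    if set(feature_sets) != set(expert):
        raise ValueError("feature_sets and expert partitions must share regime ids")

    dist = {rid: pairwise_distances(f) for rid, f in feature_sets.items()}
    if eps_grid is None:
        pooled = np.concatenate(
            [d[np.triu_indices_from(d, k=1)] for d in dist.values()]
        )
        pooled = pooled[pooled > 0]
        lo, hi = np.percentile(pooled, [1, 99])
        eps_grid = np.geomspace(max(lo, 1e-12), hi, 200)
    eps_grid = np.asarray(list(eps_grid), dtype=float)
    if eps_grid.size == 0:
        raise ValueError("epsilon grid must be non-empty")
    if np.any(np.diff(eps_grid) <= 0):
        raise ValueError("epsilon grid must be strictly increasing")

    nonresponders = nonresponders or {}
    mr_curve = np.empty((eps_grid.size, len(feature_sets)))
    rids = sorted(feature_sets)
    for e_idx, eps in enumerate(eps_grid):
        for r_idx, rid in enumerate(rids):
            labs = labels if labels is not None else expert[rid].elements
            part = epsilon_cluster(
                dist[rid], eps, labs, nonresponders.get(rid, ())
            )
            mr_curve[e_idx, r_idx] = misclustering_rate(part, expert[rid])
    mean_curve = mr_curve.mean(axis=1)
    best = int(np.argmin(mean_curve))  # argmin takes the first = smallest eps
    eps_opt = float(eps_grid[best])
    per_regime = {rid: float(mr_curve[best, r_idx]) for r_idx, rid in enumerate(rids)}
    return EpsilonCalibration(
        space=space,
        epsilon=eps_opt,
        grid=eps_grid,
        mean_mr_curve=mean_curve,
        per_regime_mr=per_regime,
    )
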