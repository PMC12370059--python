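"""Specificity (SRS), confusion (SRC), and inhibition (INH) scores.

Given the cluster partition of the 15 stimulus conditions under one drug
regime: SRS is the number of responder clusters, SRC the size of the largest
responder cluster (0 when there are none), and INH the number of
non-responder conditions. The binary confusion matrix marks stimulus pairs
sharing a responder cluster; its diagonal carries the non-responder flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from tempocode.clustering import Partition, pairwise_distances


@dataclass(frozen=True)
class RegimeScorecard:
    regime_id: str
    srs: int
    src: int
    inh: int
    partition: Partition
    confusion: np.ndarray               # 15 x 15 binary, symmetric
    nonresponder_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        n = self.partition.n_elements
        sizes = [len(c) for c in self.partition.responder_clusters]
        if sum(sizes) + self.inh != n:
            raise ValueError("responder cluster sizes + INH must equal n")


def compute_scores(partition: Partition, regime_id: str = "") -> RegimeScorecard:
    """Scores plus the confusion matrix for one regime partition."""
    responders = partition.responder_clusters
    srs = len(responders)
    src = max((len(c) for c in responders), default=0)
    inh = len(partition.nonresponders)
    confusion, flags = confusion_matrix(partition)
    return RegimeScorecard(
        regime_id=regime_id or "regime",
        srs=srs,
        src=src,
        inh=inh,
        partition=partition,
        confusion=confusion,
        nonresponder_flags=flags,
    )


def confusion_matrix(partition: Partition) -> tuple[np.ndarray, tuple[bool, ...]]:
    """Binary co-clustering matrix over the partition's element order.

    Off-diagonal entries are 1 when the two stimuli share a responder
    cluster; the diagonal holds the non-responder flags (1 = inhibited).
    """
    order = list(partition.elements)
    n = len(order)
    idx = {e: i for i, e in enumerate(order)}
    mat = np.zeros((n, n), dtype=int)
    for cluster in partition.responder_clusters:
        members = sorted(idx[e] for e in cluster)
        for a_pos, i in enumerate(members):
            for j in members[a_pos + 1:]:
                mat[i, j] = mat[j, i] = 1
    flags = tuple(e in partition.nonresponders for e in order)
    mat[np.diag_indices(n)] = np.array(flags, dtype=int)
    return mat, flags


def tally_pairwise(scorecards: Sequence[RegimeScorecard]) -> np.ndarray:
    """Count, per stimulus pair, the regimes in which the pair is confused.

    A regime where both members of a pair are non-responders contributes
    nothing to that pair (its confusion entry is already 0 because confusion
    only marks responder co-clustering).
    """
    if not scorecards:
        return np.zeros((0, 0), dtype=int)
    order = scorecards[0].partition.elements
    n = len(order)
    tally = np.zeros((n, n), dtype=int)
    for card in scorecards:
        if card.partition.elements != order:
            raise ValueError("all scorecards must share the stimulus ordering")
        off = card.confusion.copy()
        off[np.diag_indices(n)] = 0
        tally += off
    return tally


def treated_vs_untreated(
    untreated: np.ndarray,
    treated: Mapping[str, np.ndarray],
    eps: float,
    untreated_nonresponders: Iterable[str] = (),
    treated_nonresponders: Mapping[str, Iterable[str]] | None = None,
    stimulus_order: Sequence[str] | None = None,
    nonresponder_reference: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate treated-vs-untreated confusion counts across regimes.

    For each regime, entry (treated row s, untreated column u) is 1 when both
    conditions respond and their feature distance is strictly below eps.
    Treated non-responders are not counted as responder confusion; they are
    tallied separately against the untreated non-responder reference column
    (by convention the untreated non-responding condition).

    Returns (confusion counts, non-responder flag counts), both 15 x 15.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    untreated = np.asarray(untreated, dtype=float)
    n = untreated.shape[0]
    order = list(stimulus_order) if stimulus_order is not None else [
        str(i) for i in range(n)
    ]
    u_nonresp = set(untreated_nonresponders)
    t_nonresp = treated_nonresponders or {}
    counts = np.zeros((n, n), dtype=int)
    flagged = np.zeros((n, n), dtype=int)
    ref_col = (
        order.index(nonresponder_reference)
        if nonresponder_reference is not None
        else None
    )
    for rid, feats in treated.items():
        feats = np.asarray(feats, dtype=float)
        if feats.shape != untreated.shape:
            raise ValueError(
                f"regime {rid!r}: treated features shape {feats.shape} does not "
                f"match untreated {untreated.shape}; check normalization bounds"
            )
        regime_nonresp = set(t_nonresp.get(rid, ()))
        both = np.vstack([feats, untreated])
        dist = pairwise_distances(both)[:n, n:]
        for s in range(n):
            if order[s] in regime_nonresp:
                if ref_col is not None:
                    flagged[s, ref_col] += 1
                continue
            for u in range(n):
                if order[u] in u_nonresp:
                    continue
                if dist[s, u] < eps:   # strict, unlike within-regime clustering
                    counts[s, u] += 1
    return counts, flagged
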