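"""Pairwise m-DAG distances and UPGMA clustering with Newick output.

The all-pairs distance matrix applies the similarity stack to every
unordered pair of organisms and converts scores with
``d = sqrt(1 - score**2)``.  UPGMA (average linkage) then agglomerates:
at every step the two clusters at minimal mean inter-cluster distance
merge, the merge height being that mean.  Inter-cluster means are
computed directly from the input matrix over all leaf pairs, which is
exactly the unweighted average-linkage definition; ties break on the
label-sorted cluster pair so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .mdag import ClassPartition, MDag, build_mdag, classify_mbbs
from .reaction_graph import ReactionGraph
from .similarity import SimilarityParams, identity_scorer, mdag_distance, sim_mdag

__all__ = ["DistanceMatrix", "Dendrogram", "distance_matrix", "upgma", "to_newick"]


@dataclass
class DistanceMatrix:
    """A labeled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(self.values < 0):
            raise ValidationError("negative distances")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")


def distance_matrix(
    graphs: Mapping[str, ReactionGraph],
    params: SimilarityParams = SimilarityParams(),
    scorer=identity_scorer,
    pivot_reaction: str | None = None,
) -> DistanceMatrix:
    """All-pairs m-DAG distances over a labeled set of organisms.

    Each organism's reaction graph is condensed to its m-DAG; pairwise
    similarities use the matching-based m-DAG score, restricted to pivot
    classes when ``pivot_reaction`` is given, and are converted to
    distances.  Each unordered pair is computed once.
    """
    labels = sorted(graphs)
    if len(labels) < 2:
        raise ValidationError("need at least two organisms")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate organism labels")

    mdags: dict[str, MDag] = {}
    classes: dict[str, ClassPartition] = {}
    for lab in labels:
        mdags[lab] = build_mdag(graphs[lab])
        if pivot_reaction is not None:
            classes[lab] = classify_mbbs(mdags[lab], pivot_reaction)

    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            pair_classes = (classes[a], classes[b]) if pivot_reaction is not None else None
            score = sim_mdag(
                mdags[a], mdags[b], graphs[a].nodes, graphs[b].nodes,
                params=params, scorer=scorer, classes=pair_classes,
            )
            values[i, j] = values[j, i] = mdag_distance(score)
    groups = {lab: graphs[lab].group for lab in labels if graphs[lab].group}
    return DistanceMatrix(labels=labels, values=values, groups=groups or None)


@dataclass
class Dendrogram:
    """UPGMA merge history.

    ``merge_steps`` follows the scipy linkage convention: clusters
    ``0..n-1`` are the leaves in ``leaf_labels`` order, and step ``t``
    merging clusters ``a`` and ``b`` creates cluster ``n + t``.  Heights
    are non-decreasing.
    """

    leaf_labels: list[str]
    merge_steps: list[tuple[int, int, float, int]]
    groups: dict[str, str] | None = None

    def to_linkage(self) -> np.ndarray:
        return np.array(
            [[a, b, h, size] for a, b, h, size in self.merge_steps], dtype=float
        )


def upgma(matrix: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering of a distance matrix."""
    labels = matrix.labels
    d = matrix.values
    n = len(labels)
    if n < 2:
        raise ValidationError("need at least two leaves")

    # Active clusters: cluster id -> sorted tuple of leaf indices.
    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}
    # Label-sorted key per cluster, for deterministic tie-breaking.
    def key(cid: int) -> tuple[str, ...]:
        return tuple(sorted(labels[i] for i in members[cid]))

    steps: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(members) > 1:
        best = None
        for a in members:
            for b in members:
                if a >= b:
                    continue
                mean = float(
                    np.mean([d[i, j] for i in members[a] for j in members[b]])
                )
                ka, kb = sorted((key(a), key(b)))
                cand = (mean, ka, kb, a, b)
                if best is None or cand < best:
                    best = cand
        mean, _, _, a, b = best
        size = len(members[a]) + len(members[b])
        steps.append((a, b, mean, size))
        members[next_id] = tuple(sorted(members.pop(a) + members.pop(b)))
        next_id += 1
    return Dendrogram(leaf_labels=list(labels), merge_steps=steps, groups=matrix.groups)


def to_newick(dendrogram: Dendrogram, with_groups: bool = False) -> str:
    """Render a dendrogram as a rooted Newick string.

    Branch lengths are height differences between a cluster and its
    parent merge; leaves sit at height 0.  With ``with_groups``, leaf
    labels get a ``|group`` suffix for post-hoc coloring.
    """
    n = len(dendrogram.leaf_labels)
    height: dict[int, float] = {i: 0.0 for i in range(n)}

    def leaf_name(i: int) -> str:
        name = dendrogram.leaf_labels[i]
        if with_groups and dendrogram.groups and name in dendrogram.groups:
            return f"{name}|{dendrogram.groups[name]}"
        return name

    rep: dict[int, str] = {i: leaf_name(i) for i in range(n)}
    cid = n
    for a, b, h, _size in dendrogram.merge_steps:
        la = f"{rep[a]}:{h - height[a]:.10g}"
        lb = f"{rep[b]}:{h - height[b]:.10g}"
        rep[cid] = f"({la},{lb})"
        height[cid] = h
        cid += 1
    return rep[cid - 1] + ";"
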