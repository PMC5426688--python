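"""The similarity stack: enzymes -> compounds -> reactions -> MBBs -> m-DAGs.

Every level above the enzyme one is a maximum-weight bipartite matching
normalized by the size of the larger side, so scores live in [0, 1] and
are symmetric:

* ``sim_enzyme`` — hierarchical EC-number similarity, (length of the
  common fully-specified prefix) / 4.  Wildcard levels match nothing.
* ``sim_compound_sets`` — best matching between two compound sets under
  a pluggable compound scorer (exact-token identity by default, or a
  precomputed chemical-structure similarity table).
* ``sim_react`` — weighted combination of the enzyme term and the
  substrate/product compound-set terms, weights 0.4 / 0.3 / 0.3.
* ``sim_mbb`` — best matching between the reaction instances of two
  building blocks.
* ``sim_mdag`` — best matching between the blocks of two m-DAGs,
  optionally restricted so only blocks in the same pivot class may match.

A similarity ``s`` converts to the distance ``sqrt(1 - s**2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .mdag import MBB, ClassPartition, MDag
from .reaction_graph import ECNumber, ReactionNode

__all__ = [
    "SimilarityParams",
    "identity_scorer",
    "sim_enzyme",
    "sim_compound_sets",
    "sim_react",
    "sim_mbb",
    "sim_mdag",
    "mdag_distance",
]

CompoundScorer = Callable[[str, str], float]


@dataclass(frozen=True)
class SimilarityParams:
    """Weights of the reaction-similarity combination.

    ``w_e`` weighs the enzyme term, ``w_i`` the substrate term and
    ``w_o`` the product term.  The defaults 0.4/0.3/0.3 balance enzyme
    function against chemistry; they must sum to 1 unless
    ``allow_unnormalized`` is set, since only then do all scores stay
    in [0, 1].
    """

    w_e: float = 0.4
    w_i: float = 0.3
    w_o: float = 0.3
    allow_unnormalized: bool = False

    def __post_init__(self) -> None:
        if min(self.w_e, self.w_i, self.w_o) < 0:
            raise ValidationError("similarity weights must be non-negative")
        if not self.allow_unnormalized and not math.isclose(
            self.w_e + self.w_i + self.w_o, 1.0, abs_tol=1e-9
        ):
            raise ValidationError(
                f"weights sum to {self.w_e + self.w_i + self.w_o}, not 1; "
                "set allow_unnormalized=True to override"
            )


def identity_scorer(a: str, b: str) -> float:
    """Exact-token compound similarity: 1 for the same compound, else 0."""
    return 1.0 if a == b else 0.0


def sim_enzyme(e1: ECNumber | str, e2: ECNumber | str) -> float:
    """Hierarchical EC similarity: common fully-specified prefix length / 4.

    Possible values are 0, 0.25, 0.5, 0.75 and 1.  A wildcard level
    matches nothing, so the unknown placeholder ``-.-.-.-`` scores 0
    against everything, itself included.
    """
    if isinstance(e1, str):
        e1 = ECNumber.parse(e1)
    if isinstance(e2, str):
        e2 = ECNumber.parse(e2)
    return e1.common_prefix_length(e2) / 4.0


def _matching_score(weights: np.ndarray) -> float:
    """Max-weight bipartite matching total / max side size.

    Unmatched elements of the larger side contribute 0.
    """
    rows, cols = linear_sum_assignment(weights, maximize=True)
    return float(weights[rows, cols].sum()) / max(weights.shape)


def sim_compound_sets(
    x: Iterable[str], y: Iterable[str], scorer: CompoundScorer = identity_scorer
) -> float:
    """Matching-based similarity of two compound sets."""
    xs, ys = sorted(set(x)), sorted(set(y))
    if not xs or not ys:
        raise ValidationError("compound sets must be non-empty")
    weights = np.array([[scorer(a, b) for b in ys] for a in xs], dtype=float)
    return _matching_score(weights)


def sim_react(
    r1: ReactionNode,
    r2: ReactionNode,
    params: SimilarityParams = SimilarityParams(),
    scorer: CompoundScorer = identity_scorer,
) -> float:
    """Reaction similarity: weighted enzyme + substrate + product terms.

    Inputs and outputs are the node's direction-resolved sets, so the
    backward instance of a reversible reaction compares with its
    substrate/product roles swapped.
    """
    return (
        params.w_e * sim_enzyme(r1.enzyme, r2.enzyme)
        + params.w_i * sim_compound_sets(r1.inputs, r2.inputs, scorer)
        + params.w_o * sim_compound_sets(r1.outputs, r2.outputs, scorer)
    )


def _matching_over(
    left: Sequence, right: Sequence, pair_score: Callable[[object, object], float]
) -> float:
    weights = np.array(
        [[pair_score(a, b) for b in right] for a in left], dtype=float
    )
    return _matching_score(weights)


def sim_mbb(
    m1,
    m2,
    params: SimilarityParams = SimilarityParams(),
    scorer: CompoundScorer = identity_scorer,
    nodes1=None,
    nodes2=None,
) -> float:
    """Building-block similarity: best matching of member reactions.

    Accepts plain sequences of
    :class:`~metadag.reaction_graph.ReactionNode`, or
    :class:`~metadag.mdag.MBB` objects together with ``nodes1``/``nodes2``
    node-key maps from the source reaction graphs.
    """
    left = _members(m1, nodes1)
    right = _members(m2, nodes2)
    if not left or not right:
        raise ValidationError("MBBs must be non-empty")
    return _matching_over(
        left, right, lambda a, b: sim_react(a, b, params=params, scorer=scorer)
    )


def _members(m, nodes=None) -> list[ReactionNode]:
    if isinstance(m, MBB):
        if nodes is None:
            raise ValidationError(
                "resolving an MBB's reactions needs the source graph's node map"
            )
        return _resolve_members(m, nodes)
    return sorted(m, key=lambda n: n.key)


def _resolve_members(mbb: MBB, nodes) -> list[ReactionNode]:
    return sorted((nodes[k] for k in mbb.member_nodes), key=lambda n: n.key)


def sim_mdag(
    d1: MDag,
    d2: MDag,
    nodes1,
    nodes2,
    params: SimilarityParams = SimilarityParams(),
    scorer: CompoundScorer = identity_scorer,
    classes: tuple[ClassPartition, ClassPartition] | None = None,
) -> float:
    """m-DAG similarity: best matching of building blocks.

    ``nodes1``/``nodes2`` map node keys to :class:`ReactionNode` (the
    source graphs' node dictionaries).  With ``classes`` given, blocks in
    different pivot classes get weight 0 before matching — the
    class-restricted comparison used around a conserved pivot reaction.
    """
    if not d1.mbbs or not d2.mbbs:
        raise ValidationError("m-DAGs must be non-empty")
    if classes is not None:
        c1, c2 = classes
        if c1.pivot_reaction != c2.pivot_reaction:
            raise ValidationError(
                f"class partitions have different pivots: "
                f"{c1.pivot_reaction!r} vs {c2.pivot_reaction!r}"
            )

    left = d1.sorted_mbbs()
    right = d2.sorted_mbbs()
    members1 = {id(m): _resolve_members(m, nodes1) for m in left}
    members2 = {id(m): _resolve_members(m, nodes2) for m in right}

    def block_score(a: MBB, b: MBB) -> float:
        if classes is not None and classes[0].class_of[a] != classes[1].class_of[b]:
            return 0.0
        return _matching_over(
            members1[id(a)],
            members2[id(b)],
            lambda x, y: sim_react(x, y, params=params, scorer=scorer),
        )

    return _matching_over(left, right, block_score)


def mdag_distance(score: float) -> float:
    """Convert a similarity in [0, 1] into the distance sqrt(1 - score**2).

    Identical m-DAGs (score 1) are at distance 0 and maximally dissimilar
    ones (score 0) at distance 1; the map is strictly decreasing.
    """
    if not -1e-9 <= score <= 1 + 1e-9:
        raise ValidationError(f"similarity {score} outside [0, 1]")
    score = min(1.0, max(0.0, score))
    return math.sqrt(1.0 - score * score)
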