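"""Pairwise similarity and distance measures on the classification tree.

Four structural measures quantify how far apart two diagnoses sit in the
ICD-style taxonomy:

``steps``
    Edge count of the shortest path between the two nodes (a distance;
    0 means identical codes).
``weights``
    Sum of level-dependent edge weights along that path, encoding that a
    cross-chapter confusion (e.g. a metabolic disease coded as a neoplasm)
    is graver than one within a chapter.
``wupalmer``
    Wu-Palmer similarity ``2*depth(lcs) / (depth(a) + depth(b))``: position
    of the pair relative to their least common subsumer, in [0, 1].
``lietal``
    Li et al. similarity ``exp(-alpha*l) * tanh(beta*h)`` where ``l`` is the
    shortest-path length and ``h`` the depth of the least common subsumer;
    a nonlinear blend tuned to human similarity judgements, in [0, 1).

Because the taxonomy is a tree, every shortest path decomposes exactly
through the least common subsumer, so all four measures are computed in
closed form from depths and the LCS — no graph search at scoring time.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .taxonomy import Level, Resolution, Taxonomy, TaxonomyError, TaxonomyNode

__all__ = [
    "Algorithm",
    "Orientation",
    "WeightScheme",
    "LiParameters",
    "SimilarityScore",
    "steps",
    "weights",
    "wupalmer",
    "lietal",
    "score_pair",
    "score_pairs",
    "DEFAULT_WEIGHTS",
    "DEFAULT_LI_PARAMETERS",
]

logger = logging.getLogger(__name__)


class Algorithm(enum.Enum):
    STEPS = "steps"
    WEIGHTS = "weights"
    WUPALMER = "wupalmer"
    LIETAL = "lietal"


class Orientation(enum.Enum):
    DISTANCE = "distance"  # larger value = more discrepant
    SIMILARITY = "similarity"  # larger value = more similar


ORIENTATION: dict[Algorithm, Orientation] = {
    Algorithm.STEPS: Orientation.DISTANCE,
    Algorithm.WEIGHTS: Orientation.DISTANCE,
    Algorithm.WUPALMER: Orientation.SIMILARITY,
    Algorithm.LIETAL: Orientation.SIMILARITY,
}


@dataclass(frozen=True)
class SimilarityScore:
    algorithm: Algorithm
    value: float

    @property
    def orientation(self) -> Orientation:
        return ORIENTATION[self.algorithm]


@dataclass(frozen=True)
class WeightScheme:
    """Positive weight per (parent level, child level) edge transition.

    The default doubles at every step up the hierarchy — crossing between
    chapters costs 8 per edge while distinguishing two four-digit codes
    under one category costs 1 — so confusions between remote branches
    accumulate much larger distances than local ones.
    """

    weight_per_transition: dict[tuple[Level, Level], float] = field(
        default_factory=lambda: {
            (Level.ROOT, Level.CHAPTER): 8.0,
            (Level.CHAPTER, Level.GROUP): 4.0,
            (Level.GROUP, Level.CATEGORY): 2.0,
            (Level.CATEGORY, Level.CODE): 1.0,
        }
    )

    def __post_init__(self) -> None:
        for transition, w in self.weight_per_transition.items():
            if not w > 0:
                raise TaxonomyError(
                    f"weight for transition {transition} must be positive, got {w}"
                )

    def edge_weight(self, parent: TaxonomyNode, child: TaxonomyNode) -> float:
        try:
            return self.weight_per_transition[(parent.level, child.level)]
        except KeyError:
            raise TaxonomyError(
                f"no weight configured for edge {parent.level.value} -> {child.level.value}"
            ) from None


DEFAULT_WEIGHTS = WeightScheme()


@dataclass(frozen=True)
class LiParameters:
    """Parameters of the Li et al. measure.

    ``alpha`` controls the exponential decay with path length, ``beta`` how
    quickly similarity saturates with subsumer depth.  Defaults are the
    optimal values reported by Li and colleagues for WordNet-style
    hierarchies (alpha=0.2, beta=0.6).
    """

    alpha: float = 0.2
    beta: float = 0.6

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise TaxonomyError(
                f"Li parameters must be positive, got alpha={self.alpha}, beta={self.beta}"
            )


DEFAULT_LI_PARAMETERS = LiParameters()


def _path_decomposition(
    taxonomy: Taxonomy, a: TaxonomyNode, b: TaxonomyNode
) -> tuple[TaxonomyNode, int, int, int]:
    """LCS plus depths (depth_a, depth_b, depth_lcs) for a node pair."""
    lcs = taxonomy.lca(a, b)
    return lcs, taxonomy.depth(a), taxonomy.depth(b), taxonomy.depth(lcs)


def steps(taxonomy: Taxonomy, a: TaxonomyNode, b: TaxonomyNode) -> SimilarityScore:
    """Shortest-path edge count between two nodes (distance orientation)."""
    _, da, db, dl = _path_decomposition(taxonomy, a, b)
    return SimilarityScore(Algorithm.STEPS, float(da + db - 2 * dl))


def weights(
    taxonomy: Taxonomy,
    a: TaxonomyNode,
    b: TaxonomyNode,
    scheme: WeightScheme = DEFAULT_WEIGHTS,
) -> SimilarityScore:
    """Weighted shortest-path length (distance orientation).

    Sums the scheme's transition weights over every edge of the path
    a -> LCS -> b.  With an all-ones scheme this reduces exactly to
    :func:`steps`.
    """
    lcs = taxonomy.lca(a, b)
    total = 0.0
    for end in (a, b):
        node = end
        while node.code != lcs.code:
            parent = taxonomy.parent(node)
            assert parent is not None
            total += scheme.edge_weight(parent, node)
            node = parent
    return SimilarityScore(Algorithm.WEIGHTS, total)


def wupalmer(taxonomy: Taxonomy, a: TaxonomyNode, b: TaxonomyNode) -> SimilarityScore:
    """Wu-Palmer similarity ``2*depth(lcs)/(depth(a)+depth(b))`` in [0, 1].

    Equals 1 only for identical non-root nodes and 0 whenever the only
    shared ancestor is the synthetic root (depth is counted in edges from
    the root, so the root itself contributes no shared depth).
    """
    _, da, db, dl = _path_decomposition(taxonomy, a, b)
    if da + db == 0:
        raise TaxonomyError("Wu-Palmer similarity undefined for the root with itself")
    return SimilarityScore(Algorithm.WUPALMER, 2.0 * dl / (da + db))


def lietal(
    taxonomy: Taxonomy,
    a: TaxonomyNode,
    b: TaxonomyNode,
    params: LiParameters = DEFAULT_LI_PARAMETERS,
) -> SimilarityScore:
    """Li et al. similarity ``exp(-alpha*l) * tanh(beta*h)`` in [0, 1).

    ``l`` is the steps distance and ``h`` the depth of the least common
    subsumer.  Note the formula does *not* special-case identity: two equal
    codes at depth h score ``tanh(beta*h)``, which approaches but never
    reaches 1.  The cited formula is kept as published rather than patched.
    """
    _, da, db, dl = _path_decomposition(taxonomy, a, b)
    length = da + db - 2 * dl
    value = math.exp(-params.alpha * length) * math.tanh(params.beta * dl)
    return SimilarityScore(Algorithm.LIETAL, value)


def score_pair(
    taxonomy: Taxonomy,
    a: TaxonomyNode,
    b: TaxonomyNode,
    algorithm: Algorithm,
    scheme: WeightScheme = DEFAULT_WEIGHTS,
    params: LiParameters = DEFAULT_LI_PARAMETERS,
) -> SimilarityScore:
    """Dispatch a single pair to one of the four measures."""
    if algorithm is Algorithm.STEPS:
        return steps(taxonomy, a, b)
    if algorithm is Algorithm.WEIGHTS:
        return weights(taxonomy, a, b, scheme)
    if algorithm is Algorithm.WUPALMER:
        return wupalmer(taxonomy, a, b)
    if algorithm is Algorithm.LIETAL:
        return lietal(taxonomy, a, b, params)
    raise TaxonomyError(f"unknown algorithm {algorithm!r}")


def score_pairs(
    taxonomy: Taxonomy,
    pairs: pd.DataFrame,
    algorithms: list[Algorithm] | None = None,
    scheme: WeightScheme = DEFAULT_WEIGHTS,
    params: LiParameters = DEFAULT_LI_PARAMETERS,
) -> pd.DataFrame:
    """Score a table of diagnosis pairs with one column per algorithm.

    Parameters
    ----------
    pairs
        DataFrame with columns ``pair_id``, ``code_a``, ``code_b`` and
        optionally ``label``; raw codes are resolved against the taxonomy
        (over-specific codes fall back to their nearest ancestor).
    algorithms
        Subset of measures to compute; all four by default.

    Returns
    -------
    DataFrame with the input columns plus ``resolution_a``, ``resolution_b``,
    ``resolved`` and one numeric column per algorithm (NaN on unresolved
    rows, which are flagged, logged and left in place — row order is
    preserved).
    """
    if pairs is None or len(pairs) == 0:
        raise TaxonomyError("no diagnosis pairs to score")
    missing = {"pair_id", "code_a", "code_b"} - set(pairs.columns)
    if missing:
        raise TaxonomyError(f"pair table is missing columns {sorted(missing)}")
    algorithms = algorithms or list(Algorithm)

    out = pairs.reset_index(drop=True).copy()
    res_a = [taxonomy.resolve(str(c)) for c in out["code_a"]]
    res_b = [taxonomy.resolve(str(c)) for c in out["code_b"]]
    out["resolution_a"] = [r.resolution.value for r in res_a]
    out["resolution_b"] = [r.resolution.value for r in res_b]
    out["resolved"] = [ra.ok and rb.ok for ra, rb in zip(res_a, res_b)]

    for alg in algorithms:
        values: list[float] = []
        for ra, rb, pid in zip(res_a, res_b, out["pair_id"]):
            if not (ra.ok and rb.ok):
                values.append(float("nan"))
                continue
            assert ra.node is not None and rb.node is not None
            values.append(score_pair(taxonomy, ra.node, rb.node, alg, scheme, params).value)
        out[alg.value] = values

    n_failed = int((~out["resolved"]).sum())
    if n_failed:
        bad = out.loc[~out["resolved"], "pair_id"].tolist()
        logger.warning("skipped %d unresolvable pair(s): %s", n_failed, bad)
    return out
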