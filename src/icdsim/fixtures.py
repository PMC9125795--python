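"""Synthetic taxonomies and rater-labeled diagnosis pairs.

Real validation data for a diagnostic-labelling-error trigger — pairs of
ICD-coded diagnoses with an expert similar/discrepant rating — are scarce
and usually not shareable.  This module generates stand-ins at toy scale:

* a regular four-level taxonomy (chapters -> groups -> categories ->
  four-digit codes under a synthetic root), with deterministic ICD-flavoured
  codes such as ``A00-A09``, ``A03``, ``A031``;
* labeled pairs sampled uniformly over leaf codes, whose similar/discrepant
  label is a *noisy monotone function of true taxonomic distance*: the
  probability that the raters call a pair discrepant follows a logistic
  curve in the steps distance, P(discrepant) = sigmoid(slope * (steps -
  midpoint)).  The slope is the signal-strength knob (0 = labels carry no
  signal, large = labels deterministically threshold the distance) and the
  midpoint sets where raters flip from similar to discrepant.

Everything is driven by a single integer seed; identical specs produce
byte-identical fixtures.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxonomy import Level, Taxonomy, TaxonomyError, TaxonomyNode, ROOT_CODE

__all__ = ["LabelModel", "FixtureSpec", "generate_taxonomy", "generate_labeled_pairs"]


@dataclass(frozen=True)
class LabelModel:
    """Logistic link between steps distance and the rater label.

    ``logistic_slope`` in 1/steps units; ``logistic_midpoint`` in steps
    units (the distance at which a pair is a coin flip for the raters).
    """

    logistic_slope: float = 1.5
    logistic_midpoint: float = 4.0
    noise_seed: int = 0


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of the synthetic taxonomy and pair sample."""

    n_chapters: int = 2
    groups_per_chapter: int = 4
    categories_per_group: int = 4
    codes_per_category: int = 4
    n_pairs: int = 500
    label_model: LabelModel = field(default_factory=LabelModel)

    def __post_init__(self) -> None:
        counts = (
            self.n_chapters,
            self.groups_per_chapter,
            self.categories_per_group,
            self.codes_per_category,
            self.n_pairs,
        )
        if any(c < 1 for c in counts):
            raise TaxonomyError("all fixture counts must be >= 1")
        if self.n_chapters > 26:
            raise TaxonomyError("at most 26 chapters (one letter each)")
        if self.groups_per_chapter * self.categories_per_group > 100:
            raise TaxonomyError("chapter exceeds the 00-99 category numbering space")
        if self.codes_per_category > 10:
            raise TaxonomyError("at most 10 four-digit codes per category")

    @property
    def n_nodes(self) -> int:
        c, g, k, d = (
            self.n_chapters,
            self.groups_per_chapter,
            self.categories_per_group,
            self.codes_per_category,
        )
        return 1 + c + c * g + c * g * k + c * g * k * d


def generate_taxonomy(spec: FixtureSpec) -> Taxonomy:
    """Regular four-level toy taxonomy with deterministic codes.

    Chapter ``i`` is the letter ``A``, ``B``, ...; its groups are numbered
    ranges (``A00-A09``), categories are three-character rubrics (``A03``)
    and leaves are four-digit codes (``A031``).  Node count is
    ``1 + c + c*g + c*g*k + c*g*k*d``.
    """
    nodes = [TaxonomyNode(ROOT_CODE, "synthetic root", Level.ROOT, None)]
    span = spec.categories_per_group  # categories per group share a numbered range
    for ci in range(spec.n_chapters):
        letter = string.ascii_uppercase[ci]
        nodes.append(
            TaxonomyNode(letter, f"chapter {letter}", Level.CHAPTER, ROOT_CODE)
        )
        for gi in range(spec.groups_per_chapter):
            lo = gi * span
            hi = lo + span - 1
            group = f"{letter}{lo:02d}-{letter}{hi:02d}"
            nodes.append(TaxonomyNode(group, f"group {group}", Level.GROUP, letter))
            for ki in range(span):
                cat = f"{letter}{lo + ki:02d}"
                nodes.append(TaxonomyNode(cat, f"category {cat}", Level.CATEGORY, group))
                for di in range(spec.codes_per_category):
                    code = f"{cat}.{di}"
                    nodes.append(TaxonomyNode(code, f"code {code}", Level.CODE, cat))
    tax = Taxonomy.from_nodes(nodes, version_tag="synthetic")
    assert len(tax) == spec.n_nodes
    return tax


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable for large |slope|*(steps-midpoint)
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def generate_labeled_pairs(taxonomy: Taxonomy, spec: FixtureSpec) -> pd.DataFrame:
    """Sample labeled diagnosis pairs from the leaf codes of a taxonomy.

    Both members of each pair are drawn uniformly (with replacement) over
    the leaves, so identical pairs occur; the reference label is Bernoulli
    with P(discrepant) = sigmoid(slope * (steps - midpoint)).  Deterministic
    given ``spec.label_model.noise_seed``.

    Returns a DataFrame with columns ``pair_id``, ``code_a``, ``code_b``,
    ``label`` and the latent ``true_steps`` used by the label model.
    """
    leaves = taxonomy.leaves()
    if len(leaves) < 2:
        raise TaxonomyError("need at least two leaf codes to sample pairs")
    rng = np.random.default_rng(spec.label_model.noise_seed)
    ia = rng.integers(0, len(leaves), size=spec.n_pairs)
    ib = rng.integers(0, len(leaves), size=spec.n_pairs)
    d = np.array(
        [
            taxonomy.depth(leaves[a]) + taxonomy.depth(leaves[b])
            - 2 * taxonomy.depth(taxonomy.lca(leaves[a], leaves[b]))
            for a, b in zip(ia, ib)
        ],
        dtype=float,
    )
    lm = spec.label_model
    p_disc = _sigmoid(lm.logistic_slope * (d - lm.logistic_midpoint))
    disc = rng.random(spec.n_pairs) < p_disc
    return pd.DataFrame(
        {
            "pair_id": [f"P{i:05d}" for i in range(spec.n_pairs)],
            "code_a": [leaves[a].code for a in ia],
            "code_b": [leaves[b].code for b in ib],
            "label": np.where(disc, "discrepant", "similar"),
            "true_steps": d,
        }
    )
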