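"""Shared fixtures: a hand-built toy ICD tree and random leveled trees.

The toy tree mirrors the real ICD shape at miniature scale — one synthetic
root, two chapters, three groups, four categories, six four-digit codes
(16 nodes, 15 edges) — and is used for all hand-derived expected values.
Random leveled trees back the oracle-equivalence property tests.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from icdsim.similarity import WeightScheme
from icdsim.taxonomy import Level, Taxonomy, TaxonomyNode, ROOT_CODE

TOY_ROWS = [
    # code, parent, level, label
    (ROOT_CODE, None, Level.ROOT, "root"),
    ("IV", ROOT_CODE, Level.CHAPTER, "metabolic diseases"),
    ("II", ROOT_CODE, Level.CHAPTER, "neoplasms"),
    ("E10-E14", "IV", Level.GROUP, "diabetes mellitus"),
    ("E15-E16", "IV", Level.GROUP, "other glucose disorders"),
    ("C15-C26", "II", Level.GROUP, "digestive neoplasms"),
    ("E10", "E10-E14", Level.CATEGORY, "type 1 diabetes"),
    ("E11", "E10-E14", Level.CATEGORY, "type 2 diabetes"),
    ("E15", "E15-E16", Level.CATEGORY, "hypoglycaemic coma"),
    ("C18", "C15-C26", Level.CATEGORY, "colon carcinoma"),
    ("E10.1", "E10", Level.CODE, "T1DM with ketoacidosis"),
    ("E10.9", "E10", Level.CODE, "T1DM without complications"),
    ("E11.0", "E11", Level.CODE, "T2DM with coma"),
    ("E15.0", "E15", Level.CODE, "drug-induced coma"),
    ("C18.1", "C18", Level.CODE, "appendix carcinoma"),
    ("C18.9", "C18", Level.CODE, "colon carcinoma unspec."),
]


def toy_nodes() -> list[TaxonomyNode]:
    return [TaxonomyNode(c, lbl, lv, p) for c, p, lv, lbl in TOY_ROWS]


@pytest.fixture(scope="session")
def toy_taxonomy() -> Taxonomy:
    return Taxonomy.from_nodes(toy_nodes(), version_tag="toy-v1")


@pytest.fixture(scope="session")
def doubling_scheme() -> WeightScheme:
    return WeightScheme(
        {
            (Level.ROOT, Level.CHAPTER): 8.0,
            (Level.CHAPTER, Level.GROUP): 4.0,
            (Level.GROUP, Level.CATEGORY): 2.0,
            (Level.CATEGORY, Level.CODE): 1.0,
        }
    )


_CHILD_LEVEL = {
    Level.ROOT: Level.CHAPTER,
    Level.CHAPTER: Level.GROUP,
    Level.GROUP: Level.CATEGORY,
    Level.CATEGORY: Level.CODE,
}


def random_taxonomy(rng: np.random.Generator, n_nodes: int) -> Taxonomy:
    """Random leveled tree: each node attaches below a random non-leaf-level
    node, so branches terminate early at random (categories without codes,
    chapters without groups, ...)."""
    nodes = [TaxonomyNode(ROOT_CODE, "", Level.ROOT, None)]
    eligible = [0]  # indices of nodes that may still take children
    for i in range(1, n_nodes):
        j = int(rng.integers(len(eligible)))
        parent = nodes[eligible[j]]
        level = _CHILD_LEVEL[parent.level]
        nodes.append(TaxonomyNode(f"N{i:04d}", "", level, parent.code))
        if level is not Level.CODE:
            eligible.append(i)
    return Taxonomy.from_nodes(nodes)


def to_networkx(tax: Taxonomy, scheme: WeightScheme | None = None) -> nx.Graph:
    """Undirected graph view for BFS/Dijkstra oracles."""
    g = nx.Graph()
    for node in tax:
        g.add_node(node.code)
        parent = tax.parent(node)
        if parent is not None:
            w = scheme.edge_weight(parent, node) if scheme else 1.0
            g.add_edge(parent.code, node.code, weight=w)
    return g
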