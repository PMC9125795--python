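"""The four similarity/distance measures: hand-derived values, oracle
equivalence against graph search, and structural properties."""

from __future__ import annotations

import math

import numpy as np
import networkx as nx
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icdsim.similarity import (
    Algorithm,
    LiParameters,
    Orientation,
    WeightScheme,
    lietal,
    score_pairs,
    steps,
    weights,
    wupalmer,
)
from icdsim.taxonomy import Level, TaxonomyError

from conftest import random_taxonomy, to_networkx


# ---------------------------------------------------------------------------
# hand-derived values on the toy tree
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("E10.1", "E10.1", 0),  # identity
        ("E10.1", "E10.9", 2),  # siblings under one category
        ("E10.1", "E11.0", 4),  # same group, different categories
        ("E10.1", "E15.0", 6),  # same chapter, different groups
        ("E10.1", "C18.9", 8),  # different chapters, full branches
    ],
)
def test_steps_hand_counted(toy_taxonomy, a, b, expected):
    got = steps(toy_taxonomy, toy_taxonomy.get(a), toy_taxonomy.get(b))
    assert got.value == expected
    assert got.orientation is Orientation.DISTANCE


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("E10.1", "E10.9", 2.0),  # two category->code edges at weight 1
        ("E10.1", "E11.0", 6.0),  # 1+2 up, 2+1 down
        ("E10.1", "E15.0", 14.0),  # 1+2+4 both sides
        ("E10.1", "C18.9", 30.0),  # 2*(1+2+4+8) through the root
    ],
)
def test_weights_hand_summed(toy_taxonomy, doubling_scheme, a, b, expected):
    got = weights(toy_taxonomy, toy_taxonomy.get(a), toy_taxonomy.get(b), doubling_scheme)
    assert got.value == expected


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("E10.1", "E10.1", 1.0),
        ("E10.1", "E10.9", 0.75),  # 2*3 / (4+4)
        ("E10.1", "E11.0", 0.5),  # 2*2 / (4+4)
        ("E10.1", "C18.9", 0.0),  # only shared ancestor is the root
    ],
)
def test_wupalmer_formula(toy_taxonomy, a, b, expected):
    got = wupalmer(toy_taxonomy, toy_taxonomy.get(a), toy_taxonomy.get(b))
    assert got.value == pytest.approx(expected)


def test_wupalmer_root_with_itself_undefined(toy_taxonomy):
    with pytest.raises(TaxonomyError):
        wupalmer(toy_taxonomy, toy_taxonomy.root, toy_taxonomy.root)


def test_lietal_closed_form(toy_taxonomy):
    t = toy_taxonomy
    params = LiParameters(alpha=0.2, beta=0.6)
    # siblings: path length 2, subsumer depth 3
    sib = lietal(t, t.get("E10.1"), t.get("E10.9"), params)
    assert sib.value == pytest.approx(math.exp(-0.4) * math.tanh(1.8), abs=1e-12)
    # identity: path length 0, subsumer depth 4 -- tanh(2.4), deliberately not 1
    same = lietal(t, t.get("E10.1"), t.get("E10.1"), params)
    assert same.value == pytest.approx(math.tanh(2.4), abs=1e-12)
    assert same.value < 1.0
    # root subsumer: zero regardless of path length
    far = lietal(t, t.get("E10.1"), t.get("C18.9"), params)
    assert far.value == 0.0


def test_lietal_rejects_nonpositive_parameters():
    with pytest.raises(TaxonomyError):
        LiParameters(alpha=0.0, beta=0.6)
    with pytest.raises(TaxonomyError):
        LiParameters(alpha=0.2, beta=-1.0)


def test_weight_scheme_rejects_nonpositive():
    with pytest.raises(TaxonomyError):
        WeightScheme({(Level.ROOT, Level.CHAPTER): 0.0})


# ---------------------------------------------------------------------------
# oracle equivalence on random trees (BFS for steps, Dijkstra for weights)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_steps_and_weights_match_graph_search(seed, doubling_scheme):
    rng = np.random.default_rng(seed)
    tax = random_taxonomy(rng, int(rng.integers(30, 200)))
    g1 = to_networkx(tax)
    gw = to_networkx(tax, doubling_scheme)
    nodes = list(tax)
    idx = rng.integers(0, len(nodes), size=(120, 2))  # >=500 pairs over all seeds
    for i, j in idx:
        a, b = nodes[int(i)], nodes[int(j)]
        assert steps(tax, a, b).value == nx.shortest_path_length(g1, a.code, b.code)
        assert weights(tax, a, b, doubling_scheme).value == pytest.approx(
            nx.dijkstra_path_length(gw, a.code, b.code)
        )


@pytest.mark.parametrize("seed", [10, 11])
def test_all_measures_symmetric(seed, doubling_scheme):
    rng = np.random.default_rng(seed)
    tax = random_taxonomy(rng, 80)
    nodes = list(tax)
    params = LiParameters()
    for _ in range(80):
        a = nodes[int(rng.integers(len(nodes)))]
        b = nodes[int(rng.integers(len(nodes)))]
        assert steps(tax, a, b).value == steps(tax, b, a).value
        assert weights(tax, a, b, doubling_scheme).value == weights(
            tax, b, a, doubling_scheme
        ).value
        if not (a.level is Level.ROOT and b.level is Level.ROOT):
            assert wupalmer(tax, a, b).value == wupalmer(tax, b, a).value
        assert lietal(tax, a, b, params).value == lietal(tax, b, a, params).value


def test_all_ones_weights_reduce_to_steps(toy_taxonomy):
    transitions = [
        (Level.ROOT, Level.CHAPTER),
        (Level.CHAPTER, Level.GROUP),
        (Level.GROUP, Level.CATEGORY),
        (Level.CATEGORY, Level.CODE),
    ]
    ones = WeightScheme({t: 1.0 for t in transitions})
    nodes = list(toy_taxonomy)
    for a in nodes:
        for b in nodes:
            assert weights(toy_taxonomy, a, b, ones).value == steps(
                toy_taxonomy, a, b
            ).value


# ---------------------------------------------------------------------------
# range and monotonicity properties
# ---------------------------------------------------------------------------

@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    length=st.integers(min_value=0, max_value=8),
    h=st.integers(min_value=0, max_value=4),
    alpha=st.floats(min_value=0.05, max_value=2.0),
    beta=st.floats(min_value=0.05, max_value=2.0),
)
def test_lietal_closed_form_range_and_decay(length, h, alpha, beta):
    """exp(-a*l)*tanh(b*h) stays in [0,1) and strictly decreases in l for h>0."""
    val = math.exp(-alpha * length) * math.tanh(beta * h)
    assert 0.0 <= val < 1.0
    longer = math.exp(-alpha * (length + 1)) * math.tanh(beta * h)
    if h > 0:
        assert longer < val
    else:
        assert longer == val == 0.0


def test_wupalmer_decreases_with_shallower_subsumer(toy_taxonomy):
    """For fixed depth(a)+depth(b)=8, similarity drops as the subsumer climbs."""
    t = toy_taxonomy
    chain = [
        ("E10.1", "E10.9"),  # lcs depth 3
        ("E10.1", "E11.0"),  # lcs depth 2
        ("E10.1", "E15.0"),  # lcs depth 1
        ("E10.1", "C18.9"),  # lcs depth 0
    ]
    vals = [wupalmer(t, t.get(a), t.get(b)).value for a, b in chain]
    assert vals == sorted(vals, reverse=True)
    assert len(set(vals)) == len(vals)


def test_score_ranges_on_random_tree():
    rng = np.random.default_rng(42)
    tax = random_taxonomy(rng, 150)
    nodes = [n for n in tax if n.level is not Level.ROOT]
    for _ in range(200):
        a = nodes[int(rng.integers(len(nodes)))]
        b = nodes[int(rng.integers(len(nodes)))]
        assert steps(tax, a, b).value >= 0
        assert 0.0 <= wupalmer(tax, a, b).value <= 1.0
        assert 0.0 <= lietal(tax, a, b).value < 1.0


# ---------------------------------------------------------------------------
# batch scoring
# ---------------------------------------------------------------------------

def test_score_pairs_shape_and_identity(toy_taxonomy):
    pairs = pd.DataFrame(
        {
            "pair_id": ["p1", "p2", "p3"],
            "code_a": ["E10.1", "E10.1", "E10.1"],
            "code_b": ["E10.1", "E10.9", "C18.9"],
        }
    )
    out = score_pairs(toy_taxonomy, pairs)
    assert list(out["pair_id"]) == ["p1", "p2", "p3"]  # order preserved
    assert {a.value for a in Algorithm} <= set(out.columns)
    ident = out.iloc[0]
    assert ident["steps"] == 0 and ident["weights"] == 0 and ident["wupalmer"] == 1.0


def test_score_pairs_flags_unresolvable_rows(toy_taxonomy):
    pairs = pd.DataFrame(
        {
            "pair_id": ["ok1", "bad", "ok2"],
            "code_a": ["E10.1", "Z99.9", "E11.0"],
            "code_b": ["E10.9", "E10.1", "C18.1"],
        }
    )
    out = score_pairs(toy_taxonomy, pairs)
    assert len(out) == 3
    assert list(out["resolved"]) == [True, False, True]
    assert np.isnan(out.loc[1, "steps"])
    assert out.loc[2, "steps"] == 8


def test_score_pairs_truncated_resolution_scored_at_ancestor(toy_taxonomy):
    pairs = pd.DataFrame(
        {"pair_id": ["t"], "code_a": ["E10.11"], "code_b": ["E10.9"]}
    )
    out = score_pairs(toy_taxonomy, pairs)
    assert out.loc[0, "resolution_a"] == "truncated_to_ancestor"
    assert out.loc[0, "steps"] == 2  # scored at E10.1


def test_score_pairs_empty_input_rejected(toy_taxonomy):
    with pytest.raises(TaxonomyError):
        score_pairs(toy_taxonomy, pd.DataFrame(columns=["pair_id", "code_a", "code_b"]))
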