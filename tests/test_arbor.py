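"""Arbor morphometry: branch decomposition, order assignment, ACI, looping."""

import numpy as np
import pytest

from axonkit import arbor, synthgen
from axonkit.arbor import (SWCError, decompose_branches, assign_branch_orders,
                           compute_aci, order_assignment_oracle,
                           cumulative_turning, classify_looping, read_swc,
                           write_swc, analyze_tree)
from conftest import tree_from_edges, random_binary_tree


def _metrics(tree):
    br = decompose_branches(tree)
    assign_branch_orders(br, tree)
    return br, compute_aci(br)


# ---------------------------------------------------------------------------
# SWC I/O


def test_swc_round_trip(tmp_path):
    tree = synthgen.generate_arbor(synthgen.ArborParams(), seed=0)
    p = tmp_path / "a.swc"
    write_swc(tree, p)
    back = read_swc(p)
    assert back.n_nodes() == tree.n_nodes()
    _, m1 = _metrics(tree)
    _, m2 = _metrics(back)
    assert m1.counts_per_order == m2.counts_per_order
    assert m1.total_branch_length_um == pytest.approx(m2.total_branch_length_um,
                                                      abs=1e-3)


@pytest.mark.parametrize("content,msg", [
    ("1 2 0 0 0 1 1\n", "own parent"),
    ("1 2 0 0 0 1 -1\n2 2 1 0 0 1 -1\n", "one root"),
    ("1 2 0 0 0 1 -1\n2 2 1 0 0 1 9\n", "dangling"),
    ("1 2 0 0 0 1\n", "7 fields"),
])
def test_swc_malformed_rejected(tmp_path, content, msg):
    p = tmp_path / "bad.swc"
    p.write_text(content)
    with pytest.raises(SWCError, match=msg):
        read_swc(p)


def test_unbranched_path_is_one_branch():
    tree = tree_from_edges([(i, 0.0) for i in range(10)],
                           [-1] + list(range(9)))
    br = decompose_branches(tree)
    assert len(br) == 1
    assign_branch_orders(br, tree)
    m = compute_aci(br)
    assert m.aci == 1.0
    assert m.counts_per_order == {1: 1}
    assert m.total_branch_length_um == pytest.approx(9.0)


# ---------------------------------------------------------------------------
# Decomposition


def test_single_bifurcation_gives_three_branches():
    #   root - stem - split into two tips
    coords = [(0, 0), (1, 0), (2, 0), (3, 1), (3, -1)]
    tree = tree_from_edges(coords, [-1, 0, 1, 2, 2])
    br = decompose_branches(tree)
    assert len(br) == 3


def test_branch_count_matches_bifurcation_count(rng):
    """A binary tree with b bifurcations decomposes into 2b+1 branches
    (2b when the root itself bifurcates: its split yields two branches,
    not three)."""
    for _ in range(30):
        tree = random_binary_tree(rng)
        br = decompose_branches(tree)
        n_bif = sum(1 for n in tree.nodes["id"]
                    if len(tree.children(int(n))) >= 2)
        expected = 2 * n_bif + (1 if len(tree.children(tree.root)) == 1 else 0)
        assert len(br) == expected


def test_branches_partition_all_edges(rng):
    for _ in range(20):
        tree = random_binary_tree(rng)
        br = decompose_branches(tree)
        edges = set()
        for b in br:
            for a, c in zip(b.node_ids[:-1], b.node_ids[1:]):
                assert (a, c) not in edges
                edges.add((a, c))
        assert len(edges) == tree.n_nodes() - 1


# ---------------------------------------------------------------------------
# Order assignment: the two worked continuation examples


def test_continuation_prefers_daughter_with_branch_point():
    """Stem splits into A (which has a further branch point) and B
    (terminal): A continues the primary, B becomes secondary."""
    coords = [(0, 0), (1, 0),            # stem
              (2, 1), (3, 1), (4, 2), (4, 0),   # A with its own bifurcation
              (2, -1)]                   # B terminal
    parents = [-1, 0, 1, 2, 3, 3, 1]
    tree = tree_from_edges(coords, parents)
    br = decompose_branches(tree)
    assign_branch_orders(br, tree)
    orders = {tuple(b.node_ids): b.order for b in br}
    assert orders[(2, 7)] == 2          # B is secondary
    assert orders[(2, 3, 4)] == 1       # A continues order 1
    m = compute_aci(br)
    assert m.counts_per_order == {1: 3, 2: 2}


def test_continuation_tie_broken_by_length():
    """Stem splits into two terminal daughters: the longer continues."""
    coords = [(0, 0), (1, 0),
              (2, 0), (5, 0), (9, 0),    # A, length 8
              (1, 1), (1, 4)]            # B, length 3
    parents = [-1, 0, 1, 2, 3, 1, 5]
    tree = tree_from_edges(coords, parents)
    br = decompose_branches(tree)
    assign_branch_orders(br, tree)
    orders = {tuple(b.node_ids): b.order for b in br}
    assert orders[(2, 3, 4, 5)] == 1     # longer A continues as order 1
    assert orders[(2, 6, 7)] == 2        # shorter B is secondary


# ---------------------------------------------------------------------------
# ACI


@pytest.mark.parametrize("counts,expected", [
    ({1: 3}, 1.0),
    ({1: 2, 2: 2}, 1.5),
    ({1: 3, 2: 2, 3: 1}, 10 / 6),
])
def test_aci_formula(counts, expected):
    from axonkit.arbor import Branch
    branches = []
    for order, n in counts.items():
        for _ in range(n):
            branches.append(Branch(node_ids=[1, 2], length_um=1.0, order=order))
    assert compute_aci(branches).aci == pytest.approx(expected)


def test_aci_bounds_and_rigid_invariance(rng):
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0],
                    [0, 0, 1.0]])
    for _ in range(20):
        tree = random_binary_tree(rng)
        _, m = _metrics(tree)
        assert 1.0 <= m.aci <= max(m.counts_per_order)
        moved = tree.transformed(rotation=rot, translation=(5.0, -3.0, 2.0))
        _, m2 = _metrics(moved)
        assert m2.counts_per_order == m.counts_per_order
        assert m2.total_branch_length_um == pytest.approx(
            m.total_branch_length_um, rel=1e-9)


# ---------------------------------------------------------------------------
# Oracle


def test_oracle_agrees_with_greedy_on_random_trees(rng):
    """Exhaustive order-sum minimisation must reproduce greedy ACI."""
    for _ in range(100):
        tree = random_binary_tree(rng, max_bifurcations=8)
        _, m = _metrics(tree)
        _, mo = order_assignment_oracle(tree)
        assert m.aci == pytest.approx(mo.aci), \
            f"greedy ACI {m.aci} != oracle ACI {mo.aci}"


def test_oracle_guard_on_large_trees(rng):
    big = None
    while big is None:
        t = random_binary_tree(rng, max_bifurcations=8)
        n_bif = sum(1 for n in t.nodes["id"] if len(t.children(int(n))) >= 2)
        if n_bif >= 4:
            big = t
    with pytest.raises(ValueError, match="too many"):
        order_assignment_oracle(big, max_branch_points=2)


# ---------------------------------------------------------------------------
# Turning and looping


def test_turning_geometry():
    t = np.linspace(0, 2 * np.pi, 361)
    circle = np.column_stack([np.cos(t), np.sin(t)])
    semi = circle[:181]
    straight = np.column_stack([np.linspace(0, 100, 50), np.zeros(50)])
    assert cumulative_turning(straight, 2.0) == pytest.approx(0.0, abs=1e-9)
    assert cumulative_turning(circle, 0.02) == pytest.approx(360.0, abs=3.0)
    assert cumulative_turning(semi, 0.02) == pytest.approx(180.0, abs=3.0)


def test_turning_rejects_degenerate():
    with pytest.raises(ValueError):
        cumulative_turning(np.zeros((5, 2)))
    with pytest.raises(ValueError):
        cumulative_turning(np.zeros((2, 2)))


def test_looping_rule():
    from axonkit.arbor import ArborMetrics
    def call(aci, turn):
        m = ArborMetrics({1: 1}, aci, 10.0, 10.0, 0, {1: 1})
        return classify_looping(m, turn)
    assert call(1.2, 350).is_looping
    assert not call(2.0, 400).is_looping     # not simple
    assert not call(1.2, 30).is_looping      # no turn
    assert call(2.0, 400).is_looping is False and not call(2.0, 400).is_simple
    # looping implies simple
    for aci in (1.1, 1.39, 1.41, 2.5):
        for turn in (0, 269, 271, 400):
            c = call(aci, turn)
            assert not c.is_looping or c.is_simple


# ---------------------------------------------------------------------------
# Parameter recovery from the generator


def test_chain_count_recovery():
    """Analyser chain counts reproduce the generator's realised side-branch
    counts exactly, and the order-2 mean matches the configured rate."""
    params = synthgen.ArborParams()
    lam2 = params.mean_branches_per_order[1]
    a2 = []
    for s in range(150):
        tree, truth = synthgen.generate_arbor(params, seed=s, return_truth=True)
        _, m = _metrics(tree)
        got = {k: v for k, v in m.chains_per_order.items() if k >= 2}
        want = {k: v for k, v in truth["chain_counts"].items() if v > 0}
        assert got == want
        a2.append(truth["chain_counts"][2])
    se = np.std(a2) / np.sqrt(len(a2))
    assert abs(np.mean(a2) - lam2) <= 3 * se


def test_analyze_tree_readout_keys():
    tree = synthgen.generate_arbor(synthgen.ArborParams(), seed=3)
    row = analyze_tree(tree)
    assert set(row) >= {"N1", "N2", "N3", "ACI", "total_length_um",
                        "mean_primary_length_um", "turn_deg", "looping"}
    assert row["N1"] >= 1 and row["ACI"] >= 1.0
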