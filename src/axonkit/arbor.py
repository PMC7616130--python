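"""Axon arbor morphometry.

Reads SWC neuron traces, decomposes the tree into branches (maximal
unbranched chains), assigns branch orders with the continuation rule used
for axon complexity scoring, and computes the axon complexity index (ACI)

    ACI = sum_i i * N_i / sum_i N_i

where ``N_i`` is the number of branches of order ``i``.  The primary shaft
is order 1; at every branch point exactly one daughter continues its
parent's order and all other daughters take order parent+1.  The
continuation is the daughter whose subtree contains more branch points
(this keeps higher-order branch numbers minimal); when the daughters tie,
the daughter whose own segment is longer continues (keeping higher-order
branch *length* minimal).

The module also quantifies cumulative turning of the primary shaft and
classifies "looping" axons: axons whose main shaft executes a near-complete
turn while remaining simple (ACI below a cutoff, default 1.4).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArborTree",
    "Branch",
    "ArborMetrics",
    "LoopingCall",
    "SWCError",
    "read_swc",
    "write_swc",
    "decompose_branches",
    "assign_branch_orders",
    "compute_aci",
    "order_assignment_oracle",
    "primary_path",
    "cumulative_turning",
    "classify_looping",
    "analyze_tree",
    "analyze_swc_dir",
]


class SWCError(ValueError):
    """Raised for malformed SWC files or invalid tree structure."""


@dataclass
class ArborTree:
    """Rooted tree of traced nodes.

    ``nodes`` has columns (id, type, x, y, z, radius, parent); coordinates
    in micrometres; ``parent`` is -1 for the root.
    """

    nodes: pd.DataFrame
    root: int = field(init=False)
    _children: dict[int, list[int]] = field(init=False, repr=False)
    _coord: dict[int, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.nodes
        required = {"id", "x", "y", "z", "parent"}
        missing = required - set(df.columns)
        if missing:
            raise SWCError(f"node table missing columns: {sorted(missing)}")
        ids = df["id"].to_numpy()
        if len(ids) == 0:
            raise SWCError("empty node table")
        if len(np.unique(ids)) != len(ids):
            raise SWCError("duplicate node ids")
        if not np.all(np.isfinite(df[["x", "y", "z"]].to_numpy())):
            raise SWCError("non-finite coordinates")
        idset = set(int(i) for i in ids)
        roots = []
        children: dict[int, list[int]] = {int(i): [] for i in ids}
        for nid, pid in zip(df["id"].to_numpy(), df["parent"].to_numpy()):
            nid, pid = int(nid), int(pid)
            if pid == -1:
                roots.append(nid)
            else:
                if pid not in idset:
                    raise SWCError(f"node {nid}: dangling parent {pid}")
                if pid == nid:
                    raise SWCError(f"node {nid} is its own parent")
                children[pid].append(nid)
        if len(roots) != 1:
            raise SWCError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        # reachability check == acyclicity for a parent-pointer graph
        seen = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            seen.add(n)
            stack.extend(children[n])
        if len(seen) != len(ids):
            raise SWCError("cycle or disconnected nodes: "
                           f"{len(ids) - len(seen)} nodes unreachable from root")
        self._children = children
        xyz = df[["x", "y", "z"]].to_numpy(float)
        self._coord = {int(i): xyz[k] for k, i in enumerate(ids)}

    def children(self, node: int) -> list[int]:
        return self._children[node]

    def coord(self, node: int) -> np.ndarray:
        return self._coord[node]

    def n_nodes(self) -> int:
        return len(self.nodes)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: Sequence[float] = (0.0, 0.0, 0.0)) -> "ArborTree":
        """Return a copy with coordinates rigidly transformed."""
        df = self.nodes.copy()
        xyz = df[["x", "y", "z"]].to_numpy(float)
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, float).T
        xyz = xyz + np.asarray(translation, float)
        df[["x", "y", "z"]] = xyz
        return ArborTree(df)


@dataclass
class Branch:
    """Maximal unbranched chain of nodes between branch points / tips.

    ``node_ids`` runs from the proximal endpoint (root or a branch point)
    to the distal endpoint (a branch point or a tip), inclusive.
    """

    node_ids: list[int]
    length_um: float
    order: int | None = None

    @property
    def start(self) -> int:
        return self.node_ids[0]

    @property
    def end(self) -> int:
        return self.node_ids[-1]


@dataclass
class ArborMetrics:
    counts_per_order: dict[int, int]
    aci: float
    total_branch_length_um: float
    mean_primary_length_um: float
    n_branch_points: int
    chains_per_order: dict[int, int]

    @property
    def n_branches(self) -> int:
        return sum(self.counts_per_order.values())


@dataclass
class LoopingCall:
    cumulative_turn_deg: float
    is_simple: bool
    is_looping: bool


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path: str | Path) -> ArborTree:
    """Parse an SWC file into a validated :class:`ArborTree`.

    Errors (bad field count, non-numeric values, cycles, multiple roots,
    dangling parents) name the offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            try:
                rows.append(
                    (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                     float(parts[4]), float(parts[5]), int(parts[6]))
                )
            except ValueError as exc:
                raise SWCError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise SWCError(f"{path}: no nodes")
    df = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
    try:
        tree = ArborTree(df)
    except SWCError as exc:
        raise SWCError(f"{path}: {exc}") from None
    return _normalize_order(tree)


def _normalize_order(tree: ArborTree) -> ArborTree:
    """Reorder nodes parent-before-child (stable DFS from root)."""
    order: list[int] = []
    stack = [tree.root]
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(reversed(tree.children(n)))
    df = tree.nodes.set_index("id").loc[order].reset_index()
    return ArborTree(df)


def write_swc(tree: ArborTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for row in tree.nodes.itertuples(index=False):
            fh.write(f"{int(row.id)} {int(row.type)} {row.x:.4f} {row.y:.4f} "
                     f"{row.z:.4f} {row.radius:.4f} {int(row.parent)}\n")


# ---------------------------------------------------------------------------
# Branch decomposition and ordering


def decompose_branches(tree: ArborTree) -> list[Branch]:
    """Split the tree into maximal unbranched chains.

    Every edge belongs to exactly one branch; branch endpoints occur only
    at the root, at nodes with >= 2 children, or at tips.
    """
    if tree.n_nodes() < 2:
        raise SWCError("tree has no edges to decompose")
    starts = [tree.root] + [n for n, ch in tree._children.items()
                            if len(ch) >= 2 and n != tree.root]
    branches = []
    for s in starts:
        for c in tree.children(s):
            path = [s, c]
            while len(tree.children(path[-1])) == 1:
                path.append(tree.children(path[-1])[0])
            length = sum(
                float(np.linalg.norm(tree.coord(a) - tree.coord(b)))
                for a, b in zip(path[:-1], path[1:])
            )
            branches.append(Branch(node_ids=path, length_um=length))
    return branches


def _branch_children_map(branches: list[Branch]) -> dict[int, list[int]]:
    """Map branch index -> indices of daughter branches (those starting at its end)."""
    by_start: dict[int, list[int]] = {}
    for i, b in enumerate(branches):
        by_start.setdefault(b.start, []).append(i)
    return {i: by_start.get(b.end, []) for i, b in enumerate(branches)}


def _subtree_branch_points(branches: list[Branch],
                           bmap: dict[int, list[int]]) -> list[int]:
    """Number of branch points in each branch's subtree (its distal end included
    if it is a branch point)."""
    counts = [0] * len(branches)
    roots = set(range(len(branches))) - {d for ds in bmap.values() for d in ds}
    stack = [(r, False) for r in roots]
    while stack:
        i, processed = stack.pop()
        if processed:
            ds = bmap[i]
            counts[i] = (1 if len(ds) >= 2 else 0) + sum(counts[d] for d in ds)
        else:
            stack.append((i, True))
            for d in bmap[i]:
                stack.append((d, False))
    return counts


def _continuation(daughters: list[int], branches: list[Branch],
                  subtree_bp: list[int]) -> int:
    """Pick the daughter that continues the parent's order.

    More branch points in the daughter subtree wins; ties go to the longer
    immediate segment; residual ties to the first in node order (stable).
    """
    return max(daughters,
               key=lambda d: (subtree_bp[d], branches[d].length_um,
                              -branches[d].start, -branches[d].node_ids[1]))


def assign_branch_orders(branches: list[Branch], tree: ArborTree) -> list[Branch]:
    """Assign orders in place (and return the list).

    At each branching node one daughter continues the parent's order; the
    rest take order parent+1.  If the root itself branches, the chosen
    continuation carries order 1.
    """
    bmap = _branch_children_map(branches)
    subtree_bp = _subtree_branch_points(branches, bmap)
    root_branches = [i for i, b in enumerate(branches) if b.start == tree.root]
    stack: list[tuple[int, int]] = []
    if len(root_branches) == 1:
        stack.append((root_branches[0], 1))
    else:
        cont = _continuation(root_branches, branches, subtree_bp)
        for i in root_branches:
            stack.append((i, 1 if i == cont else 2))
    while stack:
        i, order = stack.pop()
        branches[i].order = order
        ds = bmap[i]
        if not ds:
            continue
        if len(ds) == 1:
            # not an actual branch point (cannot occur after decomposition),
            # but keep the chain order if it does
            stack.append((ds[0], order))
            continue
        cont = _continuation(ds, branches, subtree_bp)
        for d in ds:
            stack.append((d, order if d == cont else order + 1))
    return branches


def compute_aci(branches: list[Branch]) -> ArborMetrics:
    """Branch-count, length and complexity summaries from ordered branches."""
    if not branches:
        raise SWCError("no branches")
    if any(b.order is None for b in branches):
        raise SWCError("branch orders not assigned")
    counts: dict[int, int] = {}
    for b in branches:
        counts[b.order] = counts.get(b.order, 0) + 1
    n = sum(counts.values())
    aci = sum(i * c for i, c in counts.items()) / n
    total_len = sum(b.length_um for b in branches)
    primary = [b for b in branches if b.order == 1]
    mean_primary = sum(b.length_um for b in primary) / len(primary)
    # branch points = branching nodes (>=2 daughters)
    bmap = _branch_children_map(branches)
    n_bp = sum(1 for ds in bmap.values() if len(ds) >= 2)
    # chains: a branch starts a new order-k chain if it has no parent branch
    # of the same order feeding it (i.e. its order differs from its parent's)
    parent_of: dict[int, int] = {}
    for i, ds in bmap.items():
        for d in ds:
            parent_of[d] = i
    chains: dict[int, int] = {}
    for i, b in enumerate(branches):
        p = parent_of.get(i)
        if p is None or branches[p].order != b.order:
            chains[b.order] = chains.get(b.order, 0) + 1
    return ArborMetrics(
        counts_per_order=dict(sorted(counts.items())),
        aci=aci,
        total_branch_length_um=total_len,
        mean_primary_length_um=mean_primary,
        n_branch_points=n_bp,
        chains_per_order=dict(sorted(chains.items())),
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle


def order_assignment_oracle(tree: ArborTree,
                            max_branch_points: int = 12) -> tuple[list[Branch], ArborMetrics]:
    """Exhaustively enumerate continuation choices; return the labelling that
    minimises the total weighted order sum (equivalently the ACI, as the
    branch total is fixed), with ties broken by minimal total higher-order
    branch length.

    Intended as an independent check of the greedy rule on small trees.
    """
    branches = decompose_branches(tree)
    bmap = _branch_children_map(branches)
    decision_nodes = [i for i, ds in bmap.items() if len(ds) >= 2]
    root_branches = [i for i, b in enumerate(branches) if b.start == tree.root]
    root_decision = len(root_branches) >= 2
    n_dec = len(decision_nodes) + (1 if root_decision else 0)
    if n_dec > max_branch_points:
        raise ValueError(f"too many branch points for exhaustive search ({n_dec})")

    choice_sets = []
    if root_decision:
        choice_sets.append(root_branches)
    choice_sets.extend(bmap[i] for i in decision_nodes)

    best = None
    for picks in itertools.product(*choice_sets):
        k = 0
        if root_decision:
            root_cont = picks[0]
            k = 1
        cont_at = {decision_nodes[j]: picks[k + j] for j in range(len(decision_nodes))}
        orders = [0] * len(branches)
        stack = []
        if root_decision:
            for i in root_branches:
                stack.append((i, 1 if i == root_cont else 2))
        else:
            stack.append((root_branches[0], 1))
        while stack:
            i, o = stack.pop()
            orders[i] = o
            ds = bmap[i]
            if len(ds) == 1:
                stack.append((ds[0], o))
            elif len(ds) >= 2:
                c = cont_at[i]
                for d in ds:
                    stack.append((d, o if d == c else o + 1))
        score = (
            sum(orders),
            sum(branches[i].length_um for i in range(len(branches)) if orders[i] > 1),
        )
        if best is None or score < best[0]:
            best = (score, list(orders))
    assert best is not None
    for i, b in enumerate(branches):
        b.order = best[1][i]
    return branches, compute_aci(branches)


# ---------------------------------------------------------------------------
# Looping


def primary_path(branches: list[Branch], tree: ArborTree) -> np.ndarray:
    """Concatenated (n, 3) coordinates of the order-1 chain from the root."""
    if any(b.order is None for b in branches):
        raise SWCError("branch orders not assigned")
    bmap = _branch_children_map(branches)
    start_candidates = [i for i, b in enumerate(branches)
                        if b.start == tree.root and b.order == 1]
    path_nodes: list[int] = []
    i = start_candidates[0]
    while True:
        ids = branches[i].node_ids
        path_nodes.extend(ids if not path_nodes else ids[1:])
        nxt = [d for d in bmap[i] if branches[d].order == 1]
        if not nxt:
            break
        i = nxt[0]
    return np.array([tree.coord(n) for n in path_nodes])


def cumulative_turning(points: np.ndarray, resample_step_um: float = 2.0) -> float:
    """Absolute cumulative signed heading change (degrees) along a 2D path.

    The path is resampled at a fixed arc-length step before heading changes
    are summed, so densely and sparsely traced paths are comparable.  Only
    x and y are used (turning is measured in the imaging plane).
    """
    pts = np.asarray(points, float)[:, :2]
    if len(pts) < 3:
        raise ValueError("need at least 3 path points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate zero-length path")
    n = max(int(total / resample_step_um) + 1, 3)
    si = np.linspace(0.0, total, n)
    rx = np.interp(si, s, pts[:, 0])
    ry = np.interp(si, s, pts[:, 1])
    headings = np.arctan2(np.diff(ry), np.diff(rx))
    dh = np.diff(headings)
    dh = (dh + np.pi) % (2 * np.pi) - np.pi
    return float(abs(np.degrees(dh.sum())))


def classify_looping(metrics: ArborMetrics, turn_deg: float,
                     turn_threshold_deg: float = 270.0,
                     simple_threshold: float = 1.4) -> LoopingCall:
    """Looping = near-complete turn of the main shaft AND a simple arbor."""
    is_simple = metrics.aci < simple_threshold
    return LoopingCall(
        cumulative_turn_deg=float(turn_deg),
        is_simple=is_simple,
        is_looping=bool(turn_deg >= turn_threshold_deg and is_simple),
    )


# ---------------------------------------------------------------------------
# Convenience drivers


def analyze_tree(tree: ArborTree, turn_threshold_deg: float = 270.0,
                 simple_threshold: float = 1.4,
                 min_branch_um: float = 0.0) -> dict:
    """Full per-axon readout: counts per order, ACI, lengths, turning, looping."""
    branches = decompose_branches(tree)
    assign_branch_orders(branches, tree)
    if min_branch_um > 0:
        kept = [b for b in branches if b.length_um >= min_branch_um or b.order == 1]
        branches = kept
    m = compute_aci(branches)
    path = primary_path(branches, tree)
    turn = cumulative_turning(path) if len(path) >= 3 else 0.0
    call = classify_looping(m, turn, turn_threshold_deg, simple_threshold)
    counts = m.counts_per_order
    return {
        "N1": counts.get(1, 0),
        "N2": counts.get(2, 0),
        "N3": counts.get(3, 0),
        "N4plus": sum(c for o, c in counts.items() if o >= 4),
        "ACI": m.aci,
        "total_length_um": m.total_branch_length_um,
        "mean_primary_length_um": m.mean_primary_length_um,
        "n_branch_points": m.n_branch_points,
        "turn_deg": call.cumulative_turn_deg,
        "looping": call.is_looping,
    }


def analyze_swc_dir(swc_dir: str | Path, **kwargs) -> pd.DataFrame:
    """Analyze every ``*.swc`` under ``swc_dir``; one row per axon."""
    rows = []
    for f in sorted(Path(swc_dir).glob("**/*.swc")):
        tree = read_swc(f)
        row = analyze_tree(tree, **kwargs)
        row["axon_id"] = f.stem
        rows.append(row)
    if not rows:
        raise FileNotFoundError(f"no .swc files under {swc_dir}")
    df = pd.DataFrame(rows)
    return df[["axon_id"] + [c for c in df.columns if c != "axon_id"]]
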