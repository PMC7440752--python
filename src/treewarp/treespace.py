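"""Unrooted binary trees, Newick I/O, canonical topology keys, rearrangements.

The tree is the state an MCMC chain moves through.  It is stored as an
undirected graph: tips are degree-1 nodes carrying taxon labels, internal
nodes have degree 3, and every branch carries a nonnegative length
(expected substitutions per site) plus a *stable integer identifier*.
Branch identity survives NNI/SPR/TBR rearrangements, which is what makes
the branch-length mapping of the moves (which branch keeps which length)
well defined and testable.

All semantics are unrooted; a traversal "handle" node is chosen internally
where a rooted walk is needed (writing Newick, postorder passes) but never
leaks into results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy

__all__ = [
    "TreeError",
    "ParseError",
    "UnrootedTree",
    "TopologyKey",
    "parse_newick",
    "write_newick",
    "enumerate_topologies",
    "enumerate_trees",
    "NNIEdit",
    "SPREdit",
    "TBREdit",
    "apply_rearrangement",
]

DEFAULT_BRANCH_LENGTH = 0.1

# A topology key is the set of nontrivial splits, each split stored as the
# frozenset of taxon labels on the side *not* containing the first taxon in
# sorted order.  Invariant to branch lengths, node order and Newick rotation.
TopologyKey = frozenset


class TreeError(ValueError):
    """Contract violation on a tree operation."""


class ParseError(TreeError):
    """Malformed tree input."""


class UnrootedTree:
    """Unrooted binary tree with stable branch identifiers.

    Attributes
    ----------
    adj : dict[int, list[int]]
        node id -> incident branch ids (order irrelevant, kept stable).
    branches : dict[int, list]
        branch id -> [node_u, node_v, length].
    tip_label : dict[int, str]
        tip node id -> taxon label.
    """

    __slots__ = ("adj", "branches", "tip_label", "node_of", "_next_node", "_next_branch")

    def __init__(self) -> None:
        self.adj: dict[int, list[int]] = {}
        self.branches: dict[int, list] = {}
        self.tip_label: dict[int, str] = {}
        self.node_of: dict[str, int] = {}
        self._next_node = 0
        self._next_branch = 0

    # -- construction ----------------------------------------------------

    def new_node(self, label: Optional[str] = None) -> int:
        nid = self._next_node
        self._next_node += 1
        self.adj[nid] = []
        if label is not None:
            if label in self.node_of:
                raise ParseError(f"duplicate tip label {label!r}")
            self.tip_label[nid] = label
            self.node_of[label] = nid
        return nid

    def new_branch(self, u: int, v: int, length: float) -> int:
        bid = self._next_branch
        self._next_branch += 1
        self.branches[bid] = [u, v, float(length)]
        self.adj[u].append(bid)
        self.adj[v].append(bid)
        return bid

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree.__new__(UnrootedTree)
        t.adj = {k: v.copy() for k, v in self.adj.items()}
        t.branches = {k: v.copy() for k, v in self.branches.items()}
        t.tip_label = self.tip_label.copy()
        t.node_of = self.node_of.copy()
        t._next_node = self._next_node
        t._next_branch = self._next_branch
        return t

    # -- queries ----------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_label)

    @property
    def taxa(self) -> tuple:
        return tuple(sorted(self.node_of))

    def is_tip(self, node: int) -> bool:
        return node in self.tip_label

    def other_end(self, branch: int, node: int) -> int:
        u, v, _ = self.branches[branch]
        return v if node == u else u

    def endpoints(self, branch: int) -> tuple:
        u, v, _ = self.branches[branch]
        return u, v

    def length(self, branch: int) -> float:
        return self.branches[branch][2]

    def set_length(self, branch: int, value: float) -> None:
        self.branches[branch][2] = float(value)

    def is_terminal_branch(self, branch: int) -> bool:
        u, v, _ = self.branches[branch]
        return u in self.tip_label or v in self.tip_label

    def internal_branches(self) -> list:
        return [b for b in self.branches if not self.is_terminal_branch(b)]

    def branch_ids(self) -> list:
        return sorted(self.branches)

    def tree_length(self) -> float:
        return sum(rec[2] for rec in self.branches.values())

    def check(self) -> None:
        """Validate the unrooted-binary invariants; raise TreeError if broken."""
        n = self.n_tips
        if n < 3:
            raise TreeError("tree must have at least 3 tips")
        if len(self.branches) != 2 * n - 3:
            raise TreeError(f"expected {2 * n - 3} branches, found {len(self.branches)}")
        n_internal = len(self.adj) - n
        if n_internal != n - 2:
            raise TreeError(f"expected {n - 2} internal nodes, found {n_internal}")
        for node, inc in self.adj.items():
            want = 1 if node in self.tip_label else 3
            if len(inc) != want:
                raise TreeError(f"node {node} has degree {len(inc)}, expected {want}")
        for bid, (u, v, ln) in self.branches.items():
            if not (ln >= 0.0 and ln == ln and ln != float("inf")):
                raise TreeError(f"branch {bid} has invalid length {ln}")
            if bid not in self.adj[u] or bid not in self.adj[v]:
                raise TreeError(f"branch {bid} inconsistent with adjacency")
        # connectivity
        seen = set()
        stack = [next(iter(self.adj))]
        while stack:
            nd = stack.pop()
            if nd in seen:
                continue
            seen.add(nd)
            for b in self.adj[nd]:
                stack.append(self.other_end(b, nd))
        if len(seen) != len(self.adj):
            raise TreeError("tree is not connected")

    # -- splits and topology keys -----------------------------------------

    def side_taxa(self, branch: int, node: int) -> frozenset:
        """Taxon labels in the component containing `node` when `branch` is cut."""
        out = []
        seen = {node}
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd in self.tip_label:
                out.append(self.tip_label[nd])
            for b in self.adj[nd]:
                if b == branch:
                    continue
                nb = self.other_end(b, nd)
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(out)

    def split(self, branch: int) -> frozenset:
        """Canonical split for a branch: the side excluding the first taxon."""
        first = min(self.node_of)
        u, _v, _ = self.branches[branch]
        side = self.side_taxa(branch, u)
        if first in side:
            side = frozenset(self.node_of) - side
        return side

    def topology_key(self) -> TopologyKey:
        return frozenset(self.split(b) for b in self.branches if not self.is_terminal_branch(b))

    def subtree_size(self, branch: int, node: int) -> int:
        """Number of taxa on `node`'s side of `branch`."""
        count = 0
        seen = {node}
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd in self.tip_label:
                count += 1
            for b in self.adj[nd]:
                if b == branch:
                    continue
                nb = self.other_end(b, nd)
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return count


def topology_key_string(key: TopologyKey) -> str:
    """Stable human-readable encoding of a topology key."""
    parts = sorted(",".join(sorted(s)) for s in key)
    return "|".join(parts) if parts else "star"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> UnrootedTree:
    """Parse a Newick string into an :class:`UnrootedTree`.

    Rooted (bifurcating-root) inputs are unrooted by suppressing the
    degree-2 root and summing its two incident branch lengths.  Missing
    branch lengths default to 0.1.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ParseError(f"malformed Newick: {exc}") from None

    t = UnrootedTree()
    seen_labels = set()
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ParseError("leaf without a label")
        if leaf.taxon.label in seen_labels:
            raise ParseError(f"duplicate tip label {leaf.taxon.label!r}")
        seen_labels.add(leaf.taxon.label)
    if len(seen_labels) < 3:
        raise ParseError(f"need at least 3 tips, found {len(seen_labels)}")

    node_map: dict = {}

    def get_node(dnode) -> int:
        if dnode not in node_map:
            label = dnode.taxon.label if dnode.is_leaf() else None
            node_map[dnode] = t.new_node(label)
        return node_map[dnode]

    root = dtree.seed_node
    root_children = root.child_nodes()
    if len(root_children) == 2:
        # rooted input: suppress the root, summing the two incident lengths
        a, b = root_children
        la = a.edge.length if a.edge.length is not None else DEFAULT_BRANCH_LENGTH
        lb = b.edge.length if b.edge.length is not None else DEFAULT_BRANCH_LENGTH
        _copy_subtree(t, a, get_node)
        _copy_subtree(t, b, get_node)
        t.new_branch(get_node(a), get_node(b), la + lb)
    elif len(root_children) >= 3:
        if len(root_children) > 3:
            raise ParseError("polytomy at root: only binary trees are supported")
        for child in root_children:
            _copy_subtree(t, child, get_node)
            ln = child.edge.length if child.edge.length is not None else DEFAULT_BRANCH_LENGTH
            t.new_branch(get_node(root), get_node(child), ln)
    else:
        raise ParseError("degenerate tree (fewer than 2 children at root)")

    t.check()
    return t


def _copy_subtree(t: UnrootedTree, dnode, get_node) -> None:
    children = dnode.child_nodes()
    if children and len(children) != 2:
        raise ParseError(f"polytomy (node with {len(children)} children): only binary trees supported")
    for child in children:
        _copy_subtree(t, child, get_node)
        ln = child.edge.length if child.edge.length is not None else DEFAULT_BRANCH_LENGTH
        t.new_branch(get_node(dnode), get_node(child), ln)


def write_newick(tree: UnrootedTree) -> str:
    """Serialize as Newick with a trifurcation at an internal handle node.

    The handle is the internal node adjacent to the alphabetically first
    taxon and children are ordered by their smallest taxon label, so output
    is deterministic for a given tree.
    """
    first_tip = tree.node_of[min(tree.node_of)]
    handle = tree.other_end(tree.adj[first_tip][0], first_tip)

    def fmt(x: float) -> str:
        return format(x, ".10g")

    def label_key(node: int, via_branch: int) -> str:
        return min(tree.side_taxa(via_branch, node))

    def render(node: int, parent_branch: int) -> str:
        if tree.is_tip(node):
            return tree.tip_label[node]
        parts = []
        for b in tree.adj[node]:
            if b == parent_branch:
                continue
            child = tree.other_end(b, node)
            parts.append((label_key(child, b), f"{render(child, b)}:{fmt(tree.length(b))}"))
        parts.sort()
        return "(" + ",".join(p[1] for p in parts) + ")"

    parts = []
    for b in tree.adj[handle]:
        child = tree.other_end(b, handle)
        parts.append((label_key(child, b), f"{render(child, b)}:{fmt(tree.length(b))}"))
    parts.sort()
    return "(" + ",".join(p[1] for p in parts) + ");"


# ---------------------------------------------------------------------------
# Topology enumeration (stepwise addition)
# ---------------------------------------------------------------------------


def enumerate_trees(labels: Iterable[str]) -> list:
    """All distinct unrooted binary topologies on the given taxa.

    Built by stepwise tip addition (every topology arises exactly once),
    with unit-free default branch lengths.  Count is (2n-5)!!.
    Limited to n <= 7 to guard against combinatorial explosion.
    """
    labels = sorted(labels)
    n = len(labels)
    if not 3 <= n <= 7:
        raise TreeError(f"topology enumeration supports 3..7 taxa, got {n}")

    base = UnrootedTree()
    center = base.new_node()
    for lab in labels[:3]:
        tip = base.new_node(lab)
        base.new_branch(center, tip, DEFAULT_BRANCH_LENGTH)

    trees = [base]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            for b in t.branch_ids():
                t2 = t.copy()
                u, v, ln = t2.branches[b]
                mid = t2.new_node()
                tip = t2.new_node(lab)
                # subdivide b at mid, hang the new tip
                t2.adj[v].remove(b)
                t2.branches[b][1] = mid
                t2.adj[mid].append(b)
                t2.new_branch(mid, v, DEFAULT_BRANCH_LENGTH)
                t2.new_branch(mid, tip, DEFAULT_BRANCH_LENGTH)
                t2.branches[b][2] = ln
                nxt.append(t2)
        trees = nxt
    # stable order by canonical key string
    trees.sort(key=lambda t: topology_key_string(t.topology_key()))
    return trees


def enumerate_topologies(n_or_labels) -> list:
    """Canonical keys of all unrooted binary topologies (n between 3 and 7)."""
    if isinstance(n_or_labels, int):
        labels = [f"t{i + 1}" for i in range(n_or_labels)]
    else:
        labels = list(n_or_labels)
    return [t.topology_key() for t in enumerate_trees(labels)]


# ---------------------------------------------------------------------------
# Rearrangements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NNIEdit:
    """Swap across internal branch `branch`; `second` selects which of the
    two neighbor exchanges is performed."""

    branch: int
    second: bool = False


@dataclass(frozen=True)
class SPREdit:
    """Prune the subtree on `head`'s side of branch `a`, regraft at branch `r`."""

    a: int
    head: int
    r: int


@dataclass(frozen=True)
class TBREdit:
    """Bisect at internal branch `a`; reattach each end at `r1`/`r2`
    (None = that end keeps its original attachment)."""

    a: int
    r1: Optional[int]
    r2: Optional[int]


def apply_rearrangement(tree: UnrootedTree, edit) -> UnrootedTree:
    """Return a new tree with the edit applied; the input is not modified.

    Branch lengths are carried by branch identity: surviving branches keep
    their lengths, the merged attachment branch keeps the identity and
    length of the branch left behind, and the moved pendant branch keeps
    its own length at the new attachment point.
    """
    if isinstance(edit, NNIEdit):
        return _apply_nni(tree, edit.branch, edit.second)
    if isinstance(edit, SPREdit):
        return _apply_spr(tree, edit.a, edit.head, edit.r)
    if isinstance(edit, TBREdit):
        return _apply_tbr(tree, edit.a, edit.r1, edit.r2)
    raise TreeError(f"unknown edit type {type(edit).__name__}")


def _apply_nni(tree: UnrootedTree, branch: int, second: bool) -> UnrootedTree:
    if branch not in tree.branches:
        raise TreeError(f"no branch {branch}")
    if tree.is_terminal_branch(branch):
        raise TreeError("NNI requires an internal branch")
    t = tree.copy()
    u, v, _ = t.branches[branch]
    bu = [b for b in t.adj[u] if b != branch]
    bv = [b for b in t.adj[v] if b != branch]
    # exchange subtree across the branch: A<->C (or B<->C)
    a_b = bu[1] if second else bu[0]
    c_b = bv[0]
    _swap_endpoint(t, a_b, u, v)
    _swap_endpoint(t, c_b, v, u)
    return t


def _swap_endpoint(t: UnrootedTree, branch: int, old: int, new: int) -> None:
    rec = t.branches[branch]
    if rec[0] == old:
        rec[0] = new
    else:
        rec[1] = new
    t.adj[old].remove(branch)
    t.adj[new].append(branch)


def _near_endpoint(t: UnrootedTree, r: int, target_branch: int) -> int:
    """Endpoint of branch r in the component (r removed) containing target_branch."""
    u, v, _ = t.branches[r]
    tu, tv, _ = t.branches[target_branch]
    seen = {u}
    stack = [u]
    while stack:
        nd = stack.pop()
        if nd == tu or nd == tv:
            return u
        for b in t.adj[nd]:
            if b == r:
                continue
            nb = t.other_end(b, nd)
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return v


def _slide_junction(t: UnrootedTree, x: int, avoid: int, r: int) -> tuple:
    """Move junction node `x` (keeping its branch `avoid`) onto branch `r`.

    The two other branches at x are q (toward r, moved with the junction)
    and b (left behind, which absorbs the merged path and keeps its own
    length).  Returns (q, b).
    """
    others = [b for b in t.adj[x] if b != avoid]
    if len(others) != 2:
        raise TreeError("junction node must have degree 3")
    c1, c2 = others
    if r == c1 or r == c2 or r == avoid:
        raise TreeError("regraft branch must differ from the branches at the junction")
    if r not in t.branches:
        raise TreeError(f"no branch {r}")
    # q = branch on the path from x toward r
    y1 = t.other_end(c1, x)
    if _reaches(t, y1, c1, r):
        q, b = c1, c2
    else:
        q, b = c2, c1
    y = t.other_end(q, x)
    z = t.other_end(b, x)
    # detach q and b from the tree around x; b spans y..z
    t.adj[y].remove(q)
    t.adj[z].remove(b)
    t.branches[b][0], t.branches[b][1] = y, z
    t.adj[y].append(b)
    t.adj[z].append(b)
    t.adj[x] = [avoid, q]
    t.branches[q][0], t.branches[q][1] = x, x  # placeholder until reattach
    # reattach on r: q goes to the endpoint of r nearest the old location (b)
    near = _near_endpoint(t, r, b)
    t.adj[near].remove(r)
    rec = t.branches[r]
    if rec[0] == near:
        rec[0] = x
    else:
        rec[1] = x
    t.adj[x].append(r)
    t.branches[q][0], t.branches[q][1] = x, near
    t.adj[near].append(q)
    return q, b


def _reaches(t: UnrootedTree, start: int, via: int, target_branch: int) -> bool:
    """Is target_branch in the component containing `start` when `via` is cut?"""
    tu, tv, _ = t.branches[target_branch]
    seen = {start}
    stack = [start]
    while stack:
        nd = stack.pop()
        if nd == tu or nd == tv:
            return True
        for b in t.adj[nd]:
            if b == via:
                continue
            nb = t.other_end(b, nd)
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return False


def apply_spr_ids(tree: UnrootedTree, a: int, head: int, r: int):
    """SPR returning (new tree, pendant branch q, branch-left-behind b)."""
    if a not in tree.branches:
        raise TreeError(f"no branch {a}")
    if tree.n_tips < 4:
        raise TreeError("SPR requires at least 4 tips")
    u, v, _ = tree.branches[a]
    if head not in (u, v):
        raise TreeError("head must be an endpoint of branch a")
    x = v if head == u else u
    if tree.is_tip(x):
        raise TreeError("the attachment end of branch a must be internal")
    t = tree.copy()
    q, b = _slide_junction(t, x, a, r)
    return t, q, b


def _apply_spr(tree: UnrootedTree, a: int, head: int, r: int) -> UnrootedTree:
    return apply_spr_ids(tree, a, head, r)[0]


def apply_tbr_ids(tree: UnrootedTree, a: int, r1: Optional[int], r2: Optional[int]):
    """TBR returning (new tree, (q1, b1) or None, (q2, b2) or None)."""
    if a not in tree.branches:
        raise TreeError(f"no branch {a}")
    if tree.is_terminal_branch(a):
        raise TreeError("TBR requires an internal branch")
    t = tree.copy()
    x1, x2, _ = t.branches[a]
    ids1 = ids2 = None
    if r1 is not None:
        ids1 = _slide_junction(t, x1, a, r1)
    if r2 is not None:
        ids2 = _slide_junction(t, x2, a, r2)
    return t, ids1, ids2


def _apply_tbr(tree: UnrootedTree, a: int, r1: Optional[int], r2: Optional[int]) -> UnrootedTree:
    return apply_tbr_ids(tree, a, r1, r2)[0]
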