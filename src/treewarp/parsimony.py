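"""Fitch parsimony: whole trees, and fast scoring of SPR/TBR candidates.

The guided tree proposals need the parsimony score S_i of every candidate
regraft (SPR) or reconnection pair (TBR) of a pruned/bisected tree, where
S_i is defined as

    fitch(tree with the moving part reattached at i)
    - fitch(moving part) - fitch(remainder).

Rooting the reattached tree at the junction shows that this difference is
exactly the number of patterns (weighted) whose Fitch state sets on the
two sides of the new junction are disjoint.  So after one pass computing
direction-aware state sets on the remainder, every candidate costs a
single vectorized set intersection over patterns.  Brute-force equality
with the definition above is the module's correctness contract (tested).

State sets are bit-encoded (4 bits per cell); ambiguity codes participate
as their subsets, which is standard Fitch on subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .characters import PatternMatrix
from .treespace import TreeError, UnrootedTree

__all__ = [
    "fitch_score",
    "PrunedContext",
    "prune_context",
    "regraft_scores",
    "BisectScores",
    "bisect_scores",
]


def _tip_rows(tree: UnrootedTree, data: PatternMatrix) -> dict:
    rows = getattr(data, "_label_rows", None)
    if rows is None:
        rows = {lab: data.codes[i] for i, lab in enumerate(data.taxa)}
        object.__setattr__(data, "_label_rows", rows)
    missing = [lab for lab in tree.node_of if lab not in rows]
    if missing:
        raise TreeError(f"taxa on tree but not in data: {sorted(missing)}")
    return {node: rows[lab] for lab, node in tree.node_of.items()}


def _combine(x: np.ndarray, y: np.ndarray, weights: np.ndarray):
    """One Fitch junction: (state set, extra steps) for the union of two parts."""
    inter = x & y
    empty = inter == 0
    steps = int(weights @ empty)
    out = np.where(empty, x | y, inter)
    return out, steps


class _FitchEngine:
    """Direction-aware Fitch state sets for one tree (or tree fragment).

    ``dirset(branch, node)`` is the state-set vector (and accumulated step
    count) of the part of the tree on ``node``'s side of ``branch``.
    Computed lazily with memoization; each directed branch is visited once.
    """

    def __init__(self, tree: UnrootedTree, rows: dict, weights: np.ndarray):
        self.tree = tree
        self.rows = rows
        self.weights = weights
        self._memo: dict = {}

    def dirset(self, branch: int, node: int):
        key = (branch, node)
        memo = self._memo
        if key in memo:
            return memo[key]
        # iterative postorder over directed branches
        stack = [key]
        tree = self.tree
        while stack:
            b, nd = stack[-1]
            if (b, nd) in memo:
                stack.pop()
                continue
            if nd in tree.tip_label:
                memo[(b, nd)] = (self.rows[nd], 0)
                stack.pop()
                continue
            deps = []
            ready = True
            for nb in tree.adj[nd]:
                if nb == b:
                    continue
                far = tree.other_end(nb, nd)
                if (nb, far) not in memo:
                    stack.append((nb, far))
                    ready = False
                else:
                    deps.append(memo[(nb, far)])
            if ready:
                (s1, c1), (s2, c2) = deps
                merged, extra = _combine(s1, s2, self.weights)
                memo[(b, nd)] = (merged, c1 + c2 + extra)
                stack.pop()
        return memo[key]

    def junction_profile(self, branch: int):
        """State set presented to a subtree regrafted onto ``branch``
        (Fitch-combined view of the whole fragment from that junction),
        plus the fragment's total step count."""
        u, v, _ = self.tree.branches[branch]
        su, cu = self.dirset(branch, u)
        sv, cv = self.dirset(branch, v)
        merged, extra = _combine(su, sv, self.weights)
        return merged, cu + cv + extra


def fitch_score(tree: UnrootedTree, data: PatternMatrix) -> int:
    """Minimum weighted number of state changes under Fitch parsimony."""
    if tree.n_tips == 2:
        # degenerate two-taxon fragment: one branch
        rows = _tip_rows(tree, data)
        (n1, n2) = rows.values()
        return int(data.weights @ ((n1 & n2) == 0))
    rows = _tip_rows(tree, data)
    eng = _FitchEngine(tree, rows, data.weights)
    _profile, steps = eng.junction_profile(tree.branch_ids()[0])
    return steps


# ---------------------------------------------------------------------------
# SPR candidate scoring
# ---------------------------------------------------------------------------


@dataclass
class PrunedContext:
    """The remainder after pruning subtree A at branch ``a`` (A on ``head``'s
    side), with everything needed to score any regraft in O(patterns).

    ``merged_branch`` is the candidate branch holding the original
    attachment point (the two branches at the suppressed junction merged;
    it keeps the smaller of their two identifiers).  ``merged_parts`` maps
    that back to the original tree's branch ids.
    """

    remainder: UnrootedTree
    a: int
    head: int
    junction: int
    merged_branch: int
    merged_parts: tuple
    data: Optional[PatternMatrix]
    moving_set: Optional[np.ndarray]
    moving_steps: int
    engine: Optional[_FitchEngine]


def prune_context(
    tree: UnrootedTree, a: int, head: int, data: Optional[PatternMatrix]
) -> PrunedContext:
    """Prune the subtree on ``head``'s side of branch ``a``.

    For a terminal branch the moving subtree is necessarily the tip.  The
    remainder must retain at least 3 taxa (otherwise there is no valid
    SPR) -> TreeError.
    """
    if a not in tree.branches:
        raise TreeError(f"no branch {a}")
    u, v, _ = tree.branches[a]
    if head not in (u, v):
        raise TreeError("head must be an endpoint of branch a")
    if tree.is_tip(u) and head != u:
        head = u
    if tree.is_tip(v) and head != v:
        head = v
    x = v if head == u else u
    if tree.is_tip(x):
        raise TreeError("cannot prune: attachment end of branch a is a tip")
    n_moving = tree.subtree_size(a, head)
    if tree.n_tips - n_moving < 3:
        raise TreeError("remainder would have fewer than 3 taxa: no valid SPR")

    remainder = tree.copy()
    # drop the moving side
    drop_nodes = _component_nodes(tree, a, head)
    for nd in drop_nodes:
        for b in tree.adj[nd]:
            remainder.branches.pop(b, None)
        del remainder.adj[nd]
        if nd in remainder.tip_label:
            del remainder.node_of[remainder.tip_label[nd]]
            del remainder.tip_label[nd]
    remainder.branches.pop(a, None)
    # suppress the junction x: merge its two remaining branches
    c1, c2 = [b for b in remainder.adj[x] if b in remainder.branches]
    y = remainder.other_end(c1, x)
    z = remainder.other_end(c2, x)
    keep, drop = (c1, c2) if c1 < c2 else (c2, c1)
    length = remainder.branches[c1][2] + remainder.branches[c2][2]
    remainder.branches[keep] = [y, z, length]
    remainder.branches.pop(drop, None)
    remainder.adj[y] = [b for b in remainder.adj[y] if b in remainder.branches]
    remainder.adj[z] = [b for b in remainder.adj[z] if b in remainder.branches]
    if keep not in remainder.adj[y]:
        remainder.adj[y].append(keep)
    if keep not in remainder.adj[z]:
        remainder.adj[z].append(keep)
    del remainder.adj[x]

    moving_set = None
    moving_steps = 0
    engine = None
    if data is not None:
        rows = _tip_rows(tree, data)
        if head in tree.tip_label:
            moving_set, moving_steps = rows[head], 0
        else:
            full_engine = _FitchEngine(tree, rows, data.weights)
            moving_set, moving_steps = full_engine.dirset(a, head)
        rem_rows = {nd: rows[nd] for nd in remainder.tip_label}
        engine = _FitchEngine(remainder, rem_rows, data.weights)

    return PrunedContext(
        remainder=remainder,
        a=a,
        head=head,
        junction=x,
        merged_branch=keep,
        merged_parts=(c1, c2),
        data=data,
        moving_set=moving_set,
        moving_steps=moving_steps,
        engine=engine,
    )


def _component_nodes(tree: UnrootedTree, cut_branch: int, start: int) -> list:
    seen = {start}
    stack = [start]
    while stack:
        nd = stack.pop()
        for b in tree.adj[nd]:
            if b == cut_branch:
                continue
            nb = tree.other_end(b, nd)
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return list(seen)


def regraft_scores(ctx: PrunedContext) -> dict:
    """S_i for every branch i of the pruned remainder.

    S_i = fitch(regrafted at i) - fitch(moving part) - fitch(remainder);
    with no data all scores are zero (uniform proposal weights).
    """
    branches = ctx.remainder.branch_ids()
    if ctx.data is None:
        return {b: 0 for b in branches}
    weights = ctx.data.weights
    out = {}
    for b in branches:
        profile, _steps = ctx.engine.junction_profile(b)
        out[b] = int(weights @ ((profile & ctx.moving_set) == 0))
    return out


# ---------------------------------------------------------------------------
# TBR candidate scoring
# ---------------------------------------------------------------------------


@dataclass
class BisectScores:
    """Reconnection-pair scores after bisecting at an internal branch.

    ``side1``/``side2`` list candidate branch ids (at most ``delta`` nodes
    from the current attachment point in each half); ``scores[(i, j)]``
    holds S_ij.  ``identity`` is the pair that reconstructs the current
    topology (always a candidate, at distance 0).
    """

    half1: UnrootedTree
    half2: UnrootedTree
    side1: list
    side2: list
    scores: dict
    identity: tuple
    merged_parts1: tuple
    merged_parts2: tuple
    fitch_half1: int
    fitch_half2: int


def _bisect_half(tree: UnrootedTree, a: int, x: int, remainder_nodes: list):
    """Extract the half containing junction x's neighborhood, suppressing x."""
    half = UnrootedTree.__new__(UnrootedTree)
    half.adj = {nd: tree.adj[nd].copy() for nd in remainder_nodes}
    half.branches = {}
    half.tip_label = {nd: tree.tip_label[nd] for nd in remainder_nodes if nd in tree.tip_label}
    half.node_of = {lab: nd for nd, lab in half.tip_label.items()}
    half._next_node = tree._next_node
    half._next_branch = tree._next_branch
    for nd in remainder_nodes:
        for b in tree.adj[nd]:
            if b != a and b not in half.branches:
                half.branches[b] = tree.branches[b].copy()
    # x is in remainder_nodes; suppress it
    c1, c2 = [b for b in tree.adj[x] if b != a]
    y = tree.other_end(c1, x)
    z = tree.other_end(c2, x)
    keep, drop = (c1, c2) if c1 < c2 else (c2, c1)
    length = tree.branches[c1][2] + tree.branches[c2][2]
    half.branches[keep] = [y, z, length]
    del half.branches[drop]
    half.adj[y] = [b for b in half.adj[y] if b in half.branches]
    half.adj[z] = [b for b in half.adj[z] if b in half.branches]
    if keep not in half.adj[y]:
        half.adj[y].append(keep)
    if keep not in half.adj[z]:
        half.adj[z].append(keep)
    del half.adj[x]
    return half, keep, (c1, c2)


def _candidates_within(half: UnrootedTree, merged: int, delta: int) -> list:
    """Branches at most ``delta`` nodes from the attachment point (interior
    of the merged branch); the merged branch itself is distance 0."""
    dist = {merged: 0}
    frontier = []  # (node to cross, via branch, current distance)
    for endpoint in half.endpoints(merged):
        if not half.is_tip(endpoint):
            frontier.append((endpoint, merged, 0))
    while frontier:
        node, via, d = frontier.pop()
        if d + 1 > delta:
            continue
        for b in half.adj[node]:
            if b == via:
                continue
            if b not in dist or dist[b] > d + 1:
                dist[b] = d + 1
                far = half.other_end(b, node)
                if not half.is_tip(far):
                    frontier.append((far, b, d + 1))
    return sorted(dist)


def bisect_scores(
    tree: UnrootedTree,
    a: int,
    delta: int,
    data: Optional[PatternMatrix],
) -> BisectScores:
    """Score all reconnection pairs within ``delta`` nodes of branch ``a``.

    S_ij = fitch(reconnected at (i, j)) - fitch(half 1) - fitch(half 2).
    """
    if a not in tree.branches:
        raise TreeError(f"no branch {a}")
    if tree.is_terminal_branch(a):
        raise TreeError("TBR requires an internal branch")
    if delta < 1:
        raise TreeError("delta must be >= 1")
    x1, x2, _ = tree.branches[a]
    nodes1 = _component_nodes(tree, a, x1)
    nodes2 = _component_nodes(tree, a, x2)
    half1, merged1, parts1 = _bisect_half(tree, a, x1, nodes1)
    half2, merged2, parts2 = _bisect_half(tree, a, x2, nodes2)
    side1 = _candidates_within(half1, merged1, delta)
    side2 = _candidates_within(half2, merged2, delta)

    scores: dict = {}
    f1 = f2 = 0
    if data is None:
        for i in side1:
            for j in side2:
                scores[(i, j)] = 0
    else:
        rows = _tip_rows(tree, data)
        w = data.weights
        eng1 = _FitchEngine(half1, {nd: rows[nd] for nd in half1.tip_label}, w)
        eng2 = _FitchEngine(half2, {nd: rows[nd] for nd in half2.tip_label}, w)
        prof1 = {}
        for i in side1:
            if half1.n_tips == 2:
                u, v, _ = half1.branches[i]
                prof1[i], f1 = _two_tip_profile(half1, i, rows, w)
            else:
                prof1[i], f1 = eng1.junction_profile(i)
        prof2 = {}
        for j in side2:
            if half2.n_tips == 2:
                prof2[j], f2 = _two_tip_profile(half2, j, rows, w)
            else:
                prof2[j], f2 = eng2.junction_profile(j)
        for i in side1:
            p1 = prof1[i]
            for j in side2:
                scores[(i, j)] = int(w @ ((p1 & prof2[j]) == 0))
    return BisectScores(
        half1=half1,
        half2=half2,
        side1=side1,
        side2=side2,
        scores=scores,
        identity=(merged1, merged2),
        merged_parts1=parts1,
        merged_parts2=parts2,
        fitch_half1=f1,
        fitch_half2=f2,
    )


def _two_tip_profile(half: UnrootedTree, branch: int, rows: dict, w: np.ndarray):
    u, v, _ = half.branches[branch]
    profile, steps = _combine(rows[u], rows[v], w)
    return profile, steps
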