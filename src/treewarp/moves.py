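"""Tree proposals: sNNI, eSPR, eTBR, pSPR1/2, pTBR1/2, and branch scalers.

Every proposal returns the proposed tree together with an *exact* log
Hastings (proposal) ratio, so that a Metropolis–Hastings chain using these
moves with a constant likelihood samples the uniform distribution over
topologies — the central correctness property of guided proposals.

Guided moves (pSPR, pTBR) weight each regraft candidate i by

    omega_i = rho_i ** (epsilon * S_i)

where S_i is the parsimony-score increment of regrafting at i, epsilon is
the warp factor, and the base factor rho_i is either the constant e^-1
(variant 1) or a JC69-derived change probability evaluated at the pseudo
branch length S_i/N + eta (variant 2).  The proposal ratio

    [omega_b / sum_{i != r} omega_i] / [omega_r / sum_{j != b} omega_j]

(b = current attachment, r = proposed) corrects the preference exactly,
which is what keeps parsimony artifacts such as long-branch attraction out
of the sampled posterior.

Extending moves (eSPR, eTBR) choose the regraft point by a stochastic walk
with continuation probability p_e.  The walk's initial direction choice
costs 1/2 unless one end of the merged attachment branch is a tip (then
the direction is forced), and its final stop costs (1 - p_e) unless the
walk lands on a pendant branch (tip-forced stop).  These two constraints
are mirror images under move reversal, which reproduces the standard
constrained proposal ratios 1/(2(1-p_e)) and 2(1-p_e).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .parsimony import bisect_scores, prune_context, regraft_scores
from .treespace import (
    TreeError,
    UnrootedTree,
    apply_spr_ids,
    apply_tbr_ids,
    _apply_nni,
)

__all__ = [
    "MoveTuning",
    "ProposalResult",
    "MOVE_NAMES",
    "guide_weights",
    "log_hastings_guided",
    "scale_branch",
    "propose",
]

MOVE_NAMES = ("sNNI", "eSPR", "eTBR", "pSPR1", "pSPR2", "pTBR1", "pTBR2")

LOG_HALF = math.log(0.5)


@dataclass
class MoveTuning:
    """Tuning parameters for the tree proposals.

    Defaults follow the reference settings: p_e = 0.5, epsilon = 0.5 for
    variant-1 and 0.1 for variant-2 guided moves, delta = 5, eta = 1e-4,
    and branch scalers with lambda = 2 ln 1.05 (multipliers within +-5%).
    ``rho_factor`` selects the JC69 base-factor convention for variant 2:
    1/4 (probability of changing to one specific different state; the
    default, which reproduces the reference weight tables) or 3/4 (total
    change probability).
    """

    p_e: float = 0.5
    epsilon: float = 0.5
    variant: int = 1
    eta: float = 1e-4
    delta: int = 5
    lam: float = 2.0 * math.log(1.05)
    rho_factor: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_e < 1.0:
            raise ValueError("p_e must be in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("warp factor epsilon must be > 0")
        if self.variant not in (1, 2):
            raise ValueError("variant must be 1 or 2")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.lam <= 0:
            raise ValueError("scaler tuning lambda must be > 0")

    @classmethod
    def for_move(cls, move: str, **overrides) -> "MoveTuning":
        base = {}
        if move in ("pSPR1", "pTBR1"):
            base = dict(variant=1, epsilon=0.5)
        elif move in ("pSPR2", "pTBR2"):
            base = dict(variant=2, epsilon=0.1)
        base.update(overrides)
        return cls(**base)


@dataclass
class ProposalResult:
    """A proposed tree plus its exact log Hastings ratio.

    ``modified`` lists branch ids whose lengths were scaled; ``info``
    carries move bookkeeping (path lengths, chosen candidates, whether the
    rearrangement is NNI-equivalent) used by diagnostics and tests.
    """

    tree: UnrootedTree
    log_hastings: float
    modified: list
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Guide weights and the guided proposal ratio
# ---------------------------------------------------------------------------


def guide_weights(scores: dict, tuning: MoveTuning, n_sites: int) -> dict:
    """Log proposal weights per candidate, shifted so the minimum-score
    candidate has log-weight 0.

    Variant 1: log w_i = -epsilon * S_i  (rho = e^-1).
    Variant 2: log w_i = epsilon * S_i * log rho(S_i), with
    rho(S) = rho_factor * (1 - exp(-4/3 * (S/N + eta))).
    """
    if not scores:
        raise ValueError("empty score map")
    smin = min(scores.values())
    smax = max(scores.values())
    if smin == smax:
        return {k: 0.0 for k in scores}
    eps = tuning.epsilon
    if tuning.variant == 1:
        return {k: -eps * (s - smin) for k, s in scores.items()}
    if n_sites <= 0:
        raise ValueError("variant 2 requires the total site count N > 0")

    def lw(s: float) -> float:
        v_hat = s / n_sites + tuning.eta
        rho = tuning.rho_factor * (1.0 - math.exp(-4.0 * v_hat / 3.0))
        return eps * s * math.log(rho)

    ref = lw(smin)
    return {k: lw(s) - ref for k, s in scores.items()}


def _lse_excluding(logw: dict, exclude) -> float:
    vals = [w for k, w in logw.items() if k not in exclude]
    m = max(vals)
    return m + math.log(sum(math.exp(w - m) for w in vals))


def log_hastings_guided(logw: dict, b, r) -> float:
    """Exact log proposal ratio of a Metropolized guided choice.

    Forward picks r from candidates minus {b}; reverse picks b from
    candidates minus {r}.
    """
    if b == r:
        raise TreeError("old and new attachment must differ")
    if b not in logw or r not in logw:
        raise TreeError("b and r must be candidates")
    return (logw[b] - _lse_excluding(logw, (r,))) - (logw[r] - _lse_excluding(logw, (b,)))


def _sample_by_logweight(logw: dict, exclude, rng):
    keys = sorted(k for k in logw if k not in exclude)
    if not keys:
        return None
    m = max(logw[k] for k in keys)
    ws = [math.exp(logw[k] - m) for k in keys]
    u = rng.random() * sum(ws)
    acc = 0.0
    for k, w in zip(keys, ws):
        acc += w
        if u <= acc:
            return k
    return keys[-1]


# ---------------------------------------------------------------------------
# Branch-length scaler
# ---------------------------------------------------------------------------


def scale_branch(v: float, lam: float, rng) -> tuple:
    """Multiplier proposal v' = v * exp(lam*(u - 1/2)); returns (v', log m).

    The log Hastings contribution of a scaler is log m.  With
    lam = 2 ln 1.05 the multiplier is bounded by [1/1.05, 1.05].
    """
    if v <= 0:
        raise TreeError("scaler move undefined for nonpositive branch length")
    if lam <= 0:
        raise TreeError("scaler tuning must be positive")
    logm = lam * (rng.random() - 0.5)
    return v * math.exp(logm), logm


def _scale_branches(tree: UnrootedTree, branch_ids, lam: float, rng) -> float:
    total = 0.0
    for bid in branch_ids:
        rec = tree.branches[bid]
        v2, logm = scale_branch(rec[2], lam, rng)
        rec[2] = v2
        total += logm
    return total


# ---------------------------------------------------------------------------
# The extension walk shared by eSPR and eTBR
# ---------------------------------------------------------------------------


def _extension_walk(tree: UnrootedTree, x: int, avoid: int, p_e: float, rng):
    """Stochastic regraft walk from junction x (ignoring branch ``avoid``).

    Returns (r, forced_start, forced_end, n_steps) or None when the walk
    has nowhere to go (both neighbors of the merged attachment branch are
    tips).  forced_start: the initial direction was dictated by a tip at
    one end of the merged branch.  forced_end: the walk stopped because it
    reached a pendant branch.
    """
    c1, c2 = [b for b in tree.adj[x] if b != avoid]
    y1 = tree.other_end(c1, x)
    y2 = tree.other_end(c2, x)
    t1 = tree.is_tip(y1)
    t2 = tree.is_tip(y2)
    if t1 and t2:
        return None
    if t1:
        forced_start, prev_b, node = True, c2, y2
    elif t2:
        forced_start, prev_b, node = True, c1, y1
    else:
        forced_start = False
        if rng.random() < 0.5:
            prev_b, node = c1, y1
        else:
            prev_b, node = c2, y2
    steps = 0
    while True:
        o1, o2 = (b for b in tree.adj[node] if b != prev_b)
        nb = o1 if rng.random() < 0.5 else o2
        steps += 1
        far = tree.other_end(nb, node)
        if tree.is_tip(far):
            return nb, forced_start, True, steps
        if rng.random() >= p_e:
            return nb, forced_start, False, steps
        prev_b, node = nb, far


def _walk_log_hastings(forced_start: bool, forced_end: bool, p_e: float) -> float:
    """Exact reverse/forward path-probability ratio of one extension walk.

    The reverse walk's initial direction is forced exactly when the forward
    walk's stop was tip-forced, and vice versa; interior direction choices
    and continuation probabilities cancel.
    """
    log_stop = math.log(1.0 - p_e)
    fwd = (0.0 if forced_start else LOG_HALF) + (0.0 if forced_end else log_stop)
    rev = (0.0 if forced_end else LOG_HALF) + (0.0 if forced_start else log_stop)
    return rev - fwd


# ---------------------------------------------------------------------------
# Individual proposals
# ---------------------------------------------------------------------------


def _pick_spr_site(tree: UnrootedTree, rng):
    """Pick branch a and moving side for an SPR-type move.

    Returns (a, head, x) or None if the pick leaves a remainder of fewer
    than 3 taxa (no valid regraft; the caller treats this as a rejected
    step, keeping pick probabilities topology-independent).
    """
    bids = tree.branch_ids()
    a = bids[rng.randrange(len(bids))]
    u, v, _ = tree.branches[a]
    if tree.is_tip(u):
        head = u
    elif tree.is_tip(v):
        head = v
    else:
        head = u if rng.random() < 0.5 else v
    x = v if head == u else u
    if tree.is_tip(x):
        return None
    if tree.n_tips - tree.subtree_size(a, head) < 3:
        return None
    return a, head, x


def _propose_snni(tree: UnrootedTree, tuning: MoveTuning, rng) -> ProposalResult:
    internal = sorted(tree.internal_branches())
    branch = internal[rng.randrange(len(internal))]
    second = rng.random() < 0.5
    t2 = _apply_nni(tree, branch, second)
    return ProposalResult(t2, 0.0, [], {"move": "sNNI", "branch": branch})


def _propose_espr(tree: UnrootedTree, tuning: MoveTuning, rng):
    site = _pick_spr_site(tree, rng)
    if site is None:
        return None
    a, head, x = site
    walk = _extension_walk(tree, x, a, tuning.p_e, rng)
    if walk is None:
        return None
    r, forced_start, forced_end, steps = walk
    log_h = _walk_log_hastings(forced_start, forced_end, tuning.p_e)
    t2, q, b = apply_spr_ids(tree, a, head, r)
    scaled = [a, q, b]
    log_h += _scale_branches(t2, scaled, tuning.lam, rng)
    info = {
        "move": "eSPR",
        "path_length": steps,
        "nni_equivalent": steps == 1,
        "constrained_forward": forced_end,
        "constrained_backward": forced_start,
        # the first candidate branch was pendant, so the stop was dictated
        # by a tip rather than by 1 - p_e (inflates the NNI fraction)
        "first_step_tip_forced": forced_end and steps == 1,
        "r": r,
    }
    return ProposalResult(t2, log_h, scaled, info)


def _propose_etbr(tree: UnrootedTree, tuning: MoveTuning, rng):
    internal = sorted(tree.internal_branches())
    if not internal:
        raise TreeError("eTBR requires an internal branch")
    a = internal[rng.randrange(len(internal))]
    x1, x2, _ = tree.branches[a]

    def movable(x: int) -> bool:
        c1, c2 = [b for b in tree.adj[x] if b != a]
        return not (tree.is_tip(tree.other_end(c1, x)) and tree.is_tip(tree.other_end(c2, x)))

    ends = (x1, x2)
    forced_idx = 0 if rng.random() < 0.5 else 1
    if not movable(ends[forced_idx]):
        return None
    other_idx = 1 - forced_idx
    other_movable = movable(ends[other_idx])
    move_other = other_movable and rng.random() < 0.5

    walks = [None, None]
    for idx in (0, 1):
        if idx == forced_idx or (idx == other_idx and move_other):
            walks[idx] = _extension_walk(tree, ends[idx], a, tuning.p_e, rng)

    log_h = 0.0
    nni_steps = []
    forced_first_tip = False
    for idx, w in enumerate(walks):
        if w is not None:
            _r, fs, fe, steps = w
            log_h += _walk_log_hastings(fs, fe, tuning.p_e)
            nni_steps.append(steps)
            if idx == forced_idx:
                forced_first_tip = fe and steps == 1
    r1 = walks[0][0] if walks[0] else None
    r2 = walks[1][0] if walks[1] else None
    t2, ids1, ids2 = apply_tbr_ids(tree, a, r1, r2)
    scaled = [a]
    if ids1:
        scaled.append(ids1[0])
    if ids2:
        scaled.append(ids2[0])
    log_h += _scale_branches(t2, scaled, tuning.lam, rng)
    info = {
        "move": "eTBR",
        "sides_moved": sum(w is not None for w in walks),
        "nni_equivalent": len(nni_steps) == 1 and nni_steps[0] == 1,
        "first_step_tip_forced": forced_first_tip or not other_movable,
        "path_lengths": nni_steps,
    }
    return ProposalResult(t2, log_h, scaled, info)


def _propose_pspr_nodata(tree: UnrootedTree, tuning: MoveTuning, rng, a, head, x):
    """Guided SPR with no guide data: all scores are zero, so the regraft
    choice is uniform over the remainder branches minus the current
    attachment, and the guided proposal ratio vanishes exactly."""
    c1, c2 = (b for b in tree.adj[x] if b != a)
    # exclude the moving subtree's branches and the merged attachment
    banned = {a, c1, c2}
    seen = {head}
    stack = [head]
    while stack:
        nd = stack.pop()
        for b in tree.adj[nd]:
            if b == a:
                continue
            banned.add(b)
            nb = tree.other_end(b, nd)
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    candidates = [b for b in tree.branches if b not in banned]
    r = candidates[rng.randrange(len(candidates))]
    t2, q, b_id = apply_spr_ids(tree, a, head, r)
    scaled = [a, q, b_id]
    log_h = _scale_branches(t2, scaled, tuning.lam, rng)
    info = {
        "move": f"pSPR{tuning.variant}",
        "a": a,
        "head": head,
        "r": r,
        "merged": min(c1, c2),
        "q": q,
        "b_left": b_id,
        "topology_log_hastings": 0.0,
        "n_candidates": len(candidates) + 1,
        "score_r": 0,
        "score_b": 0,
    }
    return ProposalResult(t2, log_h, scaled, info)


def _propose_pspr(tree: UnrootedTree, tuning: MoveTuning, rng, guide):
    site = _pick_spr_site(tree, rng)
    if site is None:
        return None
    a, head, x = site
    if guide is None:
        return _propose_pspr_nodata(tree, tuning, rng, a, head, x)
    ctx = prune_context(tree, a, head, guide)
    scores = regraft_scores(ctx)
    n_sites = guide.n_sites if guide is not None else 0
    logw = guide_weights(scores, tuning, n_sites)
    b = ctx.merged_branch
    r = _sample_by_logweight(logw, (b,), rng)
    if r is None:
        return None
    topo_h = log_hastings_guided(logw, b, r)
    t2, q, b_id = apply_spr_ids(tree, a, head, r)
    scaled = [a, q, b_id]
    log_h = topo_h + _scale_branches(t2, scaled, tuning.lam, rng)
    info = {
        "move": f"pSPR{tuning.variant}",
        "a": a,
        "head": head,
        "r": r,
        "merged": b,
        "q": q,
        "b_left": b_id,
        "topology_log_hastings": topo_h,
        "n_candidates": len(logw),
        "score_r": scores[r],
        "score_b": scores[b],
    }
    return ProposalResult(t2, log_h, scaled, info)


def _tbr_side_candidates(tree: UnrootedTree, a: int, x: int, delta: int):
    """Reconnection candidates within ``delta`` nodes of junction x, computed
    on the intact tree (x treated as suppressed).  The two branches at x
    merge into one candidate labelled min of their ids (the bisected
    half's merged branch)."""
    c1, c2 = (b for b in tree.adj[x] if b != a)
    merged = c1 if c1 < c2 else c2
    dist = {merged: 0}
    frontier = []
    for via, node in ((c1, tree.other_end(c1, x)), (c2, tree.other_end(c2, x))):
        if not tree.is_tip(node):
            frontier.append((node, via, 0))
    while frontier:
        node, via, d = frontier.pop()
        if d + 1 > delta:
            continue
        for b in tree.adj[node]:
            if b == via:
                continue
            if b not in dist or dist[b] > d + 1:
                dist[b] = d + 1
                far = tree.other_end(b, node)
                if not tree.is_tip(far):
                    frontier.append((far, b, d + 1))
    return merged, sorted(dist)


def _propose_ptbr_nodata(tree: UnrootedTree, tuning: MoveTuning, rng, a):
    """Guided TBR with no guide data: uniform choice among reconnection
    pairs minus the identity; the proposal ratio reduces to the ratio of
    candidate-pair counts around the old and new attachment points."""
    x1, x2, _ = tree.branches[a]
    m1, side1 = _tbr_side_candidates(tree, a, x1, tuning.delta)
    m2, side2 = _tbr_side_candidates(tree, a, x2, tuning.delta)
    n_fwd = len(side1) * len(side2) - 1
    if n_fwd < 1:
        return None
    k = rng.randrange(n_fwd)
    pairs = [(i, j) for i in side1 for j in side2 if (i, j) != (m1, m2)]
    i, j = pairs[k]
    r1 = None if i == m1 else i
    r2 = None if j == m2 else j
    t2, ids1, ids2 = apply_tbr_ids(tree, a, r1, r2)
    _m1r, side1r = _tbr_side_candidates(t2, a, t2.branches[a][0], tuning.delta)
    _m2r, side2r = _tbr_side_candidates(t2, a, t2.branches[a][1], tuning.delta)
    b1 = ids1[1] if ids1 else m1
    b2 = ids2[1] if ids2 else m2
    if b1 not in side1r or b2 not in side2r:
        raise TreeError("reverse reconnection pair missing from its neighborhood")
    n_rev = len(side1r) * len(side2r) - 1
    log_h = math.log(n_fwd) - math.log(n_rev)
    scaled = [a]
    if ids1:
        scaled.append(ids1[0])
    if ids2:
        scaled.append(ids2[0])
    log_h += _scale_branches(t2, scaled, tuning.lam, rng)
    info = {
        "move": f"pTBR{tuning.variant}",
        "pair": (i, j),
        "n_candidates": n_fwd + 1,
        "score_pair": 0,
    }
    return ProposalResult(t2, log_h, scaled, info)


def _propose_ptbr(tree: UnrootedTree, tuning: MoveTuning, rng, guide):
    internal = sorted(tree.internal_branches())
    if not internal:
        raise TreeError("pTBR requires an internal branch")
    a = internal[rng.randrange(len(internal))]
    if guide is None:
        return _propose_ptbr_nodata(tree, tuning, rng, a)
    n_sites = guide.n_sites

    fwd = bisect_scores(tree, a, tuning.delta, guide)
    logw_f = guide_weights(fwd.scores, tuning, n_sites)
    pair = _sample_by_logweight(logw_f, (fwd.identity,), rng)
    if pair is None:
        return None
    log_fwd = logw_f[pair] - _lse_excluding(logw_f, (fwd.identity,))

    i, j = pair
    r1 = None if i == fwd.identity[0] else i
    r2 = None if j == fwd.identity[1] else j
    t2, ids1, ids2 = apply_tbr_ids(tree, a, r1, r2)

    # reverse: bisect the proposed tree; the pair that reconstructs the
    # current tree is (branch left behind on each moved side, or the merged
    # original-position branch on an unmoved side)
    rev = bisect_scores(t2, a, tuning.delta, guide)
    b1 = ids1[1] if ids1 else rev.identity[0]
    b2 = ids2[1] if ids2 else rev.identity[1]
    back_pair = (b1, b2)
    if back_pair not in rev.scores:
        raise TreeError("reverse reconnection pair missing from its neighborhood")
    logw_r = guide_weights(rev.scores, tuning, n_sites)
    log_rev = logw_r[back_pair] - _lse_excluding(logw_r, (rev.identity,))

    log_h = log_rev - log_fwd
    scaled = [a]
    if ids1:
        scaled.append(ids1[0])
    if ids2:
        scaled.append(ids2[0])
    log_h += _scale_branches(t2, scaled, tuning.lam, rng)
    info = {
        "move": f"pTBR{tuning.variant}",
        "pair": pair,
        "n_candidates": len(logw_f),
        "score_pair": fwd.scores[pair],
    }
    return ProposalResult(t2, log_h, scaled, info)


def propose(
    move: str,
    tree: UnrootedTree,
    tuning: Optional[MoveTuning],
    rng,
    guide_data=None,
) -> Optional[ProposalResult]:
    """Draw one proposal of the named move.

    Returns None when the randomly picked site admits no valid
    rearrangement (the chain counts this as a rejected step).  Raises
    TreeError when the move cannot apply to the tree at all.
    """
    n = tree.n_tips
    if move in ("sNNI", "eSPR", "pSPR1", "pSPR2"):
        if n < 4:
            raise TreeError(f"{move} requires at least 4 taxa")
    elif move in ("eTBR", "pTBR1", "pTBR2"):
        if n < 5:
            raise TreeError(f"{move} requires at least 5 taxa")
    else:
        raise TreeError(f"unknown move {move!r}")
    if tuning is None:
        tuning = MoveTuning.for_move(move)

    if move == "sNNI":
        return _propose_snni(tree, tuning, rng)
    if move == "eSPR":
        return _propose_espr(tree, tuning, rng)
    if move == "eTBR":
        return _propose_etbr(tree, tuning, rng)
    if move in ("pSPR1", "pSPR2"):
        return _propose_pspr(tree, tuning, rng, guide_data)
    return _propose_ptbr(tree, tuning, rng, guide_data)
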