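"""Sequence simulation on trees, and the long-branch-attraction fixture.

``evolve`` draws a root state from the stationary frequencies and walks
the tree, applying the model's transition probabilities branch by branch;
with a finite gamma shape, per-site rates are drawn from Gamma(alpha,
alpha).  ``lba_fixture`` builds the classic five-taxon geometry — two
long terminal branches separated by a short internal one — under which
maximum parsimony is statistically inconsistent (it joins the long
branches), while likelihood-based inference recovers the generating tree.
The fixture's branch lengths (long 0.8, short 0.05) are this package's
reconstruction of that geometry, configurable by the caller.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .characters import PatternMatrix
from .likelihood import SubstModel, transition_matrix
from .treespace import UnrootedTree, parse_newick

__all__ = ["evolve", "lba_fixture", "write_fasta"]

_STATES = "ACGT"


def evolve(
    tree: UnrootedTree,
    model: SubstModel,
    n_sites: int,
    rng: np.random.Generator,
    return_patterns: bool = False,
):
    """Simulate an alignment of ``n_sites`` columns on ``tree``.

    Returns an ordered label->sequence dict (taxa sorted), or a
    PatternMatrix when ``return_patterns`` is set.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    if model.alpha is not None:
        rates = rng.gamma(model.alpha, 1.0 / model.alpha, size=n_sites)
    else:
        rates = np.ones(n_sites)

    first_tip = tree.node_of[min(tree.node_of)]
    root = tree.other_end(tree.adj[first_tip][0], first_tip)
    states = {root: rng.choice(4, size=n_sites, p=model.freqs)}

    # unique rates are few only without gamma; group sites by rate lazily
    stack = [(None, root)]
    while stack:
        via, node = stack.pop()
        for b in tree.adj[node]:
            if b == via:
                continue
            child = tree.other_end(b, node)
            v = tree.branches[b][2]
            parent_states = states[node]
            child_states = np.empty(n_sites, dtype=np.int64)
            if model.alpha is None:
                p = transition_matrix(model, v)
                cum = p.cumsum(axis=1)
                u = rng.random(n_sites)
                child_states = (u[:, None] > cum[parent_states]).sum(axis=1)
            else:
                u = rng.random(n_sites)
                for s in range(n_sites):
                    p = transition_matrix(model, v, rates[s])
                    child_states[s] = np.searchsorted(p[parent_states[s]].cumsum(), u[s])
            states[child] = child_states
            stack.append((b, child))

    seqs = {
        lab: "".join(_STATES[s] for s in states[node])
        for lab, node in sorted(tree.node_of.items())
    }
    if return_patterns:
        return PatternMatrix.from_sequences(seqs)
    return seqs


def lba_fixture(
    long: float = 0.8,
    short: float = 0.05,
    n_sites: int = 10000,
    kappa: float = 4.0,
    rng: Optional[np.random.Generator] = None,
):
    """Five-taxon long-branch-attraction benchmark.

    True tree: ((A:short, C:long):short, (B:short, D:long):short, E:short)
    — the long branches (C, D) are separated by the short internal branch.
    Sequences evolve under K80 with the given kappa.  Returns
    (true tree, label->sequence dict).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    nwk = (
        f"((A:{short},C:{long}):{short},(B:{short},D:{long}):{short},E:{short});"
    )
    tree = parse_newick(nwk)
    model = SubstModel(name="K80", kappa=kappa)
    seqs = evolve(tree, model, n_sites, rng)
    return tree, seqs


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
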