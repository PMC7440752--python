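"""Convergence summaries: split frequencies, ASDSF, topology posteriors.

The ASDSF (average standard deviation of split frequencies) compares two
or more independent runs: over all nontrivial splits whose frequency
reaches ``min_freq`` in at least one run, take the across-run standard
deviation (n-1 denominator) of the per-run frequencies and average.
Identical runs give exactly 0; the reference convergence threshold in the
literature is 0.02.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .treespace import UnrootedTree, parse_newick

__all__ = ["SplitTable", "split_frequencies", "asdsf", "topology_posterior", "read_tree_samples"]


@dataclass
class SplitTable:
    """Sampled frequency of every nontrivial split in one run."""

    frequencies: dict  # frozenset(taxa subset) -> frequency in [0, 1]
    n_samples: int
    burnin_frac: float
    taxa: frozenset


def _as_trees(samples) -> list:
    out = []
    for item in samples:
        if isinstance(item, UnrootedTree):
            out.append(item)
        elif isinstance(item, str):
            out.append(parse_newick(item))
        elif isinstance(item, tuple) and len(item) == 2:
            out.append(item[1] if isinstance(item[1], UnrootedTree) else parse_newick(item[1]))
        else:
            raise ValueError(f"cannot interpret tree sample {item!r}")
    return out


def split_frequencies(samples: Iterable, burnin_frac: float = 0.0) -> SplitTable:
    """Nontrivial-split frequencies among post-burn-in samples.

    ``samples`` may hold UnrootedTree objects, Newick strings, or
    (generation, tree) pairs.
    """
    trees = _as_trees(list(samples))
    start = int(len(trees) * burnin_frac)
    trees = trees[start:]
    if not trees:
        raise ValueError("no post-burn-in samples")
    taxa = frozenset(trees[0].node_of)
    counts: dict = {}
    for t in trees:
        if frozenset(t.node_of) != taxa:
            raise ValueError("inconsistent taxon sets across samples")
        for split in t.topology_key():
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    return SplitTable(
        frequencies={s: c / n for s, c in counts.items()},
        n_samples=n,
        burnin_frac=burnin_frac,
        taxa=taxa,
    )


def asdsf(tables: Iterable[SplitTable], min_freq: float = 0.10) -> float:
    """Average across-run SD of split frequencies over qualifying splits.

    A split qualifies when its frequency is >= min_freq in at least one
    run.  Runs where a qualifying split never appears contribute frequency
    0.  With no qualifying split the diagnostic is defined as 0.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("ASDSF needs at least two runs")
    taxa = tables[0].taxa
    if any(t.taxa != taxa for t in tables):
        raise ValueError("runs cover different taxon sets")
    qualifying = set()
    for t in tables:
        qualifying.update(s for s, f in t.frequencies.items() if f >= min_freq)
    if not qualifying:
        return 0.0
    k = len(tables)
    total = 0.0
    for split in qualifying:
        freqs = [t.frequencies.get(split, 0.0) for t in tables]
        mean = sum(freqs) / k
        var = sum((f - mean) ** 2 for f in freqs) / (k - 1)
        total += math.sqrt(var)
    return total / len(qualifying)


def topology_posterior(samples: Iterable, burnin_frac: float = 0.0) -> dict:
    """Normalized sampled frequency of each topology key."""
    items = list(samples)
    # fast path: already topology keys (frozenset of frozensets)
    if items and isinstance(items[0], frozenset):
        keys = items[int(len(items) * burnin_frac):]
    else:
        trees = _as_trees(items)
        keys = [t.topology_key() for t in trees[int(len(trees) * burnin_frac):]]
    if not keys:
        raise ValueError("no post-burn-in samples")
    counts: dict = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    n = len(keys)
    return {k: c / n for k, c in counts.items()}


def read_tree_samples(path) -> list:
    """Read a tree-sample file (generation <TAB> Newick per line)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if "\t" in line:
                gen, nwk = line.split("\t", 1)
            else:
                gen, nwk = len(out), line
            out.append((int(gen), parse_newick(nwk)))
    return out
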