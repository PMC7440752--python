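"""Felsenstein pruning likelihood under JC69, K80 and GTR (+ discrete gamma).

Transition probabilities use closed forms for JC69/K80 and a cached
eigendecomposition for GTR (rate matrix scaled to one expected
substitution per site per unit branch length).  Rate variation across
sites uses K equal-probability gamma categories with *mean* category
rates.  Conditional likelihoods are rescaled at every internal node, so
deep trees and long alignments do not underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .characters import PatternMatrix
from .treespace import TreeError, UnrootedTree

__all__ = ["SubstModel", "transition_matrix", "log_likelihood", "discrete_gamma_rates"]

_STATE_BITS = (1, 2, 4, 8)  # A, C, G, T


@dataclass
class SubstModel:
    """Reversible nucleotide substitution model.

    name: "JC69", "K80" (kappa = transition/transversion rate ratio) or
    "GTR" (six exchangeabilities in AC, AG, AT, CG, CT, GT order plus
    stationary frequencies).  ``alpha`` switches on discrete-gamma rate
    variation with ``ncat`` categories; None means equal rates.
    """

    name: str = "JC69"
    kappa: float = 4.0
    exch: Optional[np.ndarray] = None
    freqs: Optional[np.ndarray] = None
    alpha: Optional[float] = None
    ncat: int = 4
    free_exch: bool = False
    free_alpha: bool = False
    _eig_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.name not in ("JC69", "K80", "GTR"):
            raise ValueError(f"unknown model {self.name!r}")
        if self.freqs is None:
            self.freqs = np.full(4, 0.25)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if abs(self.freqs.sum() - 1.0) > 1e-8 or np.any(self.freqs <= 0):
            raise ValueError("base frequencies must be positive and sum to 1")
        if self.name in ("JC69", "K80") and not np.allclose(self.freqs, 0.25):
            raise ValueError(f"{self.name} requires equal base frequencies")
        if self.name == "GTR":
            if self.exch is None:
                self.exch = np.full(6, 1.0 / 6.0)
            self.exch = np.asarray(self.exch, dtype=float)
            if self.exch.shape != (6,) or np.any(self.exch <= 0):
                raise ValueError("GTR needs 6 positive exchangeabilities")
            self.exch = self.exch / self.exch.sum()
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.ncat < 1:
            raise ValueError("need at least one rate category")

    # -- rate matrix -------------------------------------------------------

    def rate_matrix(self) -> np.ndarray:
        """Q scaled so the mean substitution rate is 1."""
        pi = self.freqs
        if self.name == "JC69":
            s = np.full((4, 4), 1.0)
        elif self.name == "K80":
            s = np.full((4, 4), 1.0)
            s[0, 2] = s[2, 0] = self.kappa  # A<->G
            s[1, 3] = s[3, 1] = self.kappa  # C<->T
        else:
            s = np.zeros((4, 4))
            pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
            for rate, (i, j) in zip(self.exch, pairs):
                s[i, j] = s[j, i] = rate
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def _eigen(self):
        key = (self.name, self.kappa, tuple(np.round(self.freqs, 15)),
               tuple(np.round(self.exch, 15)) if self.exch is not None else None)
        hit = self._eig_cache.get(key)
        if hit is not None:
            return hit
        q = self.rate_matrix()
        pi = self.freqs
        sq = np.sqrt(pi)
        sym = (q * sq[:, None]) / sq[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        left = u.T * sq[None, :]
        right = u / sq[:, None]
        self._eig_cache.clear()
        self._eig_cache[key] = (lam, right, left)
        return lam, right, left

    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.ncat)


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean rates of K equal-probability categories of Gamma(alpha, alpha)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if ncat == 1:
        return np.ones(1)
    bounds = _gamma_dist.ppf(np.arange(1, ncat) / ncat, alpha, scale=1.0 / alpha)
    upper = np.concatenate([alpha * bounds, [np.inf]])
    lower = np.concatenate([[0.0], alpha * bounds])
    cdf_hi = np.where(np.isinf(upper), 1.0, gammainc(alpha + 1.0, upper))
    cdf_lo = gammainc(alpha + 1.0, lower)
    return ncat * (cdf_hi - cdf_lo)


def transition_matrix(model: SubstModel, v: float, rate: float = 1.0) -> np.ndarray:
    """P(v * rate): 4x4 stochastic matrix of state-change probabilities."""
    if v < 0:
        raise TreeError("branch length must be nonnegative")
    d = v * rate
    if model.name == "JC69":
        e = math.exp(-4.0 * d / 3.0)
        off = 0.25 - 0.25 * e
        same = 0.25 + 0.75 * e
        return np.array(
            [
                [same, off, off, off],
                [off, same, off, off],
                [off, off, same, off],
                [off, off, off, same],
            ]
        )
    if model.name == "K80":
        k = model.kappa
        beta = 1.0 / (k + 2.0)
        e4 = math.exp(-4.0 * beta * d)
        e2 = math.exp(-2.0 * beta * (k + 1.0) * d)
        same = 0.25 + 0.25 * e4 + 0.5 * e2
        ts = 0.25 + 0.25 * e4 - 0.5 * e2
        tv = 0.25 - 0.25 * e4
        return np.array(
            [
                [same, tv, ts, tv],
                [tv, same, tv, ts],
                [ts, tv, same, tv],
                [tv, ts, tv, same],
            ]
        )
    lam, right, left = model._eigen()
    return (right * np.exp(lam * d)[None, :]) @ left


def _tip_conditionals(tree: UnrootedTree, data: PatternMatrix) -> dict:
    # per-label conditionals depend only on the data; cache them on it
    cache = getattr(data, "_tip_conditionals", None)
    if cache is None:
        cache = {}
        for i, lab in enumerate(data.taxa):
            codes = data.codes[i]
            cond = np.empty((4, codes.shape[0]))
            for s, bit in enumerate(_STATE_BITS):
                cond[s] = (codes & bit) != 0
            cache[lab] = cond
        object.__setattr__(data, "_tip_conditionals", cache)
    missing = [lab for lab in tree.node_of if lab not in cache]
    if missing:
        raise TreeError(f"taxa on tree but not in data: {sorted(missing)}")
    return {node: cache[lab] for lab, node in tree.node_of.items()}


def log_likelihood(
    tree: UnrootedTree,
    data: PatternMatrix,
    model: SubstModel,
    root: Optional[int] = None,
) -> float:
    """Pruning log likelihood, invariant to virtual-root placement."""
    tips = _tip_conditionals(tree, data)
    if root is None:
        first_tip = tree.node_of[min(tree.node_of)]
        root = tree.other_end(tree.adj[first_tip][0], first_tip)
    if tree.is_tip(root):
        root = tree.other_end(tree.adj[root][0], root)

    rates = model.category_rates()
    pi = model.freqs
    if len(rates) == 1:
        cond, scale_log = _pruning_pass(tree, tips, model, root, float(rates[0]))
        site = pi @ cond
        if np.any(site <= 0):
            raise TreeError("zero site likelihood (numerical failure)")
        total = float(data.weights @ (np.log(site) + scale_log))
    else:
        npat = data.n_patterns
        site_log = np.full((len(rates), npat), -np.inf)
        for ci, rate in enumerate(rates):
            cond, scale_log = _pruning_pass(tree, tips, model, root, float(rate))
            site = pi @ cond
            if np.any(site <= 0):
                raise TreeError("zero site likelihood (numerical failure)")
            site_log[ci] = np.log(site) + scale_log
        m = site_log.max(axis=0)
        site_total = m + np.log(np.mean(np.exp(site_log - m[None, :]), axis=0))
        total = float(data.weights @ site_total)
    if not math.isfinite(total):
        raise TreeError("non-finite log likelihood")
    return total


def _pruning_pass(tree: UnrootedTree, tips: dict, model: SubstModel, root: int, rate: float):
    """Postorder conditional likelihoods at ``root``; returns (cond, per-pattern
    log scaling accumulated across internal nodes).

    Every internal node is rescaled by its per-pattern peak; the peaks are
    accumulated as a running product and flushed to log space whenever
    they threaten to underflow, so the cost of the safeguard is one
    logarithm per ~250 orders of magnitude rather than one per node.
    """
    tip_label = tree.tip_label
    adj = tree.adj
    branches = tree.branches
    npat = next(iter(tips.values())).shape[1]
    scale_log = np.zeros(npat)
    scale_prod = np.ones(npat)
    memo: dict = {}

    stack = [(None, root)]
    order = []
    append = order.append
    while stack:
        via, node = stack.pop()
        append((via, node))
        if node not in tip_label:
            for b in adj[node]:
                if b != via:
                    u, v, _ = branches[b]
                    stack.append((b, v if node == u else u))
    for via, node in reversed(order):
        if node in tip_label:
            memo[node] = tips[node]
            continue
        cond = None
        for b in adj[node]:
            if b == via:
                continue
            u, v, ln = branches[b]
            child = v if node == u else u
            part = transition_matrix(model, ln, rate) @ memo[child]
            cond = part if cond is None else cond * part
        peak = cond.max(axis=0)
        peak[peak == 0.0] = 1.0
        cond /= peak
        scale_prod *= peak
        if scale_prod.min() < 1e-250:
            scale_log += np.log(scale_prod)
            scale_prod.fill(1.0)
        memo[node] = cond
    if np.any(scale_prod != 1.0):
        scale_log = scale_log + np.log(scale_prod)
    return memo[root], scale_log
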