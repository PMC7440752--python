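"""Metropolis–Hastings driver: schedules, single chains, Metropolis coupling.

One proposal is drawn per generation from a weighted move schedule.  A
proposal is accepted with probability

    min(1, exp(beta * dlogL + dlogPrior + logHastings))

where beta is the chain temperature (1 for the cold chain; heated chains
use beta_i = 1 / (1 + heat * i)).  With Metropolis coupling, one random
pair of chains attempts a state swap each generation; only the cold chain
is sampled.

Running with no data ("constant likelihood") turns the sampler into a
prior sampler — the validation mode in which every correctly
Hastings-corrected tree move must recover the uniform distribution over
topologies.  Guide data for the parsimony-guided moves can be supplied
independently of the likelihood data (e.g. a prefix of an alignment while
the likelihood stays constant), which stress-tests the proposal-ratio
correction against deliberately misleading guidance.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from typing import Optional

from .characters import PatternMatrix
from .likelihood import SubstModel, log_likelihood
from .moves import MOVE_NAMES, MoveTuning, propose, scale_branch
from .priors import PriorConfig, log_prior
from .treespace import UnrootedTree, enumerate_trees, parse_newick, write_newick

__all__ = ["ChainState", "Schedule", "RunConfig", "RunResult", "mh_step", "run", "random_tree"]

BRANCH_MOVES = ("brlen_scaler", "treelength_scaler")
PARAM_MOVES = ("shape_scaler", "exch_dirichlet")

TREELENGTH_LAM = 2.0 * math.log(1.25)
SHAPE_LAM = 2.0 * math.log(1.5)
EXCH_CONC = 300.0


@dataclass
class ChainState:
    """Tree + model parameters + cached log prior / log likelihood."""

    tree: UnrootedTree
    model: Optional[SubstModel]
    data: Optional[PatternMatrix]
    guide_data: Optional[PatternMatrix]
    priors: PriorConfig
    log_prior: float = 0.0
    log_lik: float = 0.0
    beta: float = 1.0

    def recompute(self) -> None:
        self.log_prior = log_prior(self.tree, self.priors, self.model)
        if self.data is not None:
            self.log_lik = log_likelihood(self.tree, self.data, self.model)
        else:
            self.log_lik = 0.0


@dataclass
class Schedule:
    """Weighted list of (move name, relative weight)."""

    entries: list

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty schedule")
        for name, w in self.entries:
            if w <= 0:
                raise ValueError(f"nonpositive weight for {name}")
            if name not in MOVE_NAMES and name not in BRANCH_MOVES and name not in PARAM_MOVES:
                raise ValueError(f"unknown move {name!r}")

    def category_mass(self) -> dict:
        out = {"tree": 0.0, "brlen": 0.0, "param": 0.0}
        for name, w in self.entries:
            if name in MOVE_NAMES:
                out["tree"] += w
            elif name in BRANCH_MOVES:
                out["brlen"] += w
            else:
                out["param"] += w
        total = sum(out.values())
        return {k: v / total for k, v in out.items()}

    # -- presets ----------------------------------------------------------

    @classmethod
    def simulation(cls, tree_move: str = "pSPR2") -> "Schedule":
        """5:1 tree proposal : branch-length scaler (prior-recovery runs)."""
        return cls([(tree_move, 5.0), ("brlen_scaler", 1.0)])

    @classmethod
    def reference(cls, with_params: bool = True) -> "Schedule":
        """1 sNNI : 2 eSPR : 1 eTBR : 2 pSPR2 : 1 pTBR2 at 46.67% total,
        branch-length moves 50%, substitution-model moves 3.33%."""
        mix = [("sNNI", 1.0), ("eSPR", 2.0), ("eTBR", 1.0), ("pSPR2", 2.0), ("pTBR2", 1.0)]
        tree_w = 46.67 / 7.0
        entries = [(m, w * tree_w) for m, w in mix]
        entries += [("brlen_scaler", 50.0 * 0.8), ("treelength_scaler", 50.0 * 0.2)]
        if with_params:
            entries += [("shape_scaler", 3.33 / 2.0), ("exch_dirichlet", 3.33 / 2.0)]
        return cls(entries)

    @classmethod
    def test(cls, mix: str = "pSPR2+pTBR2", with_params: bool = False) -> "Schedule":
        """36% tree (2 SPR : 1 TBR within the named mix), 60% branch
        lengths, 4% substitution parameters (dropped when the model has
        no free parameters)."""
        pairs = {
            "eSPR+eTBR": (("eSPR", 2.0), ("eTBR", 1.0)),
            "pSPR1+pTBR1": (("pSPR1", 2.0), ("pTBR1", 1.0)),
            "pSPR2+pTBR2": (("pSPR2", 2.0), ("pTBR2", 1.0)),
        }
        if mix not in pairs:
            raise ValueError(f"unknown mix {mix!r}")
        (m1, w1), (m2, w2) = pairs[mix]
        entries = [(m1, 36.0 * w1 / 3.0), (m2, 36.0 * w2 / 3.0)]
        brlen = 60.0 if with_params else 64.0
        entries += [("brlen_scaler", brlen * 0.8), ("treelength_scaler", brlen * 0.2)]
        if with_params:
            entries += [("shape_scaler", 2.0), ("exch_dirichlet", 2.0)]
        return cls(entries)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run from a seed."""

    generations: int
    sample_every: int = 100
    seed: int = 1
    burnin_frac: float = 0.25
    n_taxa: Optional[int] = None  # for constant-likelihood runs
    data: Optional[PatternMatrix] = None
    guide_sites: Optional[int] = None  # prefix of guide data used for parsimony
    guide_data: Optional[PatternMatrix] = None
    model: Optional[SubstModel] = None
    priors: PriorConfig = field(default_factory=PriorConfig)
    schedule: Schedule = field(default_factory=Schedule.reference)
    tuning: dict = field(default_factory=dict)  # move name -> MoveTuning
    chains: int = 1
    heat: float = 0.1
    start_tree: Optional[str] = None  # Newick; None = random topology

    def __post_init__(self) -> None:
        errors = []
        if self.generations < 1:
            errors.append("generations must be >= 1")
        if self.sample_every < 1:
            errors.append("sample_every must be >= 1")
        if not 0.0 <= self.burnin_frac < 1.0:
            errors.append("burnin_frac must be in [0, 1)")
        if (
            self.data is None
            and self.guide_data is None
            and self.n_taxa is None
            and self.start_tree is None
        ):
            errors.append("need data, guide data, n_taxa, or a starting tree")
        if self.data is not None and self.model is None:
            errors.append("data requires a substitution model")
        if self.chains < 1:
            errors.append("chains must be >= 1")
        if self.chains > 1 and self.heat <= 0:
            errors.append("heat must be > 0 with multiple chains")
        if self.guide_sites is not None and self.guide_data is None and self.data is None:
            errors.append("guide_sites needs guide_data or data")
        if errors:
            raise ValueError("invalid run config: " + "; ".join(errors))


@dataclass
class RunResult:
    """Cold-chain samples and bookkeeping from one run."""

    tree_samples: list  # (generation, newick string)
    topology_samples: list  # (generation, TopologyKey)
    trace: list  # dicts: generation, log_lik, log_prior, tree_length
    accept_counts: dict  # move -> [accepted, proposed]
    swap_counts: list  # [accepted, attempted]
    config: RunConfig

    def burnin_index(self) -> int:
        return int(len(self.tree_samples) * self.config.burnin_frac)

    def retained_topologies(self) -> list:
        return [k for _g, k in self.topology_samples[self.burnin_index():]]


def random_tree(labels, rng, branch_length: float = 0.1) -> UnrootedTree:
    """Random topology by stepwise addition at uniformly chosen branches."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    t = UnrootedTree()
    center = t.new_node()
    for lab in labels[:3]:
        t.new_branch(center, t.new_node(lab), branch_length)
    for lab in labels[3:]:
        bids = t.branch_ids()
        b = bids[rng.randrange(len(bids))]
        u, v, ln = t.branches[b]
        mid = t.new_node()
        tip = t.new_node(lab)
        t.adj[v].remove(b)
        t.branches[b][1] = mid
        t.branches[b][2] = ln
        t.adj[mid].append(b)
        t.new_branch(mid, v, branch_length)
        t.new_branch(mid, tip, branch_length)
    return t


# ---------------------------------------------------------------------------
# Single MH step
# ---------------------------------------------------------------------------


def mh_step(state: ChainState, move: str, tuning: Optional[MoveTuning], rng) -> bool:
    """One Metropolis–Hastings update in place; returns acceptance."""
    if move in MOVE_NAMES:
        return _tree_update(state, move, tuning, rng)
    if move == "brlen_scaler":
        return _brlen_update(state, rng, tuning)
    if move == "treelength_scaler":
        return _treelength_update(state, rng)
    if move == "shape_scaler":
        return _shape_update(state, rng)
    if move == "exch_dirichlet":
        return _exch_update(state, rng)
    raise ValueError(f"unknown move {move!r}")


def _accept(state: ChainState, new_tree, new_prior, new_lik, log_h, rng) -> bool:
    if not math.isfinite(new_lik):
        return False
    delta = state.beta * (new_lik - state.log_lik) + (new_prior - state.log_prior) + log_h
    if delta >= 0.0 or rng.random() < math.exp(delta):
        if new_tree is not None:
            state.tree = new_tree
        state.log_prior = new_prior
        state.log_lik = new_lik
        return True
    return False


def _tree_update(state: ChainState, move: str, tuning, rng) -> bool:
    result = propose(move, state.tree, tuning, rng, guide_data=state.guide_data)
    if result is None:
        return False
    new_prior = log_prior(result.tree, state.priors, state.model)
    if new_prior == float("-inf"):
        return False
    if state.data is not None:
        new_lik = log_likelihood(result.tree, state.data, state.model)
    else:
        new_lik = 0.0
    return _accept(state, result.tree, new_prior, new_lik, result.log_hastings, rng)


def _brlen_update(state: ChainState, rng, tuning=None) -> bool:
    lam = tuning.lam if tuning is not None else 2.0 * math.log(1.05)
    t = state.tree
    bids = sorted(t.branches)
    bid = bids[rng.randrange(len(bids))]
    old = t.branches[bid][2]
    if old <= 0:
        return False
    new, logm = scale_branch(old, lam, rng)
    t.branches[bid][2] = new
    new_prior = log_prior(t, state.priors, state.model)
    new_lik = (
        log_likelihood(t, state.data, state.model) if state.data is not None else 0.0
    )
    if _accept(state, None, new_prior, new_lik, logm, rng):
        return True
    t.branches[bid][2] = old
    return False


def _treelength_update(state: ChainState, rng) -> bool:
    t = state.tree
    logm = TREELENGTH_LAM * (rng.random() - 0.5)
    m = math.exp(logm)
    old = {bid: rec[2] for bid, rec in t.branches.items()}
    for rec in t.branches.values():
        rec[2] *= m
    new_prior = log_prior(t, state.priors, state.model)
    new_lik = (
        log_likelihood(t, state.data, state.model) if state.data is not None else 0.0
    )
    if _accept(state, None, new_prior, new_lik, len(old) * logm, rng):
        return True
    for bid, v in old.items():
        t.branches[bid][2] = v
    return False


def _shape_update(state: ChainState, rng) -> bool:
    model = state.model
    if model is None or not model.free_alpha or model.alpha is None:
        return False
    old = model.alpha
    logm = SHAPE_LAM * (rng.random() - 0.5)
    model.alpha = old * math.exp(logm)
    new_prior = log_prior(state.tree, state.priors, model)
    new_lik = (
        log_likelihood(state.tree, state.data, model) if state.data is not None else 0.0
    )
    if _accept(state, None, new_prior, new_lik, logm, rng):
        return True
    model.alpha = old
    return False


def _exch_update(state: ChainState, rng) -> bool:
    model = state.model
    if model is None or model.name != "GTR" or not model.free_exch:
        return False
    old = model.exch.copy()
    draws = [rng.gammavariate(EXCH_CONC * x, 1.0) for x in old]
    total = sum(draws)
    new = [d / total for d in draws]
    if min(new) <= 1e-12:
        return False
    log_h = _dirichlet_logpdf(old, [EXCH_CONC * x for x in new]) - _dirichlet_logpdf(
        new, [EXCH_CONC * x for x in old]
    )
    import numpy as np

    model.exch = np.asarray(new)
    new_prior = log_prior(state.tree, state.priors, model)
    new_lik = (
        log_likelihood(state.tree, state.data, model) if state.data is not None else 0.0
    )
    if _accept(state, None, new_prior, new_lik, log_h, rng):
        return True
    model.exch = old
    return False


def _dirichlet_logpdf(x, alpha) -> float:
    out = math.lgamma(sum(alpha))
    for xi, ai in zip(x, alpha):
        out += (ai - 1.0) * math.log(xi) - math.lgamma(ai)
    return out


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------


def _make_state(config: RunConfig, rng, beta: float = 1.0) -> ChainState:
    guide = config.guide_data if config.guide_data is not None else config.data
    if isinstance(guide, dict):
        # raw label->sequence mapping: honour a site-prefix restriction
        if config.guide_sites == 0:
            guide = None
        else:
            guide = PatternMatrix.from_sequences(guide, n_sites=config.guide_sites)
    elif config.guide_sites is not None:
        raise ValueError(
            "guide_sites requires guide_data as a label->sequence dict "
            "(pattern compression loses the site order)"
        )
    if config.start_tree is not None:
        tree = parse_newick(config.start_tree)
    else:
        if config.data is not None:
            labels = list(config.data.taxa)
        elif guide is not None:
            labels = list(guide.taxa)
        else:
            labels = [f"t{i + 1}" for i in range(config.n_taxa)]
        tree = random_tree(labels, rng)
    model = config.model
    if model is not None:
        model = replace(model, _eig_cache={})
    state = ChainState(
        tree=tree,
        model=model,
        data=config.data,
        guide_data=guide,
        priors=config.priors,
        beta=beta,
    )
    state.recompute()
    return state


def run(config: RunConfig) -> RunResult:
    """Run the sampler; reproducible given config.seed."""
    rng = random.Random(config.seed)
    n_chains = config.chains
    states = [
        _make_state(config, rng, beta=1.0 / (1.0 + config.heat * i)) for i in range(n_chains)
    ]
    entries = config.schedule.entries
    names = [name for name, _w in entries]
    cum = []
    acc = 0.0
    for _name, w in entries:
        acc += w
        cum.append(acc)
    total_w = cum[-1]

    tunings = {}
    for name in names:
        if name in MOVE_NAMES or name == "brlen_scaler":
            tunings[name] = config.tuning.get(name) or (
                MoveTuning.for_move(name) if name in MOVE_NAMES else None
            )

    tree_samples = []
    topo_samples = []
    trace = []
    accept_counts = {name: [0, 0] for name in names}
    swap_counts = [0, 0]

    for gen in range(1, config.generations + 1):
        for state in states:
            u = rng.random() * total_w
            idx = 0
            while cum[idx] < u:
                idx += 1
            name = names[idx]
            ok = mh_step(state, name, tunings.get(name), rng)
            if state.beta == 1.0:
                accept_counts[name][1] += 1
                accept_counts[name][0] += int(ok)
        if n_chains > 1:
            i = rng.randrange(n_chains - 1)
            j = i + 1 + rng.randrange(n_chains - 1 - i)
            si, sj = states[i], states[j]
            delta = (si.beta - sj.beta) * (sj.log_lik - si.log_lik)
            swap_counts[1] += 1
            if delta >= 0 or rng.random() < math.exp(delta):
                swap_counts[0] += 1
                si.tree, sj.tree = sj.tree, si.tree
                si.model, sj.model = sj.model, si.model
                si.log_prior, sj.log_prior = sj.log_prior, si.log_prior
                si.log_lik, sj.log_lik = sj.log_lik, si.log_lik
        if gen % config.sample_every == 0:
            cold = min(states, key=lambda s: -s.beta)
            tree_samples.append((gen, write_newick(cold.tree)))
            topo_samples.append((gen, cold.tree.topology_key()))
            trace.append(
                {
                    "generation": gen,
                    "log_lik": cold.log_lik,
                    "log_prior": cold.log_prior,
                    "tree_length": cold.tree.tree_length(),
                }
            )
    return RunResult(
        tree_samples=tree_samples,
        topology_samples=topo_samples,
        trace=trace,
        accept_counts=accept_counts,
        swap_counts=swap_counts,
        config=config,
    )
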