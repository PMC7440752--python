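import math
import random
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from treewarp.characters import PatternMatrix
from treewarp.mcmc import random_tree
from treewarp.moves import (
    MoveTuning,
    guide_weights,
    log_hastings_guided,
    propose,
    scale_branch,
)
from treewarp.treespace import TreeError, parse_newick


class TestGuideWeights:
    """Weight-table values for both schemes (reference tuning)."""

    SPR1 = [1.0, 0.607, 0.368, 0.223, 0.135, 0.082, 0.050]
    SPR2 = {
        2000: [1.0, 0.585, 0.346, 0.206, 0.124, 0.075, 0.045],
        500: [1.0, 0.671, 0.454, 0.310, 0.213, 0.148, 0.103],
        100: [1.0, 0.780, 0.612, 0.485, 0.386, 0.309, 0.249],
    }

    def test_variant1_reference_column(self):
        tuning = MoveTuning(variant=1, epsilon=0.5)
        logw = guide_weights({s: s for s in range(10, 17)}, tuning, 0)
        got = [round(math.exp(logw[s]), 3) for s in range(10, 17)]
        assert got == self.SPR1

    @pytest.mark.parametrize("n_sites", [2000, 500, 100])
    def test_variant2_reference_columns(self, n_sites):
        tuning = MoveTuning(variant=2, epsilon=0.1)
        logw = guide_weights({s: s for s in range(10, 17)}, tuning, n_sites)
        got = [round(math.exp(logw[s]), 3) for s in range(10, 17)]
        assert got == self.SPR2[n_sites]

    def test_equal_scores_give_equal_weights(self):
        tuning = MoveTuning(variant=2, epsilon=0.1)
        logw = guide_weights({0: 7, 1: 7, 2: 7}, tuning, 100)
        assert set(logw.values()) == {0.0}

    def test_three_quarter_factor_differs(self):
        t14 = MoveTuning(variant=2, epsilon=0.1, rho_factor=0.25)
        t34 = MoveTuning(variant=2, epsilon=0.1, rho_factor=0.75)
        scores = {s: s for s in (10, 11)}
        r14 = math.exp(guide_weights(scores, t14, 2000)[11])
        r34 = math.exp(guide_weights(scores, t34, 2000)[11])
        assert r14 == pytest.approx(0.585, abs=5e-4)
        assert r34 != pytest.approx(0.585, abs=5e-3)


class TestHastingsGuided:
    def test_equal_weights_symmetric(self):
        logw = {i: 0.0 for i in range(5)}
        assert log_hastings_guided(logw, 0, 3) == pytest.approx(0.0)

    def test_three_candidate_arithmetic(self):
        # omega = (1, e^-1, e^-2): direct evaluation of the defining ratio
        logw = {0: 0.0, 1: -1.0, 2: -2.0}
        expected = math.log(
            (1.0 / (1.0 + math.e**-1)) / (math.e**-2 / (math.e**-1 + math.e**-2))
        )
        assert log_hastings_guided(logw, 0, 2) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999), size=st.integers(3, 12))
    def test_forward_backward_antisymmetry(self, seed, size):
        rng = random.Random(seed)
        logw = {i: rng.uniform(-8, 0) for i in range(size)}
        b, r = rng.sample(range(size), 2)
        fwd = log_hastings_guided(logw, b, r)
        back = log_hastings_guided(logw, r, b)
        assert fwd + back == pytest.approx(0.0, abs=1e-12)

    def test_same_branch_rejected(self):
        with pytest.raises(TreeError):
            log_hastings_guided({0: 0.0, 1: 0.0}, 1, 1)


class TestScaleBranch:
    def test_midpoint_is_identity(self):
        class FixedRng:
            def random(self):
                return 0.5

        v2, logm = scale_branch(1.0, 2 * math.log(1.05), FixedRng())
        assert v2 == pytest.approx(1.0)
        assert logm == pytest.approx(0.0)

    def test_extreme_multipliers(self):
        lam = 2 * math.log(1.05)

        class EdgeRng:
            def __init__(self, u):
                self.u = u

            def random(self):
                return self.u

        hi, _ = scale_branch(1.0, lam, EdgeRng(1.0))
        lo, _ = scale_branch(1.0, lam, EdgeRng(0.0))
        assert hi == pytest.approx(1.05, rel=1e-12)
        assert lo == pytest.approx(1 / 1.05, rel=1e-12)

    def test_log_multiplier_uniform(self, rng):
        lam = 2 * math.log(1.05)
        draws = sorted(scale_branch(1.0, lam, rng)[1] for _ in range(20000))
        # empirical CDF of log m vs Uniform(-lam/2, lam/2)
        worst = max(
            abs((i + 1) / len(draws) - (x + lam / 2) / lam) for i, x in enumerate(draws)
        )
        assert worst < 0.015  # KS bound at n=20000, far beyond alpha=1e-3

    def test_zero_length_rejected(self, rng):
        with pytest.raises(TreeError):
            scale_branch(0.0, 1.0, rng)


class TestProposals:
    @pytest.mark.parametrize("move", ["sNNI", "eSPR", "eTBR", "pSPR1", "pSPR2", "pTBR1", "pTBR2"])
    def test_metropolized_and_valid(self, move, rng):
        t = random_tree([f"t{i}" for i in range(6)], rng)
        key = t.topology_key()
        seen = 0
        for _ in range(300):
            res = propose(move, t, None, rng)
            if res is None:
                continue
            seen += 1
            res.tree.check()
            assert res.tree.topology_key() != key
            assert math.isfinite(res.log_hastings)
            assert set(res.tree.node_of) == set(t.node_of)
        assert seen > 100

    def test_snni_ratio_zero(self, rng):
        t = random_tree([f"t{i}" for i in range(8)], rng)
        for _ in range(50):
            res = propose("sNNI", t, None, rng)
            assert res.log_hastings == 0.0

    def test_espr_constrained_ratios(self, rng):
        """Constrained-path ratios match 1/(2(1-p_e)) and 2(1-p_e) exactly."""
        t = random_tree([f"t{i}" for i in range(8)], rng)
        tuning = MoveTuning(p_e=0.8, lam=1e-12)  # degenerate scalers: pure topology term
        cases = set()
        for _ in range(4000):
            res = propose("eSPR", t, tuning, rng)
            if res is None:
                continue
            fwd = res.info["constrained_forward"]
            back = res.info["constrained_backward"]
            cases.add((fwd, back))
            expected = 0.0
            if fwd and not back:
                expected = math.log(2 * (1 - 0.8))
            elif back and not fwd:
                expected = math.log(1 / (2 * (1 - 0.8)))
            assert res.log_hastings == pytest.approx(expected, abs=1e-9)
        assert cases == {(False, False), (True, False), (False, True), (True, True)}

    def test_espr_backward_constrained_value(self):
        # 1/(2(1-0.8)) = 2.5
        assert math.log(1 / (2 * (1 - 0.8))) == pytest.approx(math.log(2.5))

    @pytest.mark.parametrize(
        "move,expected", [("eSPR", 0.5), ("eTBR", 0.25)]
    )
    def test_extension_nni_fractions(self, move, expected, rng):
        """On a large balanced tree with p_e=0.5, eSPR proposes NNI-equivalent
        rearrangements half the time and eTBR a quarter of the time, among
        walks whose stopping decision was not dictated by a tip."""
        nwk = _balanced_newick(64)
        t = parse_newick(nwk)
        n = 0
        hits = 0
        while n < 30000:
            res = propose(move, t, None, rng)
            if res is None or res.info["first_step_tip_forced"]:
                continue
            n += 1
            hits += res.info["nni_equivalent"]
        frac = hits / n
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_pspr_uniform_on_constant_data(self, rng):
        """Equal parsimony scores reduce the guided move to a uniform regraft
        choice over the remainder branches minus the current attachment."""
        labels = list("abcdefg")
        t = random_tree(labels, rng)
        data = PatternMatrix.from_sequences({k: "ACGTACGT" for k in labels})
        counts = Counter()
        n = 0
        a0 = head0 = None
        while n < 20000:
            res = propose("pSPR2", t, None, rng, guide_data=data)
            if res is None:
                continue
            if a0 is None:
                a0, head0 = res.info["a"], res.info["head"]
            if res.info["a"] != a0 or res.info["head"] != head0:
                continue
            n += 1
            counts[res.info["r"]] += 1
        p = 1 / (res.info["n_candidates"] - 1)  # all candidates except b
        se = math.sqrt(p * (1 - p) / n)
        freqs = [c / n for c in counts.values()]
        assert len(counts) == res.info["n_candidates"] - 1
        assert max(abs(f - p) for f in freqs) < 4 * se

    def test_tbr_on_four_taxa_raises(self, rng):
        t = parse_newick("((a,b),c,d);")
        with pytest.raises(TreeError):
            propose("pTBR2", t, None, rng)

    def test_guided_topology_ratio_reverses_exactly(self, rng):
        """The reverse pSPR move's topology Hastings term is exactly the
        negative of the forward one (detailed balance through real trees)."""
        from treewarp.moves import guide_weights as gw
        from treewarp.parsimony import prune_context, regraft_scores

        labels = [f"t{i}" for i in range(7)]
        data = PatternMatrix.from_sequences(
            {lab: "".join(rng.choice("ACGT") for _ in range(40)) for lab in labels}
        )
        tuning = MoveTuning.for_move("pSPR1")
        checked = 0
        while checked < 50:
            t = random_tree(labels, rng)
            res = propose("pSPR1", t, tuning, rng, guide_data=data)
            if res is None:
                continue
            info = res.info
            ctx2 = prune_context(res.tree, info["a"], info["head"], data)
            logw2 = gw(regraft_scores(ctx2), tuning, data.n_sites)
            rev = log_hastings_guided(logw2, ctx2.merged_branch, info["b_left"])
            assert rev == pytest.approx(-info["topology_log_hastings"], abs=1e-9)
            checked += 1


def _balanced_newick(n):
    def build(labels):
        if len(labels) == 1:
            return labels[0]
        mid = len(labels) // 2
        return f"({build(labels[:mid])},{build(labels[mid:])})"

    labels = [f"t{i}" for i in range(n)]
    mid = n // 2
    return f"({build(labels[:mid])},{build(labels[mid:])});"
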