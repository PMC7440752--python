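import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from treewarp.characters import PatternMatrix
from treewarp.likelihood import SubstModel, discrete_gamma_rates, log_likelihood, transition_matrix
from treewarp.treespace import parse_newick


class TestTransitionMatrix:
    @pytest.mark.parametrize("name", ["JC69", "K80", "GTR"])
    def test_zero_length_is_identity(self, name):
        m = SubstModel(name=name, kappa=3.0)
        assert transition_matrix(m, 0.0) == pytest.approx(np.eye(4))

    @pytest.mark.parametrize("name", ["JC69", "K80"])
    def test_long_branch_reaches_stationarity(self, name):
        m = SubstModel(name=name, kappa=5.0)
        assert transition_matrix(m, 200.0) == pytest.approx(np.full((4, 4), 0.25), abs=1e-8)

    def test_k80_kappa1_equals_jc(self):
        k = SubstModel(name="K80", kappa=1.0)
        j = SubstModel(name="JC69")
        for v in (0.01, 0.3, 2.5):
            assert transition_matrix(k, v) == pytest.approx(transition_matrix(j, v))

    def test_jc_closed_form(self):
        m = SubstModel(name="JC69")
        v, r = 0.37, 1.4
        p = transition_matrix(m, v, r)
        e = math.exp(-4.0 * v * r / 3.0)
        assert p[0, 0] == pytest.approx(0.25 + 0.75 * e)
        assert p[0, 1] == pytest.approx(0.25 - 0.25 * e)

    @pytest.mark.parametrize("v", [0.05, 0.4, 1.7])
    def test_gtr_matches_matrix_exponential(self, v):
        m = SubstModel(
            name="GTR",
            exch=np.array([0.1, 0.3, 0.05, 0.08, 0.37, 0.1]),
            freqs=np.array([0.3, 0.2, 0.25, 0.25]),
        )
        direct = expm(m.rate_matrix() * v)
        assert transition_matrix(m, v) == pytest.approx(direct, abs=1e-8)
        assert transition_matrix(m, v).sum(axis=1) == pytest.approx(np.ones(4))

    def test_rows_are_stochastic(self):
        m = SubstModel(name="K80", kappa=4.0)
        p = transition_matrix(m, 0.8)
        assert p.sum(axis=1) == pytest.approx(np.ones(4))
        assert np.all(p >= 0)

    def test_negative_length_rejected(self):
        from treewarp.treespace import TreeError

        with pytest.raises(TreeError):
            transition_matrix(SubstModel(), -0.1)


class TestDiscreteGamma:
    def test_category_rates_have_mean_one(self):
        for alpha in (0.1, 0.5, 1.0, 5.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-10)
            assert np.all(np.diff(rates) > 0)

    def test_large_alpha_approaches_equal_rates(self):
        rates = discrete_gamma_rates(1e5, 4)
        assert rates == pytest.approx(np.ones(4), abs=1e-2)


def brute_likelihood(tree, data, model):
    """Oracle: sum over all internal-state assignments, per rate category,
    with every branch oriented away from an arbitrary root."""
    internal = [n for n in tree.adj if n not in tree.tip_label]
    root = internal[0]
    oriented = []  # (branch, parent, child), parent closer to root
    seen = {root}
    stack = [root]
    while stack:
        nd = stack.pop()
        for b in tree.adj[nd]:
            child = tree.other_end(b, nd)
            if child not in seen:
                seen.add(child)
                oriented.append((b, nd, child))
                stack.append(child)
    idx = {lab: i for i, lab in enumerate(data.taxa)}
    rates = model.category_rates()
    total = 0.0
    for p in range(data.n_patterns):
        cells = {
            nd: [s for s in range(4) if data.codes[idx[lab], p] & (1 << s)]
            for lab, nd in tree.node_of.items()
        }
        site = 0.0
        for rate in rates:
            mats = {b: transition_matrix(model, rec[2], rate) for b, rec in tree.branches.items()}
            for assign in itertools.product(range(4), repeat=len(internal)):
                amap = dict(zip(internal, assign))
                pr = model.freqs[amap[root]]
                for b, parent, child in oriented:
                    sc = [amap[child]] if child in amap else cells[child]
                    pr *= sum(mats[b][amap[parent], s] for s in sc)
                site += pr / len(rates)
        total += math.log(site) * int(data.weights[p])
    return total


class TestLogLikelihood:
    def test_two_taxon_closed_form(self):
        # third taxon fully ambiguous: contributes a factor of one exactly
        v = 0.31
        t = parse_newick(f"(a:{v},b:0,c:0);")
        n0, n1 = 7, 3
        seq_a = "A" * n0 + "A" * n1
        seq_b = "A" * n0 + "C" * n1
        d = PatternMatrix.from_sequences({"a": seq_a, "b": seq_b, "c": "N" * (n0 + n1)})
        model = SubstModel("JC69")
        got = log_likelihood(t, d, model)
        p0 = 0.25 + 0.75 * math.exp(-4 * v / 3)
        p1 = 0.25 - 0.25 * math.exp(-4 * v / 3)
        expected = n0 * math.log(0.25 * p0) + n1 * math.log(0.25 * p1)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_identical_sequences_zero_lengths(self):
        t = parse_newick("(a:0,b:0,c:0);")
        d = PatternMatrix.from_sequences({k: "ACGT" for k in "abc"})
        got = log_likelihood(t, d, SubstModel("JC69"))
        assert got == pytest.approx(4 * math.log(0.25), abs=1e-12)

    def test_virtual_root_invariance(self):
        t = parse_newick("((a:0.1,b:0.25):0.05,(c:0.3,d:0.02):0.2,e:0.4);")
        d = PatternMatrix.from_sequences(
            {"a": "ACGTAC", "b": "ACGTTC", "c": "ACGAAC", "d": "GCGTAC", "e": "ACCTAC"}
        )
        model = SubstModel("K80", kappa=4.0, alpha=0.5, ncat=4)
        internal = [n for n in t.adj if n not in t.tip_label]
        vals = [log_likelihood(t, d, model, root=n) for n in internal]
        assert max(vals) - min(vals) < 1e-9

    @pytest.mark.parametrize(
        "model",
        [
            SubstModel("JC69"),
            SubstModel("K80", kappa=4.0),
            SubstModel(
                "GTR",
                exch=np.array([0.2, 0.25, 0.1, 0.1, 0.25, 0.1]),
                freqs=np.array([0.35, 0.15, 0.2, 0.3]),
            ),
            SubstModel("K80", kappa=2.0, alpha=0.7, ncat=3),
        ],
        ids=["JC69", "K80", "GTR", "K80+G3"],
    )
    def test_matches_assignment_enumeration(self, model):
        t = parse_newick("((a:0.12,b:0.3):0.08,c:0.5,d:0.21);")
        d = PatternMatrix.from_sequences(
            {"a": "ACGRT", "b": "ACGTT", "c": "AC-TA", "d": "GCGTA"}
        )
        assert log_likelihood(t, d, model) == pytest.approx(
            brute_likelihood(t, d, model), abs=1e-9
        )

    def test_one_category_matches_huge_alpha(self):
        t = parse_newick("((a:0.1,b:0.2):0.1,c:0.3,d:0.15);")
        d = PatternMatrix.from_sequences({"a": "ACGT", "b": "ACGA", "c": "ACTT", "d": "CCGT"})
        flat = log_likelihood(t, d, SubstModel("JC69"))
        nearly_flat = log_likelihood(t, d, SubstModel("JC69", alpha=1e6, ncat=4))
        assert nearly_flat == pytest.approx(flat, abs=1e-3)

    def test_compression_equivalence(self):
        t = parse_newick("((a:0.1,b:0.2):0.1,c:0.3,d:0.15);")
        seqs = {"a": "AAACGT", "b": "AAACGA", "c": "AAACTT", "d": "AAACGT"}
        compressed = PatternMatrix.from_sequences(seqs)
        assert compressed.n_patterns < 6
        model = SubstModel("K80", kappa=4.0)
        per_site = 0.0
        for i in range(6):
            one = PatternMatrix.from_sequences({k: v[i] for k, v in seqs.items()})
            per_site += log_likelihood(t, one, model)
        assert log_likelihood(t, compressed, model) == pytest.approx(per_site, abs=1e-9)

    def test_matches_phangorn(self, tmp_path):
        """Independent cross-check against an established likelihood engine."""
        import subprocess

        t = parse_newick("((a:0.1,b:0.25):0.05,(c:0.3,d:0.02):0.2,e:0.4);")
        seqs = {"a": "ACGTACGGTT", "b": "ACGTTCGGTA", "c": "ACGAACGCTT",
                "d": "GCGTACGGTT", "e": "ACCTACGGTT"}
        d = PatternMatrix.from_sequences(seqs)
        fasta = tmp_path / "aln.fasta"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        nwk = tmp_path / "tree.nwk"
        from treewarp.treespace import write_newick

        nwk.write_text(write_newick(t) + "\n")
        script = tmp_path / "ll.R"
        script.write_text(
            "suppressMessages(library(phangorn))\n"
            f"tr <- read.tree('{nwk}')\n"
            f"dat <- read.phyDat('{fasta}', format='fasta', type='DNA')\n"
            "fit <- pml(tr, dat, model='JC')\n"
            "cat(sprintf('%.9f', as.numeric(logLik(fit))))\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        expected = float(out.stdout.strip().split()[-1])
        got = log_likelihood(t, d, SubstModel("JC69"))
        assert got == pytest.approx(expected, abs=1e-6)
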