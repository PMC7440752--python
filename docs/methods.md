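# Methods

This note records the models, conventions and numerical choices behind
`treewarp`, at the level of detail a user needs to interpret results or
extend the code.

## State space and tree representation

The chain state is an unrooted binary tree on n labelled tips (2n−3
branches, n−2 internal nodes of degree 3) with nonnegative branch
lengths in expected substitutions per site, plus substitution-model
parameters where the model has free ones.  Trees are stored as an
undirected graph whose branches carry **stable integer identities**; all
rearrangements are defined as maps of branch identities, which pins down
exactly which branch keeps which length through a move:

- *Pruning* a subtree A at branch `a` removes the attachment junction;
  the junction's two remaining branches merge into one branch that keeps
  the identity and length of the branch *left behind* (`b`), while the
  pendant branch in the moving direction (`q`) travels with A.
- *Regrafting* at branch `r` splits `r` at a new junction; `q` attaches
  to the endpoint of `r` nearer the old location and `r` keeps its
  length on the far side.  This convention makes every SPR exactly
  invertible (the reverse move restores both topology and every branch
  length), which the suite tests directly.

Topologies are identified by the set of nontrivial splits, each split
stored as the taxon side *not* containing the alphabetically first
taxon.  This key is invariant to branch lengths, node order and Newick
rotation, and is the unit of the topology-frequency and split-frequency
diagnostics.

Newick parsing is delegated to dendropy; rooted inputs are unrooted by
suppressing the degree-2 root and summing its two incident lengths.
Missing branch lengths default to 0.1.

## Parsimony engine

Fitch parsimony operates on bit-encoded state subsets (4 bits per cell;
IUPAC ambiguity codes contribute their subsets, gaps/'?'/N the full
set).  For candidate scoring the engine computes direction-aware state
sets: for each branch and direction, the Fitch set and accumulated step
count of the subtree on that side.  Rooting the reattached tree at the
new junction shows that the score increment of regrafting subtree A at
branch i,

    S_i = fitch(regrafted at i) − fitch(A) − fitch(remainder),

equals the weighted count of patterns whose combined Fitch set at the
insertion point on i is disjoint from A's root set — one vectorised
intersection per candidate.  The same identity gives TBR pair scores
S_ij from the two bisected halves.  Equality with brute-force rescoring
is asserted over hundreds of random instances in the suite; dendropy's
Fitch pass serves as an additional independent oracle.

## Tree proposals

All seven moves are Metropolized (the proposed topology always differs)
and return exact log Hastings ratios.

**sNNI** picks an internal branch uniformly and one of its two
alternative arrangements with probability 1/2; ratio 1.

**eSPR / eTBR** use the extension mechanism: from the pruning point the
regraft point always moves at least one branch; the initial direction is
chosen with probability 1/2 (forced, probability 1, when one end of the
merged attachment branch is a tip); each further extension occurs with
probability p_e, choosing one of the two onward branches with
probability 1/2; landing on a pendant branch forces a stop (probability
1 instead of 1−p_e).  Under this mechanism the reverse walk's initial
direction is forced exactly when the forward stop was tip-forced and
vice versa, so the exact path-probability ratio collapses to the
standard constrained-case values — 1 when unconstrained or constrained
in both directions, 1/(2(1−p_e)) when only the backward move is
constrained, 2(1−p_e) when only the forward move is.  The implementation
computes the ratio from the per-walk flags, which reproduces those
values identically.  eTBR forces one uniformly chosen (movable) end of
the internal branch to move; the other end moves at all with probability
1/2 and then follows the same walk in its half.  With p_e = 0.5 the NNI
fractions among tip-unconstrained draws are exactly 1/2 (eSPR) and 1/4
(eTBR); tip truncation only raises them.

**pSPR1/2** prune as above, score every branch of the remainder, and
sample the regraft branch r from B∖{b} with probability proportional to
ω_i = ρ_i^{εS_i}.  Scheme 1: ρ = e⁻¹ (so ω_i = e^{−εS_i}), ε = 0.5.
Scheme 2: ρ_i = ¼(1 − e^{−4v̂_i/3}) with v̂_i = S_i/N + η, ε = 0.1,
η = 10⁻⁴; the ¼ factor (the JC69 probability of changing to one
*specific* different state) is the package default because it reproduces
the reference weight table; the ¾ total-change-probability variant is
available via `MoveTuning(rho_factor=0.75)`.  Both are valid proposal
distributions — the choice affects efficiency, not correctness.  The
topology part of the ratio is the Metropolized-choice expression above;
weight sums are evaluated by log-sum-exp after shifting so the
minimum-score candidate has log-weight 0, which bounds the exponent
range at large score spreads (relevant when thousands of sites drive
the weights).

**pTBR1/2** bisect at an internal branch and weight reconnection *pairs*
(i, j) jointly by ρ^{εS_ij}, restricted to candidates at most δ = 5
nodes from the current attachment point on each side (up to ~2⁶·2⁶ =
4096 pairs); the identity pair is excluded.  The forward neighborhood is
centred on the old attachment points and the reverse neighborhood on the
new ones, so the ratio uses each neighborhood's own normalising sum; the
pair scores themselves depend only on the bisected halves and are
identical in both directions.  The reverse pair's membership in its
neighborhood (guaranteed by the symmetry of node distance) is asserted
at run time.

After the topology change, SPR-type moves scale v_a, v_q and v_b — the
picked branch, the pendant branch moved with it, and the branch left
behind — with independent multiplier proposals m = exp(λ(u−½)),
λ = 2 ln 1.05 (multipliers within ±5%), adding log m per branch to the
ratio; TBR-type moves scale the internal branch and the pendant branch
of each side that actually moved (a side that keeps its attachment has
no pendant "moved with it"); sNNI scales nothing.

When a randomly picked pruning site admits no valid regraft (the
remainder would have fewer than three taxa), the move proposes the
identity and counts as a rejected step.  Re-drawing instead would
renormalise the pick probability by a topology-dependent count and
require an extra Hastings term; the auto-reject keeps the printed ratios
exact.  With no guide data all candidate scores are zero and the guided
moves reduce to uniform candidate choice; the implementation takes that
path directly (the proposal distribution is identical) and keeps the
candidate-set bookkeeping, which is what the ratio then depends on.

## Likelihood

Felsenstein pruning with closed-form transition probabilities for JC69
and K80 and a cached eigendecomposition (via symmetrisation) for GTR;
rate matrices are scaled to one expected substitution per unit branch
length.  Rate variation uses K equal-probability discrete-gamma
categories with *mean* category rates (computed from regularised
incomplete gamma functions), K = 4 by default.  Conditional likelihoods
are rescaled at every internal node by the per-pattern maximum; the
accumulated scalers are carried as a running product and flushed to log
space before they can underflow.  The likelihood is invariant to the
virtual root (asserted to 1e−9) and is cross-checked against a
closed-form two-taxon expression, exhaustive state-assignment
enumeration on four taxa, a matrix-exponential oracle for GTR, and
phangorn's `pml` through Rscript.

## Priors

Topology: uniform over unrooted binary topologies (constant, cancels).
Branch lengths: either i.i.d. Exponential(rate) or the compound
gamma-Dirichlet prior — tree length T ~ Gamma(α_T, rate β_T); given T,
branch proportions Dirichlet with concentration α_c on external and
α_c·c on internal branches; Jacobian T^−(m−1).  The reference setting is
gamma-Dirichlet(1, 0.1, 1, 1): E[T] = 10 and a flat split among
branches.  β_T is interpreted as a *rate*; this is the convention of the
compound-Dirichlet construction the setting's name refers to, and it is
configurable.  The density is validated by numerical quadrature
(integrates to 1 on a three-branch tree) and by prior-only MCMC
recovering E[T].  Substitution parameters: flat Dirichlet on GTR
exchangeabilities, Exponential(1) on the gamma shape; base frequencies
are fixed (empirical frequencies available from the data).

## MCMC driver

One move per generation, drawn from a weighted schedule.  Presets:
`simulation` (tree move : branch scaler 5:1, one tree-move family — the
prior-recovery protocol), `reference` (1 sNNI : 2 eSPR : 1 eTBR :
2 pSPR2 : 1 pTBR2 at 46.67% tree / 50% branch length / 3.33%
substitution parameters) and `test` (36% / 60% / 4% with a 2 SPR : 1 TBR
mix of one family).  Within the branch-length mass, a single-branch
scaler and a tree-length multiplier split 4:1 (the tree-length move uses
λ = 2 ln 1.25; its Jacobian contributes m branches × log m).  Acceptance
is min(1, exp(β·Δlog L + Δlog prior + log Hastings)); heated chains
apply β = 1/(1 + λ_h·i), λ_h = 0.1 by default, to the likelihood term,
and one random pair attempts a state swap per generation with the
standard ratio exp((β_i−β_j)(L_j−L_i)); only the cold chain is sampled.
Runs are bit-reproducible from the seed; samples are one Newick per line
with a generation prefix, plus a tab-separated scalar trace.

## Diagnostics

Split frequencies are tabulated over post-burn-in samples (default
burn-in fraction 0.25; the reference-run convention 0.40 is a flag).
The ASDSF averages the across-run standard deviation (n−1 denominator)
of split frequencies over splits reaching min_freq = 0.10 in at least
one run; identical runs give exactly 0, and 0.02 is the conventional
convergence threshold.  For n ≤ 7 the topology posterior can be aligned
against the exhaustive enumeration ((2n−5)!! topologies).

## Synthetic data and what the tests show

The simulator draws the root state from the stationary frequencies and
evolves sites independently along branches (per-site Gamma(α, α) rates
when α is finite).  The long-branch-attraction fixture places five taxa
on the classic geometry — two long terminal branches (0.8) separated by
a short internal branch, all other branches 0.05 — and simulates 10 kb
under K80 with κ = 4.  The published figure this emulates does not print
its branch lengths; these values are this package's reconstruction and
are configurable.  On this fixture maximum parsimony over all 15
topologies reliably joins the long branches while the likelihood at the
generating geometry prefers the true tree, which is exactly the
adversarial setting the guided moves' Hastings correction is tested
under: guide weights from the first 100 or 1000 sites, likelihood held
constant, uniform topology recovery required.

The validation experiments are scaled to desk size: uniform-prior
recovery uses 1.5 million generations per move (the original protocol's
10 million), sampling every 25 generations rather than every 100 so the
retained sample approaches the original effective sample size and the
±0.005 per-topology tolerance corresponds to ≈4 Monte-Carlo standard
errors; cross-sampler agreement uses four 150k-generation chains on an
8-taxon, 500-site simulated alignment.  Simulated data are i.i.d.
across sites under the generating model — no rate autocorrelation,
indels, alignment error or model misspecification — so passing tests
demonstrate correctness of the algorithms (proposal ratios, scoring,
likelihood, priors), not robustness of inference on real data.

## Known limitations

- Rooted/clock trees, polytomies, partitioned and non-DNA data are out
  of scope; models are unpartitioned JC69/K80/GTR(+Γ).
- Likelihoods are recomputed in full per proposal; adequate at desk
  scale (tens of taxa), not tuned for hundreds of taxa.
- Chains execute sequentially; Metropolis coupling is provided for
  correctness, not parallel throughput.
- No checkpoint/restart; a run is a single deterministic process.
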