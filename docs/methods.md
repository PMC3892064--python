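# Methods

## Model

Gene content evolves on a fixed rooted species tree with known branch
lengths.  For each gene family the state in a genome is one of absent (0),
single copy (1), or multiple in-paralogs (m); the state evolves along each
branch as a homogeneous continuous-time Markov chain with rate matrix Q,
shared across all branches of the tree (no lineage-specific rates).  Rows
of Q sum to zero and P(t) = exp(Qt).

State order is fixed as (0, 1) for the binary models and (0, 1, m) for the
three-state models; the three-state Q is

```
        0            1            m
0   −(g1+c1)        g1           c1
1      l1        −(l1+g2)        g2
m      c2           l2        −(l2+c2)
```

with g1 the gain of a first copy, g2 duplication, l1 loss of a single-copy
gene, l2 loss of in-paralogs down to one copy, and c1/c2 direct jumps
between absence and multiple copies.  M1 ties c1 = c2 = c (5 free rates),
M2 leaves both free (6).  The binary models B1 (g = l = c) and B2 (g, l
free) act on binarized vectors (m ↦ 1).

The key interpretive difference between M1 and M2 is the probability of
losing *all* copies along a branch when the ancestor had in-paralogs: tying
c2 to c1 (M1) forces the m→0 jump rate to equal the rare 0→m rate, while M2
estimates it freely.  Both c rates are kept as free parameters rather than
fixed to zero; when the data carry no signal for them the estimates sit at
the lower optimizer bound and are reported as bound hits.

## Likelihood, prior and posterior

The likelihood of a phyletic vector X is f(X|θ) = Σ_k π(k) L0(k), with the
conditional likelihoods L0 computed by the pruning recursion: leaf partials
are indicators of the observed state; an internal node's partial for state
k is the product over children c of Σ_j P(t_c)[k,j] · partial_c(j).  The
recursion is implemented vectorized over genes, with per-node rescaling of
the partials by their maximum and an accumulated log-scale, so that trees
with hundreds of leaves do not underflow (the log-likelihood is exact; the
scale cancels in the posterior).  Polytomies are supported (the recursion
never assumes out-degree 2) and zero-length branches contribute P(0) = I.
A brute-force enumeration over all internal-node state assignments (capped
at 8 internal nodes) serves as an independent oracle in the tests; the two
routes agree to 1e-9 relative on hundreds of random instances.

The root prior defaults to π = (0.5, 0.45, 0.05): half the mass on absence
and the presence mass split 9:1 between a single ancestral copy and
ancestral in-paralogs.  The binary prior is (0.5, 0.5), mirroring the
absence mass (the choice is exposed via `base_prior`).  Optional frequency
weighting multiplies the presence mass by w = n_present/n_total — the
fraction of extant genomes carrying the gene — and renormalizes; this
guards nearly universal genes against occasional root-absence calls driven
by the stochasticity of the chain.  The weight is applied to states 1 and m
jointly, preserving their 9:1 internal ratio (mode `"both"`, default); mode
`"single"` weights only state 1.  When enabled in the pipeline the
weighting is applied to every gene, with n_present counting genomes with
state ≠ 0.  The root posterior is π(k)L0(k)/f and the reported presence
probability is 1 − posterior(0).

## Rate estimation and model choice

Rates are estimated per gene by maximizing log f(X|θ) with L-BFGS-B on
log-rates, box-bounded to [1e-6, 100] per unit branch length (wide enough
to act only as a numerical guard; estimates at a bound are flagged as
non-identifiability warnings).  Multi-start: one central start (all rates
1), a warm start at the smaller nested model's optimum when fitting the
larger model of a pair — which structurally guarantees l(M2) ≥ l(M1) and
l(B2) ≥ l(B1) up to optimizer tolerance — and seeded jittered starts
(log-rates uniform on [log 0.05, log 5]) up to `n_restarts` (default 5).
Ties between restarts (within 1e-9 in log-likelihood) go to the smaller L2
norm of the log-rates.  All-absent vectors are rejected as non-identifiable
rather than silently fitted.

Model choice within a family uses AIC = −2l + 2p (p = 1, 2, 5, 6 for B1,
B2, M1, M2), minimum wins, exact ties to the fewer-parameter model.
Comparisons across families are refused: the binary and three-state models
are fitted to different encodings of the same gene and their likelihoods
are not commensurable.

The aggregate loss-to-gain ratio is defined here as
(l1 + l2 + c2)/(g1 + g2 + c1) — all loss-type rates pooled over all
gain-type rates (l/g for B2; identically 1 for B1).  The per-pair ratios
l1/g1, l2/g2 and c2/c1 are always reported alongside so the aggregation
hides nothing; a zero denominator yields an infinite ratio with an explicit
flag.

Because single-vector estimates of 5–6 rates are noisy, a pooled mode
(`PooledRateEstimator`, shared θ, summed log-likelihoods) is provided and
is the estimator used in rate-recovery experiments.

## Numerical choices

P(t) is computed from the eigendecomposition of Q, evaluated for all branch
lengths of the tree at once; if the eigenvector matrix is ill-conditioned
(condition number ≥ 1e8, e.g. near-defective Q) the code falls back to
`scipy.linalg.expm` per branch.  Entries are clipped to [0, 1] and rows
renormalized at the round-off level; accuracy is verified against the
analytic two-state solution and scipy's expm to 1e-10 entrywise.  The
stationary distribution solves πQ = 0 by least squares after an
irreducibility check on the positive-rate digraph; reducible matrices
(including Q = 0) raise a non-ergodic error.

The entrywise median transition summary (median of P(t) over genes' fitted
rates, per model, by default at the tree's median branch length) is a
median per entry, so its rows need not sum to exactly 1.

## Synthetic data

The simulator draws the root state from π and each child state from the
parent's row of P(branch length) — exactly the generative process the
likelihood assumes; states are simulated at nodes, not as event-time
realizations of the chain, which is distribution-exact for everything the
inference sees.  Count tables emit copy number 2 as the canonical
representative of state m and round-trip exactly through the count-table
reader and encoder.  Identical configuration and seed give byte-identical
output.

What the simulator does *not* emulate about real data: horizontal transfer
(handled only as the vector-editing rule), lineage- or gene-specific rate
variation, phylogenetic error in the species tree, and ortholog-clustering
noise in the count table.  Passing recovery tests therefore demonstrate
correctness of the estimator under the model's own assumptions, not
robustness to their violation.

## Validation problem sizes

The validation pipeline (tests and `scripts/acceptance.py`) uses: 200
random trees of ≤ 6 leaves for pruning-vs-enumeration agreement; a (g, l, t)
grid and 40 random matrices for the closed-form and Chapman–Kolmogorov
identities; a 32-leaf random tree with 1000 genes simulated under M2
(g1 = 0.5, g2 = 1.0, l1 = 1.5, l2 = 2.0, c1 = 0.1, c2 = 0.3) for pooled
recovery; per-gene fits of all four models on a 100–120-gene subsample of
that cohort for the nesting and ancestral-set checks; and 10,000
single-branch replicates for simulator calibration.

A known property of the recovery experiment: the direct-jump rates c1 and
c2 govern rare events, so their maximum-likelihood estimates at 1000 genes
have large sampling variance — across simulation seeds the worst-case
relative error ranges from about 10% to occasionally 50–90% on c2, with
all restarts converging to the same (global) optimum.  The fixed-seed
recovery test documents the typical case; the variance is a property of
the experiment size, not of the optimizer.

## Limitations

Rates are constant across branches; only the root marginal is
reconstructed (no joint ancestral states at internal nodes); the state
space stops at "multiple" copies (no family-size dynamics beyond m);
missing data are not supported — absent genomes must be coded 0 explicitly,
because silent imputation would change likelihoods invisibly; and HGT is
not detected, only accommodated once known, by editing the affected
vectors.
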