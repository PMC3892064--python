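"""Likelihood of phyletic vectors on the species tree, and root posteriors.

For a gene with phyletic vector X and rate parameters theta, the likelihood
is

    f(X | theta) = sum_{y0} pi(y0) * L0(y0)

where pi is the prior over the root (LUCA) state and L0(y0) is the
conditional likelihood of the leaf states given root state y0, computed by
the pruning (dynamic-programming) recursion: a leaf's partial is the
indicator of its observed state, and an internal node's partial for state k
is the product over its children c of sum_j P(t_c)[k, j] * partial_c(j).

The root-state posterior follows by Bayes' rule,

    f(y0 = k | X, theta) = pi(k) * L0(k) / f(X | theta),

and the gene's ancestral-presence probability is 1 - posterior(absent).

Partials are rescaled per node with an accumulated log-scale so that trees
with a hundred or more leaves do not underflow.  A brute-force enumeration
over all internal-node state assignments is provided as an independent
oracle for small trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .models import RateParameters, build_rate_matrix, transition_matrices
from .tree import PhylogeneticTree

__all__ = [
    "RootPrior",
    "make_root_prior",
    "LikelihoodResult",
    "RootPosterior",
    "prune_likelihood",
    "prune_loglik_batch",
    "brute_force_likelihood",
    "root_posterior",
]

# default priors over the root (LUCA) state
THREE_STATE_PRIOR = np.array([0.5, 0.45, 0.05])  # (absent, single, in-paralogs)
BINARY_PRIOR = np.array([0.5, 0.5])


@dataclass(frozen=True)
class RootPrior:
    """Prior probability vector over root states.

    The three-state default is pi(0)=0.5, pi(1)=0.45, pi(m)=0.05 — presence
    mass split 9:1 between a single ancestral copy and ancestral in-paralogs,
    reflecting the expectation that the root genome carried mostly
    single-copy genes.  The binary default is uniform (0.5, 0.5).

    Frequency weighting multiplies the presence mass by
    w = n_present / n_total (the fraction of extant genomes carrying the
    gene) and renormalizes, which guards nearly universal genes against
    implausible absence calls at the root.
    """

    probs: np.ndarray
    weighted: bool = False
    weight: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("prior entries must be >= 0 and sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def n_states(self) -> int:
        return len(self.probs)


def make_root_prior(
    state_space: str = "three-state",
    n_present: int | None = None,
    n_total: int | None = None,
    weighting: bool = False,
    weighting_mode: str = "both",
    base: np.ndarray | None = None,
) -> RootPrior:
    """Build the root prior, optionally frequency-weighted.

    Parameters
    ----------
    state_space : {"three-state", "binary"}
    n_present, n_total : int
        Number of genomes carrying the gene (state != 0) and total genomes;
        required when ``weighting`` is on.
    weighting : bool
        Multiply the presence prior mass by w = n_present / n_total, then
        renormalize.  Absence mass is left untouched before renormalization.
    weighting_mode : {"both", "single"}
        ``"both"`` (default) weights states 1 and m jointly, preserving
        their 9:1 internal ratio; ``"single"`` weights only state 1.
    base : array, optional
        Override the default prior vector (must match the state space).
    """
    if state_space in ("three-state", "three"):
        p = THREE_STATE_PRIOR.copy() if base is None else np.asarray(base, float).copy()
        k = 3
    elif state_space == "binary":
        p = BINARY_PRIOR.copy() if base is None else np.asarray(base, float).copy()
        k = 2
    else:
        raise ValueError(f"unknown state space {state_space!r}")
    if len(p) != k:
        raise ValueError("base prior length does not match the state space")
    if not weighting:
        return RootPrior(p / p.sum())
    if n_present is None or n_total is None:
        raise ValueError("weighting requires n_present and n_total")
    if n_total < 1 or not 0 <= n_present <= n_total:
        raise ValueError("need 0 <= n_present <= n_total, n_total >= 1")
    w = n_present / n_total
    p = p.copy()
    if weighting_mode == "both":
        p[1:] *= w
    elif weighting_mode == "single":
        p[1] *= w
    else:
        raise ValueError(f"unknown weighting mode {weighting_mode!r}")
    total = p.sum()
    if total <= 0:
        raise ValueError("weighted prior has zero mass")
    return RootPrior(p / total, weighted=True, weight=w)


@dataclass
class LikelihoodResult:
    """Likelihood of one phyletic vector under one model.

    ``root_partials`` are the conditional likelihoods L0(k) of the leaf data
    given each root state, on a natural scale when no rescaling occurred and
    otherwise scaled by ``exp(-log_scale)``; ``loglik`` is always the exact
    log of f(X|theta) = sum_k pi(k) L0(k).
    """

    loglik: float
    scaled_root_partials: np.ndarray
    log_scale: float
    prior: RootPrior

    @property
    def likelihood(self) -> float:
        """f(X|theta); may underflow to 0.0 for very unlikely data."""
        return float(np.exp(self.loglik)) if np.isfinite(self.loglik) else 0.0

    @property
    def root_partials(self) -> np.ndarray:
        """L0(k) on the natural scale (may underflow for large trees)."""
        return self.scaled_root_partials * np.exp(self.log_scale)


@dataclass(frozen=True)
class RootPosterior:
    """Posterior over the root (LUCA) state for one gene."""

    probs: np.ndarray
    state_labels: tuple[str, ...]

    @property
    def presence_probability(self) -> float:
        """P(gene present at the root) = 1 - posterior(absent)."""
        return float(1.0 - self.probs[0])

    @property
    def argmax_state(self) -> str:
        """The state assigned to the root (highest posterior probability)."""
        return self.state_labels[int(np.argmax(self.probs))]


def _states_matrix(v, n_leaves: int) -> np.ndarray:
    X = np.atleast_2d(np.asarray(v, dtype=int))
    if X.shape[1] != n_leaves:
        raise ValueError(
            f"phyletic vector covers {X.shape[1]} leaves, tree has {n_leaves}"
        )
    return X

def prune_loglik_batch(
    tree: PhylogeneticTree,
    X: np.ndarray,
    params: RateParameters,
    prior: RootPrior,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pruning recursion, vectorized over genes.

    Parameters
    ----------
    X : int array, shape (n_genes, n_leaves)
        Phyletic states per gene, columns in ``tree.leaf_names`` order,
        coded 0/1(/2 for state m).
    Returns
    -------
    loglik : (n_genes,) log f(X|theta) per gene (-inf for impossible data)
    scaled_root_partials : (n_genes, k)
    log_scale : (n_genes,) so that L0 = scaled_root_partials * exp(log_scale)
    """
    k = params.n_states
    if prior.n_states != k:
        raise ValueError("prior state space does not match the model")
    X = _states_matrix(X, tree.n_leaves)
    if X.min() < 0 or X.max() >= k:
        raise ValueError(
            f"state codes must lie in [0, {k - 1}] for model {params.model_id}"
        )
    n_genes = X.shape[0]
    Q = build_rate_matrix(params)
    P = transition_matrices(Q, tree.branch_length)  # (n_nodes, k, k)

    leaf_col = {node: j for j, node in enumerate(tree.leaf_nodes)}
    partials = [None] * tree.n_nodes
    log_scale = np.zeros(n_genes)
    eye = np.eye(k)
    for node in tree.postorder:
        ch = tree.children[node]
        if not ch:
            partials[node] = eye[X[:, leaf_col[node]]]
            continue
        acc = np.ones((n_genes, k))
        for c in ch:
            acc *= partials[c] @ P[c].T
            partials[c] = None  # free as soon as consumed
        if node != tree.root:
            m = acc.max(axis=1)
            pos = m > 0
            acc[pos] /= m[pos, None]
            with np.errstate(divide="ignore"):
                log_scale += np.where(pos, np.log(np.where(pos, m, 1.0)), -np.inf)
        partials[node] = acc
    root_part = partials[tree.root]
    f_scaled = root_part @ prior.probs
    with np.errstate(divide="ignore"):
        loglik = np.where(f_scaled > 0, np.log(np.maximum(f_scaled, 1e-320)), -np.inf)
    loglik = loglik + log_scale
    return loglik, root_part, log_scale


def prune_likelihood(
    tree: PhylogeneticTree,
    v,
    params: RateParameters,
    prior: RootPrior,
) -> LikelihoodResult:
    """Likelihood of a single phyletic vector by pruning.

    ``v`` is the vector of integer-coded states, one per leaf, in
    ``tree.leaf_names`` order.
    """
    loglik, root_part, log_scale = prune_loglik_batch(tree, v, params, prior)
    return LikelihoodResult(
        loglik=float(loglik[0]),
        scaled_root_partials=root_part[0],
        log_scale=float(log_scale[0]),
        prior=prior,
    )


MAX_BRUTE_FORCE_INTERNAL = 8


def brute_force_likelihood(
    tree: PhylogeneticTree,
    v,
    params: RateParameters,
    prior: RootPrior,
) -> LikelihoodResult:
    """Likelihood by explicit enumeration over internal-node states.

    Sums pi(y0) * prod_edges p_{state(parent), state(child)}(t) over every
    assignment of states to the internal nodes and the root.  Exponential in
    the number of internal nodes, so it refuses trees with more than
    8 of them; it exists as the independent oracle for the pruning
    recursion.
    """
    k = params.n_states
    if prior.n_states != k:
        raise ValueError("prior state space does not match the model")
    X = _states_matrix(v, tree.n_leaves)[0]
    internal = [n for n in range(tree.n_nodes) if tree.children[n]]
    if len(internal) > MAX_BRUTE_FORCE_INTERNAL:
        raise ValueError(
            f"brute force refuses {len(internal)} internal nodes "
            f"(max {MAX_BRUTE_FORCE_INTERNAL})"
        )
    Q = build_rate_matrix(params)
    P = transition_matrices(Q, tree.branch_length)
    leaf_col = {node: j for j, node in enumerate(tree.leaf_nodes)}

    root_part = np.zeros(k)
    for assignment in itertools.product(range(k), repeat=len(internal)):
        state = {n: s for n, s in zip(internal, assignment)}
        for node, j in leaf_col.items():
            state[node] = X[j]
        prob = 1.0
        for node in range(tree.n_nodes):
            if node == tree.root:
                continue
            prob *= P[node][state[tree.parent[node]], state[node]]
        root_part[state[tree.root]] += prob
    f = float(prior.probs @ root_part)
    loglik = np.log(f) if f > 0 else -np.inf
    return LikelihoodResult(
        loglik=loglik,
        scaled_root_partials=root_part,
        log_scale=0.0,
        prior=prior,
    )


def root_posterior(res: LikelihoodResult) -> RootPosterior:
    """Posterior over root states from a likelihood result.

    posterior(k) = pi(k) * L0(k) / f(X|theta); the scale factor of the
    partials cancels.  Raises ``ValueError`` when the data are impossible
    under the model (f = 0).
    """
    unnorm = res.prior.probs * res.scaled_root_partials
    total = unnorm.sum()
    if total <= 0 or not np.isfinite(res.loglik):
        raise ValueError("data impossible under the model (likelihood is 0)")
    k = res.prior.n_states
    labels = ("0", "1") if k == 2 else ("0", "1", "m")
    return RootPosterior(probs=unnorm / total, state_labels=labels)
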