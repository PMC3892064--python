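"""Scikit-learn style estimators for ancestral gene-content reconstruction.

:class:`GeneContentReconstructor` is the primary interface: given a rooted
species tree, ``fit(X)`` on a genes x genomes copy-count table estimates
per-gene gain/loss rates under both models of a family (binary B1/B2 or
three-state M1/M2), picks the AIC-preferred model per gene, and exposes the
root (LUCA) posterior for every gene as fitted attributes.

:class:`PooledRateEstimator` fits one shared set of rates to a whole cohort
by summed log-likelihood — the estimator used for rate-recovery experiments
and cohort-level rate statements.

Both compose with sklearn tooling (``get_params``/``set_params``/``clone``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import inference
from .inference import FitOptions, GeneFit, PooledFit
from .likelihood import make_root_prior
from .models import BINARY_MODELS, THREE_STATE_MODELS
from .phyletic import binarize_vector, encode_counts
from .tree import PhylogeneticTree, parse_newick

__all__ = ["GeneContentReconstructor", "PooledRateEstimator"]


def _as_tree(tree) -> PhylogeneticTree:
    if isinstance(tree, PhylogeneticTree):
        return tree
    return parse_newick(tree)


def _states_from_input(X, tree: PhylogeneticTree) -> tuple[np.ndarray, list[str]]:
    """Copy counts -> three-state matrix in tree leaf order, plus gene ids."""
    if isinstance(X, pd.DataFrame):
        missing = [n for n in tree.leaf_names if n not in X.columns]
        extra = [c for c in X.columns if c not in tree.leaf_names]
        if missing or extra:
            raise ValueError(
                f"count-table species do not match tree leaves "
                f"(missing {missing}, extra {extra})"
            )
        counts = X.loc[:, tree.leaf_names].to_numpy()
        gene_ids = [str(g) for g in X.index]
    else:
        counts = np.atleast_2d(np.asarray(X))
        if counts.shape[1] != tree.n_leaves:
            raise ValueError(
                f"X has {counts.shape[1]} columns, tree has {tree.n_leaves} leaves"
            )
        gene_ids = [f"gene{i}" for i in range(counts.shape[0])]
    return encode_counts(counts), gene_ids


class GeneContentReconstructor(BaseEstimator):
    """Per-gene ML reconstruction of ancestral presence at the tree root.

    Parameters
    ----------
    tree : PhylogeneticTree or Newick str
        Rooted species tree with branch lengths; leaf names must match the
        count-table columns.
    family : {"three-state", "binary"}
        ``"three-state"`` fits M1 and M2 to the 0/1/m vectors;
        ``"binary"`` binarizes (m -> 1) and fits B1 and B2.
    weighting : bool, default True
        Weight each gene's root prior by its frequency of occurrence
        n_present / n_genomes (guards nearly universal genes against
        implausible root-absence calls).
    weighting_mode : {"both", "single"}
        Whether the weight multiplies the presence mass of states 1 and m
        jointly (preserving their 9:1 ratio) or of state 1 only.
    base_prior : array, optional
        Override the default root prior (0.5, 0.45, 0.05) / (0.5, 0.5).
    n_restarts : int, default 5
        Optimization starts per model per gene.
    rate_bounds : (float, float)
        Box bounds on each rate during optimization.
    random_state : int, default 0
        Seed for the jittered optimizer starts.

    Attributes
    ----------
    fits_ : list of dict
        Per gene, model_id -> :class:`GeneFit` for both family members.
    selected_ : list of GeneFit
        The AIC-preferred fit per gene.
    summary_ : DataFrame
        One row per gene: chosen model, log-likelihoods and AICs of both
        candidates, fitted rates, root posterior, presence probability,
        loss/gain ratio, convergence diagnostics.
    presence_probability_ : ndarray (n_genes,)
        1 - posterior(absent) under each gene's preferred model.

    Examples
    --------
    >>> rec = GeneContentReconstructor(tree="((A:0.3,B:0.4):0.2,(C:0.3,D:0.5):0.1);")
    >>> rec.fit(pd.DataFrame([[1, 2, 0, 1]], index=["geneA"],
    ...                      columns=["A", "B", "C", "D"]))  # doctest: +SKIP
    >>> rec.presence_probability_  # doctest: +SKIP
    """

    def __init__(
        self,
        tree=None,
        family: str = "three-state",
        weighting: bool = True,
        weighting_mode: str = "both",
        base_prior=None,
        n_restarts: int = 5,
        rate_bounds: tuple[float, float] = inference.RATE_BOUNDS,
        random_state: int = 0,
    ) -> None:
        self.tree = tree
        self.family = family
        self.weighting = weighting
        self.weighting_mode = weighting_mode
        self.base_prior = base_prior
        self.n_restarts = n_restarts
        self.rate_bounds = rate_bounds
        self.random_state = random_state

    def fit(self, X, y=None) -> "GeneContentReconstructor":
        """Estimate rates and root posteriors for every gene in X.

        X is a genes x genomes copy-count DataFrame (columns = tree leaf
        names) or integer array in tree leaf order.
        """
        if self.tree is None:
            raise ValueError("tree must be provided")
        if self.family not in ("three-state", "binary"):
            raise ValueError(f"unknown family {self.family!r}")
        tree = _as_tree(self.tree)
        states, gene_ids = _states_from_input(X, tree)
        if self.family == "binary":
            states = binarize_vector(states)
        n_total = tree.n_leaves

        self.tree_ = tree
        self.fits_ = []
        self.selected_ = []
        records = []
        for i, gene_id in enumerate(gene_ids):
            v = states[i]
            options = FitOptions(
                bounds=tuple(self.rate_bounds),
                n_restarts=self.n_restarts,
                seed=(self.random_state + i) % (2**31),
            )
            prior = make_root_prior(
                self.family,
                n_present=int(np.count_nonzero(v)),
                n_total=n_total,
                weighting=self.weighting,
                weighting_mode=self.weighting_mode,
                base=self.base_prior,
            )
            fits = inference.fit_family(
                tree, v, self.family, prior, options, gene_id=gene_id
            )
            chosen = inference.select_model(list(fits.values()))
            self.fits_.append(fits)
            self.selected_.append(chosen)
            rec = inference.summarize_gene(chosen)
            for model_id, f in fits.items():
                rec[f"loglik_{model_id}"] = f.loglik
                rec[f"aic_{model_id}"] = f.aic
            records.append(rec)
        self.summary_ = pd.DataFrame(records).set_index("gene_id")
        self.gene_ids_ = gene_ids
        self.presence_probability_ = np.array(
            [f.presence_probability for f in self.selected_]
        )
        self.posterior_ = np.stack([f.posterior.probs for f in self.selected_])
        self.n_features_in_ = n_total
        self.feature_names_in_ = np.asarray(tree.leaf_names, dtype=object)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the (n_genes, n_states) root posterior matrix."""
        return self.fit(X).posterior_

    # -- post-fit summaries ------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "selected_"):
            raise AttributeError("not fitted; call fit(X) first")

    def presence_probabilities(self) -> dict[str, float]:
        self._check_fitted()
        return dict(zip(self.gene_ids_, self.presence_probability_.tolist()))

    def ancestral_set(self, x: float = 0.7) -> inference.AncestralSet:
        """LUCA-MLx: genes with root presence probability >= x."""
        self._check_fitted()
        return inference.build_ancestral_set(self.presence_probabilities(), x)

    def ancestral_count_series(
        self, thresholds=inference.DEFAULT_THRESHOLDS
    ) -> pd.Series:
        """Ancestral-set sizes over the threshold grid 0.5, 0.55, ..., 1.0."""
        self._check_fitted()
        return inference.ancestral_count_series(
            self.presence_probabilities(), thresholds
        )

    def median_transition(self, t: float | None = None) -> dict[str, np.ndarray]:
        """Entrywise-median P(t) per model over the genes' fitted rates.

        ``t`` defaults to the median branch length of the species tree.
        """
        self._check_fitted()
        if t is None:
            t = self.tree_.median_branch_length()
        all_fits = [f for fits in self.fits_ for f in fits.values()]
        return inference.median_transition_summary(all_fits, t)


class PooledRateEstimator(BaseEstimator):
    """One shared set of gain/loss rates for a cohort of genes.

    Maximizes the summed log-likelihood over all genes under a single
    model.  Fitted attributes: ``rates_`` (dict of rate estimates),
    ``params_``, ``log_likelihood_``, ``aic_``, ``bound_hits_``.
    """

    def __init__(
        self,
        tree=None,
        model: str = "M2",
        weighting: bool = False,
        weighting_mode: str = "both",
        base_prior=None,
        n_restarts: int = 5,
        rate_bounds: tuple[float, float] = inference.RATE_BOUNDS,
        random_state: int = 0,
    ) -> None:
        self.tree = tree
        self.model = model
        self.weighting = weighting
        self.weighting_mode = weighting_mode
        self.base_prior = base_prior
        self.n_restarts = n_restarts
        self.rate_bounds = rate_bounds
        self.random_state = random_state

    def _prior(self, states: np.ndarray):
        family = "binary" if self.model in BINARY_MODELS else "three-state"
        n_total = states.size
        return make_root_prior(
            family,
            n_present=int(np.count_nonzero(states)),
            n_total=max(n_total, 1),
            weighting=self.weighting,
            weighting_mode=self.weighting_mode,
            base=self.base_prior,
        )

    def fit(self, X, y=None) -> "PooledRateEstimator":
        if self.tree is None:
            raise ValueError("tree must be provided")
        tree = _as_tree(self.tree)
        states, _ = _states_from_input(X, tree)
        if self.model in BINARY_MODELS:
            states = binarize_vector(states)
        elif self.model not in THREE_STATE_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        options = FitOptions(
            bounds=tuple(self.rate_bounds),
            n_restarts=self.n_restarts,
            seed=self.random_state,
        )
        prior = self._prior(states)
        pooled = inference.fit_pooled(tree, states, self.model, prior, options)
        self.tree_ = tree
        self.fit_ = pooled
        self.params_ = pooled.params
        self.rates_ = dict(pooled.params.rates)
        self.log_likelihood_ = pooled.loglik
        self.aic_ = pooled.aic
        self.n_params_ = pooled.n_params
        self.converged_ = pooled.converged
        self.bound_hits_ = pooled.bound_hits
        self.n_features_in_ = tree.n_leaves
        return self

    def score(self, X, y=None) -> float:
        """Summed log-likelihood of X under the fitted rates."""
        from .likelihood import prune_loglik_batch

        if not hasattr(self, "params_"):
            raise AttributeError("not fitted; call fit(X) first")
        states, _ = _states_from_input(X, self.tree_)
        if self.model in BINARY_MODELS:
            states = binarize_vector(states)
        prior = self._prior(states)
        ll, _, _ = prune_loglik_batch(self.tree_, states, self.params_, prior)
        return float(ll.sum())
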