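"""Per-gene maximum-likelihood rate estimation and model selection.

Each gene's rates are estimated by maximizing the pruning likelihood over
the model's free parameters, optimized on the log-rate scale with bound
constraints.  Within a family (binary B1/B2 or three-state M1/M2) the
preferred model per gene is the one with the lower AIC = -2 l + 2 p;
cross-family comparison is refused because the two families are fitted to
different encodings of the data.

The module also assembles ancestral gene sets: LUCA-MLx is the set of genes
whose root presence probability, under their AIC-preferred model, is at
least x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .likelihood import (
    RootPosterior,
    RootPrior,
    prune_likelihood,
    prune_loglik_batch,
    root_posterior,
)
from .models import (
    BINARY_MODELS,
    MODEL_PARAM_NAMES,
    THREE_STATE_MODELS,
    RateParameters,
    build_rate_matrix,
    transition_matrix,
)
from .tree import PhylogeneticTree

__all__ = [
    "NonIdentifiableError",
    "FitOptions",
    "GeneFit",
    "PooledFit",
    "AncestralSet",
    "fit_model",
    "fit_family",
    "fit_pooled",
    "aic_score",
    "select_model",
    "summarize_gene",
    "build_ancestral_set",
    "ancestral_count_series",
    "median_transition_summary",
    "DEFAULT_THRESHOLDS",
]

RATE_BOUNDS = (1e-6, 100.0)
DEFAULT_THRESHOLDS = np.round(np.arange(0.5, 1.0001, 0.05), 10)

_FAMILY_OF = {m: "binary" for m in BINARY_MODELS}
_FAMILY_OF.update({m: "three-state" for m in THREE_STATE_MODELS})

# smaller-model optimum -> start for the larger model of the nested pair
_NESTED_EXPANSION = {
    ("B1", "B2"): lambda r: {"g": r["c"], "l": r["c"]},
    ("M1", "M2"): lambda r: {k: r[k] for k in ("g1", "g2", "l1", "l2")}
    | {"c1": r["c"], "c2": r["c"]},
}


class NonIdentifiableError(ValueError):
    """Raised when a vector carries no information about the rates."""


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for rate estimation.

    ``n_restarts`` counts optimization starts: one central start (all rates
    1), plus any warm start from a nested smaller model, plus seeded
    jittered starts up to the total.  Rates are bounded to
    ``bounds = [1e-6, 100]`` per unit branch length to keep exp(Qt)
    well-conditioned; estimates at a bound are reported as a
    non-identifiability warning, not clipped silently.
    """

    bounds: tuple[float, float] = RATE_BOUNDS
    n_restarts: int = 5
    seed: int = 0
    ftol: float = 1e-11
    maxiter: int = 1000


@dataclass
class GeneFit:
    """Result of fitting one model to one gene's phyletic vector."""

    gene_id: str
    model_id: str
    params: RateParameters
    loglik: float
    n_params: int
    aic: float
    posterior: "RootPosterior"
    presence_probability: float
    loss_gain_ratio: float
    ratio_components: dict[str, float]
    converged: bool
    n_starts: int
    bound_hits: tuple[str, ...]
    prior: RootPrior

    @property
    def family(self) -> str:
        return _FAMILY_OF[self.model_id]


@dataclass
class PooledFit:
    """A single set of rates fitted to many genes jointly (summed log-lik)."""

    model_id: str
    params: RateParameters
    loglik: float
    n_params: int
    aic: float
    n_genes: int
    converged: bool
    n_starts: int
    bound_hits: tuple[str, ...]


@dataclass(frozen=True)
class AncestralSet:
    """Genes with root presence probability >= threshold."""

    threshold: float
    members: tuple[str, ...]


# ---------------------------------------------------------------------------
# optimization core


def _starts(
    model_id: str,
    options: FitOptions,
    warm_start: RateParameters | None,
) -> list[np.ndarray]:
    n_par = len(MODEL_PARAM_NAMES[model_id])
    lo, hi = np.log(options.bounds[0]), np.log(options.bounds[1])
    starts = [np.zeros(n_par)]  # central: all rates 1
    if warm_start is not None:
        key = (warm_start.model_id, model_id)
        if key in _NESTED_EXPANSION:
            expanded = _NESTED_EXPANSION[key](warm_start.rates)
            vec = RateParameters(model_id, expanded).as_vector()
        elif warm_start.model_id == model_id:
            vec = warm_start.as_vector()
        else:
            raise ValueError(
                f"cannot warm-start {model_id} from {warm_start.model_id}"
            )
        starts.append(np.clip(np.log(np.maximum(vec, options.bounds[0])), lo, hi))
    rng = np.random.default_rng(options.seed)
    while len(starts) < max(options.n_restarts, len(starts)):
        starts.append(rng.uniform(np.log(0.05), np.log(5.0), size=n_par))
    return starts


def _minimize_neg_loglik(
    model_id: str,
    neg_loglik,
    options: FitOptions,
    warm_start: RateParameters | None,
) -> tuple[np.ndarray, float, bool, int]:
    lo, hi = np.log(options.bounds[0]), np.log(options.bounds[1])
    best_x, best_f, any_ok = None, np.inf, False
    starts = _starts(model_id, options, warm_start)
    for x0 in starts:
        res = scipy.optimize.minimize(
            neg_loglik,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * len(x0),
            options={"ftol": options.ftol, "maxiter": options.maxiter},
        )
        if not np.isfinite(res.fun):
            continue
        any_ok = any_ok or res.success
        better = res.fun < best_f - 1e-9
        tie = abs(res.fun - best_f) <= 1e-9
        if better or (
            tie
            and best_x is not None
            and np.linalg.norm(res.x) < np.linalg.norm(best_x)
        ):
            best_x, best_f = res.x, min(res.fun, best_f)
    if best_x is None:
        raise NonIdentifiableError(
            f"optimizer failed on all {len(starts)} starts for {model_id}"
        )
    return best_x, best_f, any_ok, len(starts)


def _bound_hits(model_id: str, x: np.ndarray, options: FitOptions) -> tuple[str, ...]:
    lo, hi = np.log(options.bounds[0]), np.log(options.bounds[1])
    names = MODEL_PARAM_NAMES[model_id]
    hits = [
        n
        for n, xi in zip(names, x)
        if xi <= lo + 1e-6 or xi >= hi - 1e-6
    ]
    return tuple(hits)


def _check_state_space(model_id: str, X: np.ndarray) -> None:
    k = 2 if model_id in BINARY_MODELS else 3
    if X.max(initial=0) >= k:
        raise ValueError(
            f"state codes exceed the state space of model {model_id}; "
            "binarize the vectors for binary models"
        )


def _loss_gain_ratio(params: RateParameters) -> tuple[float, dict[str, float]]:
    """Aggregate loss-to-gain rate ratio plus the per-pair ratios.

    The aggregate pools all loss-type rates over all gain-type rates:
    (l1 + l2 + c2) / (g1 + g2 + c1) for three-state models (with
    c1 = c2 = c under M1), l / g for B2, and 1 by construction for B1.
    """

    def safe_div(a: float, b: float) -> float:
        return a / b if b > 0 else math.inf

    r = params.rates
    if params.model_id == "B1":
        return 1.0, {}
    if params.model_id == "B2":
        return safe_div(r["l"], r["g"]), {"l/g": safe_div(r["l"], r["g"])}
    c1 = c2 = r.get("c", None)
    if params.model_id == "M2":
        c1, c2 = r["c1"], r["c2"]
    agg = safe_div(r["l1"] + r["l2"] + c2, r["g1"] + r["g2"] + c1)
    return agg, {
        "l1/g1": safe_div(r["l1"], r["g1"]),
        "l2/g2": safe_div(r["l2"], r["g2"]),
        "c2/c1": safe_div(c2, c1),
    }


# ---------------------------------------------------------------------------
# public fitting API


def fit_model(
    tree: PhylogeneticTree,
    v,
    model_id: str,
    prior: RootPrior,
    options: FitOptions | None = None,
    warm_start: RateParameters | None = None,
    gene_id: str = "gene",
) -> GeneFit:
    """Fit one model to one gene by maximum likelihood.

    Optimizes the log-likelihood over log-rates with a multi-start
    L-BFGS-B; pass the smaller nested model's optimum as ``warm_start``
    when fitting the larger model, which guarantees l(M2) >= l(M1) and
    l(B2) >= l(B1) up to optimizer tolerance.

    Raises :class:`NonIdentifiableError` for an all-absent vector.
    """
    options = options or FitOptions()
    X = np.atleast_2d(np.asarray(v, dtype=int))
    _check_state_space(model_id, X)
    if np.all(X == 0):
        raise NonIdentifiableError(
            f"gene {gene_id!r}: all-absent vector carries no rate information"
        )

    def neg_loglik(log_rates: np.ndarray) -> float:
        params = RateParameters.from_vector(model_id, np.exp(log_rates))
        ll, _, _ = prune_loglik_batch(tree, X, params, prior)
        return -float(ll[0])

    x, f, converged, n_starts = _minimize_neg_loglik(
        model_id, neg_loglik, options, warm_start
    )
    params = RateParameters.from_vector(model_id, np.exp(x))
    res = prune_likelihood(tree, X[0], params, prior)
    post = root_posterior(res)
    ratio, components = _loss_gain_ratio(params)
    p = params.n_free
    return GeneFit(
        gene_id=gene_id,
        model_id=model_id,
        params=params,
        loglik=-f,
        n_params=p,
        aic=-2.0 * (-f) + 2.0 * p,
        posterior=post,
        presence_probability=post.presence_probability,
        loss_gain_ratio=ratio,
        ratio_components=components,
        converged=converged,
        n_starts=n_starts,
        bound_hits=_bound_hits(model_id, x, options),
        prior=prior,
    )


def fit_family(
    tree: PhylogeneticTree,
    v,
    family: str,
    prior: RootPrior,
    options: FitOptions | None = None,
    gene_id: str = "gene",
) -> dict[str, GeneFit]:
    """Fit both models of a family to one gene, warm-starting the larger.

    ``family`` is ``"binary"`` (B1 then B2) or ``"three-state"`` (M1 then
    M2).  Returns a dict model_id -> GeneFit.
    """
    models = BINARY_MODELS if family == "binary" else THREE_STATE_MODELS
    small = fit_model(tree, v, models[0], prior, options, gene_id=gene_id)
    large = fit_model(
        tree, v, models[1], prior, options, warm_start=small.params, gene_id=gene_id
    )
    return {small.model_id: small, large.model_id: large}


def fit_pooled(
    tree: PhylogeneticTree,
    X,
    model_id: str,
    prior: RootPrior,
    options: FitOptions | None = None,
    warm_start: RateParameters | None = None,
) -> PooledFit:
    """Fit one shared set of rates to many genes (summed log-likelihood).

    Single-vector estimates of 5-6 rates are noisy; the pooled fit is the
    estimate of choice for rate-recovery experiments and cohort-level rate
    statements.
    """
    options = options or FitOptions()
    X = np.atleast_2d(np.asarray(X, dtype=int))
    _check_state_space(model_id, X)
    if X.shape[0] == 0:
        raise NonIdentifiableError("no genes to fit")
    if np.all(X == 0):
        raise NonIdentifiableError("all-absent dataset carries no rate information")

    def neg_loglik(log_rates: np.ndarray) -> float:
        params = RateParameters.from_vector(model_id, np.exp(log_rates))
        ll, _, _ = prune_loglik_batch(tree, X, params, prior)
        return -float(ll.sum())

    x, f, converged, n_starts = _minimize_neg_loglik(
        model_id, neg_loglik, options, warm_start
    )
    params = RateParameters.from_vector(model_id, np.exp(x))
    p = params.n_free
    return PooledFit(
        model_id=model_id,
        params=params,
        loglik=-f,
        n_params=p,
        aic=-2.0 * (-f) + 2.0 * p,
        n_genes=X.shape[0],
        converged=converged,
        n_starts=n_starts,
        bound_hits=_bound_hits(model_id, x, options),
    )


def aic_score(fit: GeneFit | PooledFit) -> float:
    """AIC = -2 l + 2 p with p the model's free-parameter count."""
    return -2.0 * fit.loglik + 2.0 * fit.n_params


def select_model(fits: list[GeneFit]) -> GeneFit:
    """Pick the AIC-preferred fit among models of one family for one gene.

    Minimum AIC wins; an exact tie goes to the model with fewer parameters.
    Fits from different families (e.g. M1 vs B2) are refused: AIC comparisons
    are valid only between models fitted to the same data encoding.
    """
    if not fits:
        raise ValueError("no fits to select from")
    families = {f.family for f in fits}
    if len(families) > 1:
        raise ValueError(
            "AIC comparison across families (binary vs three-state) is invalid: "
            "the models are fitted to different encodings of the data"
        )
    genes = {f.gene_id for f in fits}
    if len(genes) > 1:
        raise ValueError(f"fits belong to different genes: {sorted(genes)}")
    return min(fits, key=lambda f: (f.aic, f.n_params))


def summarize_gene(fit: GeneFit) -> dict:
    """Flat per-gene summary record for tabular output."""
    rec = {
        "gene_id": fit.gene_id,
        "family": fit.family,
        "model": fit.model_id,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "presence_probability": fit.presence_probability,
        "root_state": fit.posterior.argmax_state,
        "loss_gain_ratio": fit.loss_gain_ratio,
        "ratio_infinite": not math.isfinite(fit.loss_gain_ratio),
        "converged": fit.converged,
        "n_starts": fit.n_starts,
        "bound_hits": ",".join(fit.bound_hits),
    }
    for label, prob in zip(fit.posterior.state_labels, fit.posterior.probs):
        rec[f"posterior_{label}"] = float(prob)
    for name, value in fit.params.rates.items():
        rec[f"rate_{name}"] = value
    for name, value in fit.ratio_components.items():
        rec[f"ratio_{name}"] = value
    return rec


def build_ancestral_set(presence_probs: dict[str, float], x: float) -> AncestralSet:
    """Genes whose root presence probability is at least x (inclusive)."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    members = tuple(sorted(g for g, p in presence_probs.items() if p >= x))
    return AncestralSet(threshold=float(x), members=members)


def ancestral_count_series(
    presence_probs: dict[str, float],
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.Series:
    """Member counts of the ancestral set over a threshold grid.

    The series is non-increasing in the threshold (set nesting).
    """
    counts = {
        float(x): len(build_ancestral_set(presence_probs, x).members)
        for x in thresholds
    }
    return pd.Series(counts, name="n_ancestral").sort_index()


def median_transition_summary(
    fits: list[GeneFit],
    t: float,
) -> dict[str, np.ndarray]:
    """Per-model entrywise median of P(t) across genes' fitted rates.

    Evaluated by default at the median branch length of the tree (see
    ``validate_tree``).  The median is taken entry by entry, so the rows of
    the summary matrix need not sum to exactly 1.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    by_model: dict[str, list[np.ndarray]] = {}
    for fit in fits:
        P = transition_matrix(build_rate_matrix(fit.params), t)
        by_model.setdefault(fit.model_id, []).append(P)
    return {m: np.median(np.stack(Ps), axis=0) for m, Ps in by_model.items()}
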