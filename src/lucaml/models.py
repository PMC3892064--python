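"""Substitution-rate matrices for gene gain, loss and duplication.

Four continuous-time Markov models of the evolution of a gene's state in a
genome.  The binary models act on presence/absence (states ``0,1``):

* **B1** — a single rate ``c`` for both gain (0→1) and loss (1→0); 1 free
  parameter.
* **B2** — independent gain ``g`` and loss ``l`` rates; 2 free parameters.

The three-state models act on absence / single copy / multiple in-paralogs
(states ``0,1,m``), distinguishing gene gain (``g1``: 0→1), duplication
(``g2``: 1→m), loss of a single-copy gene (``l1``: 1→0), loss of in-paralogs
down to one copy (``l2``: m→1), and direct jumps between absence and
multiple copies (``c1``: 0→m, ``c2``: m→0):

* **M1** — the direct-jump rates are tied, ``c1 = c2 = c``; 5 free
  parameters.
* **M2** — ``c1`` and ``c2`` are free; 6 free parameters.

State order is fixed as ``(0, 1)`` respectively ``(0, 1, m)``; rows of Q sum
to zero and transition probabilities are ``P(t) = expm(Q t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "MODEL_PARAM_NAMES",
    "MODEL_N_STATES",
    "BINARY_MODELS",
    "THREE_STATE_MODELS",
    "RateParameters",
    "build_rate_matrix",
    "transition_matrix",
    "transition_matrices",
    "two_state_closed_form",
    "stationary_distribution",
    "NonErgodicError",
]

BINARY_MODELS = ("B1", "B2")
THREE_STATE_MODELS = ("M1", "M2")

MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "B1": ("c",),
    "B2": ("g", "l"),
    "M1": ("g1", "g2", "l1", "l2", "c"),
    "M2": ("g1", "g2", "l1", "l2", "c1", "c2"),
}

MODEL_N_STATES: dict[str, int] = {"B1": 2, "B2": 2, "M1": 3, "M2": 3}

STATE_LABELS: dict[int, tuple[str, ...]] = {2: ("0", "1"), 3: ("0", "1", "m")}


class NonErgodicError(ValueError):
    """Raised when a rate matrix has no unique stationary distribution."""


@dataclass(frozen=True)
class RateParameters:
    """Rates of one of the models B1, B2, M1 or M2.

    Parameters
    ----------
    model_id : str
        One of ``"B1"``, ``"B2"``, ``"M1"``, ``"M2"``.
    rates : dict
        Maps the model's free-parameter names to nonnegative finite rates
        (per unit branch length).  Names must match
        ``MODEL_PARAM_NAMES[model_id]`` exactly.
    """

    model_id: str
    rates: dict[str, float]

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_PARAM_NAMES:
            raise ValueError(f"unknown model {self.model_id!r}")
        expected = MODEL_PARAM_NAMES[self.model_id]
        if set(self.rates) != set(expected):
            raise ValueError(
                f"model {self.model_id} expects parameters {expected}, "
                f"got {tuple(sorted(self.rates))}"
            )
        for name, value in self.rates.items():
            v = float(value)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name}={value!r} must be finite and >= 0")

    @property
    def n_free(self) -> int:
        """Number of free parameters p (B1:1, B2:2, M1:5, M2:6)."""
        return len(MODEL_PARAM_NAMES[self.model_id])

    @property
    def n_states(self) -> int:
        return MODEL_N_STATES[self.model_id]

    @property
    def is_binary(self) -> bool:
        return self.n_states == 2

    def as_vector(self) -> np.ndarray:
        """Rates in the model's canonical parameter order."""
        return np.array(
            [self.rates[n] for n in MODEL_PARAM_NAMES[self.model_id]], dtype=float
        )

    @classmethod
    def from_vector(cls, model_id: str, vec) -> "RateParameters":
        names = MODEL_PARAM_NAMES[model_id]
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(names),):
            raise ValueError(
                f"model {model_id} expects {len(names)} rates, got {vec.shape}"
            )
        return cls(model_id, dict(zip(names, vec.tolist())))


def build_rate_matrix(params: RateParameters) -> np.ndarray:
    """Build the substitution-rate matrix Q for a parameterized model.

    Off-diagonal entries are the instantaneous rates of fixation of the
    corresponding state change; diagonals are set so that each row sums to
    zero.  State order is (0, 1) for binary models and (0, 1, m) for
    three-state models.
    """
    r = params.rates
    if params.model_id == "B1":
        g = l = r["c"]
        Q = np.array([[-g, g], [l, -l]], dtype=float)
    elif params.model_id == "B2":
        g, l = r["g"], r["l"]
        Q = np.array([[-g, g], [l, -l]], dtype=float)
    else:
        g1, g2, l1, l2 = r["g1"], r["g2"], r["l1"], r["l2"]
        if params.model_id == "M1":
            c1 = c2 = r["c"]
        else:
            c1, c2 = r["c1"], r["c2"]
        Q = np.array(
            [
                [-(g1 + c1), g1, c1],
                [l1, -(l1 + g2), g2],
                [c2, l2, -(l2 + c2)],
            ],
            dtype=float,
        )
    return Q


def _check_rate_matrix(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q[~np.eye(Q.shape[0], dtype=bool)]
    if np.any(off < 0):
        raise ValueError("off-diagonal rates must be >= 0")
    if np.max(np.abs(Q.sum(axis=1))) > 1e-12 * max(1.0, np.abs(Q).max()):
        raise ValueError("rows of Q must sum to 0")
    return Q


def transition_matrices(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Transition-probability matrices ``P(t_i) = expm(Q t_i)`` for an array
    of branch lengths, shape ``(len(t), k, k)``.

    Uses the eigendecomposition of Q, so that an arbitrary number of branch
    lengths costs a single decomposition; falls back to ``scipy.linalg.expm``
    per branch when the eigenvector matrix is ill-conditioned.  Entries are
    clipped to [0, 1] at the 1e-12 level to remove round-off noise.
    """
    Q = _check_rate_matrix(Q)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("branch lengths must be >= 0")
    k = Q.shape[0]
    P = None
    try:
        w, V = np.linalg.eig(Q)
        cond = np.linalg.cond(V)
        if np.isfinite(cond) and cond < 1e8:
            Vinv = np.linalg.inv(V)
            E = np.exp(np.multiply.outer(t, w))  # (n, k)
            P = np.real(np.einsum("jk,nk,kl->njl", V, E, Vinv))
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        P = None
    if P is None:
        P = np.stack([scipy.linalg.expm(Q * ti) for ti in t.ravel()])
        P = P.reshape(t.shape + (k, k))
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=-1, keepdims=True)
    return P


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition-probability matrix ``P(t) = expm(Q t)`` for one branch.

    Raises ``ValueError`` for negative t.  ``P(0)`` is the identity.
    """
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    return transition_matrices(Q, np.array([t]))[0]


def two_state_closed_form(g: float, l: float, t: float) -> np.ndarray:
    """Analytic two-state transition matrix, the oracle for binary models.

    For gain rate g (0→1) and loss rate l (1→0)::

        p_00 = (l + g e^{-(g+l)t}) / (g+l),  p_01 = 1 - p_00
        p_11 = (g + l e^{-(g+l)t}) / (g+l),  p_10 = 1 - p_11

    Returns the identity when g = l = 0 (frozen chain).
    """
    if g < 0 or l < 0:
        raise ValueError("rates must be >= 0")
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    s = g + l
    if s == 0:
        return np.eye(2)
    e = np.exp(-s * t)
    p00 = (l + g * e) / s
    p11 = (g + l * e) / s
    return np.array([[p00, 1.0 - p00], [1.0 - p11, p11]])


def _is_irreducible(Q: np.ndarray) -> bool:
    # strong connectivity of the positive-rate digraph (k <= 3: matrix powers)
    k = Q.shape[0]
    A = (Q > 0).astype(float) + np.eye(k)
    R = np.linalg.matrix_power(A, k)
    return bool(np.all(R > 0))


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with ``pi @ Q = 0`` and ``sum(pi) = 1``.

    Raises :class:`NonErgodicError` if the chain is reducible (including the
    all-zero matrix), in which case no unique stationary distribution exists.
    """
    Q = _check_rate_matrix(Q)
    if not _is_irreducible(Q):
        raise NonErgodicError("rate matrix is not irreducible (non-ergodic)")
    k = Q.shape[0]
    # solve pi Q = 0 with the normalization row appended
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
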