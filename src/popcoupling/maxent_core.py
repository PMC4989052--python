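"""Maximum-entropy models of neuron-population-rate coupling.

Three nested model structures over binary spike patterns sigma in {0,1}^N are
supported, all of the exponential form

    P(sigma) = (1/Z) exp( sum_i h_{i,K(sigma)} sigma_i ),

where K(sigma) = sum_i sigma_i is the population rate and h is an N x (N+1)
matrix of effective fields:

* ``minimal``   : h_{iK} = alpha_i + beta_K          (rates and P(K) constrained)
* ``linear``    : h_{iK} = alpha_i + beta_K + gamma_i K  (plus <K sigma_i>)
* ``complete``  : h_{iK} unconstrained               (full joints P(sigma_i, K))

The models are tractable: the partition function decomposes over K into
coefficients of generating polynomials, Z = sum_K Coeff[prod_i (1 + X e^{h_iK}),
X^K], each computed by a linear recursion.  All predicted statistics (P(K),
joint neuron/population-rate distributions, pairwise correlations, tuning
curves, pattern probabilities) derive from the same coefficients and are exact.

The field column h[:, 0] multiplies sigma_i in patterns where no neuron spikes
and therefore never enters any probability; it is pinned to 0.  At K = N only
the sum over i of h_{iN} enters (the all-ones pattern), which leaves one
identifiable degree of freedom in that column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._poly import (
    _log_conv_at,
    leave_one_out_log_coeff,
    log_poly_coeffs,
    log_prefix_suffix,
)

__all__ = [
    "CouplingModel",
    "PartitionTerms",
    "ModelMoments",
    "structured_to_h",
    "gauge_fix",
    "log_partition",
    "predict_rate_distribution",
    "predict_joint",
    "predict_pairwise",
    "pattern_log_prob",
    "tuning_curve",
    "moments",
]

STRUCTURES = ("minimal", "linear", "complete")

LOG2 = np.log(2.0)


@dataclass
class CouplingModel:
    """One of the three population-coupling model structures.

    The canonical internal representation is always the full field matrix
    ``h`` of shape (N, N+1); ``structure`` is metadata describing which
    projection of the field matrix the model lives on.  Structured models also
    carry their (gauge-dependent) parameters alpha, beta, gamma.
    """

    h: np.ndarray
    structure: str = "complete"
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.array(self.h, dtype=float)
        if self.h.ndim != 2 or self.h.shape[1] != self.h.shape[0] + 1:
            raise ValueError("field matrix must have shape (N, N+1)")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        self.h[:, 0] = 0.0

    @property
    def n_neurons(self) -> int:
        return self.h.shape[0]

    @classmethod
    def from_parameters(
        cls,
        alpha: np.ndarray,
        beta: np.ndarray,
        gamma: np.ndarray | None = None,
        structure: str | None = None,
    ) -> "CouplingModel":
        """Build a structured model from alpha (N), beta (N+1), gamma (N)."""
        alpha = np.asarray(alpha, dtype=float)
        beta = np.asarray(beta, dtype=float)
        n = alpha.size
        if beta.size != n + 1:
            raise ValueError("beta must have length N + 1")
        if structure is None:
            structure = "minimal" if gamma is None else "linear"
        k = np.arange(n + 1)
        h = alpha[:, None] + beta[None, :]
        g = None
        if gamma is not None:
            g = np.asarray(gamma, dtype=float)
            if g.size != n:
                raise ValueError("gamma must have length N")
            h = h + g[:, None] * k[None, :]
        elif structure == "linear":
            g = np.zeros(n)
        return cls(h=h, structure=structure, alpha=alpha.copy(), beta=beta.copy(), gamma=g)

    @classmethod
    def from_fields(cls, h: np.ndarray) -> "CouplingModel":
        return cls(h=h, structure="complete")

    def as_structure(self, structure: str) -> "CouplingModel":
        """Re-label the model within a larger structure (nesting is exact)."""
        order = {s: i for i, s in enumerate(STRUCTURES)}
        if order[structure] < order[self.structure]:
            raise ValueError("can only embed into an equal or larger structure")
        gamma = self.gamma
        if structure == "linear" and gamma is None and self.alpha is not None:
            gamma = np.zeros(self.n_neurons)
        if structure == "complete":
            return CouplingModel(h=self.h.copy(), structure="complete")
        return CouplingModel(
            h=self.h.copy(), structure=structure, alpha=self.alpha, beta=self.beta, gamma=gamma
        )

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "n_neurons": self.n_neurons,
            "alpha": None if self.alpha is None else self.alpha.tolist(),
            "beta": None if self.beta is None else self.beta.tolist(),
            "gamma": None if self.gamma is None else self.gamma.tolist(),
            "h": self.h.tolist(),
            "gauge": {"beta0": 0.0, "h_i0": 0.0},
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingModel":
        arr = lambda x: None if x is None else np.asarray(x, dtype=float)
        return cls(
            h=np.asarray(d["h"], dtype=float),
            structure=d["structure"],
            alpha=arr(d.get("alpha")),
            beta=arr(d.get("beta")),
            gamma=arr(d.get("gamma")),
            metadata=d.get("metadata", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CouplingModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def structured_to_h(
    alpha: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray | None = None,
    structure: str | None = None,
) -> CouplingModel:
    """Assemble the full field matrix from structured parameters."""
    return CouplingModel.from_parameters(alpha, beta, gamma, structure)


def gauge_fix(model: CouplingModel) -> CouplingModel:
    """Return an equivalent model in the canonical gauge.

    The distribution is invariant under alpha_i -> alpha_i + c,
    beta_K -> beta_K - c (minimal), and additionally beta_K -> beta_K + dK,
    gamma_i -> gamma_i - d (linear).  The canonical gauge pins beta_0 = 0 and
    beta_1 = 0, and for linear models also beta_2 = 0, which removes both
    degeneracies; the field matrix h (hence every probability) is unchanged.
    For complete models the inert column h[:, 0] is zeroed and the K = N
    column, of which only the sum is identifiable, is symmetrized.
    """
    if model.structure == "complete" or model.alpha is None:
        h = model.h.copy()
        h[:, 0] = 0.0
        h[:, -1] = h[:, -1].mean()
        return CouplingModel(h=h, structure=model.structure, metadata=dict(model.metadata))
    alpha = model.alpha.copy()
    beta = model.beta.copy()
    beta[0] = 0.0
    n = alpha.size
    k = np.arange(n + 1, dtype=float)
    if model.structure == "minimal":
        c = beta[1]
        alpha += c
        beta -= c
        gamma = None
    else:
        d = beta[1] - beta[2]
        c = beta[1] + d
        alpha += c
        beta = beta - c + d * k
        gamma = model.gamma - d
    beta[0] = 0.0
    return CouplingModel.from_parameters(alpha, beta, gamma, model.structure)


# --------------------------------------------------------------------------
# Predicted statistics
# --------------------------------------------------------------------------


@dataclass
class PartitionTerms:
    """Per-population-rate log partition terms: Z = sum_K Z_K."""

    log_zk: np.ndarray  # length N+1; log Z_K
    log_z: float

    @property
    def rate_distribution(self) -> np.ndarray:
        return np.exp(self.log_zk - self.log_z)


def _check_fields(model: CouplingModel) -> None:
    if not np.all(np.isfinite(model.h)):
        raise ValueError("model fields must be finite")


def log_partition(model: CouplingModel) -> PartitionTerms:
    """Exact log partition function via the coefficient recursion.

    For each K, log Z_K is the log of the X^K coefficient of
    prod_i (1 + X e^{h_iK}), computed in the log domain; total cost O(N^3).
    """
    _check_fields(model)
    n = model.n_neurons
    log_zk = np.empty(n + 1)
    log_zk[0] = 0.0
    for k in range(1, n + 1):
        log_zk[k] = log_poly_coeffs(model.h[:, k], max_order=k)[k]
    m = log_zk.max()
    log_z = m + np.log(np.exp(log_zk - m).sum())
    return PartitionTerms(log_zk=log_zk, log_z=log_z)


def predict_rate_distribution(model: CouplingModel) -> np.ndarray:
    """P(K) = Z_K / Z for K = 0..N."""
    return log_partition(model).rate_distribution


def predict_joint(model: CouplingModel, terms: PartitionTerms | None = None) -> np.ndarray:
    """Joint distribution P(sigma_i = 1, K = k), shape (N, N+1).

    Equals the derivative of log Z with respect to h_{ik}:
    (1/Z) e^{h_ik} Coeff[X prod_{j != i} (1 + X e^{h_jk}), X^k].
    """
    _check_fields(model)
    if terms is None:
        terms = log_partition(model)
    n = model.n_neurons
    joint = np.zeros((n, n + 1))
    for k in range(1, n + 1):
        loo = leave_one_out_log_coeff(model.h[:, k], k - 1)
        # the argument is a log-probability, <= 0 up to roundoff
        joint[:, k] = np.exp(np.minimum(model.h[:, k] + loo - terms.log_z, 0.0))
    return joint


def _pair_second_moment_k(log_b: np.ndarray, k: int) -> np.ndarray:
    """Upper-triangular log Coeff of X^{k-2} over products excluding i and j.

    Returns an (N, N) array, filled for j > i, with the log-coefficient of
    order k-2 of prod_{m not in {i,j}} (1 + X e^{log_b[m]}).
    """
    n = log_b.size
    out = np.full((n, n), -np.inf)
    if k < 2:
        return out
    for i in range(n - 1):
        reduced = np.delete(log_b, i)
        lp, ls = log_prefix_suffix(reduced, k - 2)
        for j in range(i + 1, n):
            out[i, j] = _log_conv_at(lp[j - 1], ls[j], k - 2)
    return out


def pair_second_moments_by_k(
    model: CouplingModel, terms: PartitionTerms | None = None
) -> np.ndarray:
    """S[k][i, j] = <sigma_i sigma_j delta_{K,k}> under the model.

    Shape (N+1, N, N), symmetric in (i, j) with diagonal
    S[k][i, i] = P(sigma_i = 1, K = k).  These are the second moments needed
    for pairwise correlations and for the Hessian of the log-likelihood.
    """
    _check_fields(model)
    if terms is None:
        terms = log_partition(model)
    n = model.n_neurons
    joint = predict_joint(model, terms)
    s = np.zeros((n + 1, n, n))
    for k in range(2, n + 1):
        logb = model.h[:, k]
        c2 = _pair_second_moment_k(logb, k)
        sk = np.exp(np.minimum(logb[:, None] + logb[None, :] + c2 - terms.log_z, 0.0))
        sk = sk + sk.T
        s[k] = sk
    for k in range(n + 1):
        np.fill_diagonal(s[k], joint[:, k])
    return s


def predict_pairwise(
    model: CouplingModel, terms: PartitionTerms | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Second moments <sigma_i sigma_j> and covariances under the model.

    The diagonal of the second-moment matrix equals the firing rates.
    """
    s = pair_second_moments_by_k(model, terms)
    second = s.sum(axis=0)
    rates = np.diag(second)
    cov = second - np.outer(rates, rates)
    return second, cov


def pattern_log_prob(model: CouplingModel, patterns: np.ndarray) -> np.ndarray | float:
    """log2-probability of binary patterns under the model (in bits)."""
    _check_fields(model)
    patterns = np.asarray(patterns)
    single = patterns.ndim == 1
    pats = np.atleast_2d(patterns).astype(float)
    if pats.shape[1] != model.n_neurons:
        raise ValueError("pattern length must equal the number of neurons")
    k = pats.sum(axis=1).astype(int)
    energy = np.einsum("si,si->s", pats, model.h[:, k].T)
    terms = log_partition(model)
    out = (energy - terms.log_z) / LOG2
    return float(out[0]) if single else out


def tuning_curve(joint: np.ndarray, rate_distribution: np.ndarray) -> np.ndarray:
    """Tuning curves p(sigma_i = 1 | K_other) from a joint P(sigma_i=1, K).

    K_other is the summed activity of all neurons but i, ranging 0..N-1.
    Uses P(sigma_i=1, K_other) = P(sigma_i=1, K=K_other+1) and
    P(sigma_i=0, K_other) = P(K=K_other) - P(sigma_i=1, K=K_other).
    Entries whose conditioning probability vanishes are NaN (missing), not 0.
    """
    joint = np.asarray(joint, dtype=float)
    pk = np.asarray(rate_distribution, dtype=float)
    n = joint.shape[0]
    num = joint[:, 1:]  # P(sigma_i=1, K_other = 0..N-1)
    p_silent = np.clip(pk[None, :n] - joint[:, :n], 0.0, None)
    den = num + p_silent
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return curve


@dataclass
class ModelMoments:
    """Bundle of exact model moments used by inference and evaluation."""

    terms: PartitionTerms
    rate_distribution: np.ndarray
    joint: np.ndarray
    second_by_k: np.ndarray | None = None

    @property
    def firing_rates(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def couplings(self) -> np.ndarray:
        k = np.arange(self.joint.shape[1])
        return self.joint @ k


def moments(model: CouplingModel, pairwise: bool = False) -> ModelMoments:
    """Compute the model's exact moments in one pass."""
    terms = log_partition(model)
    joint = predict_joint(model, terms)
    second = pair_second_moments_by_k(model, terms) if pairwise else None
    return ModelMoments(
        terms=terms,
        rate_distribution=terms.rate_distribution,
        joint=joint,
        second_by_k=second,
    )
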