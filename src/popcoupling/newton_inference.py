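"""Maximum-likelihood inference of population-coupling models by Newton's method.

All three model structures are exponential families, so the normalized
log-likelihood L(mu) = <sum_i h_{iK} sigma_i>_data - log Z is concave and its
derivatives are moment differences:

    dL/dmu_a      = <O_a>_data - <O_a>_model
    d2L/dmu_a dmu_b = <O_a><O_b> - <O_a O_b>   (minus the model covariance)

Every structured observable is a linear combination of the complete-model
features sigma_i delta_{K,k} (k = 1..N), so gradients and Hessians for all
structures are projections of the same exact model moments.  The update is
mu <- mu - a H^{-1} grad L with backtracking on the step size a, the Hessian
being refreshed only every ``hessian_refresh_every`` iterations.  Convergence
is declared on the fitting error: the maximum absolute discrepancy on the
statistics each structure constrains (P(K) and rates for the minimal model;
plus <K sigma_i> for the linear model; P(K) and the conditionals
P(sigma_i=1|K) for the complete model).

Free parameters (gauge): the minimal model optimizes {alpha_i} and
{beta_K, K >= 2} with beta_1 = 0 (2N-1 parameters); the linear model
additionally {gamma_i} with beta_1 = beta_2 = 0 (3N-2); the complete model
optimizes h_{iK} for K = 1..N-1 plus the single pooled field sum_i h_{iN}
(N(N-1)+1).  The complete model's Hessian is block-diagonal in K minus a
rank-one term, which the solver exploits via the Woodbury identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .maxent_core import LOG2, CouplingModel, ModelMoments, moments
from .raster_stats import EmpiricalStats

__all__ = [
    "FitOptions",
    "FitResult",
    "gradient",
    "hessian",
    "normalized_log_likelihood",
    "fitting_error",
    "fit",
]


@dataclass
class FitOptions:
    step_size: float = 1.0
    tolerance: float = 1e-6
    max_iterations: int = 2000
    hessian_refresh_every: int = 100
    ridge: float = 1e-8
    init: str = "independent"

    def __post_init__(self) -> None:
        if not (0 < self.step_size <= 1):
            raise ValueError("step size must lie in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class FitResult:
    model: CouplingModel
    converged: bool
    iterations: int
    final_fitting_error: float
    ll_trace: list[float] = field(default_factory=list)  # bits per pattern

    def save_diagnostics(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "structure": self.model.structure,
                    "converged": self.converged,
                    "iterations": self.iterations,
                    "final_fitting_error": self.final_fitting_error,
                    "ll_trace_bits": self.ll_trace,
                },
                indent=1,
            )
        )


# --------------------------------------------------------------------------
# Parameterizations: free parameters <-> field matrix, plus the linear map T
# from the complete-model features sigma_i delta_{K,k} to each observable.
# Features are ordered K-major: index (k-1)*N + i for k = 1..N.
# --------------------------------------------------------------------------


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError(
            "statistics contain probabilities at 0 or 1; regularize with a "
            "positive pseudocount before fitting"
        )
    return np.log(p) - np.log1p(-p)


class _Parameterization:
    def __init__(self, structure: str, n: int):
        if structure not in ("minimal", "linear", "complete"):
            raise ValueError(f"unknown structure {structure!r}")
        if n < 1 or (structure != "minimal" and n < 2):
            raise ValueError("population too small for this structure")
        self.structure = structure
        self.n = n
        if structure == "minimal":
            self.n_params = 2 * n - 1
        elif structure == "linear":
            self.n_params = 3 * n - 2
        else:
            self.n_params = n * (n - 1) + 1
        self._T = None

    # -- parameter vector <-> field matrix ---------------------------------
    def init(self, stats: EmpiricalStats) -> np.ndarray:
        """Independent-model start close to the optimum's basin.

        Minimal/linear: alpha_i = logit(rate_i), beta = gamma = 0.  Complete:
        h_{ik} = logit P(sigma_i=1|K=k) plus a per-column offset c_k.  Adding
        c_k to a whole column rescales Z_k by exactly e^{k c_k}, so the
        offsets are chosen to make the initial P(K) match the empirical one
        exactly; without them the logit start concentrates P(K) near K = N
        and the likelihood surface is numerically degenerate there.
        """
        from .maxent_core import CouplingModel, log_partition

        mu = np.zeros(self.n_params)
        n = self.n
        if self.structure == "complete":
            cond = stats.conditional
            body = _logit(cond[:, 1:n])  # (N, N-1)
            pk = stats.rate_distribution
            if np.any(pk <= 0):
                raise ValueError(
                    "P(K) has zeros; regularize with a positive pseudocount before fitting"
                )
            h = np.zeros((n, n + 1))
            h[:, 1:n] = body
            base = log_partition(CouplingModel(h=h)).log_zk
            log_target = np.log(pk) - np.log(pk[0])
            ks = np.arange(1, n)
            offsets = (log_target[1:n] - base[1:n]) / ks
            mu[:-1] = (body + offsets[None, :]).T.ravel()
            mu[-1] = log_target[n]
        else:
            mu[:n] = _logit(stats.firing_rates)
        return mu

    def fields(self, mu: np.ndarray) -> np.ndarray:
        n = self.n
        h = np.zeros((n, n + 1))
        if self.structure == "complete":
            h[:, 1:n] = mu[:-1].reshape(n - 1, n).T
            h[:, n] = mu[-1] / n
            return h
        alpha = mu[:n]
        beta = np.zeros(n + 1)
        if self.structure == "minimal":
            beta[2:] = mu[n:]
            h = alpha[:, None] + beta[None, :]
        else:
            gamma = mu[n : 2 * n]
            beta[3:] = mu[2 * n :]
            k = np.arange(n + 1, dtype=float)
            h = alpha[:, None] + beta[None, :] + gamma[:, None] * k[None, :]
        h[:, 0] = 0.0
        return h

    def model(self, mu: np.ndarray) -> CouplingModel:
        n = self.n
        if self.structure == "complete":
            return CouplingModel(h=self.fields(mu), structure="complete")
        alpha = mu[:n].copy()
        beta = np.zeros(n + 1)
        gamma = None
        if self.structure == "minimal":
            beta[2:] = mu[n:]
        else:
            gamma = mu[n : 2 * n].copy()
            beta[3:] = mu[2 * n :]
        return CouplingModel.from_parameters(alpha, beta, gamma, self.structure)

    def pack(self, model: CouplingModel) -> np.ndarray:
        """Extract the free-parameter vector from a model (canonical gauge)."""
        from .maxent_core import gauge_fix

        g = gauge_fix(model)
        mu = np.zeros(self.n_params)
        n = self.n
        if self.structure == "complete":
            mu[:-1] = g.h[:, 1:n].T.ravel()
            mu[-1] = g.h[:, n].sum()
        elif self.structure == "minimal":
            mu[:n] = g.alpha
            mu[n:] = g.beta[2:]
        else:
            mu[:n] = g.alpha
            mu[n : 2 * n] = g.gamma
            mu[2 * n :] = g.beta[3:]
        return mu

    # -- feature projection -------------------------------------------------
    def feature_map(self) -> np.ndarray:
        """Dense map T (N*N features -> n_params observables)."""
        if self._T is not None:
            return self._T
        n = self.n
        t = np.zeros((n * n, self.n_params))
        if self.structure == "complete":
            t[: n * (n - 1), : n * (n - 1)] = np.eye(n * (n - 1))
            t[n * (n - 1) :, -1] = 1.0 / n
        else:
            for k in range(1, n + 1):
                rows = slice((k - 1) * n, k * n)
                t[rows, :n] += np.eye(n)  # alpha_i: sigma_i
                if self.structure == "minimal":
                    if k >= 2:
                        t[rows, n + k - 2] = 1.0  # beta_k: K delta_{K,k}
                else:
                    t[rows, n : 2 * n] += k * np.eye(n)  # gamma_i: K sigma_i
                    if k >= 3:
                        t[rows, 2 * n + k - 3] = 1.0
        self._T = t
        return t

    @staticmethod
    def vec(joint: np.ndarray) -> np.ndarray:
        """Flatten a joint matrix over features (K-major, k = 1..N)."""
        return joint[:, 1:].T.ravel()


# --------------------------------------------------------------------------
# Likelihood, gradient, Hessian
# --------------------------------------------------------------------------


def normalized_log_likelihood(
    model: CouplingModel, stats: EmpiricalStats, mom: ModelMoments | None = None
) -> float:
    """Normalized log-likelihood of the target statistics, in bits/pattern."""
    if mom is None:
        mom = moments(model)
    energy = float(np.sum(model.h[:, 1:] * stats.joint[:, 1:]))
    return (energy - mom.terms.log_z) / LOG2


def gradient(
    model: CouplingModel, stats: EmpiricalStats, mom: ModelMoments | None = None
) -> np.ndarray:
    """Gradient of the normalized log-likelihood (nats) over free parameters.

    Each entry is the observed minus the model mean of that parameter's
    observable; it vanishes exactly at the maximum-likelihood point.
    """
    if stats.n_neurons != model.n_neurons:
        raise ValueError("model and statistics dimensions disagree")
    par = _Parameterization(model.structure, model.n_neurons)
    if mom is None:
        mom = moments(model)
    diff = par.vec(stats.joint) - par.vec(mom.joint)
    return par.feature_map().T @ diff


def hessian(model: CouplingModel, mom: ModelMoments | None = None) -> np.ndarray:
    """Dense Hessian of the normalized log-likelihood (nats): minus the
    covariance matrix of the constrained observables under the model."""
    par = _Parameterization(model.structure, model.n_neurons)
    if mom is None or mom.second_by_k is None:
        mom = moments(model, pairwise=True)
    t = par.feature_map()
    n = model.n_neurons
    m = t.T @ par.vec(mom.joint)
    second = np.zeros((par.n_params, par.n_params))
    for k in range(1, n + 1):
        tk = t[(k - 1) * n : k * n]
        second += tk.T @ mom.second_by_k[k] @ tk
    return np.outer(m, m) - second


def _robust_cho_factor(a: np.ndarray, ridge: float):
    """Cholesky of a PSD matrix with escalating scale-relative ridge.

    Observables at rarely visited population rates have second moments many
    orders of magnitude below 1, and conditioning on a fixed population rate
    makes the covariance within a rate block nearly singular (the sum of the
    sigma_i is constant there); the ridge is therefore scaled to each block's
    own diagonal, escalating until the factorization succeeds.
    """
    scale = max(float(a.diagonal().max()), 1e-300)
    r = ridge
    for _ in range(16):
        b = a.copy()
        b[np.diag_indices_from(b)] += r * scale
        try:
            return scipy.linalg.cho_factor(b)
        except np.linalg.LinAlgError:
            r *= 100.0
    raise np.linalg.LinAlgError(
        f"Hessian block not positive definite even at relative ridge {r:g}"
    )


class _DenseNewtonSolver:
    """Factorized solve of (-H + ridge) d = g."""

    def __init__(self, model: CouplingModel, mom: ModelMoments, ridge: float):
        self._f = _robust_cho_factor(-hessian(model, mom), ridge)

    def solve(self, g: np.ndarray) -> np.ndarray:
        return scipy.linalg.cho_solve(self._f, g)


class _WoodburyNewtonSolver:
    """Complete-model Newton solve exploiting block-plus-rank-one structure.

    -H = blockdiag_k(S_k) - m m^T with S_k the second-moment block of the
    features at population rate k (k = 1..N-1) plus a scalar block P(K=N) for
    the pooled K=N parameter.  With A = blockdiag + ridge I,
    (A - m m^T)^{-1} g = A^{-1} g + A^{-1} m (m^T A^{-1} g) / (1 - m^T A^{-1} m).
    """

    def __init__(self, model: CouplingModel, mom: ModelMoments, ridge: float):
        n = model.n_neurons
        if mom.second_by_k is None:
            mom = moments(model, pairwise=True)
        self.n = n
        self._factors = []
        for k in range(1, n):
            self._factors.append(_robust_cho_factor(mom.second_by_k[k], ridge))
        self._scalar = mom.rate_distribution[n] * (1 + ridge) + 1e-300
        m = np.empty(n * (n - 1) + 1)
        m[:-1] = mom.joint[:, 1:n].T.ravel()
        m[-1] = mom.rate_distribution[n]
        self._m = m
        self._aim = self._block_solve(m)
        self._denom = 1.0 - m @ self._aim
        if self._denom <= 1e-14:
            raise np.linalg.LinAlgError(
                "Hessian rank-one correction is numerically singular; "
                "increase the ridge damping"
            )

    def _block_solve(self, g: np.ndarray) -> np.ndarray:
        n = self.n
        out = np.empty_like(g)
        for k in range(1, n):
            sl = slice((k - 1) * n, k * n)
            out[sl] = scipy.linalg.cho_solve(self._factors[k - 1], g[sl])
        out[-1] = g[-1] / self._scalar
        return out

    def solve(self, g: np.ndarray) -> np.ndarray:
        y = self._block_solve(g)
        return y + self._aim * (self._m @ y) / self._denom


def fitting_error(
    model: CouplingModel, stats: EmpiricalStats, mom: ModelMoments | None = None
) -> float:
    """Maximum absolute discrepancy on the structure's constrained statistics.

    minimal:  P(K) and the firing rates P(sigma_i).
    linear:   P(K), firing rates, and the couplings <K sigma_i>.
    complete: P(K) and the conditionals P(sigma_i = 1 | K).
    """
    if stats.n_neurons != model.n_neurons:
        raise ValueError("model and statistics dimensions disagree")
    if mom is None:
        mom = moments(model)
    err = float(np.abs(mom.rate_distribution - stats.rate_distribution).max())
    if model.structure == "complete":
        cond_data = stats.conditional
        pk = mom.rate_distribution
        with np.errstate(invalid="ignore", divide="ignore"):
            cond_model = np.where(pk > 0, mom.joint / np.where(pk > 0, pk, 1.0), np.nan)
        d = np.abs(cond_model[:, 1:] - cond_data[:, 1:])
        valid = np.isfinite(d)
        if valid.any():
            err = max(err, float(d[valid].max()))
    else:
        err = max(err, float(np.abs(mom.firing_rates - stats.firing_rates).max()))
        if model.structure == "linear":
            err = max(err, float(np.abs(mom.couplings - stats.couplings).max()))
    return err


# --------------------------------------------------------------------------
# Newton loop
# --------------------------------------------------------------------------

_MIN_BACKTRACK = 2.0**-20


def fit(
    stats: EmpiricalStats,
    structure: str = "linear",
    options: FitOptions | None = None,
) -> FitResult:
    """Fit a model structure to empirical statistics by Newton ascent.

    The statistics should be pseudocount-regularized so that every constrained
    probability is strictly inside (0, 1).  The fit is deterministic given the
    statistics and options.  Non-convergence within ``max_iterations`` returns
    an unconverged :class:`FitResult` (never silent).
    """
    if options is None:
        options = FitOptions()
    par = _Parameterization(structure, stats.n_neurons)
    solver_cls = _WoodburyNewtonSolver if structure == "complete" else _DenseNewtonSolver
    mu = par.init(stats)
    model = par.model(mu)
    mom = moments(model)
    ll = normalized_log_likelihood(model, stats, mom)
    trace = [ll]
    solver = None
    stale = options.hessian_refresh_every  # force refresh on first iteration
    err = fitting_error(model, stats, mom)
    iterations = 0
    for iterations in range(1, options.max_iterations + 1):
        if err <= options.tolerance:
            return FitResult(model, True, iterations - 1, err, trace)
        g = gradient(model, stats, mom)
        if solver is None or stale >= options.hessian_refresh_every:
            solver = solver_cls(model, mom, options.ridge)
            stale = 0
        direction = solver.solve(g)
        a = options.step_size
        while True:
            mu_new = mu + a * direction
            model_new = par.model(mu_new)
            mom_new = moments(model_new)
            ll_new = normalized_log_likelihood(model_new, stats, mom_new)
            if ll_new >= ll - 1e-12:
                break
            a /= 2
            if a < _MIN_BACKTRACK:
                if stale > 0:  # retry with a fresh Hessian
                    solver = solver_cls(model, mom, options.ridge)
                    stale = 0
                    direction = solver.solve(g)
                    a = options.step_size
                else:
                    break  # accept the tiny step; ascent is numerically flat
        mu, model, mom, ll = mu_new, model_new, mom_new, ll_new
        trace.append(ll)
        stale += 1
        err = fitting_error(model, stats, mom)
    converged = err <= options.tolerance
    return FitResult(model, converged, iterations, err, trace)
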