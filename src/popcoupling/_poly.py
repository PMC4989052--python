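"""Log-domain polynomial-coefficient recursions.

The partition function of the population-coupling models decomposes over the
population rate K into coefficients of generating polynomials of the form
``prod_i (1 + b_i X)`` with ``b_i = exp(h_i)``.  The same recursion yields the
Poisson-binomial distribution of a sum of independent Bernoulli variables.
All coefficients are positive, so they are carried as logarithms and combined
with log-sum-exp, which stays finite for arbitrarily large fields.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "log_poly_coeffs",
    "log_prefix_suffix",
    "leave_one_out_log_coeff",
    "log_poisson_binomial",
]


def log_poly_coeffs(log_b: np.ndarray, max_order: int | None = None) -> np.ndarray:
    """Log-coefficients of ``prod_i (1 + exp(log_b[i]) * X)``.

    Parameters
    ----------
    log_b:
        Logarithms of the per-factor weights (length N).  ``-inf`` entries are
        allowed and correspond to factors equal to 1.
    max_order:
        Highest polynomial order to carry (default N).

    Returns
    -------
    Array ``c`` of length ``max_order + 1`` with ``c[l] = log Coeff[., X^l]``.
    """
    log_b = np.asarray(log_b, dtype=float)
    n = log_b.size
    if max_order is None:
        max_order = n
    c = np.full(max_order + 1, -np.inf)
    c[0] = 0.0
    for i in range(n):
        hi = min(i + 1, max_order)
        c[1 : hi + 1] = np.logaddexp(c[1 : hi + 1], log_b[i] + c[0:hi])
    return c


def log_prefix_suffix(log_b: np.ndarray, max_order: int) -> tuple[np.ndarray, np.ndarray]:
    """Prefix and suffix coefficient tables for leave-one-out queries.

    Returns ``(LP, LS)`` where ``LP[m]`` holds the log-coefficients (orders
    ``0..max_order``) of the product of factors ``0..m-1`` and ``LS[m]`` those
    of factors ``m..N-1``; ``LP[0]`` and ``LS[N]`` are the unit polynomial.
    """
    log_b = np.asarray(log_b, dtype=float)
    n = log_b.size
    lp = np.full((n + 1, max_order + 1), -np.inf)
    ls = np.full((n + 1, max_order + 1), -np.inf)
    lp[0, 0] = 0.0
    ls[n, 0] = 0.0
    for i in range(n):
        lp[i + 1] = lp[i]
        lp[i + 1, 1:] = np.logaddexp(lp[i, 1:], log_b[i] + lp[i, :-1])
    for i in range(n - 1, -1, -1):
        ls[i] = ls[i + 1]
        ls[i, 1:] = np.logaddexp(ls[i + 1, 1:], log_b[i] + ls[i + 1, :-1])
    return lp, ls


def _log_conv_at(a: np.ndarray, b: np.ndarray, order: int) -> float:
    """log of sum_r exp(a[r] + b[order-r]) for one polynomial order."""
    lo = max(0, order - (b.size - 1))
    hi = min(order, a.size - 1)
    if lo > hi:
        return -np.inf
    terms = a[lo : hi + 1] + b[order - hi : order - lo + 1][::-1]
    m = terms.max()
    if m == -np.inf:
        return -np.inf
    return m + np.log(np.exp(terms - m).sum())


def leave_one_out_log_coeff(
    log_b: np.ndarray,
    order: int,
    tables: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """For each i, the log-coefficient of X^order of the product excluding i.

    Computed by convolving precomputed prefix and suffix tables, avoiding the
    numerically unstable deconvolution of a single factor.
    """
    log_b = np.asarray(log_b, dtype=float)
    n = log_b.size
    if order < 0:
        return np.full(n, -np.inf)
    if tables is None:
        tables = log_prefix_suffix(log_b, max(order, 0))
    lp, ls = tables
    out = np.empty(n)
    for i in range(n):
        out[i] = _log_conv_at(lp[i], ls[i + 1], order)
    return out


def log_poisson_binomial(p: np.ndarray) -> np.ndarray:
    """Log-PMF of the sum of independent Bernoulli(p_i) variables.

    Uses the same coefficient recursion as the partition function: the PMF of
    K is the X^K coefficient of ``prod_i (1-p_i) (1 + X p_i/(1-p_i))``.
    Handles p_i in the closed interval [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n = p.size
    sure = p == 1.0
    n_sure = int(sure.sum())
    q = p[~sure]
    with np.errstate(divide="ignore"):
        log_odds = np.log(q) - np.log1p(-q)
        log_miss = np.log1p(-q).sum()
    c = log_poly_coeffs(log_odds) + log_miss
    out = np.full(n + 1, -np.inf)
    out[n_sure : n_sure + c.size] = c
    return out
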