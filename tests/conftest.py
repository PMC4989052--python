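"""Shared fixtures and the brute-force enumeration oracle.

The oracle computes every model statistic by direct summation over all 2^N
binary patterns.  It is deliberately independent of the package's
coefficient-recursion code paths and is only usable for small N.
"""

from __future__ import annotations

import numpy as np
import pytest

from popcoupling.maxent_core import CouplingModel


def enumerate_patterns(n: int) -> np.ndarray:
    """All 2^n binary patterns; pattern p has bit i = (p >> i) & 1."""
    codes = np.arange(2**n)
    return ((codes[:, None] >> np.arange(n)) & 1).astype(float)


def brute_force(model: CouplingModel) -> dict:
    """Exact model statistics by enumeration over all patterns."""
    n = model.n_neurons
    pats = enumerate_patterns(n)
    k = pats.sum(axis=1).astype(int)
    energy = np.einsum("si,si->s", pats, model.h[:, k].T)
    w = np.exp(energy)
    z = w.sum()
    p = w / z
    pk = np.array([p[k == kk].sum() for kk in range(n + 1)])
    joint = np.zeros((n, n + 1))
    for i in range(n):
        for kk in range(n + 1):
            joint[i, kk] = p[(pats[:, i] == 1) & (k == kk)].sum()
    second = (pats.T * p) @ pats
    # tuning curves: P(sigma_i=1 | K_other), K_other = 0..n-1
    tuning = np.full((n, n), np.nan)
    for i in range(n):
        k_other = k - pats[:, i].astype(int)
        for ko in range(n):
            den = p[k_other == ko].sum()
            if den > 0:
                tuning[i, ko] = p[(pats[:, i] == 1) & (k_other == ko)].sum() / den
    return {
        "patterns": pats,
        "log_z": np.log(z),
        "zk": np.array([w[k == kk].sum() for kk in range(n + 1)]),
        "pattern_probs": p,
        "rate_distribution": pk,
        "joint": joint,
        "second_moments": second,
        "tuning": tuning,
    }


def random_model(
    structure: str, n: int, rng: np.random.Generator, scale: float = 1.0
) -> CouplingModel:
    """A random model of the requested structure with O(1) fields."""
    alpha = rng.uniform(-scale, scale, n)
    beta = rng.uniform(-scale, scale, n + 1)
    beta[0] = 0.0
    if structure == "minimal":
        return CouplingModel.from_parameters(alpha, beta)
    gamma = rng.uniform(-scale / n, scale / n, n)
    if structure == "linear":
        return CouplingModel.from_parameters(alpha, beta, gamma)
    h = np.zeros((n, n + 1))
    h[:, 1:] = rng.uniform(-scale, scale, (n, n))
    return CouplingModel(h=h)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2016)
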