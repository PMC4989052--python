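"""Binned spike rasters and the empirical observables the models constrain.

A recording enters the pipeline either as per-neuron spike-time lists (binned
here, default 20 ms bins, binarized: a bin is 1 if the neuron fired at least
once in it) or directly as a binary matrix of shape (n_bins, n_neurons).

From a raster we measure the plug-in statistics that parameterize the models:
per-neuron firing rates <sigma_i>, the population-rate distribution P(K) with
K = sum_i sigma_i, linear couplings <K sigma_i>, the joints P(sigma_i=1, K),
and optionally pairwise moments <sigma_i sigma_j>.  Pseudocount
regularization mixes the empirical P(K) and conditionals P(sigma_i=1|K) with
the predictions of an independent-neuron model carrying total weight lambda
(default 1, i.e. one observed pattern's worth), which removes the zeros that
would otherwise break maximum-likelihood inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ._poly import log_poisson_binomial

__all__ = [
    "BinnedRaster",
    "EmpiricalStats",
    "bin_spike_times",
    "empirical_stats",
    "independent_rate_distribution",
    "regularize",
    "split_halves",
    "read_spike_times",
    "write_spike_times",
]

logger = logging.getLogger(__name__)


@dataclass
class BinnedRaster:
    """Binary spike matrix over time bins (rows) and neurons (columns)."""

    spikes: np.ndarray
    bin_width: float = 0.02

    def __post_init__(self) -> None:
        spikes = np.asarray(self.spikes)
        if spikes.ndim != 2:
            raise ValueError("spike matrix must be 2-dimensional (bins x neurons)")
        if not np.isin(spikes, (0, 1)).all():
            raise ValueError("spike matrix entries must be 0 or 1")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        self.spikes = spikes.astype(np.uint8)

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[1]

    @property
    def population_rate(self) -> np.ndarray:
        """Per-bin population rate K = sum_i sigma_i."""
        return self.spikes.sum(axis=1).astype(np.int64)

    def subset(self, bins: np.ndarray) -> "BinnedRaster":
        return BinnedRaster(self.spikes[np.asarray(bins)], self.bin_width)

    # ------------------------------------------------------------------ io
    def save_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.spikes, fmt="%d", delimiter=",")

    @classmethod
    def load_csv(cls, path: str | Path, bin_width: float = 0.02) -> "BinnedRaster":
        spikes = np.loadtxt(path, delimiter=",", dtype=np.uint8, ndmin=2)
        return cls(spikes=spikes, bin_width=bin_width)

    def save_npz(self, path: str | Path) -> None:
        np.savez_compressed(path, spikes=self.spikes, bin_width=self.bin_width)

    @classmethod
    def load_npz(cls, path: str | Path) -> "BinnedRaster":
        with np.load(path) as data:
            return cls(spikes=data["spikes"], bin_width=float(data["bin_width"]))


@dataclass
class EmpiricalStats:
    """Observables measured from a raster; the targets of model inference.

    ``joint[i, k]`` is P(sigma_i = 1, K = k); ``couplings[i]`` is
    <K sigma_i>.  Raw counts (``rate_counts`` = n_K, ``joint_counts`` = n_iK)
    are kept so pseudocount regularization can be applied after the fact.
    """

    n_neurons: int
    n_samples: int
    firing_rates: np.ndarray
    rate_distribution: np.ndarray
    couplings: np.ndarray
    joint: np.ndarray
    pairwise: np.ndarray | None = None
    regularized: bool = False
    pseudocount: float = 0.0
    rate_counts: np.ndarray | None = None
    joint_counts: np.ndarray | None = None

    @property
    def conditional(self) -> np.ndarray:
        """P(sigma_i = 1 | K = k); NaN where P(K = k) = 0."""
        pk = self.rate_distribution
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(pk > 0, self.joint / np.where(pk > 0, pk, 1.0), np.nan)
        return cond


def bin_spike_times(
    spike_times: list[np.ndarray],
    bin_width: float = 0.02,
    time_range: tuple[float, float] | None = None,
) -> BinnedRaster:
    """Bin per-neuron spike-time lists into a binary raster.

    Bins are half-open intervals [start + t*w, start + (t+1)*w); several
    spikes in one bin collapse to a single 1.  Spikes outside ``time_range``
    are dropped (their count is logged).
    """
    if not spike_times:
        raise ValueError("need at least one neuron")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    trains = [np.asarray(t, dtype=float) for t in spike_times]
    for t in trains:
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError("spike times must be finite")
    if time_range is None:
        hi = max((t.max() for t in trains if t.size), default=0.0)
        time_range = (0.0, hi + bin_width)
    start, end = time_range
    n_bins = int(np.floor((end - start) / bin_width))
    if n_bins <= 0:
        raise ValueError("time range shorter than one bin")
    spikes = np.zeros((n_bins, len(trains)), dtype=np.uint8)
    dropped = 0
    for i, t in enumerate(trains):
        idx = np.floor((t - start) / bin_width).astype(int)
        ok = (t >= start) & (idx < n_bins)
        dropped += int((~ok).sum())
        spikes[idx[ok], i] = 1
    if dropped:
        logger.info("dropped %d spikes outside the requested time range", dropped)
    return BinnedRaster(spikes=spikes, bin_width=bin_width)


def empirical_stats(raster: BinnedRaster, include_pairwise: bool = False) -> EmpiricalStats:
    """Plug-in averages over bins of all constrained observables."""
    if raster.n_bins == 0:
        raise ValueError("raster has no bins")
    x = raster.spikes.astype(np.float64)
    n, n_neurons = x.shape
    k = raster.population_rate
    rate_counts = np.bincount(k, minlength=n_neurons + 1).astype(float)
    joint_counts = np.zeros((n_neurons, n_neurons + 1))
    np.add.at(joint_counts.T, k, x)
    firing_rates = x.mean(axis=0)
    rate_distribution = rate_counts / n
    joint = joint_counts / n
    couplings = (x * k[:, None]).mean(axis=0)
    pairwise = (x.T @ x) / n if include_pairwise else None
    return EmpiricalStats(
        n_neurons=n_neurons,
        n_samples=n,
        firing_rates=firing_rates,
        rate_distribution=rate_distribution,
        couplings=couplings,
        joint=joint,
        pairwise=pairwise,
        rate_counts=rate_counts,
        joint_counts=joint_counts,
    )


def independent_rate_distribution(firing_rates: np.ndarray) -> np.ndarray:
    """P(K) under independent neurons with the given rates (Poisson binomial)."""
    rates = np.asarray(firing_rates, dtype=float)
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("firing rates must lie in [0, 1]")
    return np.exp(log_poisson_binomial(rates))


def _independent_joint(firing_rates: np.ndarray) -> np.ndarray:
    """P_indep(sigma_i = 1, K = k): rate_i times the others' Poisson binomial."""
    rates = np.asarray(firing_rates, dtype=float)
    n = rates.size
    joint = np.zeros((n, n + 1))
    for i in range(n):
        others = np.exp(log_poisson_binomial(np.delete(rates, i)))
        joint[i, 1:] = rates[i] * others
    return joint


def regularize(stats: EmpiricalStats, pseudocount: float = 1.0) -> EmpiricalStats:
    """Pseudocount regularization shaped by an independent-neuron model.

    With lambda = ``pseudocount`` and raw counts n_K, n_iK over n patterns:

        P(K)            = (n_K  + lambda P_indep(K)) / (n + lambda)
        P(sigma_i=1|K)  = (n_iK + lambda P_indep(sigma_i=1|K)) / (n_K + lambda)

    Joints and couplings are recomputed from the regularized P(K) and
    conditionals, which preserves the identity sum_i P(sigma_i=1,K) = K P(K)
    exactly (the pseudo-conditionals sum to K).  The two denominators follow
    different totals, so the regularized conditionals are not the exact
    conditionals of a single mixture distribution; the discrepancy carries
    total weight of order lambda/n.
    """
    lam = float(pseudocount)
    if lam < 0:
        raise ValueError("pseudocount weight must be nonnegative")
    if lam == 0:
        return stats
    if stats.rate_counts is None or stats.joint_counts is None:
        raise ValueError("raw counts are required for regularization")
    n = stats.n_samples
    n_neurons = stats.n_neurons
    p_indep_k = independent_rate_distribution(stats.firing_rates)
    joint_indep = _independent_joint(stats.firing_rates)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond_indep = np.where(
            p_indep_k > 0, joint_indep / np.where(p_indep_k > 0, p_indep_k, 1.0), 0.0
        )
    pk = (stats.rate_counts + lam * p_indep_k) / (n + lam)
    cond = (stats.joint_counts + lam * cond_indep) / (stats.rate_counts + lam)[None, :]
    # identities P(sigma_i=1|K=N) = 1 and P(sigma_i=1|K=0) = 0 hold exactly;
    # re-impose them against floating-point noise in the pseudocount shape
    cond[:, -1] = 1.0
    joint = cond * pk[None, :]
    joint[:, 0] = 0.0
    k = np.arange(n_neurons + 1, dtype=float)
    return replace(
        stats,
        firing_rates=joint.sum(axis=1),
        rate_distribution=pk,
        couplings=joint @ k,
        joint=joint,
        regularized=True,
        pseudocount=lam,
    )


def split_halves(
    n_bins: int, n_splits: int, seed: int | np.random.Generator = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random half/half partitions of bin indices (train, test).

    Bins are treated as exchangeable patterns; each split is a permutation
    cut in two halves whose sizes differ by at most one.
    """
    if n_bins < 2:
        raise ValueError("need at least two bins to split")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    half = n_bins // 2
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(n_bins)
        splits.append((np.sort(perm[:half]), np.sort(perm[half:])))
    return splits


# ---------------------------------------------------------------------- io
def read_spike_times(path: str | Path) -> list[np.ndarray]:
    """Read two-column text (neuron_id, time_in_seconds) into per-neuron lists."""
    data = np.loadtxt(path, ndmin=2, delimiter=None)
    if data.size == 0:
        raise ValueError("empty spike-time file")
    if data.shape[1] == 1:  # possibly comma separated
        data = np.loadtxt(path, ndmin=2, delimiter=",")
    ids = data[:, 0].astype(int)
    times = data[:, 1]
    if ids.min() < 0:
        raise ValueError("neuron ids must be nonnegative")
    n = ids.max() + 1
    return [np.sort(times[ids == i]) for i in range(n)]


def write_spike_times(path: str | Path, spike_times: list[np.ndarray]) -> None:
    rows = [(i, t) for i, ts in enumerate(spike_times) for t in np.asarray(ts)]
    arr = np.array(rows, dtype=float).reshape(-1, 2)
    np.savetxt(path, arr, fmt=["%d", "%.9f"])
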