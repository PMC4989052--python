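"""Model-assessment statistics for population-coupling models.

Covers the cross-validated comparison machinery: Kullback-Leibler divergences
between held-out and model joints P(sigma_i, K), normalized to the sampling
noise measured between test and train halves (the z statistic); a
goodness-of-fit index C for pairwise correlations ranging from 0 (model
ignores correlations) to 1 (model accounts for all correlations up to
sampling noise); mean log-likelihoods in bits per pattern; detection of
significant extrema in tuning curves across split replicates; and
multi-information I = S_indep - S_data with the fraction captured by a model,
I_model / I_data (exact model entropies, plug-in data entropies for
subpopulations of at most 20 neurons).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import maxent_core, newton_inference, raster_stats
from .maxent_core import LOG2, CouplingModel, moments, pattern_log_prob, tuning_curve
from .raster_stats import BinnedRaster, EmpiricalStats

__all__ = [
    "kl_divergence",
    "normalized_kl",
    "goodness_of_fit_C",
    "Extremum",
    "TuningCurve",
    "detect_extrema",
    "mean_log_likelihood",
    "likelihood_improvement_ratio",
    "multi_information",
    "entropy_data",
    "entropy_independent",
    "entropy_model",
    "EvalReport",
    "cross_validate",
    "tuning_replicates",
]


# --------------------------------------------------------------------------
# Elementary statistics
# --------------------------------------------------------------------------


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """D_KL(P || Q) in bits; requires Q > 0 wherever P > 0."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise ValueError("distributions must share a support")
    mask = p > 0
    if np.any(q[mask] <= 0):
        raise ValueError(
            "Q vanishes where P does not; regularize the distributions first"
        )
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask]))) / LOG2)


def normalized_kl(divs_test_model: np.ndarray, divs_test_train: np.ndarray) -> float:
    """z = mean(d) / sd(d) with d = D(test||model) - D(test||train) over splits.

    Measures by how many SDs of the sampling noise the model deviates from the
    held-out data.  Returns NaN when the SD across splits is zero (undefined).
    """
    a = np.asarray(divs_test_model, dtype=float)
    b = np.asarray(divs_test_train, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 splits")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        # identical divergence vectors give z = 0; equal nonzero differences
        # leave z undefined
        return 0.0 if d.mean() == 0 else float("nan")
    return float(d.mean() / sd)


def goodness_of_fit_C(
    c_test: np.ndarray, c_model: np.ndarray, c_train: np.ndarray
) -> float:
    """Fraction of held-out pairwise correlations captured by the model.

    C = [sum c_test^2 - sum (c_test - c_model)^2]
        / [sum c_test^2 - sum (c_test - c_train)^2].

    C = 1 when the model reproduces the training correlations exactly and
    C = 0 for a model with no correlations (c_model = 0).  NaN when the
    denominator vanishes (undefined).
    """
    ct = np.asarray(c_test, dtype=float).ravel()
    cm = np.asarray(c_model, dtype=float).ravel()
    cr = np.asarray(c_train, dtype=float).ravel()
    if not (ct.shape == cm.shape == cr.shape):
        raise ValueError("correlation vectors must have equal length")
    num = np.sum(ct**2) - np.sum((ct - cm) ** 2)
    den = np.sum(ct**2) - np.sum((ct - cr) ** 2)
    if den == 0:
        return float("nan")
    return float(num / den) + 0.0  # normalize -0.0


# --------------------------------------------------------------------------
# Tuning-curve extrema
# --------------------------------------------------------------------------


@dataclass
class Extremum:
    kind: str  # "max" | "min"
    location: float  # population rate of the other neurons, K_other
    significant: bool
    height: float


@dataclass
class TuningCurve:
    """Tuning curve of one neuron in the population rate of the others."""

    neuron: int
    values: np.ndarray  # mean over splits; NaN = undefined
    replicates: np.ndarray | None = None  # (n_splits, n_points)
    extrema: list[Extremum] = field(default_factory=list)


def _significant_side(diffs: np.ndarray, threshold: float, sign: float) -> bool:
    """Is the mean of sign*diffs at least ``threshold`` SDs above 0?"""
    d = sign * diffs
    mean = d.mean()
    if mean <= 0:
        return False
    sd = d.std(ddof=1)
    if sd == 0:
        return True  # noiseless, strictly positive difference
    return mean >= threshold * sd


def detect_extrema(
    replicates: np.ndarray,
    sd_threshold: float = 5.0,
    neighborhood: int = 1,
) -> list[Extremum]:
    """Significant local maxima and minima of a tuning curve across splits.

    ``replicates`` has shape (n_splits, n_points).  A point is a significant
    maximum when its value exceeds the points ``neighborhood`` steps below and
    above it, with each difference at least ``sd_threshold`` SDs (across
    splits, sample SD) above 0; minima are symmetric.  The reported location
    is the median, across splits, of the per-split argmax (argmin) within the
    candidate's neighborhood.  All significant extrema are returned, ordered
    by height (depth).
    """
    reps = np.atleast_2d(np.asarray(replicates, dtype=float))
    if reps.shape[0] < 2:
        raise ValueError("need at least two split replicates")
    n_points = reps.shape[1]
    w = int(neighborhood)
    found: list[Extremum] = []
    for j in range(w, n_points - w):
        window = reps[:, j - w : j + w + 1]
        if not np.isfinite(window).all():
            continue
        d_lo = reps[:, j] - reps[:, j - w]
        d_hi = reps[:, j] - reps[:, j + w]
        for kind, sign in (("max", 1.0), ("min", -1.0)):
            if _significant_side(d_lo, sd_threshold, sign) and _significant_side(
                d_hi, sd_threshold, sign
            ):
                per_split = (
                    np.argmax(sign * window, axis=1) + j - w
                )  # per-split extremum within the neighborhood
                found.append(
                    Extremum(
                        kind=kind,
                        location=float(np.median(per_split)),
                        significant=True,
                        height=float(sign * reps[:, j].mean()),
                    )
                )
    found.sort(key=lambda e: -e.height)
    return found


# --------------------------------------------------------------------------
# Likelihood and multi-information
# --------------------------------------------------------------------------


def mean_log_likelihood(model: CouplingModel, raster: BinnedRaster) -> float:
    """Mean log2-probability per pattern (bits) of the raster under the model."""
    return float(np.mean(pattern_log_prob(model, raster.spikes)))


def likelihood_improvement_ratio(
    minimal: CouplingModel,
    linear: CouplingModel,
    complete: CouplingModel,
    raster: BinnedRaster,
) -> float:
    """<log P_complete - log P_minimal> / <log P_linear - log P_minimal>.

    Measures how much of the likelihood gain over the minimal model requires
    the nonlinear (complete) coupling rather than the linear one.
    """
    lp_min = pattern_log_prob(minimal, raster.spikes)
    lp_lin = pattern_log_prob(linear, raster.spikes)
    lp_com = pattern_log_prob(complete, raster.spikes)
    return float(np.mean(lp_com - lp_min) / np.mean(lp_lin - lp_min))


def entropy_data(raster: BinnedRaster) -> float:
    """Plug-in entropy (bits) of the observed pattern frequencies; N <= 20."""
    if raster.n_neurons > 20:
        raise ValueError("plug-in pattern entropy is limited to 20 neurons")
    codes = raster.spikes.astype(np.int64) @ (1 << np.arange(raster.n_neurons, dtype=np.int64))
    _, counts = np.unique(codes, return_counts=True)
    freq = counts / counts.sum()
    return float(-(freq * np.log(freq)).sum() / LOG2)


def entropy_independent(firing_rates: np.ndarray) -> float:
    """Entropy (bits) of independent neurons with the given rates."""
    p = np.asarray(firing_rates, dtype=float)
    p = p[(p > 0) & (p < 1)]
    return float(-np.sum(p * np.log(p) + (1 - p) * np.log1p(-p)) / LOG2)


def entropy_model(model: CouplingModel) -> float:
    """Exact entropy (bits) of a coupling model: log2 Z - <energy>/ln 2."""
    mom = moments(model)
    energy = float(np.sum(model.h[:, 1:] * mom.joint[:, 1:]))
    return (mom.terms.log_z - energy) / LOG2


@dataclass
class MultiInformation:
    i_data: float
    i_model: float | None
    ratio: float | None
    s_data: float
    s_indep: float
    s_model: float | None


def multi_information(
    raster: BinnedRaster, model: CouplingModel | None = None
) -> MultiInformation:
    """Multi-information I = S_indep - S_data and the model-captured fraction.

    ``S_indep`` uses the empirical firing rates; ``S_data`` is the plug-in
    pattern entropy (subpopulations of at most 20 neurons); ``S_model`` is the
    model's exact entropy.  The ratio I_model / I_data lies in (0, 1) for a
    fitted maximum-entropy model, up to plug-in sampling noise.
    """
    if raster.n_neurons > 20:
        raise ValueError("multi-information is limited to 20 neurons")
    s_data = entropy_data(raster)
    s_indep = entropy_independent(raster.spikes.mean(axis=0))
    i_data = s_indep - s_data
    if model is None:
        return MultiInformation(i_data, None, None, s_data, s_indep, None)
    s_model = entropy_model(model)
    i_model = s_indep - s_model
    ratio = i_model / i_data if i_data != 0 else float("nan")
    return MultiInformation(i_data, i_model, ratio, s_data, s_indep, s_model)


# --------------------------------------------------------------------------
# Cross-validated model comparison
# --------------------------------------------------------------------------


def _joint_distribution(joint_row: np.ndarray, pk: np.ndarray) -> np.ndarray:
    """Distribution of (sigma_i, K) over 2(N+1) states from P(sigma_i=1, K)."""
    silent = np.clip(pk - joint_row, 0.0, None)
    return np.concatenate([silent, joint_row])


def _upper(c: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(c.shape[0], k=1)
    return c[iu]


@dataclass
class EvalReport:
    """Cross-validated comparison of the three model structures."""

    n_neurons: int
    n_splits: int
    structures: tuple[str, ...]
    z: dict  # structure -> per-neuron normalized KL (length N)
    goodness_of_fit: dict  # structure -> (mean, sd) over splits
    mean_ll_bits: dict  # structure -> (mean, sd) over splits, test sets
    improvement_ratio: tuple[float, float] | None = None
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        out = {
            "n_neurons": self.n_neurons,
            "n_splits": self.n_splits,
            "structures": list(self.structures),
            "z": {s: np.asarray(v).tolist() for s, v in self.z.items()},
            "goodness_of_fit": {s: list(v) for s, v in self.goodness_of_fit.items()},
            "mean_ll_bits": {s: list(v) for s, v in self.mean_ll_bits.items()},
            "improvement_ratio": (
                None if self.improvement_ratio is None else list(self.improvement_ratio)
            ),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(out, indent=1))

    def to_tsv(self, path: str | Path) -> None:
        lines = ["neuron\t" + "\t".join(f"z_{s}" for s in self.structures)]
        for i in range(self.n_neurons):
            vals = "\t".join(f"{self.z[s][i]:.6g}" for s in self.structures)
            lines.append(f"{i}\t{vals}")
        Path(path).write_text("\n".join(lines) + "\n")


def cross_validate(
    raster: BinnedRaster,
    structures: tuple[str, ...] = ("minimal", "linear", "complete"),
    n_splits: int = 100,
    pseudocount: float = 1.0,
    seed: int = 0,
    options: newton_inference.FitOptions | None = None,
) -> EvalReport:
    """Train/test the model structures on random halves of the raster.

    For each split, models are fitted to the regularized training statistics;
    per-neuron KL divergences of the held-out joints P(sigma_i, K) against the
    model and against the training half yield the z statistic, held-out
    pairwise covariances yield the goodness-of-fit index C, and held-out mean
    log-likelihoods (bits/pattern) are recorded.
    """
    n = raster.n_neurons
    splits = raster_stats.split_halves(raster.n_bins, n_splits, seed)
    dm = {s: np.zeros((n_splits, n)) for s in structures}
    dt = np.zeros((n_splits, n))
    cs = {s: np.zeros(n_splits) for s in structures}
    lls = {s: np.zeros(n_splits) for s in structures}
    ratios = np.zeros(n_splits) if set(structures) >= {"minimal", "linear", "complete"} else None
    for si, (train_idx, test_idx) in enumerate(splits):
        train = raster.subset(train_idx)
        test = raster.subset(test_idx)
        stats_train = raster_stats.regularize(
            raster_stats.empirical_stats(train, include_pairwise=True), pseudocount
        )
        stats_test = raster_stats.regularize(
            raster_stats.empirical_stats(test, include_pairwise=True), pseudocount
        )
        cov_test = _upper(
            stats_test.pairwise - np.outer(stats_test.firing_rates, stats_test.firing_rates)
        )
        cov_train = _upper(
            stats_train.pairwise - np.outer(stats_train.firing_rates, stats_train.firing_rates)
        )
        fitted: dict[str, CouplingModel] = {}
        for s in structures:
            res = newton_inference.fit(stats_train, s, options)
            fitted[s] = res.model
            mom = moments(res.model)
            _, cov_model = maxent_core.predict_pairwise(res.model, mom.terms)
            cs[s][si] = goodness_of_fit_C(cov_test, _upper(cov_model), cov_train)
            lls[s][si] = mean_log_likelihood(res.model, test)
            for i in range(n):
                p = _joint_distribution(stats_test.joint[i], stats_test.rate_distribution)
                q = _joint_distribution(mom.joint[i], mom.rate_distribution)
                dm[s][si, i] = kl_divergence(p, q)
        for i in range(n):
            p = _joint_distribution(stats_test.joint[i], stats_test.rate_distribution)
            q = _joint_distribution(stats_train.joint[i], stats_train.rate_distribution)
            dt[si, i] = kl_divergence(p, q)
        if ratios is not None:
            ratios[si] = likelihood_improvement_ratio(
                fitted["minimal"], fitted["linear"], fitted["complete"], test
            )
    z = {
        s: np.array([normalized_kl(dm[s][:, i], dt[:, i]) for i in range(n)])
        for s in structures
    }
    report = EvalReport(
        n_neurons=n,
        n_splits=n_splits,
        structures=tuple(structures),
        z=z,
        goodness_of_fit={s: (float(cs[s].mean()), float(cs[s].std(ddof=1))) for s in structures},
        mean_ll_bits={s: (float(lls[s].mean()), float(lls[s].std(ddof=1))) for s in structures},
        improvement_ratio=(
            None if ratios is None else (float(ratios.mean()), float(ratios.std(ddof=1)))
        ),
        seed=seed,
    )
    return report


def tuning_replicates(
    raster: BinnedRaster,
    n_splits: int = 100,
    source: str = "data",
    pseudocount: float = 1.0,
    seed: int = 0,
    options: newton_inference.FitOptions | None = None,
) -> np.ndarray:
    """Per-split tuning curves, shape (n_splits, N, N).

    ``source`` is either "data" (regularized empirical tuning curves of each
    training half) or a model structure name, in which case the model is
    fitted to each training half and its predicted tuning curves are returned.
    """
    n = raster.n_neurons
    splits = raster_stats.split_halves(raster.n_bins, n_splits, seed)
    out = np.zeros((n_splits, n, n))
    for si, (train_idx, _) in enumerate(splits):
        stats = raster_stats.regularize(
            raster_stats.empirical_stats(raster.subset(train_idx)), pseudocount
        )
        if source == "data":
            joint, pk = stats.joint, stats.rate_distribution
        else:
            res = newton_inference.fit(stats, source, options)
            mom = moments(res.model)
            joint, pk = mom.joint, mom.rate_distribution
        out[si] = tuning_curve(joint, pk)
    return out
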