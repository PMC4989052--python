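"""KL statistics, goodness-of-fit, extrema detection, and multi-information."""

import numpy as np
import pytest

from popcoupling import evaluation as ev
from popcoupling import maxent_core as mc
from popcoupling import newton_inference as ni
from popcoupling import raster_stats as rs
from popcoupling import sampler
from popcoupling.raster_stats import BinnedRaster


class TestKLDivergence:
    def test_zero_iff_equal(self, rng):
        p = rng.random(5)
        p /= p.sum()
        assert ev.kl_divergence(p, p) == pytest.approx(0, abs=1e-14)

    def test_closed_form_one_bit(self):
        assert ev.kl_divergence([1, 0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_matches_direct_summation(self, rng):
        p = rng.random(4)
        p /= p.sum()
        q = rng.random(4)
        q /= q.sum()
        expected = sum(pi * np.log2(pi / qi) for pi, qi in zip(p, q))
        assert ev.kl_divergence(p, q) == pytest.approx(expected)

    def test_error_on_missing_support(self):
        with pytest.raises(ValueError):
            ev.kl_divergence([0.5, 0.5], [1.0, 0.0])

    def test_nonnegative(self, rng):
        for _ in range(5):
            p = rng.random(6)
            p /= p.sum()
            q = rng.random(6) + 0.01
            q /= q.sum()
            assert ev.kl_divergence(p, q) >= 0


class TestNormalizedKL:
    def test_direct_arithmetic(self):
        # differences (1, 2, 3): mean 2, sample SD 1 -> z = 2
        assert ev.normalized_kl([2.0, 3.0, 4.0], [1.0, 1.0, 1.0]) == pytest.approx(2.0)

    def test_zero_when_model_equals_train(self):
        d = np.array([0.3, 0.5, 0.4])
        noise = np.array([0.01, -0.02, 0.01])
        assert ev.normalized_kl(d + noise, d + noise) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_when_sd_zero(self):
        assert np.isnan(ev.normalized_kl([2.0, 2.0], [1.0, 1.0]))

    def test_scale_invariance_of_differences(self):
        a = np.array([0.2, 0.5, 0.9, 0.4])
        b = np.array([0.1, 0.2, 0.3, 0.2])
        z1 = ev.normalized_kl(a, b)
        z2 = ev.normalized_kl(b + 2 * (a - b), b)
        assert z1 == pytest.approx(z2)


class TestGoodnessOfFit:
    def test_perfect_model_is_one(self, rng):
        c_train = rng.normal(size=10)
        c_test = c_train + rng.normal(scale=0.01, size=10)
        assert ev.goodness_of_fit_C(c_test, c_train, c_train) == pytest.approx(1.0)

    def test_correlation_blind_model_is_zero(self, rng):
        c_train = rng.normal(size=10)
        c_test = c_train + rng.normal(scale=0.01, size=10)
        assert ev.goodness_of_fit_C(c_test, np.zeros(10), c_train) == pytest.approx(0.0)

    def test_direct_substitution(self):
        c_test = np.array([0.1, 0.2])
        c_train = np.array([0.12, 0.18])
        c_model = np.array([0.05, 0.1])
        num = (0.1**2 + 0.2**2) - ((0.1 - 0.05) ** 2 + (0.2 - 0.1) ** 2)
        den = (0.1**2 + 0.2**2) - ((0.1 - 0.12) ** 2 + (0.2 - 0.18) ** 2)
        assert ev.goodness_of_fit_C(c_test, c_model, c_train) == pytest.approx(num / den)

    def test_undefined_when_denominator_vanishes(self):
        c = np.array([0.1, -0.1])
        train = np.array([0.1 + 0.2, -0.1 - 0.2])  # (c-train)^2 sums to c^2... not zero
        # construct exact zero denominator: c_train such that sum(c^2) == sum((c-train)^2)
        assert np.isnan(ev.goodness_of_fit_C(c, c, np.array([0.2, -0.2])))


class TestDetectExtrema:
    def test_monotone_curve_has_no_extrema(self, rng):
        base = np.linspace(0, 1, 8)
        reps = base[None, :] + rng.normal(scale=1e-4, size=(10, 8))
        assert ev.detect_extrema(reps) == []

    def test_noiseless_bump_detected_at_three(self):
        base = np.array([0.1, 0.2, 0.3, 0.8, 0.3, 0.2, 0.1])
        reps = np.tile(base, (6, 1))
        found = ev.detect_extrema(reps)
        assert len(found) == 1
        assert found[0].kind == "max"
        assert found[0].location == 3
        assert found[0].significant

    def test_noisy_bump_not_significant(self, rng):
        base = np.array([0.1, 0.2, 0.3, 0.35, 0.3, 0.2, 0.1])
        # cross-split SD of the neighbour differences exceeds bump height / 5
        reps = base[None, :] + rng.normal(scale=0.2, size=(20, 7))
        found = [e for e in ev.detect_extrema(reps) if e.kind == "max"]
        assert found == []

    def test_minimum_detected(self):
        base = np.array([0.8, 0.5, 0.1, 0.5, 0.8])
        reps = np.tile(base, (5, 1))
        found = ev.detect_extrema(reps)
        kinds = {e.kind for e in found}
        assert "min" in kinds
        assert [e.location for e in found if e.kind == "min"] == [2]

    def test_nan_entries_are_skipped(self):
        base = np.array([0.1, 0.9, np.nan, 0.2, 0.1])
        reps = np.tile(base, (4, 1))
        # positions adjacent to the NaN cannot be tested; no crash, no extrema there
        found = ev.detect_extrema(reps)
        assert all(e.location not in (1.0, 2.0, 3.0) for e in found)


class TestLikelihoods:
    def test_uniform_model_three_bits(self, rng):
        m = mc.CouplingModel(h=np.zeros((3, 4)))
        raster = BinnedRaster((rng.random((50, 3)) < 0.5).astype(int))
        assert ev.mean_log_likelihood(m, raster) == pytest.approx(-3.0)

    def test_repeated_pattern_gives_its_log_prob(self, rng):
        m = mc.CouplingModel(h=rng.uniform(-1, 1, (4, 5)))
        pattern = np.array([1, 0, 1, 0])
        raster = BinnedRaster(np.tile(pattern, (30, 1)))
        assert ev.mean_log_likelihood(m, raster) == pytest.approx(
            mc.pattern_log_prob(m, pattern)
        )

    def test_matches_per_pattern_average(self, rng):
        m = mc.CouplingModel(h=rng.uniform(-1, 1, (5, 6)))
        raster = BinnedRaster((rng.random((100, 5)) < 0.3).astype(int))
        expected = np.mean([mc.pattern_log_prob(m, row) for row in raster.spikes])
        assert ev.mean_log_likelihood(m, raster) == pytest.approx(expected)


class TestMultiInformation:
    def test_independent_raster_has_tiny_multi_information(self):
        ds = sampler.make_synthetic_dataset(
            "independent-with-gain", n_neurons=6, n_bins=50000, seed=1, gain_sd=0.0,
            alpha_range=(-2.0, -1.0),
        )
        mi = ev.multi_information(ds.raster)
        assert 0 <= mi.i_data < 0.01

    def test_perfectly_coupled_pair_closed_form(self):
        # patterns 00 and 11 equiprobable: S_data = 1 bit, S_indep = 2 bits
        x = np.zeros((100, 2), dtype=int)
        x[::2] = 1
        mi = ev.multi_information(BinnedRaster(x))
        assert mi.s_data == pytest.approx(1.0)
        assert mi.s_indep == pytest.approx(2.0)
        assert mi.i_data == pytest.approx(1.0)

    def test_ratio_two_computations_agree(self):
        """For a maxent model fitted to the raster, S_model equals the negative
        mean test log-likelihood on the fitting data (the energies match), so
        I_model from entropies equals S_indep + mean log-likelihood."""
        ds = sampler.make_synthetic_dataset("known-model", n_neurons=8, n_bins=40000, seed=2)
        stats = rs.regularize(rs.empirical_stats(ds.raster), 1.0)
        res = ni.fit(stats, "linear")
        mi = ev.multi_information(ds.raster, res.model)
        i_model_ll = mi.s_indep + ev.mean_log_likelihood(res.model, ds.raster)
        assert mi.i_model == pytest.approx(i_model_ll, abs=5e-3)
        assert 0 < mi.ratio <= 1.05

    def test_size_limit(self, rng):
        raster = BinnedRaster((rng.random((10, 21)) < 0.5).astype(int))
        with pytest.raises(ValueError):
            ev.multi_information(raster)

    def test_entropy_ordering_on_fitted_models(self):
        ds = sampler.make_synthetic_dataset("known-model", n_neurons=8, n_bins=40000, seed=4)
        stats = rs.regularize(rs.empirical_stats(ds.raster), 1.0)
        s_data = ev.entropy_data(ds.raster)
        s_indep = ev.entropy_independent(ds.raster.spikes.mean(axis=0))
        for structure in ("minimal", "linear", "complete"):
            res = ni.fit(stats, structure)
            s_model = ev.entropy_model(res.model)
            assert s_indep >= s_model - 1e-6
            assert s_model >= s_data - 0.02  # plug-in S_data is biased down


class TestCompleteModelReproducesTuningCurves:
    def test_by_construction(self):
        ds = sampler.make_synthetic_dataset("known-model", n_neurons=7, n_bins=20000, seed=5)
        stats = rs.regularize(rs.empirical_stats(ds.raster), 1.0)
        res = ni.fit(stats, "complete", ni.FitOptions(tolerance=1e-8))
        assert res.converged
        mom = mc.moments(res.model)
        emp = mc.tuning_curve(stats.joint, stats.rate_distribution)
        mod = mc.tuning_curve(mom.joint, mom.rate_distribution)
        ok = np.isfinite(emp) & np.isfinite(mod)
        assert np.abs(emp[ok] - mod[ok]).max() < 1e-6


class TestCrossValidate:
    def test_small_pipeline(self):
        ds = sampler.make_synthetic_dataset("known-model", n_neurons=5, n_bins=6000, seed=6)
        report = ev.cross_validate(ds.raster, n_splits=4, seed=1)
        assert set(report.structures) == {"minimal", "linear", "complete"}
        for s in report.structures:
            assert report.z[s].shape == (5,)
            c_mean, _ = report.goodness_of_fit[s]
            assert np.isfinite(c_mean)
            ll_mean, _ = report.mean_ll_bits[s]
            assert -10 < ll_mean < 0
        # nested models: held-out likelihood ordering holds on average here
        assert report.mean_ll_bits["complete"][0] >= report.mean_ll_bits["minimal"][0] - 0.05

    def test_report_io(self, tmp_path):
        ds = sampler.make_synthetic_dataset("known-model", n_neurons=4, n_bins=3000, seed=7)
        report = ev.cross_validate(ds.raster, structures=("minimal",), n_splits=3, seed=2)
        report.to_json(tmp_path / "r.json")
        report.to_tsv(tmp_path / "r.tsv")
        assert (tmp_path / "r.json").exists()
        lines = (tmp_path / "r.tsv").read_text().strip().splitlines()
        assert len(lines) == 5  # header + 4 neurons

    def test_tuning_replicates_shapes(self):
        ds = sampler.make_synthetic_dataset("known-model", n_neurons=4, n_bins=3000, seed=8)
        reps = ev.tuning_replicates(ds.raster, n_splits=3, source="data", seed=3)
        assert reps.shape == (3, 4, 4)
        reps_m = ev.tuning_replicates(ds.raster, n_splits=2, source="minimal", seed=3)
        assert reps_m.shape == (2, 4, 4)
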