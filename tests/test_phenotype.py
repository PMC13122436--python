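"""Dip test, mixture EM, and the density-crossing phenotype cutoff."""

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from otolife.phenotype import (
    MixtureFit,
    classify_phenotype,
    density_crossing,
    dip_null_distribution,
    dip_statistic,
    dip_test,
    fit_mixture,
)

from .oracles import density_crossing_grid_oracle, dip_lp_oracle


class TestDipStatistic:
    def test_equally_spaced_floor(self):
        """Perfectly regular data attain the 1/(2n) lower bound."""
        for n in (5, 10, 40):
            assert dip_statistic(np.arange(n)) == pytest.approx(1 / (2 * n), abs=1e-12)

    def test_two_tight_clusters_near_quarter(self):
        x = np.concatenate([np.linspace(0, 1e-3, 50), 1 + np.linspace(0, 1e-3, 50)])
        assert dip_statistic(x) == pytest.approx(0.25, abs=0.01)

    def test_matches_lp_oracle_on_random_samples(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(5, 16))
            if trial % 3 == 0:
                x = rng.normal(size=n)
            elif trial % 3 == 1:
                x = np.concatenate(
                    [rng.normal(-3, 0.3, n // 2), rng.normal(3, 0.3, n - n // 2)]
                )
            else:
                x = rng.random(n)
            assert dip_statistic(x) == pytest.approx(dip_lp_oracle(x), abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        assert dip_statistic(x) == dip_statistic(rng.permutation(x))

    def test_scale_and_shift_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        assert dip_statistic(x) == pytest.approx(dip_statistic(5.0 * x + 3.0), abs=1e-12)


class TestDipTest:
    def test_bimodal_mixture_rejected(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(35, 3, 1000), rng.normal(72, 8, 1000)])
        d, p = dip_test(x, n_boot=200, seed=0)
        assert p < 0.01

    def test_unimodal_ocean_entry_sizes_not_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(80, 9, 2000)
        d, p = dip_test(x, n_boot=200, seed=0)
        assert p > 0.1

    def test_conservative_for_normal_samples(self):
        """Calibrated on the least-favourable (uniform) null, the test can
        only under-reject for normal data — never exceed its nominal level."""
        rng = np.random.default_rng(7)
        null = dip_null_distribution(100, 500, rng)
        crit = np.quantile(null, 0.95)
        rej = sum(dip_statistic(rng.normal(size=100)) > crit for _ in range(100))
        assert rej / 100 <= 0.08  # nominal 0.05 plus binomial slack, one-sided

    def test_small_samples_and_n_boot_warning(self):
        with pytest.raises(ValueError):
            dip_test([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            dip_test(np.arange(10.0), n_boot=50, seed=0)


class TestMixtureEM:
    def test_recovers_well_separated_components(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(40.5, 3.0, 1400), rng.normal(70.0, 8.0, 600)])
        fit = fit_mixture(x, seed=3)
        assert fit.converged
        assert fit.means[0] == pytest.approx(40.5, abs=1.0)
        assert fit.means[1] == pytest.approx(70.0, abs=1.0)
        assert fit.weights[0] == pytest.approx(0.7, abs=0.05)

    def test_symmetric_mixture_fits_symmetrically(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-20, 4, 1000), rng.normal(20, 4, 1000)])
        fit = fit_mixture(x, seed=4)
        assert fit.means[0] == pytest.approx(-fit.means[1], abs=0.5)
        assert fit.weights[0] == pytest.approx(0.5, abs=0.05)

    def test_duplicated_data_same_estimates(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(40, 3, 300), rng.normal(70, 8, 200)])
        f1 = fit_mixture(x, seed=5)
        f2 = fit_mixture(np.repeat(x, 2), seed=5)
        assert np.allclose(f1.means, f2.means, atol=1e-3)
        assert np.allclose(f1.sds, f2.sds, atol=1e-3)
        assert np.allclose(f1.weights, f2.weights, atol=1e-3)

    def test_agrees_with_sklearn_gaussian_mixture(self):
        """Independent EM implementation reaches the same optimum."""
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(40.5, 3.0, 700), rng.normal(70.0, 8.0, 300)])
        ours = fit_mixture(x, seed=6)
        gm = GaussianMixture(2, tol=1e-8, n_init=5, random_state=6).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        assert np.allclose(np.sort(gm.means_.ravel()), ours.means, atol=0.2)
        assert np.allclose(np.sqrt(gm.covariances_.ravel())[order], ours.sds, atol=0.2)
        assert np.allclose(gm.weights_[order], ours.weights, atol=0.02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture(np.ones(50))
        with pytest.raises(ValueError):
            fit_mixture(np.arange(5.0))


class TestDensityCrossing:
    def test_symmetric_case_is_midpoint(self):
        fit = MixtureFit((0.5, 0.5), (35.0, 72.0), (5.0, 5.0), 0.0, True, 1)
        assert density_crossing(fit) == pytest.approx(53.5, abs=1e-6)

    def test_matches_grid_oracle_on_random_draws(self):
        rng = np.random.default_rng(8)
        checked = 0
        while checked < 100:
            w1 = rng.uniform(0.2, 0.8)
            m1 = rng.uniform(30, 50)
            m2 = m1 + rng.uniform(15, 40)
            s1 = rng.uniform(2, 6)
            s2 = rng.uniform(4, 10)
            fit = MixtureFit((w1, 1 - w1), (m1, m2), (s1, s2), 0.0, True, 1)
            want = density_crossing_grid_oracle(w1, m1, s1, 1 - w1, m2, s2)
            if want is None:
                continue
            assert density_crossing(fit) == pytest.approx(want, abs=1e-3)
            checked += 1

    def test_minor_component_pulls_cutoff_toward_itself(self):
        base = MixtureFit((0.5, 0.5), (40.0, 70.0), (5.0, 5.0), 0.0, True, 1)
        skew = MixtureFit((0.9, 0.1), (40.0, 70.0), (5.0, 5.0), 0.0, True, 1)
        assert density_crossing(skew) > density_crossing(base)

    def test_overlapping_components_raise(self):
        fit = MixtureFit((0.02, 0.98), (40.0, 41.0), (10.0, 10.0), 0.0, True, 1)
        with pytest.raises(ValueError):
            density_crossing(fit)


def test_classify_boundary_inclusive():
    assert classify_phenotype(47.0, 47.0) == "early"
    assert classify_phenotype(47.01, 47.0) == "late"
    assert classify_phenotype(30.0, 47.0) == "early"
    out = classify_phenotype(np.array([30.0, 47.0, 60.0]), 47.0)
    assert list(out) == ["early", "early", "late"]
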