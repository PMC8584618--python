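"""Gaussian-mixture mode discovery: PDE, EM fitting, BIC scan, Bayes boundaries."""

import numpy as np
import pytest
from scipy import stats

from olfrisk.modes import (
    GMMFit,
    _em,
    assign_modes,
    bayes_boundaries,
    fit_gmm,
    mixture_cdf,
    pareto_density,
    pde_local_maxima,
    select_mode_count,
)
from olfrisk.synth import sample_tdi_mixture

from conftest import PRINTED_MEANS, PRINTED_SDS, PRINTED_WEIGHTS


def printed_fit(n=163):
    return GMMFit(
        means=np.array(PRINTED_MEANS),
        sds=np.array(PRINTED_SDS),
        weights=np.array(PRINTED_WEIGHTS) / np.sum(PRINTED_WEIGHTS),
        log_likelihood=0.0,
        n=n,
    )


class TestParetoDensity:
    def test_normalization_and_nonnegativity(self, rng):
        c = pareto_density(rng.exponential(size=300))
        assert (c.density >= 0).all()
        assert np.trapezoid(c.density, c.grid) == pytest.approx(1.0, abs=0.02)

    def test_standard_normal_peak(self, rng):
        c = pareto_density(rng.normal(size=2000))
        peak = c.grid[np.argmax(c.density)]
        assert abs(peak) < 0.1
        assert c.density.max() == pytest.approx(stats.norm.pdf(0), abs=0.05)

    def test_separated_bimodal_sample_shows_two_maxima(self, rng):
        x = np.concatenate([rng.normal(0, 1, 800), rng.normal(10, 1, 1200)])
        maxima = pde_local_maxima(pareto_density(x))
        assert len(maxima) == 2
        assert abs(maxima[0] - 0) < 1 and abs(maxima[1] - 10) < 1

    def test_printed_tdi_mixture_density_is_unimodal(self, rng):
        # the low-performance component is too small/overlapping to raise its
        # own peak: analytically the mixture density has a single maximum
        g = np.linspace(10, 48, 4001)
        f = printed_fit()
        d = (f.weights[0] * stats.norm.pdf(g, *[f.means[0], f.sds[0]])
             + f.weights[1] * stats.norm.pdf(g, f.means[1], f.sds[1]))
        turns = np.flatnonzero(np.diff(np.sign(np.diff(d))) != 0)
        assert len(turns) == 1
        assert abs(g[turns[0] + 1] - 34.3) < 0.2
        # and the empirical PDE on a large sample agrees (one dominant peak)
        x, _ = sample_tdi_mixture(2000, rng)
        maxima = pde_local_maxima(pareto_density(x), min_prominence_frac=0.2)
        assert len(maxima) == 1
        assert abs(maxima[0] - 34.32) < 1.5

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pareto_density(np.full(50, 2.0))


class TestFitGmm:
    def test_single_component_closed_form(self, rng):
        x = rng.normal(5, 2, size=400)
        f = fit_gmm(x, 1)
        assert f.means[0] == pytest.approx(x.mean(), abs=1e-6)
        assert f.sds[0] == pytest.approx(x.std(ddof=0), abs=1e-6)
        assert f.weights[0] == 1.0

    def test_weight_recovery_on_separated_clusters(self, rng):
        x = np.concatenate([rng.normal(0, 0.01, 300), rng.normal(50, 0.01, 700)])
        f = fit_gmm(x, 2, seed=1)
        np.testing.assert_allclose(f.weights, [0.3, 0.7], atol=0.01)

    def test_lower_mean_recovery_printed_mixture(self):
        # average lower-component mean over replicate fits stays near 24.9
        lows = []
        for seed in range(20):
            x, _ = sample_tdi_mixture(163, np.random.default_rng(seed))
            lows.append(fit_gmm(x, 2, seed=seed).means[0])
        assert abs(np.mean(lows) - 24.9) < 1.0

    def test_em_loglikelihood_monotone(self, rng):
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(4, 1, 100)])
        trace: list[float] = []
        _em(
            x, np.array([-1.0, 5.0]), np.array([1.5, 1.5]),
            np.array([0.5, 0.5]), floor=1e-4 * x.std(), trace=trace,
        )
        assert len(trace) > 1
        assert np.all(np.diff(trace) >= -1e-8)

    def test_agrees_with_reference_mixture_fitter(self, rng):
        from sklearn.mixture import GaussianMixture

        x = np.concatenate([rng.normal(0, 1, 250), rng.normal(6, 1.5, 250)])
        f = fit_gmm(x, 2, seed=0)
        ref = GaussianMixture(2, n_init=5, random_state=0).fit(x[:, None])
        ref_means = np.sort(ref.means_.ravel())
        np.testing.assert_allclose(f.means, ref_means, atol=0.1)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_gmm(rng.normal(size=6), 2)


class TestSelectModeCount:
    def test_bic_identity(self, rng):
        x = rng.normal(size=200)
        sel = select_mode_count(x, m_max=3, seed=0)
        for m, fit in sel.fits.items():
            expected = -2 * fit.log_likelihood + (3 * m - 1) * np.log(len(x))
            assert sel.bic_table[m] == pytest.approx(expected, rel=1e-12)

    def test_unimodal_data_selects_one(self):
        chosen = []
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=500)
            chosen.append(select_mode_count(x, m_max=3, seed=seed).chosen_m)
        assert np.bincount(chosen).argmax() == 1

    def test_printed_mixture_selects_two(self):
        chosen = []
        for seed in range(20):
            x, _ = sample_tdi_mixture(163, np.random.default_rng(seed))
            chosen.append(select_mode_count(x, m_max=5, seed=seed).chosen_m)
        assert np.bincount(chosen).argmax() == 2

    def test_ks_pvalue_reasonable_for_true_model(self, rng):
        x, _ = sample_tdi_mixture(400, rng)
        sel = select_mode_count(x, m_max=3, seed=0)
        assert sel.ks_pvalue > 0.01
        assert sel.lrt_pvalue is not None


class TestBayesBoundaries:
    def test_printed_parameters_boundary(self):
        (b,) = bayes_boundaries(printed_fit())
        assert b == pytest.approx(27.85, abs=0.05)

    def test_symmetric_components_midpoint(self):
        f = GMMFit(
            means=np.array([2.0, 8.0]), sds=np.array([1.0, 1.0]),
            weights=np.array([0.5, 0.5]), log_likelihood=0.0, n=100,
        )
        assert bayes_boundaries(f)[0] == pytest.approx(5.0, abs=1e-9)

    def test_dense_grid_oracle(self, rng):
        for _ in range(5):
            m1 = rng.uniform(0, 5)
            m2 = m1 + rng.uniform(2, 8)
            f = GMMFit(
                means=np.array([m1, m2]),
                sds=np.array([rng.uniform(0.5, 2), rng.uniform(0.5, 2)]),
                weights=np.array([0.4, 0.6]),
                log_likelihood=0.0, n=100,
            )
            bounds = bayes_boundaries(f)
            if not bounds:
                continue
            grid = np.arange(m1, m2, 1e-4)
            post = np.stack(
                [
                    f.weights[i] * stats.norm.pdf(grid, f.means[i], f.sds[i])
                    for i in range(2)
                ]
            )
            grid_b = grid[np.argmin(np.abs(post[0] - post[1]))]
            assert bounds[0] == pytest.approx(grid_b, abs=2e-4)

    def test_absent_boundary_reported_not_fabricated(self):
        # an extreme weight/sd imbalance leaves no crossing between the means
        f = GMMFit(
            means=np.array([0.0, 1.0]), sds=np.array([10.0, 0.1]),
            weights=np.array([0.999, 0.001]), log_likelihood=0.0, n=100,
        )
        bounds = bayes_boundaries(f)
        assert bounds == []
        assert f.absent_boundaries == [0]

    def test_single_component_rejected(self, rng):
        f = fit_gmm(rng.normal(size=100), 1)
        with pytest.raises(ValueError):
            bayes_boundaries(f)


class TestAssignModes:
    def test_printed_fit_assignment_around_boundary(self):
        f = printed_fit()
        assert assign_modes(f, [27.0])[0] == 0
        assert assign_modes(f, [28.5])[0] == 1
        assert assign_modes(f, [24.9])[0] == 0
        assert assign_modes(f, [34.32])[0] == 1

    def test_grid_posterior_argmax_oracle(self, rng):
        f = printed_fit()
        x = rng.uniform(10, 48, size=1000)
        labels = assign_modes(f, x)
        post = np.stack(
            [
                f.weights[i] * stats.norm.pdf(x, f.means[i], f.sds[i])
                for i in range(2)
            ]
        )
        np.testing.assert_array_equal(labels, np.argmax(post, axis=0))

    def test_boundary_posterior_consistency(self, rng):
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(5, 1, 300)])
        f = fit_gmm(x, 2, seed=3)
        (b,) = bayes_boundaries(f)
        grid = np.linspace(x.min(), x.max(), 500)
        labels = assign_modes(f, grid)
        assert (labels[grid < b - 1e-9] == 0).all()
        assert (labels[grid > b + 1e-9] == 1).all()

    def test_parameter_recovery_within_monte_carlo_error(self):
        # all five free parameters, averaged over 20 simulations at n=163
        est = []
        for seed in range(20):
            x, _ = sample_tdi_mixture(163, np.random.default_rng(1000 + seed))
            f = fit_gmm(x, 2, seed=seed)
            est.append([f.means[0], f.means[1], f.sds[0], f.sds[1], f.weights[0]])
        est = np.array(est)
        truth = [24.9, 34.32, 3.42, 3.2, 0.167 / 0.997]
        for j, tv in enumerate(truth):
            mean, se = est[:, j].mean(), est[:, j].std(ddof=1) / np.sqrt(20)
            assert abs(mean - tv) < 3 * max(se, 1e-3), f"param {j}"

    def test_model_cdf_is_proper(self, rng):
        f = printed_fit()
        g = np.linspace(0, 60, 100)
        c = mixture_cdf(g, f)
        assert np.all(np.diff(c) >= 0)
        assert c[0] < 1e-6 and c[-1] > 1 - 1e-6
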