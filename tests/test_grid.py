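"""Grid posterior: census, likelihood, oracle equivalence, summaries."""

import numpy as np
import pytest
from scipy.stats import norm

from tuningbayes import (
    GridEvaluator,
    GridSpec,
    NoiseModel,
    ResponseData,
    TuningParams,
    compute_posterior,
    index_histograms,
    joint_2d,
    log_likelihood,
    marginal,
    mle,
    predict_responses,
    rpref_likelihood,
)
from tuningbayes.grid import PARAM_NAMES
from tuningbayes.noise import noise_sd
from tuningbayes.tuning import double_gaussian


def brute_force_posterior(data, grid, noise):
    """Nested-loop reference implementation of the normalized joint."""
    ll = np.empty(grid.shape)
    sqrt_t = np.sqrt(data.trial_counts())
    for ic, c in enumerate(grid.c):
        for ir, rp in enumerate(grid.rp):
            for ia, a in enumerate(grid.alpha):
                for it, th in enumerate(grid.theta_pref):
                    for is_, sg in enumerate(grid.sigma):
                        p = TuningParams(c, rp, a, th, sg)
                        rhat = predict_responses(p, data.angles)
                        sd = noise_sd(rhat, noise) / sqrt_t
                        ll[ic, ir, ia, it, is_] = norm.logpdf(data.means, rhat, sd).sum()
    w = np.exp(ll - ll.max())
    return w / w.sum()


class TestGridSpec:
    def test_production_census(self):
        assert GridSpec.spiking_default().n_combinations == 233_280_000
        assert GridSpec.calcium_default(0.5).n_combinations == 326_592_000

    def test_axis_lookup_and_step(self, tiny_grid):
        assert tiny_grid.axis("theta_pref") is tiny_grid.theta_pref
        assert tiny_grid.step("C") == pytest.approx(0.75)  # median of {0.5, 1.0}
        with pytest.raises(KeyError):
            tiny_grid.axis("gamma")

    def test_rejects_unsorted_axis(self):
        with pytest.raises(ValueError):
            GridSpec(c=np.array([1.0, 0.5]), rp=np.array([1.0]),
                     alpha=np.array([0.0]), theta_pref=np.array([0.0]),
                     sigma=np.array([30.0]))

    def test_roundtrip_dict(self, tiny_grid):
        clone = GridSpec.from_dict(tiny_grid.to_dict())
        for name in PARAM_NAMES:
            assert np.array_equal(clone.axis(name), tiny_grid.axis(name))


class TestPredictAndLikelihood:
    def test_flat_cell(self):
        p = TuningParams(C=2.0, Rp=0.0, alpha=0.0, theta_pref=0.0, sigma=30.0)
        assert np.allclose(predict_responses(p, np.arange(0, 360, 45.0)), 2.0)

    def test_empty_angles(self, well_tuned_params):
        assert predict_responses(well_tuned_params, []).size == 0

    def test_peak_value(self, well_tuned_params):
        expected = 1.0 + 10.0 + 5.0 * np.exp(-18.0)
        assert predict_responses(well_tuned_params, [90.0])[0] == pytest.approx(expected)

    def test_normal_peak_density(self, well_tuned_params):
        unit_noise = NoiseModel(Cn=1.0, K=0.0, S=1.0)
        rhat = double_gaussian(33.0, well_tuned_params)
        data = ResponseData.from_means([33.0], [rhat], T=1)
        assert log_likelihood(data, well_tuned_params, unit_noise) == pytest.approx(
            np.log(1.0 / np.sqrt(2.0 * np.pi))
        )

    def test_sem_shrinks_with_trials(self, well_tuned_params):
        unit_noise = NoiseModel(Cn=1.0, K=0.0, S=1.0)
        rhat = double_gaussian(33.0, well_tuned_params)
        data = ResponseData.from_means([33.0], [rhat], T=4)
        assert log_likelihood(data, well_tuned_params, unit_noise) == pytest.approx(
            np.log(2.0 / np.sqrt(2.0 * np.pi))
        )

    def test_additivity_over_angles(self, well_tuned_params, linear_noise):
        d1 = ResponseData.from_means([0.0], [2.0], T=3)
        d2 = ResponseData.from_means([90.0], [9.0], T=3)
        both = ResponseData.from_means([0.0, 90.0], [2.0, 9.0], T=3)
        assert log_likelihood(both, well_tuned_params, linear_noise) == pytest.approx(
            log_likelihood(d1, well_tuned_params, linear_noise)
            + log_likelihood(d2, well_tuned_params, linear_noise)
        )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_posterior_matches_brute_force_oracle(seed, linear_noise):
    """Vectorized joint equals naive nested loops on randomized small grids."""
    rng = np.random.default_rng(seed)
    grid = GridSpec(
        c=np.sort(rng.uniform(0.2, 4.0, rng.integers(2, 5))),
        rp=np.sort(rng.uniform(0.5, 15.0, rng.integers(2, 5))),
        alpha=np.sort(rng.uniform(0.0, 1.0, rng.integers(2, 4))),
        theta_pref=np.sort(rng.uniform(0.0, 359.0, rng.integers(3, 7))),
        sigma=np.sort(rng.uniform(5.0, 60.0, rng.integers(2, 5))),
    )
    angles = np.arange(0.0, 360.0, 45.0)
    truth = TuningParams(1.0, 8.0, 0.4, 100.0, 28.0)
    means = double_gaussian(angles, truth) * rng.uniform(0.8, 1.2, angles.size)
    data = ResponseData.from_means(angles, means, T=5)

    expected = brute_force_posterior(data, grid, linear_noise)
    summary, joint = compute_posterior(data, grid, linear_noise, return_joint=True)

    scale = expected.max()
    assert np.max(np.abs(joint - expected)) / scale < 1e-12
    assert joint.sum() == pytest.approx(1.0, abs=1e-9)
    for i, name in enumerate(PARAM_NAMES):
        ref = expected.sum(axis=tuple(j for j in range(5) if j != i))
        assert np.max(np.abs(summary.marginals[name] - ref / ref.sum())) < 1e-12
        assert summary.marginals[name].sum() == pytest.approx(1.0, abs=1e-9)
    assert summary.oi_hist.sum() == pytest.approx(1.0, abs=1e-9)
    assert summary.di_hist.sum() == pytest.approx(1.0, abs=1e-9)
    assert summary.rpref_hist.sum() == pytest.approx(1.0, abs=1e-9)
    # MLE equals the brute-force argmax
    idx = np.unravel_index(np.argmax(expected), grid.shape)
    assert summary.mle == grid.params_at(idx)


class TestComputePosterior:
    def test_mle_recovers_grid_point_with_tiny_noise(self, tiny_grid):
        truth = tiny_grid.params_at((1, 2, 1, 1, 1))  # C=1, Rp=10, a=0.5, 90, 30
        angles = np.arange(0.0, 360.0, 30.0)
        data = ResponseData.from_means(angles, double_gaussian(angles, truth), T=5)
        tight = NoiseModel(Cn=0.05, K=0.01, S=1.0)
        summary = compute_posterior(data, tiny_grid, tight)
        assert summary.mle == truth
        assert not summary.mle_tied

    def test_flat_grid_estimates_mean(self):
        # amplitude pinned at zero: the posterior over C is plain Gaussian
        # mean estimation, peaking at the grid value nearest the data mean
        grid = GridSpec(
            c=np.linspace(0.5, 6.0, 23), rp=np.array([0.0]),
            alpha=np.array([0.0]), theta_pref=np.array([0.0]),
            sigma=np.array([30.0]),
        )
        angles = np.arange(0.0, 360.0, 45.0)
        data = ResponseData.from_means(angles, np.full(angles.size, 3.17), T=4)
        summary = compute_posterior(data, grid, NoiseModel(Cn=1.0, K=0.0, S=1.0))
        expected_c = grid.c[np.argmin(np.abs(grid.c - 3.17))]
        assert summary.mle.C == pytest.approx(expected_c)

    def test_angle_order_invariance(self, tiny_grid, linear_noise):
        angles = np.arange(0.0, 360.0, 45.0)
        rng = np.random.default_rng(3)
        means = rng.uniform(1.0, 10.0, angles.size)
        data = ResponseData.from_means(angles, means, T=5)
        perm = rng.permutation(angles.size)
        shuffled = ResponseData.from_means(angles[perm], means[perm], T=5)
        _, j1 = compute_posterior(data, tiny_grid, linear_noise, return_joint=True)
        _, j2 = compute_posterior(shuffled, tiny_grid, linear_noise, return_joint=True)
        assert np.allclose(j1, j2, rtol=1e-12, atol=0)

    def test_streamed_equals_cached(self, tiny_grid, linear_noise):
        angles = np.arange(0.0, 360.0, 45.0)
        rng = np.random.default_rng(4)
        data = ResponseData.from_means(angles, rng.uniform(1.0, 10.0, angles.size), T=5)
        cached = GridEvaluator(tiny_grid, linear_noise, angles, 5, cache=True)
        streamed = GridEvaluator(tiny_grid, linear_noise, angles, 5, cache=False)
        l1 = cached.log_likelihood(data.means)
        l2 = streamed.log_likelihood(data.means)
        assert np.allclose(l1, l2, rtol=1e-12, atol=1e-9)

    def test_extreme_data_still_normalizes(self, tiny_grid, linear_noise):
        # log-space accumulation: likelihoods of ~e^-100000 must not underflow
        angles = np.arange(0.0, 360.0, 45.0)
        data = ResponseData.from_means(angles, np.full(angles.size, 5000.0), T=5)
        _, joint = compute_posterior(data, tiny_grid, linear_noise, return_joint=True)
        assert joint.sum() == pytest.approx(1.0, abs=1e-9)


class TestSummaries:
    def _point_mass_joint(self, grid, index):
        joint = np.zeros(grid.shape)
        joint[index] = 1.0
        return joint

    def test_marginal_of_uniform_is_uniform(self, tiny_grid):
        joint = np.full(tiny_grid.shape, 1.0 / tiny_grid.n_combinations)
        m = marginal(joint, tiny_grid, "sigma")
        assert np.allclose(m, 1.0 / tiny_grid.sigma.size)

    def test_marginal_unknown_name(self, tiny_grid):
        with pytest.raises(KeyError):
            marginal(np.full(tiny_grid.shape, 1.0), tiny_grid, "width")

    def test_mle_tie_takes_first_in_axis_order(self, tiny_grid):
        joint = np.full(tiny_grid.shape, 1.0 / tiny_grid.n_combinations)
        params, _, tied = mle(joint, tiny_grid)
        assert tied
        assert params == tiny_grid.params_at((0, 0, 0, 0, 0))

    def test_index_histograms_concentrated_at_truth(self, tiny_grid):
        # posterior mass entirely at the well-tuned parameters: OI=0.8627
        # lands in [0.85, 0.90), DI=0.4545 in [0.45, 0.50)
        joint = self._point_mass_joint(tiny_grid, (1, 2, 1, 1, 1))
        oi_hist, di_hist, edges = index_histograms(joint, tiny_grid)
        assert oi_hist.sum() == pytest.approx(1.0)
        assert di_hist.sum() == pytest.approx(1.0)
        assert oi_hist[17] == pytest.approx(1.0)  # bin [0.85, 0.90)
        assert di_hist[9] == pytest.approx(1.0)   # bin [0.45, 0.50)

    def test_flat_grid_oi_mass_in_lowest_bin(self):
        grid = GridSpec(
            c=np.array([1.0, 2.0]), rp=np.array([0.0]), alpha=np.array([0.0]),
            theta_pref=np.array([0.0, 90.0]), sigma=np.array([30.0]),
        )
        joint = np.full(grid.shape, 1.0 / grid.n_combinations)
        oi_hist, _, _ = index_histograms(joint, grid)
        assert oi_hist[0] == pytest.approx(1.0)

    def test_rpref_single_combination(self, tiny_grid):
        index = (1, 2, 1, 1, 1)
        joint = self._point_mass_joint(tiny_grid, index)
        p = tiny_grid.params_at(index)
        hist, edges = rpref_likelihood(joint, tiny_grid)
        occupied = np.flatnonzero(hist)
        assert occupied.size == 1
        val = p.C + p.Rp + p.alpha * p.Rp * np.exp(-180.0 ** 2 / (2 * p.sigma ** 2))
        assert edges[occupied[0]] <= val <= edges[occupied[0] + 1]

    def test_rpref_flat_cell_mode_at_offset(self):
        grid = GridSpec(
            c=np.linspace(0.5, 4.0, 8), rp=np.array([0.0]), alpha=np.array([0.0]),
            theta_pref=np.array([0.0]), sigma=np.array([30.0]),
        )
        joint = np.zeros(grid.shape)
        joint[5, 0, 0, 0, 0] = 1.0
        hist, edges = rpref_likelihood(joint, grid)
        i = np.argmax(hist)
        assert edges[i] <= grid.c[5] <= edges[i + 1]

    def test_joint2d_product_form(self, tiny_grid):
        # independent joint: the 2-D marginal is the outer product of the
        # 1-D marginals (the "no slant" case)
        rng = np.random.default_rng(5)
        factors = [rng.uniform(0.5, 2.0, n) for n in tiny_grid.shape]
        joint = np.einsum("a,b,c,d,e->abcde", *factors)
        joint /= joint.sum()
        table = joint_2d(joint, tiny_grid, "Rp", "sigma")
        assert table.sum() == pytest.approx(1.0)
        outer = np.outer(marginal(joint, tiny_grid, "Rp"),
                         marginal(joint, tiny_grid, "sigma"))
        assert np.allclose(table, outer, atol=1e-12)

    def test_joint2d_axis_order_transpose(self, tiny_grid):
        rng = np.random.default_rng(6)
        joint = rng.uniform(0.0, 1.0, tiny_grid.shape)
        joint /= joint.sum()
        ab = joint_2d(joint, tiny_grid, "C", "sigma")
        ba = joint_2d(joint, tiny_grid, "sigma", "C")
        assert np.allclose(ab, ba.T)

    def test_joint2d_identical_names_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            joint_2d(np.full(tiny_grid.shape, 1.0), tiny_grid, "C", "C")


class TestResponseData:
    def test_duplicate_angles_rejected(self):
        with pytest.raises(ValueError):
            ResponseData.from_means([0.0, 360.0], [1.0, 2.0], T=5)

    def test_from_trials_means(self):
        data = ResponseData.from_trials([0.0, 90.0], [[1.0, 3.0], [2.0, 6.0]])
        assert data.means == pytest.approx([2.0, 4.0])
        assert data.T == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ResponseData.from_means([], [], T=1)
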