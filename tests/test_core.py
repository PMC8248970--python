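"""Unit tests of the estimation and adjustment stages."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import combatkit as ck
from combatkit.containers import BatchEstimates, StandardizedMatrix
from combatkit.core import shrinkage_off_posterior

from conftest import make_batches, make_matrix


# ---------------------------------------------------------------- design


class TestBuildDesign:
    def test_empty_covariates_give_zero_width_design(self):
        d = ck.build_design(None)
        assert d.n_covariates == 0

    def test_binary_covariate_reference_level_encoding(self):
        d = ck.build_design(pd.DataFrame({"grp": ["A", "A", "B", "B"]}))
        assert d.column_names == ["grp[B]"]
        assert d.design[:, 0].tolist() == [0.0, 0.0, 1.0, 1.0]

    def test_constant_numeric_column_rejected_by_name(self):
        with pytest.raises(ck.SchemaError, match="age"):
            ck.build_design(pd.DataFrame({"age": [3.0, 3.0, 3.0]}))

    def test_missing_values_rejected(self):
        with pytest.raises(ck.SchemaError, match="missing"):
            ck.build_design(pd.DataFrame({"age": [1.0, np.nan, 3.0]}))

    def test_numeric_passthrough_no_intercept(self):
        d = ck.build_design(pd.DataFrame({"age": [1.0, 2.0, 4.0]}))
        assert d.design[:, 0].tolist() == [1.0, 2.0, 4.0]


# ------------------------------------------------------------- global fit


class TestEstimateGlobal:
    def test_single_batch_reduces_to_mean_and_sd(self):
        y = make_matrix(np.array([[1.0], [2.0], [3.0], [4.0]]))
        g = ck.estimate_global(y, make_batches(["A"] * 4))
        assert g.alpha[0] == pytest.approx(2.5)
        assert g.sigma[0] == pytest.approx(np.std([1, 2, 3, 4]))  # denominator n

    def test_grand_mean_weights_batches_by_size(self):
        # batch means 0 and 2, equal sizes -> grand mean 1
        y = make_matrix(np.array([[-1.0], [1.0], [1.0], [3.0]]))
        g = ck.estimate_global(y, make_batches(["A", "A", "B", "B"]))
        assert g.alpha[0] == pytest.approx(1.0)

    def test_unequal_sizes_weighted_grand_mean(self):
        # batch means 0 (n=3) and 3 (n=1) -> weighted grand mean 0.75
        y = make_matrix(np.array([[-1.0], [0.0], [1.0], [3.0]]))
        b = make_batches(["A", "A", "A", "B"])
        g = ck.estimate_global(y, b)
        assert g.alpha[0] == pytest.approx(0.75)

    def test_covariate_slope_recovered_on_simulated_draws(self):
        rng = np.random.default_rng(7)
        n = 500
        x = rng.standard_normal(n)
        y = make_matrix((2.0 + 3.0 * x + rng.standard_normal(n))[:, None])
        g = ck.estimate_global(
            y, make_batches(["A"] * n),
            ck.CovariateMatrix(x[:, None], ["x"]))
        assert abs(g.beta[0, 0] - 3.0) < 0.1

    def test_zero_variance_feature_listed_in_error(self):
        vals = np.column_stack([np.ones(6), np.arange(6.0)])
        y = make_matrix(vals)
        with pytest.raises(ck.ZeroVarianceError) as exc:
            ck.estimate_global(y, make_batches(["A", "A", "A", "B", "B", "B"]))
        assert exc.value.feature_names == ["f0"]

    def test_per_batch_moments_use_population_sd(self):
        vals = np.array([[0.0], [2.0], [5.0], [9.0]])
        y = make_matrix(vals)
        g = ck.estimate_global(y, make_batches(["A", "A", "B", "B"]))
        assert g.per_batch_alpha[0, 0] == pytest.approx(1.0)
        assert g.per_batch_sigma[0, 0] == pytest.approx(1.0)  # ddof=0
        assert g.per_batch_sigma[1, 0] == pytest.approx(2.0)


# ---------------------------------------------------------- standardize


class TestStandardize:
    def test_values_equal_to_alpha_give_zero(self):
        rng = np.random.default_rng(0)
        y = make_matrix(rng.standard_normal((4, 3)))
        b = make_batches(["A", "A", "B", "B"])
        g = ck.estimate_global(y, b)
        y2 = make_matrix(np.tile(g.alpha, (4, 1)))
        z = ck.standardize(y2, g)
        assert np.allclose(z.values, 0.0)

    def test_direct_substitution(self):
        rng = np.random.default_rng(0)
        y = make_matrix(rng.standard_normal((4, 1)))
        b = make_batches(["A", "A", "B", "B"])
        g = ck.estimate_global(y, b)
        g.alpha[:] = 10.0
        g.sigma[:] = 2.0
        z = ck.standardize(make_matrix(np.full((4, 1), 14.0)), g)
        assert np.allclose(z.values, 2.0)

    def test_large_sample_mean_zero_sd_one(self):
        rng = np.random.default_rng(11)
        n = 4000
        y = make_matrix(5 + 2 * rng.standard_normal((n, 3)))
        b = make_batches(["A"] * n)
        g = ck.estimate_global(y, b)
        z = ck.standardize(y, g)
        bound = 3 / np.sqrt(n)
        assert np.all(np.abs(z.values.mean(axis=0)) < bound)
        assert np.all(np.abs(z.values.std(axis=0) - 1) < bound)

    def test_feature_name_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        y = make_matrix(rng.standard_normal((4, 2)))
        g = ck.estimate_global(y, make_batches(["A", "A", "B", "B"]))
        other = ck.FeatureMatrix(y.values, y.sample_ids, ["g0", "g1"])
        with pytest.raises(ck.SchemaError):
            ck.standardize(other, g)


# ------------------------------------------------------- batch moments


class TestBatchEffects:
    def _z(self, vals, labels):
        vals = np.asarray(vals, float)
        return (StandardizedMatrix(vals,
                                   [f"s{i}" for i in range(len(vals))],
                                   [f"f{j}" for j in range(vals.shape[1])]),
                make_batches(labels))

    def test_two_point_moments_denominator_n(self):
        z, b = self._z([[-1.0], [1.0]], ["A", "A"])
        est = ck.estimate_batch_effects(z, b)
        assert est.gamma_hat[0, 0] == pytest.approx(0.0)
        assert est.delta2_hat[0, 0] == pytest.approx(1.0)

    def test_constant_batch_gives_zero_variance(self):
        z, b = self._z([[2.0], [2.0], [0.0], [1.0]], ["A", "A", "B", "B"])
        est = ck.estimate_batch_effects(z, b)
        assert est.delta2_hat[0, 0] == 0.0

    def test_singleton_batch_rejected_by_name(self):
        z, b = self._z([[1.0], [2.0], [3.0]], ["A", "A", "B"])
        with pytest.raises(ck.BatchTooSmallError, match="B"):
            ck.estimate_batch_effects(z, b)

    def test_small_batch_warns(self):
        z, b = self._z([[1.0], [2.0], [3.0], [4.0]], ["A", "A", "A", "A"][:4])
        z2, b2 = self._z([[1.0], [2.0], [3.0]], ["A", "A", "A"])
        with pytest.warns(UserWarning, match="unstable"):
            ck.estimate_batch_effects(z2, b2)

    def test_moment_recovery_on_seeded_draws(self):
        rng = np.random.default_rng(3)
        n = 500
        z, b = self._z(0.8 + 1.5 * rng.standard_normal((n, 1)), ["A"] * n)
        est = ck.estimate_batch_effects(z, b)
        assert abs(est.gamma_hat[0, 0] - 0.8) < 0.15
        assert abs(est.delta2_hat[0, 0] - 2.25) < 0.4


# --------------------------------------------------------------- priors


class TestHyperparameters:
    def test_normal_prior_moments_recovered(self):
        rng = np.random.default_rng(5)
        g = 2000
        gamma_hat = rng.normal(0.5, np.sqrt(0.1), g)
        est = BatchEstimates(gamma_hat[None, :], np.ones((1, g)),
                             np.array([50]))
        h = ck.estimate_hyperparameters(est)
        assert abs(h.gamma_bar[0] - 0.5) < 0.03
        assert abs(h.tau2_bar[0] - 0.1) < 0.02

    def test_inverse_gamma_moment_matching(self):
        rng = np.random.default_rng(6)
        g = 5000
        d2 = 3.0 / rng.gamma(4.0, 1.0, g)  # InverseGamma(4, 3)
        est = BatchEstimates(np.zeros((1, g)), d2[None, :], np.array([50]))
        h = ck.estimate_hyperparameters(est)
        assert abs(h.lambda_bar[0] - 4.0) / 4.0 < 0.10
        assert abs(h.theta_bar[0] - 3.0) / 3.0 < 0.10

    def test_identical_variances_disable_scale_shrinkage(self):
        est = BatchEstimates(np.array([[0.1, -0.2, 0.3]]),
                             np.full((1, 3), 2.0), np.array([10]))
        h = ck.estimate_hyperparameters(est)
        assert not h.scale_shrink[0]
        # posterior keeps the raw variance on the degenerate path
        z = StandardizedMatrix(np.zeros((10, 3)), [str(i) for i in range(10)],
                               ["a", "b", "c"])
        post = ck.eb_posterior_parametric(z, make_batches(["A"] * 10), est, h)
        assert np.allclose(post.delta2_star, 2.0)
        assert post.converged.all()


# ------------------------------------------------------------ posterior


def _one_batch_setup(rng, n=200, g=30):
    z = rng.standard_normal((n, g))
    zm = StandardizedMatrix(z, [f"s{i}" for i in range(n)],
                            [f"f{j}" for j in range(g)])
    b = make_batches(["A"] * n)
    est = ck.estimate_batch_effects(zm, b)
    return zm, b, est


class TestParametricPosterior:
    def test_infinite_tau2_turns_location_shrinkage_off(self, rng):
        zm, b, est = _one_batch_setup(rng)
        h = ck.estimate_hyperparameters(est)
        h.tau2_bar[:] = np.inf
        post = ck.eb_posterior_parametric(zm, b, est, h)
        assert np.allclose(post.gamma_star, est.gamma_hat)

    def test_large_sample_limit_approaches_raw_moments(self):
        rng = np.random.default_rng(8)
        zm, b, est = _one_batch_setup(rng, n=10_000, g=20)
        h = ck.estimate_hyperparameters(est)
        post = ck.eb_posterior_parametric(zm, b, est, h)
        assert np.all(np.abs(post.delta2_star - est.delta2_hat)
                      / est.delta2_hat < 0.02)
        assert np.all(np.abs(post.gamma_star - est.gamma_hat) < 0.02)

    def test_closed_form_when_data_term_vanishes(self):
        n, g = 10, 3
        z = StandardizedMatrix(np.zeros((n, g)),
                               [f"s{i}" for i in range(n)], ["a", "b", "c"])
        b = make_batches(["A"] * n)
        est = BatchEstimates(np.zeros((1, g)), np.zeros((1, g)), np.array([n]))
        h = ck.Hyperparameters(np.array([0.0]), np.array([0.5]),
                               np.array([4.0]), np.array([3.0]))
        post = ck.eb_posterior_parametric(z, b, est, h)
        assert np.allclose(post.gamma_star, 0.0)
        assert np.allclose(post.delta2_star, 3.0 / (n / 2 + 4.0 - 1.0))

    def test_nonconvergence_warns_not_raises(self, rng):
        zm, b, est = _one_batch_setup(rng, n=50, g=5)
        h = ck.estimate_hyperparameters(est)
        with pytest.warns(UserWarning, match="did not"):
            post = ck.eb_posterior_parametric(zm, b, est, h,
                                              tol=1e-14, max_iter=2)
        assert not post.converged.all()


class TestNonparametricPosterior:
    def test_two_features_leave_one_out_swaps_candidates(self):
        rng = np.random.default_rng(9)
        zm, b, est = _one_batch_setup(rng, n=40, g=2)
        post = ck.eb_posterior_nonparametric(zm, b, est)
        n = 40
        adj = est.delta2_hat * n / (n - 1)
        assert post.gamma_star[0, 0] == pytest.approx(est.gamma_hat[0, 1])
        assert post.delta2_star[0, 0] == pytest.approx(adj[0, 1])
        assert post.gamma_star[0, 1] == pytest.approx(est.gamma_hat[0, 0])

    def test_agrees_with_parametric_when_features_exchangeable(self):
        rng = np.random.default_rng(10)
        n, g = 100, 1000
        z = 0.4 + rng.standard_normal((n, g))
        zm = StandardizedMatrix(z, [f"s{i}" for i in range(n)],
                                [f"f{j}" for j in range(g)])
        b = make_batches(["A"] * n)
        est = ck.estimate_batch_effects(zm, b)
        h = ck.estimate_hyperparameters(est)
        par = ck.eb_posterior_parametric(zm, b, est, h)
        nonpar = ck.eb_posterior_nonparametric(zm, b, est)
        assert np.max(np.abs(par.gamma_star - nonpar.gamma_star)) < 0.05

    def test_log_space_weights_survive_extreme_values(self):
        rng = np.random.default_rng(11)
        z = rng.standard_normal((30, 5))
        z[:, 0] += 50.0  # |Z| up to ~50
        zm = StandardizedMatrix(z, [f"s{i}" for i in range(30)],
                                [f"f{j}" for j in range(5)])
        b = make_batches(["A"] * 30)
        est = ck.estimate_batch_effects(zm, b)
        post = ck.eb_posterior_nonparametric(zm, b, est)
        assert np.all(np.isfinite(post.gamma_star))
        assert np.all(np.isfinite(post.delta2_star))
        assert np.all(post.delta2_star > 0)


# ------------------------------------------------------------ adjustment


class TestAdjustment:
    def test_adjust_inverts_standardize_under_identity_posterior(self, rng):
        y = make_matrix(5 + 2 * rng.standard_normal((30, 4)))
        b = make_batches(["A"] * 15 + ["B"] * 15)
        g = ck.estimate_global(y, b)
        z = ck.standardize(y, g)
        post = ck.PosteriorEstimates(np.zeros((2, 4)), np.ones((2, 4)),
                                     np.ones(2, bool), np.zeros(2, int))
        out = ck.adjust_standard(z, post, g, None, b)
        assert np.max(np.abs(out.values - y.values)) < 1e-10

    def test_direct_substitution_standard(self):
        # sigma=2, delta*=0.5, Z=1.5, gamma*=0.5, alpha=10 -> 14.0
        z = StandardizedMatrix(np.array([[1.5]]), ["s0"], ["f0"])
        b = make_batches(["A"])
        g = ck.GlobalEstimates(np.array([10.0]), np.array([2.0]),
                               np.empty((0, 1)), np.array([[10.0]]),
                               np.array([[2.0]]), ["f0"], [], ["A"])
        post = ck.PosteriorEstimates(np.array([[0.5]]), np.array([[0.25]]),
                                     np.ones(1, bool), np.zeros(1, int))
        out = ck.adjust_standard(z, post, g, None, b)
        assert out.values[0, 0] == pytest.approx(14.0)

    def test_direct_substitution_reference_batch(self):
        # same but sigma_r=4, alpha_r=20 -> 4/0.5*1.0 + 20 = 28
        z = StandardizedMatrix(np.array([[1.5]]), ["s0"], ["f0"])
        b = make_batches(["A"])
        g = ck.GlobalEstimates(np.array([10.0]), np.array([2.0]),
                               np.empty((0, 1)), np.array([[20.0]]),
                               np.array([[4.0]]), ["f0"], [], ["A"])
        post = ck.PosteriorEstimates(np.array([[0.5]]), np.array([[0.25]]),
                                     np.ones(1, bool), np.zeros(1, int))
        out = ck.adjust_mcombat(z, post, g, None, b, "A")
        assert out.values[0, 0] == pytest.approx(28.0)

    def test_constant_z_at_gamma_star_returns_location_term(self, rng):
        y = make_matrix(rng.standard_normal((10, 2)))
        b = make_batches(["A"] * 10)
        g = ck.estimate_global(y, b)
        post = ck.PosteriorEstimates(np.array([[0.3, -0.2]]),
                                     np.ones((1, 2)), np.ones(1, bool),
                                     np.zeros(1, int))
        z = StandardizedMatrix(np.tile(post.gamma_star[0], (10, 1)),
                               y.sample_ids, y.feature_names)
        out = ck.adjust_standard(z, post, g, None, b)
        assert np.allclose(out.values, g.alpha)

    def test_unknown_reference_batch_rejected(self, three_batch_data):
        y, b = three_batch_data
        with pytest.raises(ck.UnknownBatchError):
            ck.fit_transform(y, b, variant="m-combat", reference_batch="Z")


# --------------------------------------------------------- orchestration


class TestFitTransform:
    def test_single_batch_shrinkage_off_is_identity(self, rng):
        y = make_matrix(3 + rng.standard_normal((40, 6)))
        b = make_batches(["A"] * 40)
        _, adj = ck.fit_transform(y, b, eb="none")
        assert np.max(np.abs(adj.values - y.values)) < 1e-8

    def test_mcombat_self_reference_identity(self, rng):
        y = make_matrix(3 + rng.standard_normal((40, 6)))
        b = make_batches(["A"] * 40)
        _, adj = ck.fit_transform(y, b, variant="m-combat",
                                  reference_batch="A", eb="none")
        assert np.max(np.abs(adj.values - y.values)) < 1e-10

    def test_deterministic_rerun_bitwise_identical(self, three_batch_data):
        y, b = three_batch_data
        _, a1 = ck.fit_transform(y, b)
        _, a2 = ck.fit_transform(y, b)
        assert np.array_equal(a1.values, a2.values)

    def test_shape_and_identifier_conservation(self, three_batch_data):
        y, b = three_batch_data
        for variant, ref in [("combat", None), ("m-combat", "A")]:
            _, adj = ck.fit_transform(y, b, variant=variant,
                                      reference_batch=ref)
            assert adj.values.shape == y.values.shape
            assert adj.sample_ids == y.sample_ids
            assert adj.feature_names == y.feature_names
            assert np.all(np.isfinite(adj.values))

    def test_location_and_scale_removal(self):
        # per-feature center effects from the generative priors, n_i >= 50
        spec = ck.SyntheticSpec(
            seed=31, n_features=80,
            batches=[ck.BatchSpec("A", 70, gamma_mean=0.0, gamma_var=0.25,
                                  scale_range=(0.7, 1.4)),
                     ck.BatchSpec("B", 60, gamma_mean=0.9, gamma_var=0.25,
                                  scale_range=(0.7, 1.4)),
                     ck.BatchSpec("C", 50, gamma_mean=-0.7, gamma_var=0.25,
                                  scale_range=(0.7, 1.4))])
        ds = ck.generate(spec)
        y, b = ds.features, ds.batches

        def max_mean_gap(vals):
            means = np.stack([vals[b.indices(x)].mean(axis=0)
                              for x in b.registry])
            return np.max(np.ptp(means, axis=0))

        pre = max_mean_gap(y.values)
        _, adj = ck.fit_transform(y, b)
        assert max_mean_gap(adj.values) < 0.10 * pre

    def test_scale_removal_variances_agree_across_batches(self):
        spec = ck.SyntheticSpec(
            seed=32, n_features=40,
            batches=[ck.BatchSpec("A", 250, gamma_mean=0.0, gamma_var=0.2,
                                  scale_range=(0.6, 1.6)),
                     ck.BatchSpec("B", 220, gamma_mean=0.7, gamma_var=0.2,
                                  scale_range=(0.6, 1.6))])
        ds = ck.generate(spec)
        _, adj = ck.fit_transform(ds.features, ds.batches)
        va = adj.values[ds.batches.indices("A")].var(axis=0)
        vb = adj.values[ds.batches.indices("B")].var(axis=0)
        assert np.all(np.abs(va - vb) / np.maximum(va, vb) < 0.20)

    def test_mcombat_keeps_positive_volume_like_features(self):
        rng = np.random.default_rng(21)
        # strictly positive, volume-like features with moderate effects
        rows, labels = [], []
        for bid, n, shift in [("R", 60, 0.0), ("S", 60, 0.6)]:
            rows.append(np.exp(1.0 + shift + 0.3 * rng.standard_normal((n, 5))))
            labels += [bid] * n
        y = make_matrix(np.vstack(rows))
        b = make_batches(labels)
        _, adj = ck.fit_transform(y, b, variant="m-combat",
                                  reference_batch="R")
        assert np.all(adj.values[b.indices("R")] > 0)

    def test_reference_batch_only_for_m_variants(self, three_batch_data):
        y, b = three_batch_data
        with pytest.raises(ck.SchemaError):
            ck.fit_transform(y, b, variant="combat", reference_batch="A")
        with pytest.raises(ck.SchemaError):
            ck.fit_transform(y, b, variant="m-combat")


# shrinkage-off oracle: closed-form per-batch location-scale alignment
def combat_oracle(values, batches):
    """Independent closed form: ((y - batch mean)/batch sd) * sigma + alpha."""
    n = values.shape[0]
    means = {b: values[batches.indices(b)].mean(axis=0)
             for b in batches.registry}
    counts = batches.counts()
    alpha = sum((c / n) * means[b]
                for b, c in zip(batches.registry, counts))
    rss = sum(((values[batches.indices(b)] - means[b]) ** 2).sum(axis=0)
              for b in batches.registry)
    sigma = np.sqrt(rss / n)
    out = np.empty_like(values)
    for b in batches.registry:
        idx = batches.indices(b)
        sd = values[idx].std(axis=0)
        out[idx] = (values[idx] - means[b]) / sd * sigma + alpha
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_shrinkage_off_matches_closed_form_alignment(seed):
    rng = np.random.default_rng(seed)
    sizes = rng.integers(5, 20, 3)
    labels = sum([[f"b{i}"] * int(n) for i, n in enumerate(sizes)], [])
    y = make_matrix(rng.normal(2, 3, (int(sizes.sum()), 7)))
    b = make_batches(labels)
    _, adj = ck.fit_transform(y, b, eb="none")
    assert np.max(np.abs(adj.values - combat_oracle(y.values, b))) < 1e-10
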