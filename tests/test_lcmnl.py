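"""Latent class MNL estimation: weighting identities, E-step oracle, EM ascent."""

import numpy as np
import pytest

from latentchoice.cohort import ClassSpec, CohortSpec, simulate_cohort, utilities_matrix
from latentchoice.design import Design, DesignConfig, generate_design
from latentchoice.lcmnl import (
    ChoiceData,
    EMConfig,
    LatentClassMNL,
    e_step,
    em_fit,
    expand_coefficients,
    fit_weighted_mnl,
    sweep_classes,
)


def _true_betas(classes, attributes, scale):
    """Effects-coded coefficient vectors equivalent to stored class utilities."""
    mat, none = utilities_matrix(classes, attributes)
    betas = []
    for c in range(len(classes)):
        row, off = [], 0
        for a in attributes:
            row.extend(mat[c, off : off + a.n_levels - 1] * scale)
            off += a.n_levels
        row.append(none[c] * scale)
        betas.append(row)
    return np.asarray(betas)


class TestWeightedMNL:
    def test_equal_weights_match_unweighted(self, small_cohort):
        data = small_cohort["data"]
        ref = fit_weighted_mnl(data)
        scaled = fit_weighted_mnl(data, weights=np.full(data.n_respondents, 2.0))
        np.testing.assert_allclose(scaled.beta, ref.beta, atol=1e-6)
        assert scaled.loglik == pytest.approx(2.0 * ref.loglik, rel=1e-8)

    def test_zero_weights_equal_subset_fit(self, small_cohort):
        data = small_cohort["data"]
        keep = np.zeros(data.n_respondents, dtype=bool)
        keep[: data.n_respondents // 2] = True
        w = keep.astype(float)
        full = fit_weighted_mnl(data, weights=w)
        half = fit_weighted_mnl(data.subset(keep))
        np.testing.assert_allclose(full.beta, half.beta, atol=1e-6)
        assert full.loglik == pytest.approx(half.loglik, abs=1e-8)

    def test_single_class_coefficient_recovery(self, fixture_classes, attributes):
        """At n=20,000 the aggregate conditional logit recovers the simulating
        coefficients within 3 reported standard errors."""
        fast = fixture_classes[1]
        single = [ClassSpec(fast.label, 1.0, fast.utilities, fast.none_utility)]
        spec = CohortSpec(classes=single, n_respondents=20_000, seed=17)
        obs, _, design = simulate_cohort(spec)
        chosen = obs["chosen"].to_numpy(dtype=np.int64).reshape(-1, 3).argmax(axis=1)
        data = ChoiceData.from_design(design, chosen)
        fit = fit_weighted_mnl(data)
        truth = _true_betas(single, design.attributes, spec.scale)[0]
        assert fit.converged
        assert (np.abs(fit.beta - truth) <= 3 * fit.se).all()

    def test_invalid_weights_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            fit_weighted_mnl(small_cohort["data"], weights=np.zeros(300))


class TestEStep:
    def test_single_class_posterior_is_one(self, small_cohort, fixture_classes):
        data = small_cohort["data"]
        betas = _true_betas(fixture_classes[:1], data.attributes, 0.02)
        post, _ = e_step(data, np.array([1.0]), betas)
        np.testing.assert_array_equal(post, np.ones((data.n_respondents, 1)))

    def test_identical_classes_give_half(self, small_cohort, fixture_classes):
        data = small_cohort["data"]
        beta = _true_betas(fixture_classes[:1], data.attributes, 0.02)[0]
        post, _ = e_step(data, np.array([0.5, 0.5]), np.stack([beta, beta]))
        np.testing.assert_allclose(post, 0.5)

    def test_posteriors_match_brute_force_bayes(self, attributes):
        """Two respondents, two tasks, two classes: posteriors equal explicit
        enumeration of pi_c times the product of task probabilities."""
        design = generate_design(DesignConfig(seed=4, tasks_per_respondent=2), 2)
        chosen = np.array([0, 2, 1, 0])
        data = ChoiceData.from_design(design, chosen)
        rng = np.random.default_rng(8)
        betas = rng.normal(0, 0.5, size=(2, data.n_features))
        shares = np.array([0.3, 0.7])
        post, ll = e_step(data, shares, betas)

        def task_prob(t, c):
            u = data.X[t] @ betas[c]
            e = np.exp(u - u.max())
            return e[chosen[t]] / e.sum()

        joint = np.empty((2, 2))
        for i in range(2):
            for c in range(2):
                prod = 1.0
                for t in np.flatnonzero(data.resp_idx == i):
                    prod *= task_prob(t, c)
                joint[i, c] = shares[c] * prod
        expected_post = joint / joint.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(post, expected_post, atol=1e-12)
        assert ll == pytest.approx(np.log(joint.sum(axis=1)).sum(), abs=1e-12)


class TestEM:
    def test_k1_equals_aggregate_logit(self, small_cohort):
        data = small_cohort["data"]
        model = em_fit(data, EMConfig(n_classes=1, n_replications=1, random_state=0))
        ref = fit_weighted_mnl(data)
        assert model.loglik == pytest.approx(ref.loglik, abs=1e-8)
        np.testing.assert_allclose(model.betas[0], ref.beta, atol=1e-6)

    def test_loglik_trace_non_decreasing(self, small_cohort):
        data = small_cohort["data"]
        model = em_fit(data, EMConfig(n_classes=3, n_replications=2, max_iter=40,
                                      random_state=3))
        trace = model.convergence["best"]["ll_trace"]
        assert len(trace) > 2
        diffs = np.diff(trace)
        assert (diffs >= -1e-8).all()

    def test_label_permutation_invariance(self, small_cohort):
        """Permuting class order leaves the mixture LL (hence AIC/BIC) unchanged."""
        data = small_cohort["data"]
        model = em_fit(data, EMConfig(n_classes=3, n_replications=1, max_iter=30,
                                      random_state=3))
        perm = np.array([2, 0, 1])
        _, ll_perm = e_step(data, model.shares[perm], model.betas[perm])
        assert ll_perm == pytest.approx(model.loglik, abs=1e-9)

    def test_posteriors_and_shares_normalized(self, small_cohort):
        data = small_cohort["data"]
        model = em_fit(data, EMConfig(n_classes=3, n_replications=1, max_iter=30,
                                      random_state=3))
        np.testing.assert_allclose(model.posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert model.shares.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(model.shares) <= 1e-12).all()  # descending report order

    def test_expanded_utilities_zero_centered(self, small_cohort):
        data = small_cohort["data"]
        model = em_fit(data, EMConfig(n_classes=2, n_replications=1, max_iter=20,
                                      random_state=1))
        utilities, _ = model.expanded_utilities()
        off = 0
        for attr in data.attributes:
            np.testing.assert_allclose(
                utilities[:, off : off + attr.n_levels].sum(axis=1), 0.0, atol=1e-9
            )
            off += attr.n_levels

    def test_toy_mixture_likelihood_matches_enumeration(self):
        """Full mixture likelihood on a 2-respondent toy equals brute force."""
        design = generate_design(DesignConfig(seed=6, tasks_per_respondent=2), 2)
        chosen = np.array([1, 2, 0, 1])
        data = ChoiceData.from_design(design, chosen)
        betas = np.random.default_rng(2).normal(0, 0.4, size=(2, data.n_features))
        shares = np.array([0.6, 0.4])
        _, ll = e_step(data, shares, betas)
        total = 0.0
        for i in range(2):
            mix = 0.0
            for c in range(2):
                prod = 1.0
                for t in np.flatnonzero(data.resp_idx == i):
                    u = data.X[t] @ betas[c]
                    e = np.exp(u)
                    prod *= e[chosen[t]] / e.sum()
                mix += shares[c] * prod
            total += np.log(mix)
        assert ll == pytest.approx(total, abs=1e-12)


class TestSweepAndEstimator:
    def test_information_criteria_formulas(self):
        # AIC = -2LL + 2k ; BIC = -2LL + k ln n
        ll, k, n = -100.0, 10, 100
        assert -2 * ll + 2 * k == 220.0
        assert -2 * ll + k * np.log(n) == pytest.approx(246.0517, abs=1e-3)

    def test_sweep_table_contents(self, small_cohort):
        data = small_cohort["data"]
        cfg = EMConfig(n_classes=1, n_replications=1, max_iter=15, tol=1e-4,
                       random_state=2)
        table = sweep_classes(data, [1, 2], cfg)
        assert list(table["n_classes"]) == [1, 2]
        n = data.n_respondents
        for _, row in table.iterrows():
            assert row["aic"] == pytest.approx(-2 * row["loglik"] + 2 * row["n_parameters"])
            assert row["bic"] == pytest.approx(
                -2 * row["loglik"] + row["n_parameters"] * np.log(n)
            )
        assert (table.loc[1, "loglik"] >= table.loc[0, "loglik"] - 1e-6)

    def test_sklearn_estimator_interface(self, small_cohort):
        est = LatentClassMNL(n_classes=2, n_replications=1, max_iter=20, random_state=0)
        params = est.get_params()
        assert params["n_classes"] == 2
        est.set_params(max_iter=25)
        est.fit(small_cohort["observations"])
        assert est.class_shares_.shape == (2,)
        post = est.predict_proba(small_cohort["observations"])
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        pred = est.predict(small_cohort["observations"])
        assert set(pred) <= {0, 1}
        assert est.score(small_cohort["observations"]) < 0
        pw = est.part_worths()
        assert {"class", "attribute", "level", "utility"} <= set(pw.columns)

    def test_estimator_clones(self, small_cohort):
        from sklearn.base import clone

        est = LatentClassMNL(n_classes=2, random_state=0)
        clone(est)  # must not raise
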