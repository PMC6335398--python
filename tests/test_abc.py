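"""Rejection bookkeeping, model posteriors, local-linear adjustment and the
confusion-matrix machinery."""

import numpy as np
import pandas as pd
import pytest

from abcdl import abc_core as abc
from abcdl.coalsim import JointSFS
from abcdl.dlsum import TrainingSet


class TestRejection:
    def test_matches_exhaustive_sort_oracle(self, rng):
        sims = rng.normal(size=(10, 3))
        obs = rng.normal(size=3)
        acc = abc.rejection_sample(obs, sims, abc.AbcConfig(10, 4))
        center, scale = abc.mad_standardize(sims)
        dist = np.sqrt((((sims - center) / scale
                         - (obs - center) / scale) ** 2).sum(axis=1))
        assert set(acc.indices) == set(np.argsort(dist)[:4])
        assert np.all(np.diff(acc.distances) >= 0)

    def test_exact_simulation_retained_at_distance_zero(self, rng):
        sims = rng.normal(size=(200, 2))
        acc = abc.rejection_sample(sims[17], sims, abc.AbcConfig(200, 5))
        assert acc.indices[0] == 17
        assert acc.distances[0] == 0.0

    def test_boundary_ties_break_by_index(self):
        sims = np.zeros((6, 2))  # all equidistant
        acc = abc.rejection_sample(np.ones(2), sims, abc.AbcConfig(6, 3))
        assert list(acc.indices) == [0, 1, 2]

    def test_n_accept_validation(self):
        with pytest.raises(ValueError):
            abc.AbcConfig(10, 11)
        with pytest.raises(ValueError, match="exceeds"):
            abc.rejection_sample(np.zeros(2), np.zeros((5, 2)),
                                 abc.AbcConfig(100, 50))


class TestModelPosterior:
    def test_single_label_accepted_set(self, rng):
        sims = rng.normal(size=(50, 2))
        acc = abc.rejection_sample(np.zeros(2), sims, abc.AbcConfig(50, 10),
                                   labels=np.array(["H"] * 50))
        post = abc.mnlogistic_model_posterior(acc)
        assert post.probabilities == {"H": 1.0}

    def test_null_calibration_and_frequency_agreement(self, rng):
        """Labels independent of the summaries: the multinomial-logistic
        posterior stays near uniform and near the rejection frequencies."""
        K, devs, gaps = 3, [], []
        for _ in range(50):
            sims = rng.normal(size=(3000, 2))
            labels = np.repeat([f"M{i}" for i in range(K)], 1000)
            acc = abc.rejection_sample(rng.normal(size=2), sims,
                                       abc.AbcConfig(3000, 1000), labels=labels)
            post = abc.mnlogistic_model_posterior(acc)
            freq = {m: (acc.labels == m).mean() for m in post.probabilities}
            devs.append(max(abs(p - 1 / K) for p in post.probabilities.values()))
            gaps.append(max(abs(post.probabilities[m] - freq[m]) for m in freq))
        assert np.mean(devs) < 0.05
        assert np.mean(gaps) < 0.1

    def test_separable_models_give_confident_posterior(self, rng):
        ss = np.vstack([rng.normal(-3, 0.3, size=(100, 1)),
                        rng.normal(+3, 0.3, size=(100, 1))])
        labels = np.array(["near"] * 100 + ["far"] * 100)
        # accept 150 of 200 so both labels remain in the accepted set
        acc = abc.rejection_sample(np.array([-3.0]), ss,
                                   abc.AbcConfig(200, 150), labels=labels)
        post = abc.mnlogistic_model_posterior(acc)
        assert post.probabilities["near"] > 0.99
        assert post.method == "mnlogistic"

    def test_bayes_factor_is_probability_ratio(self):
        post = abc.ModelPosterior({"H": 0.46, "F": 0.38, "E": 0.16},
                                  "mnlogistic")
        assert abc.bayes_factor(post, "H", "F") == pytest.approx(0.46 / 0.38)
        assert post.map_label() == "H"


class TestLoclinear:
    def _accepted(self, ss, theta, obs, n_accept, names=("x",)):
        return abc.rejection_sample(obs, ss, abc.AbcConfig(len(ss), n_accept),
                                    params=np.atleast_2d(theta.T).T,
                                    param_names=list(names))

    def test_zero_offset_when_all_summaries_equal_observed(self):
        ss = np.zeros((20, 2))
        theta = np.linspace(1.0, 2.0, 20)
        acc = self._accepted(ss, theta, np.zeros(2), 20)
        post = abc.loclinear_adjust(acc, transforms={"x": "none"})
        # rank-deficient design (constant summaries) degrades to unadjusted
        assert np.allclose(np.sort(post.samples[:, 0]), np.sort(theta))

    def test_exact_linear_relation_recovered(self, rng):
        ss = rng.normal(size=(400, 1))
        theta = 2.0 * ss[:, 0] + 5.0
        obs = np.array([0.3])
        acc = self._accepted(ss, theta, obs, 200)
        post = abc.loclinear_adjust(acc, transforms={"x": "none"})
        assert np.allclose(post.samples[:, 0], 2.0 * 0.3 + 5.0, atol=1e-6)
        summary = abc.posterior_summary(post)
        assert summary["mean"].iloc[0] == pytest.approx(5.6, abs=1e-6)

    def test_constant_parameter_stays_degenerate(self, rng):
        ss = rng.normal(size=(100, 2))
        theta = np.full(100, 7.0)
        acc = self._accepted(ss, theta, np.zeros(2), 50)
        post = abc.loclinear_adjust(acc, transforms={"x": "none"})
        summary = abc.posterior_summary(post)
        assert summary["mean"].iloc[0] == pytest.approx(7.0)
        assert summary["q97.5"].iloc[0] - summary["q2.5"].iloc[0] == pytest.approx(0.0)

    def test_logit_transform_keeps_fractions_in_unit_interval(self, rng):
        ss = rng.normal(size=(300, 1))
        frac = 1 / (1 + np.exp(-(ss[:, 0] + rng.normal(0, 0.3, 300))))
        acc = abc.rejection_sample(np.array([2.5]), ss, abc.AbcConfig(300, 100),
                                   params=frac[:, None], param_names=["f_x"])
        post = abc.loclinear_adjust(acc)
        assert np.all((post.samples >= 0) & (post.samples <= 1))


class TestPosteriorSummary:
    def test_normal_sample_credible_interval(self, rng):
        post = abc.ParameterPosterior(["z"], rng.normal(size=(100_000, 1)),
                                      np.ones(100_000), adjusted=False)
        s = abc.posterior_summary(post)
        assert s["q2.5"].iloc[0] == pytest.approx(-1.96, abs=0.03)
        assert s["q97.5"].iloc[0] == pytest.approx(1.96, abs=0.03)

    def test_concentrated_weights_return_that_sample(self, rng):
        samples = rng.normal(size=(50, 1))
        w = np.zeros(50)
        w[13] = 1.0
        post = abc.ParameterPosterior(["z"], samples, w, adjusted=False)
        s = abc.posterior_summary(post)
        assert s["mean"].iloc[0] == pytest.approx(samples[13, 0])
        assert s["q2.5"].iloc[0] == pytest.approx(samples[13, 0])

    def test_zero_weights_rejected(self, rng):
        post = abc.ParameterPosterior(["z"], rng.normal(size=(5, 1)),
                                      np.zeros(5), adjusted=False)
        with pytest.raises(ValueError, match="zero"):
            abc.posterior_summary(post)


class TestConfusion:
    @staticmethod
    def _label_encoding_sim(label, rng):
        """The spectrum encodes its label, so an oracle summarizer exists."""
        cells = rng.poisson(5.0, size=(3, 3)).astype(float)
        cells[1, 1] = 1000.0 * (ord(label) - ord("A") + 1)
        return JointSFS(cells, ["P1", "P2"])

    def test_oracle_classifier_gives_identity_matrix(self, rng):
        def factory(train):
            def oracle(X):
                code = np.round(X[:, 3] / 1000.0).astype(int) - 1
                out = np.zeros((len(X), 3))
                out[np.arange(len(X)), code] = 1.0
                return out
            return oracle

        confusion, true_post = abc.cross_validation_confusion(
            ["A", "B", "C"], self._label_encoding_sim, n_train=60, n_pseudo=5,
            rng=rng, cfg=abc.AbcConfig(180, 20), summarizer_factory=factory)
        assert np.allclose(confusion.values, np.eye(3))
        assert (true_post > 0.9).all()

    def test_rows_sum_to_one(self, rng):
        confusion, _ = abc.cross_validation_confusion(
            ["A", "B"], self._label_encoding_sim, n_train=40, n_pseudo=4,
            rng=rng, cfg=abc.AbcConfig(80, 10),
            hyper={"hidden_layer_sizes": (4, 2), "max_epochs": 15})
        assert np.allclose(confusion.sum(axis=1).values, 1.0)

    def test_zero_pseudo_rejected(self, rng):
        with pytest.raises(ValueError, match="n_pseudo"):
            abc.cross_validation_confusion(["A", "B"], self._label_encoding_sim,
                                           10, 0, rng)


class TestPipelineCoverage:
    def test_one_parameter_pipeline_interval_coverage(self, rng):
        """Full SFS -> summary net -> rejection -> local-linear pipeline on a
        single-population model with the effective size as the only free
        parameter: 95% credible intervals must cover the truth in >= 85% of
        100 pseudo-observed runs."""
        from abcdl import coalsim as cs
        from abcdl import dlsum
        from conftest import make_regions, one_pop_spec

        mu = cs.MutationRateSpec()
        regions = make_regions(8, 20_000)

        def simulate(size, rng):
            return cs.simulate_joint_sfs(one_pop_spec(size), None, regions,
                                         mu, rng)

        log_lo, log_hi = np.log(1_000.0), np.log(20_000.0)
        sizes = np.exp(rng.uniform(log_lo, log_hi, size=1500))
        X = np.array([simulate(s, rng).to_vector() for s in sizes])
        reg = dlsum.SFSRegressor(hidden_layer_sizes=(6, 3),
                                 proportion_normalize=False, random_state=0)
        reg.fit(X, np.log(sizes))
        ss = reg.predict(X)[:, None]
        est = abc.ABCParameterEstimator(n_accept=100).fit(
            ss, sizes[:, None], param_names=["n_pop"])
        covered = 0
        for _ in range(100):
            true_size = float(np.exp(rng.uniform(log_lo, log_hi)))
            obs = simulate(true_size, rng)
            ss_obs = reg.predict(obs.to_vector()[None, :])[:, None][0]
            post = est.posterior(ss_obs)
            lo, hi = abc.weighted_quantile(post.samples[:, 0], [0.025, 0.975],
                                           post.weights)
            covered += lo <= true_size <= hi
        assert covered >= 85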