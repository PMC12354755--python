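import numpy as np
import pytest
from scipy.special import ndtr

from rlpupil.synth import (
    CohortGroundTruth,
    GroupHyperParameters,
    generate_cohort_behaviour,
)
from rlpupil.transforms import transform_to_natural
from rlpupil.inference import (
    PosteriorSamples,
    SamplerConfig,
    build_model,
    convergence_report,
    max_rhat,
    nuts_sample,
    posterior_predictive_check,
    rhat,
    sample_posterior,
)


@pytest.fixture(scope="module")
def tiny_cohort():
    return generate_cohort_behaviour(CohortGroundTruth(), 5, rng_seed=10)


class TestTransforms:
    def test_zero_probit_maps_to_midpoints(self):
        a, b = transform_to_natural(0.0, 0.0, "placebo")
        assert a == pytest.approx(0.5)
        assert b == pytest.approx(5.0)

    def test_zero_offset_is_identity(self):
        a_p, b_p = transform_to_natural(0.3, -0.2, "placebo")
        a_d, b_d = transform_to_natural(0.3, -0.2, "atomoxetine", 0.0, 0.0)
        assert a_p == a_d and b_p == b_d

    def test_beta_upper_bound_in_limit(self):
        _, b = transform_to_natural(0.0, 40.0, "placebo")
        assert b == pytest.approx(10.0, abs=1e-12)

    def test_offset_applied_before_cdf(self):
        a, _ = transform_to_natural(0.5, 0.0, "atomoxetine", delta_alpha=0.5)
        assert a == pytest.approx(ndtr(1.0))

    def test_unknown_drug_state_rejected(self):
        with pytest.raises(ValueError):
            transform_to_natural(0.0, 0.0, "caffeine")


class TestModel:
    @pytest.mark.parametrize("design", ["single_session", "crossover"])
    def test_gradient_matches_finite_differences(self, tiny_cohort, design):
        data = tiny_cohort.data
        if design == "single_session":
            sub = data.df[data.df["drug_state"] == "placebo"].copy()
            sub["drug_state"] = "none"
            from rlpupil.qlearning import ChoiceDataset

            data = ChoiceDataset(sub)
        model = build_model(data, "gain", design)
        rng = np.random.default_rng(0)
        theta = 0.2 * rng.standard_normal(model.dim)
        _, grad = model.logp_grad(theta)
        eps = 1e-6
        for i in rng.choice(model.dim, size=min(model.dim, 12), replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (model.logp(tp) - model.logp(tm)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_crossover_adds_four_group_pairs(self, tiny_cohort):
        cross = build_model(tiny_cohort.data, "gain", "crossover")
        names = cross.parameter_names()
        assert "mu_delta_alpha" in names and "sigma_delta_beta" in names
        # 4 extra location/scale pairs and 2 extra nu blocks vs single_session
        assert cross.n_group_params == 8
        assert cross.dim == 8 + 4 * cross.n_participants

    def test_single_session_has_no_delta(self, tiny_cohort):
        from rlpupil.qlearning import ChoiceDataset

        sub = tiny_cohort.data.df[tiny_cohort.data.df["drug_state"] == "placebo"].copy()
        sub["drug_state"] = "none"
        model = build_model(ChoiceDataset(sub), "gain", "single_session")
        assert not any("delta" in n for n in model.parameter_names())

    def test_missing_drug_state_rejected(self, tiny_cohort):
        from rlpupil.qlearning import ChoiceDataset

        df = tiny_cohort.data.df
        broken = df[
            ~((df["participant_id"] == "p000") & (df["drug_state"] == "atomoxetine"))
        ]
        with pytest.raises(ValueError, match="missing drug state"):
            build_model(ChoiceDataset(broken), "gain", "crossover")

    def test_sigma_always_positive_in_unpacked_draws(self, tiny_cohort):
        # the sigma < 0 region is excluded by construction: the sampler works
        # on log(sigma), so any unconstrained vector maps to sigma > 0
        model = build_model(tiny_cohort.data, "gain", "crossover")
        rng = np.random.default_rng(1)
        unpacked = model.unpack(5.0 * rng.standard_normal((100, model.dim)))
        for key in ("sigma_alpha", "sigma_beta", "sigma_delta_alpha", "sigma_delta_beta"):
            assert np.all(unpacked[key] > 0)


class TestNuts:
    def test_recovers_gaussian_target(self):
        cov = np.array([[1.0, 0.6, 0.0], [0.6, 2.0, 0.3], [0.0, 0.3, 0.5]])
        prec = np.linalg.inv(cov)

        def logp_grad(theta):
            g = -prec @ theta
            return 0.5 * float(theta @ g), g

        draws, stats = nuts_sample(
            logp_grad, 3, SamplerConfig(chains=2, iterations=3000, warmup=1000), 0
        )
        flat = draws.reshape(-1, 3)
        assert np.allclose(flat.mean(axis=0), 0.0, atol=0.1)
        assert np.allclose(np.cov(flat.T), cov, atol=0.25)

    def test_deterministic_under_seed(self):
        def logp_grad(theta):
            return -0.5 * float(theta @ theta), -theta

        a, _ = nuts_sample(logp_grad, 2, SamplerConfig(chains=2, iterations=300, warmup=150), 7)
        b, _ = nuts_sample(logp_grad, 2, SamplerConfig(chains=2, iterations=300, warmup=150), 7)
        assert np.array_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(iterations=100, warmup=100)


class TestRhat:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        r = rhat(rng.standard_normal((4, 4000)))
        assert r == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_far_above_threshold(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(100, 1, 1000)])
        r = rhat(chains)
        # closed-form check: B/n ~ var of the two means = (50)^2 * 2
        n = 500  # split halves
        w = chains.reshape(4, n).var(axis=1, ddof=1).mean()
        means = chains.reshape(4, n).mean(axis=1)
        expected = np.sqrt(((n - 1) / n * w + means.var(ddof=1)) / w)
        assert r > 1.1
        assert r == pytest.approx(expected, rel=1e-10)

    def test_constant_parameter_gives_nan(self):
        assert np.isnan(rhat(np.ones((2, 100))))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))

    def test_agrees_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(2)
        chains = rng.standard_normal((4, 500)) + rng.normal(0, 0.2, size=(4, 1))
        ours = rhat(chains)
        theirs = float(
            az.rhat(az.convert_to_dataset(chains), method="split")["x"].values
        )
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestSampling:
    def test_prior_dominance_with_minimal_data(self):
        # 1 participant, 4 trials: posterior of mu should stay near the prior
        import pandas as pd

        from rlpupil.qlearning import ChoiceDataset

        frames = []
        for drug in ("placebo", "atomoxetine"):
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": "p0",
                        "drug_state": drug,
                        "condition": "gain",
                        "trial": range(4),
                        "action": [0, 1, 0, 1],
                        "outcome": [0.5, 0.0, 0.5, 0.0],
                        "rt": np.nan,
                    }
                )
            )
        data = ChoiceDataset(pd.concat(frames, ignore_index=True))
        model = build_model(data, "gain", "crossover")
        samples = sample_posterior(
            model, SamplerConfig(chains=2, iterations=800, warmup=400), rng_seed=3
        )
        mu = samples.stacked("mu_alpha")
        # prior is N(0, 1); Monte-Carlo prior check with generous tolerance
        assert abs(mu.mean()) < 0.5
        assert 0.5 < mu.std() < 1.5

    def test_natural_draws_respect_bounds(self, small_fit):
        for drug in ("placebo", "atomoxetine"):
            a = small_fit.participant_natural("alpha", drug)
            b = small_fit.participant_natural("beta", drug)
            assert np.all((a >= 0) & (a <= 1))
            assert np.all((b >= 0) & (b <= 10))

    def test_reduced_fit_converges(self, small_fit):
        assert max_rhat(small_fit) < 1.1

    def test_convergence_report_covers_all_parameters(self, small_fit):
        report = convergence_report(small_fit)
        # 8 group-level + 4 blocks x 12 participants
        assert len(report) == 8 + 4 * 12
        assert report["converged"].all()


class TestPosteriorSamplesIO:
    def test_round_trip_is_lossless(self, small_fit, tmp_path):
        prefix = tmp_path / "fit"
        small_fit.to_files(prefix)
        loaded = PosteriorSamples.from_files(prefix)
        assert loaded.condition == small_fit.condition
        assert loaded.participant_ids == [str(p) for p in small_fit.participant_ids]
        for name, arr in small_fit.draws.items():
            assert np.array_equal(loaded.draws[name], arr), name


class TestPPC:
    def test_single_rep_shape_contract(self, small_cohort, small_fit):
        ppc = posterior_predictive_check(
            small_fit, small_cohort.data, small_cohort.schedules, n_rep=1, rng_seed=0
        )
        assert ppc.replicated.shape == (1, 8)
        assert ppc.observed.shape == (8,)

    def test_self_consistency_coverage(self, small_cohort, small_fit):
        # the data were generated from the model family, so observed bins
        # should sit inside the replicated 89% envelope ~89% of the time
        ppc = posterior_predictive_check(
            small_fit, small_cohort.data, small_cohort.schedules, n_rep=200, rng_seed=1
        )
        assert ppc.coverage >= 0.79

    def test_misfit_detected_on_deterministic_data(self, small_cohort, small_fit):
        from rlpupil.qlearning import ChoiceDataset

        df = small_cohort.data.df.copy()
        df["action"] = 0  # all-correct, impossible under the fitted noise level
        adversarial = ChoiceDataset(df)
        ppc_self = posterior_predictive_check(
            small_fit, small_cohort.data, small_cohort.schedules, n_rep=200, rng_seed=2
        )
        ppc_bad = posterior_predictive_check(
            small_fit, adversarial, small_cohort.schedules, n_rep=200, rng_seed=2
        )
        assert ppc_bad.coverage < ppc_self.coverage
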