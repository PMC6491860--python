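"""Joint Rasch/lognormal-RT model: densities, sampler, diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, stats

from taskrt import joint_model as jm
from taskrt.data_model import ItemMeta, TaskDataset
from taskrt.presets import ITEM_PARAMS
from taskrt.synthetic import GenerativeConfig, generate, study_like_config


class TestRaschProbability:
    def test_equal_ability_and_difficulty(self):
        assert jm.rasch_probability(0.3, 0.3) == pytest.approx(0.5)

    def test_unit_logit(self):
        assert jm.rasch_probability(1.0, 0.0) == pytest.approx(0.731059, abs=1e-6)

    def test_saturation_without_under_or_overflow(self):
        assert jm.rasch_probability(-50.0, 0.0) == pytest.approx(0.0, abs=1e-20)
        assert jm.rasch_probability(700.0, 0.0) == 1.0
        assert np.isfinite(jm.rasch_probability(-700.0, 0.0))


class TestRtLogDensity:
    def test_standard_normal_at_origin(self):
        """t=1, alpha=1, beta=tau: density is 1/sqrt(2*pi)."""
        val = np.exp(jm.rt_log_density(1.0, 0.5, 0.5, 1.0))
        assert val == pytest.approx(1.0 / np.sqrt(2 * np.pi), abs=1e-9)

    def test_integrates_to_one(self):
        f = lambda t: np.exp(jm.rt_log_density(t, 0.0, 3.0, 2.0))  # noqa: E731
        total, err = integrate.quad(f, 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mode_matches_numeric_argmax(self):
        tau, beta, alpha = 0.0, 3.0, 2.0
        analytic = np.exp(beta - tau - 1.0 / alpha**2)
        res = optimize.minimize_scalar(
            lambda t: -jm.rt_log_density(t, tau, beta, alpha),
            bounds=(1.0, 60.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.x == pytest.approx(analytic, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            jm.rt_log_density(-1.0, 0.0, 3.0, 2.0)
        with pytest.raises(ValueError):
            jm.rt_log_density(1.0, 0.0, 3.0, -2.0)


class TestPsr:
    def test_identical_chains(self):
        """Two identical chains: B = 0 so R-hat = sqrt((n-1)/n)."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        assert jm.psr(np.vstack([x, x])) == pytest.approx(np.sqrt(999 / 1000))

    def test_separated_chains_exceed_threshold(self):
        rng = np.random.default_rng(1)
        chains = np.vstack(
            [rng.standard_normal(1000), 5.0 + rng.standard_normal(1000)]
        )
        assert jm.psr(chains) > 1.1

    def test_matches_two_pass_oracle(self):
        """Hand computation on 3 chains x 10 draws agrees to 1e-12."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 10))
        m, n = x.shape
        means = [sum(row) / n for row in x]
        W = sum(sum((v - mu) ** 2 for v in row) / (n - 1) for row, mu in zip(x, means)) / m
        grand = sum(means) / m
        B = n * sum((mu - grand) ** 2 for mu in means) / (m - 1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert jm.psr(x) == pytest.approx(expected, abs=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            jm.psr(np.ones((1, 100)))


class TestEapSummary:
    def test_small_example(self):
        s = jm.eap_summary(np.array([1.0, 2.0, 3.0]))
        assert s["eap"] == pytest.approx(2.0)

    def test_credible_interval_of_standard_normal(self):
        rng = np.random.default_rng(3)
        s = jm.eap_summary(rng.standard_normal(10_000))
        assert s["ci_lower"] == pytest.approx(-1.96, abs=0.06)
        assert s["ci_upper"] == pytest.approx(1.96, abs=0.06)

    def test_pooling_two_equal_chains(self):
        a, b = np.full(50, 1.0), np.full(50, 3.0)
        s = jm.eap_summary(np.vstack([a, b]))
        assert s["eap"] == pytest.approx(2.0)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            jm.eap_summary(np.array([]))


class TestCorrelations:
    def test_worked_example_rho_b_beta(self):
        """cov 0.24 with variances 2.77 and 0.43 gives rho = 0.22."""
        rho = jm.correlation_from_covariance(0.24, 2.77, 0.43)
        assert round(rho, 2) == 0.22

    def test_diagonal_draws_give_zero_correlation(self, scaled_fit):
        _, _, draws = scaled_fit
        fake = jm.PosteriorDraws(
            theta=draws.theta,
            tau=draws.tau,
            b=draws.b,
            beta=draws.beta,
            alpha=draws.alpha,
            mu_b=draws.mu_b,
            mu_beta=draws.mu_beta,
            sigma_p=np.broadcast_to(
                np.array([1.0, 0.0, 1.0]), draws.sigma_p.shape
            ).copy(),
            sigma_i=draws.sigma_i,
            config=draws.config,
        )
        est = jm.correlation_estimates(fake)["rho_theta_tau"]
        assert est["eap"] == 0.0
        assert est["ci_lower"] == est["ci_upper"] == 0.0

    def test_correlations_bounded_in_every_draw(self, scaled_fit):
        _, _, draws = scaled_fit
        for key in ("sigma_p", "sigma_i"):
            s = draws.pooled(key)
            rho = s[:, 1] / np.sqrt(s[:, 0] * s[:, 2])
            assert np.all(np.abs(rho) <= 1.0)


def test_inverse_wishart_sampler_mean():
    """Bartlett-based IW draws reproduce E[IW(psi, df)] = psi/(df-3)."""
    rng = np.random.default_rng(4)
    psi = np.array([[2.0, 0.3], [0.3, 1.0]])
    df = 10.0
    acc = np.zeros((2, 2))
    n = 20_000
    for _ in range(n):
        acc += jm._invwishart_2x2(rng, df, psi)
    mean = acc / n
    assert np.allclose(mean, psi / (df - 3.0), atol=0.03)


class TestSampler:
    def test_retained_draw_count_matches_schedule(self, scaled_fit):
        """(iterations - burn_in)/thin draws per chain; the default
        study schedule retains 2,000."""
        _, _, draws = scaled_fit
        assert draws.theta.shape[:2] == (2, 600)
        default = jm.McmcConfig(seed=0)
        assert default.retained_per_chain == 2000

    def test_identifiability_constraint_in_every_draw(self, scaled_fit):
        _, _, draws = scaled_fit
        assert np.all(np.abs(draws.theta.mean(axis=2)) < 1e-10)
        assert np.all(np.abs(draws.tau.mean(axis=2)) < 1e-10)

    def test_scaled_run_converges(self, scaled_fit):
        """Max PSR over all reported parameters below 1.1."""
        _, _, draws = scaled_fit
        table = jm.psr_table(draws)
        assert float(table.max()) < 1.1

    def test_item_parameter_recovery(self, scaled_fit):
        """EAPs of b and beta within 0.3 of truth for >=9 of 11 items."""
        _, truth, draws = scaled_fit
        eap_b = draws.pooled("b").mean(axis=0)
        eap_beta = draws.pooled("beta").mean(axis=0)
        ok_b = np.abs(eap_b - truth.items["b"].to_numpy()) <= 0.3
        ok_beta = np.abs(eap_beta - truth.items["beta"].to_numpy()) <= 0.3
        assert ok_b.sum() >= 9
        assert ok_beta.sum() >= 9

    def test_posterior_predictive_median_rts(self, scaled_fit):
        """Data regenerated from EAPs reproduce per-item median RTs
        within 15%."""
        dataset, _, draws = scaled_fit
        beta = draws.pooled("beta").mean(axis=0)
        tau = draws.pooled("tau").mean(axis=0)
        implied = np.exp(beta[None, :] - tau[:, None])
        ratio = np.median(implied, axis=0) / np.median(dataset.T, axis=0)
        assert np.all(np.abs(ratio - 1.0) < 0.15)

    def test_rt_only_conjugate_limit(self):
        """With huge fixed alpha and responses ignored, the posterior
        mean of beta_i collapses to the column mean of log T."""
        cfg = GenerativeConfig(
            J=150,
            I=4,
            fixed_b=[0.0] * 4,
            fixed_beta=[2.0, 2.5, 3.0, 3.5],
            alpha_spec=[5.0, 5.0, 5.0, 5.0],
            seed=20,
        )
        dataset, _ = generate(cfg)
        mcmc = jm.McmcConfig(
            chains=2,
            iterations=800,
            burn_in=300,
            thin=1,
            seed=21,
            fix_alpha=np.full(4, 1e4),
            use_responses=False,
        )
        draws = jm.sample_posterior(dataset, mcmc)
        eap_beta = draws.pooled("beta").mean(axis=0)
        assert np.allclose(eap_beta, np.log(dataset.T).mean(axis=0), atol=0.02)

    def test_level2_correlation_interval_coverage(self):
        """Across 20 scaled-down refits the 95% credible interval for the
        ability-speed correlation covers the generating value (0.153)
        in at least 80%."""
        truth_rho = 0.04 / np.sqrt(0.85 * 0.08)
        covered = 0
        for rep in range(20):
            dataset, _ = generate(
                study_like_config(seed=5000 + rep, covariates=False)
            )
            mcmc = jm.McmcConfig(
                chains=1, iterations=5_000, burn_in=2_000, thin=5, seed=600 + rep
            )
            draws = jm.sample_posterior(dataset, mcmc)
            est = jm.correlation_estimates(draws)["rho_theta_tau"]
            covered += est["ci_lower"] <= truth_rho <= est["ci_upper"]
        assert covered >= 16


class TestIccCheck:
    def test_twelve_persons_make_six_pairs(self):
        rng = np.random.default_rng(5)
        ds = TaskDataset(
            Y=rng.integers(0, 2, size=(12, 2)),
            T=np.full((12, 2), 10.0),
            items=[
                ItemMeta(1, "MC", "single-selection", 0.25),
                ItemMeta(2, "CR", "explanation", 0.0),
            ],
        )
        check = jm.icc_check(ds, rng.standard_normal(12), np.zeros(2))
        assert check.group_sizes.tolist() == [2, 2, 2, 2, 2, 2]

    def test_rasch_data_tracks_model_curve(self):
        """On exactly Rasch data at large J the observed group accuracy
        stays within 0.03 of the model-implied group proportion (the
        member-averaged Rasch probability), and close to the curve
        evaluated at the group-mean ability."""
        cfg = GenerativeConfig(
            J=20_000,
            I=11,
            fixed_b=ITEM_PARAMS["b"].tolist(),
            fixed_beta=ITEM_PARAMS["beta"].tolist(),
            alpha_spec=ITEM_PARAMS["alpha"].tolist(),
            seed=30,
        )
        dataset, truth = generate(cfg)
        theta = truth.persons["theta"].to_numpy()
        check = jm.icc_check(dataset, theta, ITEM_PARAMS["b"])
        order = np.argsort(theta, kind="stable")
        groups = np.array_split(order, 6)
        exact = np.vstack(
            [
                jm.rasch_probability(theta[g][:, None], ITEM_PARAMS["b"][None, :]).mean(
                    axis=0
                )
                for g in groups
            ]
        )
        assert np.max(np.abs(check.observed - exact)) < 0.03
        # the group-mean curve is a close (Jensen-biased) approximation
        assert np.max(np.abs(check.model - exact)) < 0.02

    def test_constant_column(self):
        ds = TaskDataset(
            Y=np.ones((30, 1), dtype=int),
            T=np.full((30, 1), 5.0),
            items=[ItemMeta(1, "MC", "single-selection", 0.25)],
        )
        check = jm.icc_check(ds, np.linspace(-1, 1, 30), np.array([0.0]))
        assert np.all(check.observed == 1.0)

    def test_too_few_persons_rejected(self):
        ds = TaskDataset(
            Y=np.ones((3, 1), dtype=int),
            T=np.full((3, 1), 5.0),
            items=[ItemMeta(1, "MC", "single-selection", 0.25)],
        )
        with pytest.raises(ValueError):
            jm.icc_check(ds, np.zeros(3), np.zeros(1))


def test_posterior_summary_round_trip(tmp_path, scaled_fit):
    from taskrt.data_model import load_results, save_results

    _, _, draws = scaled_fit
    summary = jm.summarize_posterior(draws)
    path = save_results(summary, tmp_path / "posterior.json")
    loaded = load_results(path)
    assert loaded == summary
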