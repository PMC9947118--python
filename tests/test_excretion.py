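"""Excretion model: density oracles, priors, fitting contract, diagnostics."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from ichthyocarb.data import Dataset, DomainError, FishObservation
from ichthyocarb.excretion import (
    ExcretionModelSpec,
    PriorSet,
    _BoundModel,
    bayes_r2,
    fit,
    levene_method_test,
    log_likelihood,
    log_prior,
    pointwise_log_likelihood,
    ppc_coverage,
)
from ichthyocarb.sampler import numerical_gradient
from ichthyocarb.synthetic import (
    SimulationConfig,
    default_truth,
    simulate_community,
    simulate_dataset,
    simulate_excretion,
)


def _params_for(ds, spec, rng, scale=0.5):
    K = len(ds.families)
    return {
        "gamma0": float(rng.normal(0, scale)),
        "beta": rng.normal(0, scale, size=len(spec.location_terms)),
        "u": rng.normal(0, scale, size=K),
        "tau": float(rng.uniform(0.1, 1.0)),
        "gamma_sigma": float(rng.normal(-0.5, 0.3)),
        "beta_sigma": float(rng.normal(0.5, 0.3)),
        "nu": float(rng.uniform(3, 40)),
    }


class TestLogLikelihood:
    def test_weight_two_doubles_the_contribution(self, rng):
        base = dict(
            family="F",
            species="s",
            region="R",
            body_mass_kg=0.2,
            ril=1.1,
            ar=1.4,
            temperature_C=26.0,
            salinity=35.0,
            sampling_period_h=48.0,
            titration_method="double",
            excretion_rate_umol_h=2.5,
        )
        spec = ExcretionModelSpec(group_factor=None)
        params = {
            "gamma0": 0.3,
            "beta": np.array([0.7, -0.5, 0.6, 0.05]),
            "gamma_sigma": -0.8,
            "beta_sigma": 0.7,
            "nu": 12.0,
        }
        single = Dataset([FishObservation(obs_id="a", n_individuals=1, **base)])
        grouped = Dataset([FishObservation(obs_id="a", n_individuals=4, **base)])
        l1 = log_likelihood(params, single, spec)
        l2 = log_likelihood(params, grouped, spec)
        assert l2 == pytest.approx(2.0 * l1, rel=1e-12)

    def test_matches_scipy_t_density_at_random_points(self, community, rng):
        ds, _, _ = community
        spec = ExcretionModelSpec()
        m = _BoundModel(spec, PriorSet(), ds, standardise=False)
        for _ in range(20):
            p = _params_for(ds, spec, rng)
            got = log_likelihood(p, ds, spec)
            eta = p["gamma0"] + m.X @ p["beta"] + p["u"][m.fam_idx]
            sig = np.exp(p["gamma_sigma"] + p["beta_sigma"] * m.method)
            want = float(
                np.sum(
                    m.w * stats.t.logpdf(m.lny, p["nu"], loc=eta, scale=sig)
                )
            )
            assert got == pytest.approx(want, abs=1e-10)

    def test_gaussian_limit_at_large_df(self):
        # at nu = 1e6 the t log density matches the normal to 1e-4 for
        # residuals within a few SD (the correction is O(r^4 / nu))
        from ichthyocarb.excretion import _t_logpdf

        x = np.linspace(-3.5, 3.5, 41)
        got = _t_logpdf(x, 1e6, 0.4, 1.3)
        want = stats.norm.logpdf(x, 0.4, 1.3)
        np.testing.assert_allclose(got, want, atol=1e-4)

    def test_invariant_to_observation_ordering(self, community, rng):
        ds, _, _ = community
        spec = ExcretionModelSpec()
        p = _params_for(ds, spec, rng)
        perm = rng.permutation(len(ds))
        shuffled = Dataset(
            observations=[ds.observations[i] for i in perm],
            profiles=list(ds.profiles),
        )
        assert log_likelihood(p, ds, spec) == pytest.approx(
            log_likelihood(p, shuffled, spec), rel=1e-12
        )


class TestLogPrior:
    def test_matches_scipy_densities_at_random_points(self, community, rng):
        ds, _, _ = community
        spec = ExcretionModelSpec()
        pr = PriorSet()
        for _ in range(20):
            p = _params_for(ds, spec, rng)
            got = log_prior(p, pr, spec)
            want = (
                stats.norm.logpdf(p["gamma0"], 0, 5)
                + stats.norm.logpdf(p["beta"], 0, 5).sum()
                + stats.t.logpdf(p["gamma_sigma"], 3, 0, 2.5)
                + stats.norm.logpdf(p["beta_sigma"], 0, 5)
                + stats.gamma.logpdf(p["nu"], 2, scale=10.0)
                + np.log(2) + stats.norm.logpdf(p["tau"], 0, 5)
                + stats.norm.logpdf(p["u"], 0, p["tau"]).sum()
            )
            assert got == pytest.approx(float(want), abs=1e-10)

    def test_symmetric_in_coefficient_signs(self, community, rng):
        ds, _, _ = community
        spec = ExcretionModelSpec()
        p = _params_for(ds, spec, rng)
        q = dict(p)
        q["beta"] = -p["beta"]
        q["gamma0"] = -p["gamma0"]
        q["u"] = -p["u"]
        assert log_prior(p, PriorSet(), spec) == pytest.approx(
            log_prior(q, PriorSet(), spec), rel=1e-12
        )

    def test_negative_tau_excluded(self, community, rng):
        ds, _, _ = community
        spec = ExcretionModelSpec()
        p = _params_for(ds, spec, rng)
        p["tau"] = -0.1
        assert log_prior(p, PriorSet(), spec) == -np.inf


class TestGradients:
    @pytest.mark.parametrize(
        "spec",
        [
            ExcretionModelSpec(),
            ExcretionModelSpec(group_factor=None, scale_terms=()),
            ExcretionModelSpec(location_terms=(), scale_terms=()),
        ],
        ids=["full", "linear", "intercept-only"],
    )
    def test_posterior_gradient_matches_finite_differences(
        self, community, spec, rng
    ):
        ds, _, _ = community
        m = _BoundModel(spec, PriorSet(), ds)
        q = m.initial_position(rng) + 0.3 * rng.standard_normal(m.dim)
        _, g = m.logpost_and_grad(q)
        gn = numerical_gradient(lambda x: m.logpost_and_grad(x)[0], q, 1e-5)
        np.testing.assert_allclose(g, gn, rtol=1e-5, atol=1e-6)


class TestFit:
    def test_recovers_generating_mass_exponent(self, community, excretion_fit):
        ds, truth, _ = community
        s = excretion_fit.summary()
        j = excretion_fit.spec.location_terms.index("ln_mass")
        row = s.loc[f"beta[{j}]"]
        assert row["q2.5"] < truth.excretion.beta["ln_mass"] < row["q97.5"]

    def test_convergence_contract_on_well_specified_data(self, excretion_fit):
        s = excretion_fit.summary()
        assert (s["rhat"] < 1.03).all()
        assert excretion_fit.draws.divergences == 0

    def test_scale_pair_recovered(self, community, excretion_fit):
        ds, truth, _ = community
        p = excretion_fit.stacked_params()
        sig_double = np.exp(p["gamma_sigma"])
        sig_single = np.exp(p["gamma_sigma"] + p["beta_sigma"])
        t_double = np.exp(truth.excretion.gamma_sigma)
        t_single = np.exp(
            truth.excretion.gamma_sigma + truth.excretion.beta_sigma
        )
        assert (
            np.quantile(sig_double, 0.025)
            < t_double
            < np.quantile(sig_double, 0.975)
        )
        assert (
            np.quantile(sig_single, 0.025)
            < t_single
            < np.quantile(sig_single, 0.975)
        )

    def test_intercept_only_matches_weighted_mean_of_lny(self):
        # iid lognormal data: the intercept posterior concentrates on the
        # weighted mean of ln y
        rng = np.random.default_rng(2)
        obs = [
            FishObservation(
                obs_id=f"o{i}",
                family="A" if i % 2 else "B",
                species="s",
                region="R",
                n_individuals=1,
                body_mass_kg=1.0,
                ril=1.0,
                ar=1.0,
                temperature_C=25.0,
                salinity=35.0,
                sampling_period_h=24.0,
                titration_method="double",
                excretion_rate_umol_h=float(np.exp(rng.normal(1.2, 0.3))),
            )
            for i in range(120)
        ]
        ds = Dataset(observations=obs)
        spec = ExcretionModelSpec(
            location_terms=(), group_factor=None, scale_terms=()
        )
        f = fit(
            spec, PriorSet(), ds, chains=2, iter=800, warmup=400, seed=4
        )
        g0 = f.draws.stacked("gamma0")
        lny = np.log([o.excretion_rate_umol_h for o in obs])
        assert g0.mean() == pytest.approx(lny.mean(), abs=0.08)

    def test_standardisation_invariance_of_natural_coefficients(
        self, small_community
    ):
        ds, _, _ = small_community
        spec = ExcretionModelSpec()
        kw = dict(chains=2, iter=900, warmup=450, seed=5)
        f_std = fit(spec, PriorSet(), ds, standardise=True, **kw)
        f_nat = fit(spec, PriorSet(), ds, standardise=False, **kw)
        b_std = f_std.draws.stacked("beta").mean(axis=0)
        b_nat = f_nat.draws.stacked("beta").mean(axis=0)
        se = f_std.draws.stacked("beta").std(axis=0, ddof=1)
        assert np.all(np.abs(b_std - b_nat) < 4 * se / np.sqrt(50) + 0.02)

    def test_empty_dataset_rejected(self):
        with pytest.raises(DomainError):
            fit(
                ExcretionModelSpec(),
                PriorSet(),
                Dataset(observations=[]),
                chains=1,
                iter=10,
                warmup=5,
            )


class TestPosteriorContraction:
    def test_recovery_error_shrinks_with_sample_size(self):
        def one(n_obs, seed):
            cfg = SimulationConfig(
                n_families=10, species_per_family=2, n_obs=n_obs
            )
            truth = default_truth(cfg, seed=seed)
            skel = simulate_community(cfg, seed=seed + 1)
            obs = simulate_excretion(skel, truth.excretion, seed=seed + 2)
            ds = Dataset.from_frames(obs)
            f = fit(
                ExcretionModelSpec(),
                PriorSet(),
                ds,
                chains=2,
                iter=700,
                warmup=350,
                seed=seed + 3,
            )
            j = f.spec.location_terms.index("ln_mass")
            b = f.draws.stacked("beta")[:, j]
            return abs(b.mean() - truth.excretion.beta["ln_mass"]), b.std()

    # average over three replicates per size to damp seed noise
        small = np.mean([one(50, s)[0] for s in (10, 20, 30)])
        large = np.mean([one(500, s)[0] for s in (40, 50, 60)])
        assert large < small


class TestDiagnostics:
    def test_r2_approaches_one_without_noise(self):
        cfg = SimulationConfig(n_families=6, species_per_family=2, n_obs=60)
        truth = default_truth(cfg, seed=31)
        exc = replace(
            truth.excretion, gamma_sigma=np.log(0.05), beta_sigma=0.0
        )
        skel = simulate_community(cfg, seed=32)
        obs = simulate_excretion(skel, exc, seed=33)
        ds = Dataset.from_frames(obs)
        f = fit(
            ExcretionModelSpec(),
            PriorSet(),
            ds,
            chains=2,
            iter=700,
            warmup=350,
            seed=34,
        )
        assert bayes_r2(f)["mean"] > 0.99

    def test_r2_near_zero_for_pure_noise(self):
        cfg = SimulationConfig(n_families=6, species_per_family=2, n_obs=60)
        truth = default_truth(cfg, seed=41)
        exc = replace(
            truth.excretion,
            beta={k: 0.0 for k in truth.excretion.beta},
            tau_u=0.0,
            u=tuple([0.0] * 6),
        )
        skel = simulate_community(cfg, seed=42)
        obs = simulate_excretion(skel, exc, seed=43)
        ds = Dataset.from_frames(obs)
        f = fit(
            ExcretionModelSpec(),
            PriorSet(),
            ds,
            chains=2,
            iter=700,
            warmup=350,
            seed=44,
        )
        # overfit wiggle with 4 free slopes keeps this above zero; "near
        # zero" relative to the ~0.85 of structured data
        assert bayes_r2(f)["mean"] < 0.3

    def test_full_level_interval_covers_everything(self, excretion_fit):
        assert ppc_coverage(excretion_fit, level=1.0) == 1.0

    def test_levene_flat_when_spreads_equal(self):
        cfg = SimulationConfig(n_families=6, species_per_family=2, n_obs=80)
        truth = default_truth(cfg, seed=51)
        exc = replace(truth.excretion, beta_sigma=0.0)
        skel = simulate_community(cfg, seed=52)
        obs = simulate_excretion(skel, exc, seed=53)
        ds = Dataset.from_frames(obs)
        f = fit(
            ExcretionModelSpec(scale_terms=()),
            PriorSet(),
            ds,
            chains=2,
            iter=700,
            warmup=350,
            seed=54,
        )
        out = levene_method_test(f)
        assert out["p"] > 0.01

    def test_levene_matches_bruteforce_anova(self, excretion_fit):
        # oracle: one-way ANOVA on mean-centred absolute residuals
        out = levene_method_test(excretion_fit)
        eta, _, _ = excretion_fit.location_scale_df()
        resid = excretion_fit.model.lny - eta.mean(axis=0)
        groups = [
            resid[excretion_fit.model.method == v] for v in (0.0, 1.0)
        ]
        z = [np.abs(g - g.mean()) for g in groups]
        zall = np.concatenate(z)
        k, n = 2, zall.size
        ssb = sum(len(g) * (g.mean() - zall.mean()) ** 2 for g in z)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in z)
        F = (ssb / (k - 1)) / (ssw / (n - k))
        assert out["F"] == pytest.approx(F, rel=1e-10)
        assert out["df2"] == n - 2

    def test_pointwise_sums_to_total_likelihood(self, excretion_fit, rng):
        ll = pointwise_log_likelihood(excretion_fit)
        p = excretion_fit.stacked_params()
        ds_frame = excretion_fit.model
        for s in rng.choice(ll.shape[0], size=5, replace=False):
            params = {
                "gamma0": p["gamma0"][s],
                "beta": p["beta"][s],
                "u": p["u"][s],
                "gamma_sigma": p["gamma_sigma"][s],
                "beta_sigma": p["beta_sigma"][s],
                "nu": p["nu"][s],
            }
            eta = (
                params["gamma0"]
                + ds_frame.natural_X() @ params["beta"]
                + params["u"][ds_frame.fam_idx]
            )
            sig = np.exp(
                params["gamma_sigma"] + params["beta_sigma"] * ds_frame.method
            )
            want = float(
                np.sum(
                    ds_frame.w
                    * stats.t.logpdf(
                        ds_frame.lny, params["nu"], loc=eta, scale=sig
                    )
                )
            )
            assert ll[s].sum() == pytest.approx(want, abs=1e-8)
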