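"""Hurdle-lognormal model: density oracles, joint density, fit behaviour."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import integrate, stats
from scipy.special import expit

from ichthyocarb.data import POLYMORPHS, DomainError
from ichthyocarb.mineralogy import (
    CovarianceSpec,
    HurdleModelSpec,
    _BoundHurdleModel,
    _responses_from,
    excretion_probability,
    family_correlation_matrix,
    hurdle_lognormal_logpdf,
    joint_log_density,
    marginal_expected_rate,
    mvn_logpdf,
    reduced_spec_from_fit,
)
from ichthyocarb.sampler import numerical_gradient
from ichthyocarb.synthetic import (
    POSITIVE_TERMS,
    SimulationConfig,
    default_truth,
    simulate_community,
    simulate_dataset,
    simulate_polymorphs,
)


class TestHurdleDensity:
    def test_zero_branch_is_log_theta(self):
        assert hurdle_lognormal_logpdf(0.0, 0.3, 1.0, 0.5) == pytest.approx(
            np.log(0.3)
        )

    def test_positive_branch_matches_scipy_lognormal(self, rng):
        for _ in range(20):
            y = float(rng.uniform(0.01, 20))
            theta = float(rng.uniform(0.05, 0.95))
            mu = float(rng.normal(0, 1))
            sigma = float(rng.uniform(0.2, 2))
            got = hurdle_lognormal_logpdf(y, theta, mu, sigma)
            want = np.log1p(-theta) + stats.lognorm.logpdf(
                y, sigma, scale=np.exp(mu)
            )
            assert got == pytest.approx(float(want), abs=1e-12)

    @pytest.mark.parametrize("theta", [0.2, 0.7])
    def test_density_integrates_to_one(self, theta):
        mu, sigma = 0.3, 0.8
        integral, _ = integrate.quad(
            lambda y: np.exp(hurdle_lognormal_logpdf(y, theta, mu, sigma)),
            1e-12,
            np.inf,
        )
        assert theta + integral == pytest.approx(1.0, abs=1e-6)

    def test_negative_y_rejected(self):
        with pytest.raises(DomainError):
            hurdle_lognormal_logpdf(-0.1, 0.5, 0.0, 1.0)


class TestJointDensity:
    def _point(self, ds, rng, K, corr=None):
        if corr is None:
            corr = np.eye(10)
        tau = rng.uniform(0.2, 1.0, size=10)
        return {
            "intercept_pos": rng.normal(0, 1, 5),
            "beta_pos": {
                t: rng.normal(0, 0.3, 5) for t in POSITIVE_TERMS
            },
            "intercept_hurdle": rng.normal(0, 1, 5),
            "beta_hurdle": {
                "ln_ril": rng.normal(0, 0.3, 5),
                "temperature": rng.normal(0, 0.1, 5),
            },
            "gamma_sigma": rng.normal(-0.3, 0.2, 5),
            "beta_sigma": rng.normal(0.3, 0.2, 5),
            "u": rng.normal(0, 0.3, (K, 5)),
            "v": rng.normal(0, 0.5, (K, 5)),
            "tau": tau,
            "corr": corr,
        }

    def test_identity_correlation_reduces_to_independent_hurdles(
        self, small_community, rng
    ):
        # with rho = I the joint density equals five univariate hurdle
        # models plus independent normal effect densities
        _, _, raw = small_community
        spec = HurdleModelSpec(
            positive_terms={m: POSITIVE_TERMS for m in POLYMORPHS}
        )
        frame, Y = _responses_from(raw, spec)
        m = _BoundHurdleModel(spec, frame, Y, CovarianceSpec(), standardise=False)
        K = m.K
        p = self._point(raw, rng, K)
        got = joint_log_density(p, raw, spec)

        want = 0.0
        for m_i, poly in enumerate(POLYMORPHS):
            bp = np.array([p["beta_pos"][t][m_i] for t in POSITIVE_TERMS])
            mu = p["intercept_pos"][m_i] + m.Xp @ bp + p["u"][m.fam_idx, m_i]
            bh = np.array(
                [p["beta_hurdle"][t][m_i] for t in spec.hurdle_terms]
            )
            s = (
                p["intercept_hurdle"][m_i]
                + m.Xh @ bh
                + p["v"][m.fam_idx, m_i]
            )
            sig = np.exp(
                p["gamma_sigma"][m_i] + p["beta_sigma"][m_i] * m.method
            )
            y = m.Y[:, m_i]
            theta = expit(s)
            dens = np.where(
                y == 0,
                np.log(theta),
                np.log1p(-theta)
                + stats.norm.logpdf(
                    np.log(np.where(y > 0, y, 1.0)), mu, sig
                )
                - np.log(np.where(y > 0, y, 1.0)),
            )
            want += float(np.sum(m.w * dens))
            want += float(
                stats.norm.logpdf(p["u"][:, m_i], 0, p["tau"][m_i]).sum()
            )
            want += float(
                stats.norm.logpdf(
                    p["v"][:, m_i], 0, p["tau"][5 + m_i]
                ).sum()
            )
        assert got == pytest.approx(want, abs=1e-8)

    def test_effect_density_matches_scipy_mvn(self, rng):
        for _ in range(10):
            A = rng.standard_normal((10, 10))
            cov = A @ A.T + 10 * np.eye(10)
            x = rng.standard_normal(10)
            got = mvn_logpdf(x, cov)
            want = stats.multivariate_normal.logpdf(
                x, mean=np.zeros(10), cov=cov
            )
            assert got == pytest.approx(float(want), abs=1e-8)

    def test_non_psd_covariance_rejected(self, rng):
        cov = -np.eye(10)
        with pytest.raises(DomainError):
            mvn_logpdf(rng.standard_normal(10), cov)


class TestGradients:
    def test_posterior_gradient_matches_finite_differences(
        self, small_community, rng
    ):
        _, _, raw = small_community
        spec = HurdleModelSpec()
        frame, Y = _responses_from(raw, spec)
        m = _BoundHurdleModel(spec, frame, Y, CovarianceSpec())
        q = m.initial_position(rng) + 0.2 * rng.standard_normal(m.dim)
        _, g = m.logpost_and_grad(q)
        gn = numerical_gradient(lambda x: m.logpost_and_grad(x)[0], q, 1e-5)
        np.testing.assert_allclose(g, gn, rtol=1e-5, atol=1e-6)

    def test_masked_terms_are_absent_from_the_model(self, small_community):
        # the reduced spec carries no parameter (hence no gradient entry)
        # for LMC RIL/AR/temperature or MHC temperature
        _, _, raw = small_community
        spec = HurdleModelSpec()
        frame, Y = _responses_from(raw, spec)
        m = _BoundHurdleModel(spec, frame, Y, CovarianceSpec())
        full = _BoundHurdleModel(
            HurdleModelSpec(
                positive_terms={p: POSITIVE_TERMS for p in POLYMORPHS}
            ),
            frame,
            Y,
            CovarianceSpec(),
        )
        assert full.dim - m.dim == 4  # 3 LMC terms + 1 MHC term


class TestFit:
    def test_mass_exponents_recovered(self, community, mineralogy_fit):
        # joint check over five exponents: 99% intervals keep the family-
        # wise miss rate near 5%
        _, truth, _ = community
        for poly, t_val in zip(
            POLYMORPHS, truth.mineralogy.beta_pos["ln_mass"]
        ):
            d = mineralogy_fit.draws.stacked(f"beta_pos_{poly}_ln_mass")
            lo, hi = np.quantile(d, [0.005, 0.995])
            assert lo < t_val < hi, poly

    def test_convergence_diagnostics_reported(self, mineralogy_fit):
        s = mineralogy_fit.summary()
        assert np.isfinite(s["rhat"]).all()
        assert (s["rhat"] < 1.06).all()
        assert mineralogy_fit.draws.divergences == 0

    def test_predicted_zero_fractions_match_observed(
        self, community, mineralogy_fit
    ):
        # posterior-predictive zero share per polymorph within 3 binomial
        # SEs of the observed share
        _, _, raw = community
        m = mineralogy_fit.model
        p = mineralogy_fit.stacked_params()
        n = m.n
        for m_i, poly in enumerate(POLYMORPHS):
            s = (
                p["intercept_hurdle"][:, m_i][:, None]
                + p[f"beta_hurdle_{poly}_ln_ril"][:, None]
                * np.log(raw["ril"].to_numpy())[None, :]
                + p[f"beta_hurdle_{poly}_temperature"][:, None]
                * raw["temperature_C"].to_numpy()[None, :]
                + p["v"][:, m.fam_idx, m_i]
            )
            pred_zero = expit(s).mean()
            obs_zero = (raw[f"rate_{poly}"] == 0).mean()
            se = np.sqrt(obs_zero * (1 - obs_zero) / n)
            assert abs(pred_zero - obs_zero) < 3 * se, poly

    def test_all_zero_response_flagged(self, small_community):
        _, _, raw = small_community
        bad = raw.copy()
        bad["rate_LMC"] = 0.0
        spec = HurdleModelSpec()
        frame, Y = _responses_from(bad, spec)
        with pytest.warns(UserWarning, match="all-zero"):
            _BoundHurdleModel(spec, frame, Y, CovarianceSpec())


class TestDerived:
    def test_probability_complements_the_hurdle_logit(self, mineralogy_fit):
        # at RIL = 1 and T = 0 the linear predictor collapses to the
        # intercept, so P(excrete) = 1 - logit^-1(intercept) draw by draw;
        # a zero intercept would give exactly 1/2
        f = mineralogy_fit
        p = f.stacked_params()
        probs = excretion_probability(f, None, ril=1.0, temperature=0.0)
        for m_i in range(5):
            s0 = p["intercept_hurdle"][:, m_i]
            np.testing.assert_allclose(
                probs[:, m_i], 1 - expit(s0), atol=1e-12
            )
        assert np.allclose(1 - expit(0.0), 0.5)

    def test_probability_monotone_in_temperature(self, mineralogy_fit):
        f = mineralogy_fit
        p = f.stacked_params()
        lo = excretion_probability(f, None, ril=1.0, temperature=24.0)
        hi = excretion_probability(f, None, ril=1.0, temperature=30.0)
        for m_i, poly in enumerate(POLYMORPHS):
            slope = p[f"beta_hurdle_{poly}_temperature"]
            # P(excrete) moves against the P(zero) slope, draw by draw
            expected_sign = np.sign(-slope)
            diff = hi[:, m_i] - lo[:, m_i]
            agree = np.sign(diff) == expected_sign
            assert agree[np.abs(slope) > 1e-8].all()

    def test_marginal_curve_shapes_follow_hurdle_signs(
        self, community, mineralogy_fit
    ):
        _, truth, _ = community
        grid = np.geomspace(0.33, 7.56, 60)
        curves = marginal_expected_rate(mineralogy_fit, grid)
        # ACMC: excretion probability flat/up but rate declines with RIL ->
        # monotone decreasing; HMC: opposite-sign parts -> interior maximum
        acmc = curves["ACMC"]["median"].to_numpy()
        assert acmc[0] > acmc[-1]
        hmc = curves["HMC"]["median"].to_numpy()
        peak = hmc.argmax()
        assert 0 < peak < len(grid) - 1

    def test_interior_maximum_from_opposing_parts(self):
        # calculus check on a known truth: p(excrete) rising in RIL while
        # the positive-part mean falls yields a hump; the posterior median
        # curve must peak strictly inside the grid
        theta = lambda r: expit(1.2 - 1.4 * np.log(r))  # P(zero) falls
        mean_rate = lambda r: np.exp(0.5 - 0.9 * np.log(r))
        grid = np.geomspace(0.33, 7.56, 200)
        curve = (1 - theta(grid)) * mean_rate(grid)
        peak = curve.argmax()
        assert 0 < peak < len(grid) - 1
        # exactly one stationary point of log curve in log-RIL
        lg = np.log(grid)
        d = np.gradient(np.log(curve), lg)
        root_idx = np.where(np.diff(np.sign(d)))[0]
        assert len(root_idx) == 1

    def test_correlation_summaries_valid(self, mineralogy_fit):
        out = family_correlation_matrix(mineralogy_fit)
        med = out["median"]
        np.testing.assert_allclose(np.diag(med), 1.0, atol=1e-12)
        np.testing.assert_allclose(med, med.T, atol=1e-12)
        assert (out["q2.5"] <= out["median"] + 1e-12).all()
        C = mineralogy_fit.corr_draws()
        eig = np.linalg.eigvalsh(C)
        assert eig.min() > -1e-8  # every draw PSD by construction

    def test_hurdle_block_correlation_signs_recovered(
        self, community, mineralogy_fit
    ):
        # strong generating structure: HMC vs MHC hurdle effects negative,
        # aragonite vs LMC positive
        _, truth, _ = community
        C_true = np.asarray(truth.mineralogy.corr)
        out = family_correlation_matrix(mineralogy_fit)
        med = out["hurdle_block_median"]
        i = {m: j for j, m in enumerate(POLYMORPHS)}
        assert np.sign(med[i["HMC"], i["MHC"]]) == np.sign(
            C_true[5 + i["HMC"], 5 + i["MHC"]]
        )
        assert np.sign(med[i["aragonite"], i["LMC"]]) == np.sign(
            C_true[5 + i["aragonite"], 5 + i["LMC"]]
        )

    def test_reduction_rule_prunes_weak_effects(self, mineralogy_fit):
        spec = reduced_spec_from_fit(mineralogy_fit)
        for poly in POLYMORPHS:
            assert "ln_mass" in spec.positive_terms[poly]
            assert set(spec.positive_terms[poly]) <= set(POSITIVE_TERMS)
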