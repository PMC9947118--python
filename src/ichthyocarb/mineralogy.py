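"""Multivariate hurdle-lognormal model of the five polymorph excretion rates.

Each polymorph rate is zero with a logistic hurdle probability and
lognormal when positive.  The hurdle logit depends on log RIL, temperature
and a family deviation; the positive part gets the same trait/environment
predictors as the total-excretion model (subject to per-response masks)
and its own family deviation; the lognormal scale varies by titration
method per response.  The ten family intercepts (five hurdle, five
positive) are jointly multivariate normal with per-component scales under
half-normal priors and an LKJ(1) prior on their correlation, so the model
captures which polymorphs families tend to co-produce.

The sampler works on an unconstrained vector — non-centred family effects
through the Cholesky factor of the correlation (canonical partial
correlation transform), log scales, log taus — with fully analytic
gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logit

from .data import (
    POLYMORPHS,
    Dataset,
    DomainError,
    build_design,
    polymorph_response_matrix,
)
from .posterior import PosteriorDraws
from .sampler import (
    chol_corr_backward,
    chol_corr_forward,
    lkj_chol_logprior_grad,
    lkj_chol_logprior_unconstrained,
    n_corr_params,
    sample_hmc,
)
from .synthetic import HURDLE_TERMS, POSITIVE_TERMS, RATE_COLUMNS

LN_2PI = float(np.log(2.0 * np.pi))

#: Positive-part fixed effects retained in the reduced (default) model:
#: effects whose estimation error exceeded the estimate are dropped —
#: RIL, AR and temperature for LMC, and temperature for MHC.
DEFAULT_POSITIVE_MASKS: dict[str, tuple[str, ...]] = {
    "LMC": ("ln_mass",),
    "HMC": POSITIVE_TERMS,
    "aragonite": POSITIVE_TERMS,
    "MHC": ("ln_mass", "ln_ril", "sqrt_ar"),
    "ACMC": POSITIVE_TERMS,
}


@dataclass(frozen=True)
class HurdleModelSpec:
    """Structure of the multivariate hurdle model."""

    responses: tuple[str, ...] = POLYMORPHS
    positive_terms: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_POSITIVE_MASKS)
    )
    hurdle_terms: tuple[str, ...] = HURDLE_TERMS
    scale_terms: tuple[str, ...] = ("titration_method",)
    group_factor: str | None = "family"
    weights: bool = True

    def __post_init__(self) -> None:
        if tuple(self.responses) != POLYMORPHS:
            raise DomainError(f"responses must be {POLYMORPHS}")
        for m in self.responses:
            terms = self.positive_terms.get(m, ())
            if not set(terms) <= set(POSITIVE_TERMS):
                raise DomainError(
                    f"positive terms for {m} must be a subset of "
                    f"{POSITIVE_TERMS}"
                )


@dataclass(frozen=True)
class CovarianceSpec:
    """Priors on the 2m family-effect scales and their correlation."""

    tau_scale: float = 5.0  # half-normal SD prior on each tau
    lkj_eta: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_scale <= 0 or self.lkj_eta <= 0:
            raise DomainError("covariance hyperparameters must be positive")


def hurdle_lognormal_logpdf(
    y: float | np.ndarray,
    theta: float | np.ndarray,
    mu: float | np.ndarray,
    sigma: float | np.ndarray,
) -> float | np.ndarray:
    """Log density of the hurdle-lognormal.

    ``ln theta`` at y = 0 and ``ln(1 - theta)`` plus the lognormal log
    density at y > 0.  The truncation denominator of the positive branch is
    identically 1 because the lognormal places no mass at zero.
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise DomainError("y must be non-negative")
    theta = np.asarray(theta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0).any():
        raise DomainError("sigma must be positive")
    if ((theta <= 0) & (y == 0)).any() or ((theta >= 1) & (y > 0)).any():
        raise DomainError("theta must be interior for the observed branch")
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = (
            np.log1p(-theta)
            - np.log(np.where(y > 0, y, 1.0))
            - np.log(sigma)
            - 0.5 * LN_2PI
            - 0.5 * ((np.log(np.where(y > 0, y, 1.0)) - mu) / sigma) ** 2
        )
    out = np.where(y == 0, np.log(np.where(theta > 0, theta, 1.0)), pos)
    return float(out) if out.ndim == 0 else out


def mvn_logpdf(x: np.ndarray, cov: np.ndarray) -> float:
    """Zero-mean multivariate normal log density via Cholesky."""
    cov = np.asarray(cov, dtype=float)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise DomainError("covariance must be positive definite") from e
    z = np.linalg.solve(L, np.asarray(x, dtype=float))
    return float(
        -0.5 * z @ z
        - np.log(np.diag(L)).sum()
        - 0.5 * cov.shape[0] * LN_2PI
    )


# ---------------------------------------------------------------------------
# Bound model
# ---------------------------------------------------------------------------


class _BoundHurdleModel:
    """Hurdle model bound to data: design matrices, packing layout, and the
    weighted log-posterior with analytic gradients."""

    def __init__(
        self,
        spec: HurdleModelSpec,
        frame: pd.DataFrame,
        Y: np.ndarray,
        cov: CovarianceSpec,
        standardise: bool = True,
    ):
        self.spec, self.cov = spec, cov
        self.Y = np.asarray(Y, dtype=float)
        if self.Y.shape != (len(frame), 5):
            raise DomainError("response matrix must be (n_obs, 5)")
        if (self.Y < 0).any():
            raise DomainError("polymorph rates must be non-negative")
        self.n = len(frame)
        self.w = (
            frame["weight"].to_numpy(dtype=float)
            if spec.weights
            else np.ones(self.n)
        )
        Xp, self.pos_info = build_design(
            frame, POSITIVE_TERMS, standardise=standardise
        )
        Xh, self.hur_info = build_design(
            frame, spec.hurdle_terms, standardise=standardise
        )
        self.Xp, self.Xh = Xp.to_numpy(), Xh.to_numpy()
        self.method = (
            frame["titration_method"].to_numpy() == "single_endpoint"
        ).astype(float)
        self.has_scale = bool(spec.scale_terms)
        fams = sorted(frame["family"].unique())
        self.families = fams
        self.K = len(fams)
        self.fam_idx = frame["family"].map(
            {f: i for i, f in enumerate(fams)}
        ).to_numpy()
        self.masks = [
            tuple(POSITIVE_TERMS.index(t) for t in spec.positive_terms[m])
            for m in POLYMORPHS
        ]
        self.zero = self.Y == 0.0
        self.lnY = np.where(self.zero, 0.0, np.log(np.where(self.zero, 1.0, self.Y)))
        for m_i, m in enumerate(POLYMORPHS):
            nz = int(self.zero[:, m_i].sum())
            if nz == 0 or nz == self.n:
                warnings.warn(
                    f"polymorph {m} is all-{'zero' if nz else 'positive'}: "
                    "its hurdle intercept is identified by the prior only",
                    stacklevel=2,
                )

        # packed layout, per response: c, beta(mask), a, b(2), gs, [bs]
        self.block_sizes = [
            1 + len(mk) + 1 + 2 + 1 + int(self.has_scale)
            for mk in self.masks
        ]
        self.n_x = n_corr_params(10)
        self.dim = sum(self.block_sizes) + 10 + self.n_x + self.K * 10
        self.i_tau = sum(self.block_sizes)
        self.i_x = self.i_tau + 10
        self.i_z = self.i_x + self.n_x

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        q = 0.05 * rng.standard_normal(self.dim)
        off = 0
        for m_i, mk in enumerate(self.masks):
            pos_vals = self.lnY[~self.zero[:, m_i], m_i]
            q[off] += float(pos_vals.mean()) if pos_vals.size else 0.0
            ia = off + 1 + len(mk)
            zf = float(self.zero[:, m_i].mean())
            q[ia] += float(logit(np.clip(zf, 0.05, 0.95)))
            igs = ia + 3
            if pos_vals.size > 2:
                q[igs] += float(np.log(max(pos_vals.std(), 0.2)))
            off += self.block_sizes[m_i]
        q[self.i_tau : self.i_tau + 10] += np.log(0.5)
        return q

    def logpost_and_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        if np.abs(q).max() > 100.0:
            return -np.inf, np.zeros_like(q)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            lp, grad = self._logpost_and_grad(q)
        if not (np.isfinite(lp) and np.all(np.isfinite(grad))):
            return -np.inf, np.zeros_like(q)
        return lp, grad

    def _logpost_and_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        cov = self.cov
        grad = np.zeros_like(q)
        ltau = q[self.i_tau : self.i_tau + 10]
        tau = np.exp(ltau)
        x_corr = q[self.i_x : self.i_x + self.n_x]
        Lc, z_cpc = chol_corr_forward(x_corr, 10)
        Z = q[self.i_z :].reshape(self.K, 10)
        ZLt = Z @ Lc.T  # (K, 10): L z_k rows
        E = tau[None, :] * ZLt  # family effects u (cols 0-4), v (cols 5-9)

        lp = 0.0
        G = np.zeros((self.K, 10))  # d lp / d E
        off = 0
        for m_i, mk in enumerate(self.masks):
            bs_len = self.block_sizes[m_i]
            c = q[off]
            beta = q[off + 1 : off + 1 + len(mk)]
            ia = off + 1 + len(mk)
            a = q[ia]
            b = q[ia + 1 : ia + 3]
            gs = q[ia + 3]
            bs = q[ia + 4] if self.has_scale else 0.0

            zero = self.zero[:, m_i]
            s = a + self.Xh @ b + E[self.fam_idx, 5 + m_i]
            theta = expit(s)
            lp += float(
                np.sum(
                    self.w * np.where(zero, log_expit(s), log_expit(-s))
                )
            )
            ds = self.w * np.where(zero, 1.0 - theta, -theta)
            grad[ia] += ds.sum()
            grad[ia + 1 : ia + 3] += self.Xh.T @ ds
            np.add.at(G[:, 5 + m_i], self.fam_idx, ds)

            pos = ~zero
            if pos.any():
                Xm = self.Xp[np.ix_(pos, mk)]
                lny = self.lnY[pos, m_i]
                wp = self.w[pos]
                lns = gs + bs * self.method[pos]
                sig = np.exp(lns)
                mu = c + Xm @ beta + E[self.fam_idx[pos], m_i]
                r = (lny - mu) / sig
                lp += float(
                    np.sum(
                        wp * (-lny - lns - 0.5 * LN_2PI - 0.5 * r * r)
                    )
                )
                de = wp * r / sig
                dls = wp * (r * r - 1.0)
                grad[off] += de.sum()
                grad[off + 1 : off + 1 + len(mk)] += Xm.T @ de
                grad[ia + 3] += dls.sum()
                if self.has_scale:
                    grad[ia + 4] += float(np.sum(dls * self.method[pos]))
                np.add.at(G[:, m_i], self.fam_idx[pos], de)

            # fixed-effect priors: N(0,5) except logistic(0,1) on a
            lp += float(
                -0.5 * (c**2 + np.sum(beta**2) + np.sum(b**2)) / 25.0
            )
            grad[off] += -c / 25.0
            grad[off + 1 : off + 1 + len(mk)] += -beta / 25.0
            grad[ia + 1 : ia + 3] += -b / 25.0
            lp += float(a + 2.0 * log_expit(-a))  # logistic(0, 1)
            grad[ia] += 1.0 - 2.0 * expit(a)
            # gs ~ t(3, 0, 2.5); bs ~ N(0, 5)
            lp += float(-2.0 * np.log1p(gs**2 / 18.75))
            grad[ia + 3] += -4.0 * gs / (18.75 + gs**2)
            if self.has_scale:
                lp += -0.5 * bs**2 / 25.0
                grad[ia + 4] += -bs / 25.0
            off += bs_len

        # family-effect backprop: E = tau * (Z Lc^T)
        grad[self.i_z :] += ((G * tau[None, :]) @ Lc).ravel()
        grad[self.i_tau : self.i_tau + 10] += tau * np.sum(G * ZLt, axis=0)
        M = tau[:, None] * (G.T @ Z)  # d lp / d Lc
        grad[self.i_x : self.i_x + self.n_x] += chol_corr_backward(
            M, Lc, z_cpc
        )

        # priors: z ~ N(0,1); tau ~ half-N(0, tau_scale) with log Jacobian;
        # correlation ~ LKJ(eta) on the unconstrained scale
        lp += float(np.sum(-0.5 * Z**2))
        grad[self.i_z :] += -Z.ravel()
        lp += float(
            np.sum(-0.5 * tau**2 / cov.tau_scale**2 + ltau)
        )
        grad[self.i_tau : self.i_tau + 10] += (
            -(tau**2) / cov.tau_scale**2 + 1.0
        )
        lp += lkj_chol_logprior_unconstrained(x_corr, 10, cov.lkj_eta)
        grad[self.i_x : self.i_x + self.n_x] += lkj_chol_logprior_grad(
            x_corr, 10, cov.lkj_eta
        )
        return lp, grad


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def _responses_from(data, spec: HurdleModelSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Accept a Dataset (totals x species profiles) or a raw frame with
    rate_* columns."""
    if isinstance(data, Dataset):
        return data.to_frame(), polymorph_response_matrix(data)
    df = data
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"frame lacks polymorph rate columns: {missing}")
    return df, df[list(RATE_COLUMNS)].to_numpy(dtype=float)


def joint_log_density(
    params: Mapping[str, object],
    data,
    spec: HurdleModelSpec = HurdleModelSpec(),
    cov: CovarianceSpec = CovarianceSpec(),
) -> float:
    """Joint log density at an explicit (centred) parameter point.

    Sums the weighted hurdle-lognormal log densities over observations and
    responses plus the 2m-dimensional multivariate normal log density of
    the stacked family effects.  ``params`` uses natural-scale entries:
    ``intercept_pos`` (5,), ``beta_pos`` {term: (5,)} (masked entries
    ignored), ``intercept_hurdle`` (5,), ``beta_hurdle`` {term: (5,)},
    ``gamma_sigma`` (5,), ``beta_sigma`` (5,), ``u`` (K,5), ``v`` (K,5),
    ``tau`` (10,), ``corr`` (10,10).  Used as the mathematical reference
    for the sampler's non-centred internal form.
    """
    frame, Y = _responses_from(data, spec)
    m = _BoundHurdleModel(spec, frame, Y, cov, standardise=False)
    u = np.asarray(params["u"], dtype=float)
    v = np.asarray(params["v"], dtype=float)
    tau = np.asarray(params["tau"], dtype=float)
    corr = np.asarray(params["corr"], dtype=float)
    cpos = np.asarray(params["intercept_pos"], dtype=float)
    ahur = np.asarray(params["intercept_hurdle"], dtype=float)
    gsig = np.asarray(params["gamma_sigma"], dtype=float)
    bsig = np.asarray(params.get("beta_sigma", np.zeros(5)), dtype=float)

    lp = 0.0
    for m_i, poly in enumerate(POLYMORPHS):
        terms = spec.positive_terms[poly]
        bp = np.array(
            [params["beta_pos"][t][m_i] for t in terms], dtype=float
        )
        cols = [POSITIVE_TERMS.index(t) for t in terms]
        mu = cpos[m_i] + m.Xp[:, cols] @ bp + u[m.fam_idx, m_i]
        bh = np.array(
            [params["beta_hurdle"][t][m_i] for t in spec.hurdle_terms],
            dtype=float,
        )
        s = ahur[m_i] + m.Xh @ bh + v[m.fam_idx, m_i]
        sigma = np.exp(gsig[m_i] + bsig[m_i] * m.method)
        lp += float(
            np.sum(
                m.w
                * hurdle_lognormal_logpdf(m.Y[:, m_i], expit(s), mu, sigma)
            )
        )
    Sigma = np.outer(tau, tau) * corr
    for k in range(m.K):
        lp += mvn_logpdf(np.concatenate([u[k], v[k]]), Sigma)
    return lp


@dataclass
class MineralogyFit:
    """Fitted multivariate hurdle model with natural-scale draws."""

    spec: HurdleModelSpec
    cov: CovarianceSpec
    draws: PosteriorDraws
    model: _BoundHurdleModel = field(repr=False)

    def corr_draws(self) -> np.ndarray:
        """(stacked draw, 10, 10) correlation matrices."""
        tri = self.draws.stacked("corr_tri")
        S = tri.shape[0]
        rows, cols = np.tril_indices(10, k=-1)
        C = np.zeros((S, 10, 10))
        C[:, rows, cols] = tri
        C += np.transpose(C, (0, 2, 1))
        C[:, np.arange(10), np.arange(10)] = 1.0
        return C

    def stacked_params(self) -> dict[str, np.ndarray]:
        return {k: self.draws.stacked(k) for k in self.draws.params}

    def summary(self) -> pd.DataFrame:
        return self.draws.summary()


def fit_mineralogy(
    data,
    spec: HurdleModelSpec = HurdleModelSpec(),
    cov: CovarianceSpec = CovarianceSpec(),
    chains: int = 3,
    iter: int = 4000,
    warmup: int = 2000,
    seed: int = 0,
    max_leapfrog: int = 64,
) -> MineralogyFit:
    """Fit the multivariate hurdle model by adaptive HMC.

    ``data`` is either a :class:`Dataset` (polymorph rates reconstructed
    from totals and species profiles) or a frame already carrying
    ``rate_*`` columns.  ``iter`` counts total iterations per chain
    including warm-up.
    """
    if iter <= warmup:
        raise DomainError("iter must exceed warmup")
    frame, Y = _responses_from(data, spec)
    m = _BoundHurdleModel(spec, frame, Y, cov, standardise=True)
    res = sample_hmc(
        m.logpost_and_grad,
        m.initial_position,
        n_chains=chains,
        n_warmup=warmup,
        n_draws=iter - warmup,
        seed=seed,
        max_leapfrog=max_leapfrog,
    )
    pos = res.positions
    nc, nd, _ = pos.shape
    p_mean, p_sd = m.pos_info.means, m.pos_info.sds
    h_mean, h_sd = m.hur_info.means, m.hur_info.sds

    params: dict[str, np.ndarray] = {
        "intercept_pos": np.empty((nc, nd, 5)),
        "intercept_hurdle": np.empty((nc, nd, 5)),
        "gamma_sigma": np.empty((nc, nd, 5)),
    }
    if m.has_scale:
        params["beta_sigma"] = np.empty((nc, nd, 5))
    off = 0
    for m_i, poly in enumerate(POLYMORPHS):
        mk = m.masks[m_i]
        c = pos[:, :, off]
        ia = off + 1 + len(mk)
        a = pos[:, :, ia]
        b_std = pos[:, :, ia + 1 : ia + 3]
        b_nat = b_std / h_sd
        params["intercept_hurdle"][:, :, m_i] = a - b_nat @ h_mean
        for t_j, term in enumerate(m.spec.hurdle_terms):
            params[f"beta_hurdle_{poly}_{term}"] = b_nat[:, :, t_j]
        beta_std = pos[:, :, off + 1 : off + 1 + len(mk)]
        beta_nat = beta_std / p_sd[list(mk)]
        params["intercept_pos"][:, :, m_i] = c - beta_nat @ p_mean[list(mk)]
        for t_j, term in enumerate(m.spec.positive_terms[poly]):
            params[f"beta_pos_{poly}_{term}"] = beta_nat[:, :, t_j]
        params["gamma_sigma"][:, :, m_i] = pos[:, :, ia + 3]
        if m.has_scale:
            params["beta_sigma"][:, :, m_i] = pos[:, :, ia + 4]
        off += m.block_sizes[m_i]

    tau = np.exp(pos[:, :, m.i_tau : m.i_tau + 10])
    params["tau"] = tau
    x_corr = pos[:, :, m.i_x : m.i_x + m.n_x]
    rows10, cols10 = np.tril_indices(10, k=-1)
    tri = np.empty((nc, nd, m.n_x))
    U = np.empty((nc, nd, m.K, 5))
    V = np.empty((nc, nd, m.K, 5))
    for ci in range(nc):
        for di in range(nd):
            Lc, _ = chol_corr_forward(x_corr[ci, di], 10)
            C = Lc @ Lc.T
            tri[ci, di] = C[rows10, cols10]
            Z = pos[ci, di, m.i_z :].reshape(m.K, 10)
            E = tau[ci, di][None, :] * (Z @ Lc.T)
            U[ci, di] = E[:, :5]
            V[ci, di] = E[:, 5:]
    params["corr_tri"] = tri
    params["u"] = U
    params["v"] = V

    draws = PosteriorDraws(
        params=params,
        divergences=res.divergences,
        accept_rate=res.accept_rate,
    )
    return MineralogyFit(spec=spec, cov=cov, draws=draws, model=m)


def excretion_probability(
    fit: MineralogyFit,
    family: str | None,
    ril: float,
    temperature: float,
) -> np.ndarray:
    """(stacked draw, 5) posterior probabilities of excreting each polymorph.

    The hurdle models the probability of a zero, so the returned values are
    its complement.  ``family=None`` gives the population-average fish
    (family effect zero).
    """
    if ril <= 0:
        raise DomainError("ril must be positive")
    p = fit.stacked_params()
    S = p["intercept_hurdle"].shape[0]
    out = np.empty((S, 5))
    for m_i, poly in enumerate(POLYMORPHS):
        s = (
            p["intercept_hurdle"][:, m_i]
            + p[f"beta_hurdle_{poly}_ln_ril"] * np.log(ril)
            + p[f"beta_hurdle_{poly}_temperature"] * temperature
        )
        if family is not None:
            k = fit.model.families.index(family)
            s = s + p["v"][:, k, m_i]
        out[:, m_i] = 1.0 - expit(s)
    return out


def marginal_expected_rate(
    fit: MineralogyFit,
    ril_grid: Sequence[float],
    reference: Mapping[str, float] | None = None,
    levels: tuple[float, ...] = (0.5, 0.8, 0.95),
) -> dict[str, pd.DataFrame]:
    """Per-polymorph marginal curves over RIL with credible ribbons.

    Per draw and grid point: probability of excretion times the lognormal
    conditional mean, with every other predictor held at its data mean, no
    family effect, and the reference (double) titration scale.  Returns a
    table per polymorph with the median and central interval bounds.
    """
    grid = np.asarray(ril_grid, dtype=float)
    if (grid <= 0).any():
        raise DomainError("RIL grid must be positive")
    p = fit.stacked_params()
    means = dict(zip(POSITIVE_TERMS, fit.model.pos_info.means))
    if reference:
        means.update(reference)
    h_means = dict(zip(fit.model.spec.hurdle_terms, fit.model.hur_info.means))
    h_means.setdefault("temperature", means.get("temperature", 26.0))
    out: dict[str, pd.DataFrame] = {}
    for m_i, poly in enumerate(POLYMORPHS):
        terms = fit.model.spec.positive_terms[poly]
        mu = np.repeat(
            p["intercept_pos"][:, m_i][:, None], grid.size, axis=1
        )
        for term in terms:
            x = (
                np.log(grid)[None, :]
                if term == "ln_ril"
                else means[term]
            )
            mu = mu + p[f"beta_pos_{poly}_{term}"][:, None] * x
        sig = np.exp(p["gamma_sigma"][:, m_i])[:, None]
        s = (
            p["intercept_hurdle"][:, m_i][:, None]
            + p[f"beta_hurdle_{poly}_ln_ril"][:, None] * np.log(grid)[None, :]
            + p[f"beta_hurdle_{poly}_temperature"][:, None]
            * h_means["temperature"]
        )
        curve = (1.0 - expit(s)) * np.exp(mu + 0.5 * sig**2)
        cols = {"ril": grid, "median": np.median(curve, axis=0)}
        for lv in levels:
            a = (1 - lv) / 2
            cols[f"q{100 * a:g}"] = np.quantile(curve, a, axis=0)
            cols[f"q{100 * (1 - a):g}"] = np.quantile(curve, 1 - a, axis=0)
        out[poly] = pd.DataFrame(cols)
    return out


def family_correlation_matrix(
    fit: MineralogyFit, probability_scale: bool = True
) -> dict[str, np.ndarray]:
    """Posterior summaries of the 10x10 family-effect correlation.

    With ``probability_scale`` the cross-block (rate vs hurdle) entries are
    sign-flipped so hurdle components read as "probability of excretion"
    (the within-hurdle block is invariant to flipping both margins).
    Returns median and 95% interval arrays plus the hurdle-only block.
    """
    C = fit.corr_draws()
    if probability_scale:
        flip = np.ones((10, 10))
        flip[:5, 5:] = -1.0
        flip[5:, :5] = -1.0
        C = C * flip[None, :, :]
    med = np.median(C, axis=0)
    lo = np.quantile(C, 0.025, axis=0)
    hi = np.quantile(C, 0.975, axis=0)
    return {
        "median": med,
        "q2.5": lo,
        "q97.5": hi,
        "hurdle_block_median": med[5:, 5:],
        "hurdle_block_q2.5": lo[5:, 5:],
        "hurdle_block_q97.5": hi[5:, 5:],
    }


def reduced_spec_from_fit(fit: MineralogyFit) -> HurdleModelSpec:
    """Generic model-reduction rule: drop positive-part fixed effects whose
    posterior SD exceeds the magnitude of their posterior mean."""
    masks: dict[str, tuple[str, ...]] = {}
    for poly in POLYMORPHS:
        kept = []
        for term in fit.spec.positive_terms[poly]:
            d = fit.draws.stacked(f"beta_pos_{poly}_{term}")
            if np.abs(d.mean()) >= d.std(ddof=1):
                kept.append(term)
        masks[poly] = tuple(kept) if kept else ("ln_mass",)
    return HurdleModelSpec(
        positive_terms=masks,
        hurdle_terms=fit.spec.hurdle_terms,
        scale_terms=fit.spec.scale_terms,
        group_factor=fit.spec.group_factor,
        weights=fit.spec.weights,
    )
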