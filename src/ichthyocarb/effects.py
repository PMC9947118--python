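"""Derived ecological quantities from a fitted excretion model.

All summaries are per-draw transforms of the posterior — the temperature
coefficient Q10, percent changes across observed covariate ranges,
marginal effect curves on the µmol h⁻¹ scale, and population-level
prediction surfaces — so reported means are means of the transformed
draws, not transforms of posterior means (the two differ by Jensen's
inequality for these convex maps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DomainError
from .excretion import ExcretionFit


@dataclass(frozen=True)
class EffectSummary:
    """A named per-draw derived quantity with its posterior summary."""

    name: str
    draws: np.ndarray
    transform: str

    def __post_init__(self) -> None:
        if np.asarray(self.draws).size == 0:
            raise DomainError("effect summary needs at least one draw")

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def median(self) -> float:
        return float(np.median(self.draws))

    @property
    def q2_5(self) -> float:
        return float(np.quantile(self.draws, 0.025))

    @property
    def q97_5(self) -> float:
        return float(np.quantile(self.draws, 0.975))

    def as_dict(self) -> dict[str, float]:
        return {
            "name": self.name,
            "mean": self.mean,
            "median": self.median,
            "q2.5": self.q2_5,
            "q97.5": self.q97_5,
        }


def q10(temperature_coefficient_draws: np.ndarray) -> EffectSummary:
    """Q10: multiplicative change in excretion rate per 10 °C.

    The input draws are the temperature coefficient on the ln-rate-per-°C
    scale; each draw maps to exp(10 * beta) before summarising.
    """
    d = np.asarray(temperature_coefficient_draws, dtype=float)
    if d.size == 0:
        raise DomainError("empty draws")
    return EffectSummary(
        name="Q10", draws=np.exp(10.0 * d), transform="exp(10*beta)"
    )


_TRANSFORMS = {
    "identity": lambda x: x,
    "ln": np.log,
    "sqrt": np.sqrt,
}


def range_percent_change(
    coef_draws: np.ndarray,
    transform: str,
    lo: float,
    hi: float,
    name: str = "range_change",
) -> EffectSummary:
    """Percent change in rate across an observed covariate range.

    Per draw: ``100 * (exp(beta * (g(hi) - g(lo))) - 1)`` with g the
    covariate transform used in the linear predictor.
    """
    if transform not in _TRANSFORMS:
        raise DomainError(f"unknown transform {transform!r}")
    if lo >= hi:
        raise DomainError("lo must be < hi")
    if transform in ("ln", "sqrt") and lo <= 0:
        raise DomainError(f"bounds must be positive for {transform}")
    g = _TRANSFORMS[transform]
    d = np.asarray(coef_draws, dtype=float)
    if d.size == 0:
        raise DomainError("empty draws")
    pct = 100.0 * (np.exp(d * (g(hi) - g(lo))) - 1.0)
    return EffectSummary(
        name=name,
        draws=pct,
        transform=f"100*(exp(beta*({transform}(hi)-{transform}(lo)))-1)",
    )


def _term_value(term: str, value: float) -> float:
    if term == "ln_mass" or term == "ln_ril":
        if value <= 0:
            raise DomainError(f"{term} source value must be positive")
        return float(np.log(value))
    if term == "sqrt_ar":
        if value <= 0:
            raise DomainError("AR must be positive")
        return float(np.sqrt(value))
    return float(value)


def marginal_effect_curve(
    fit: ExcretionFit,
    predictor: str,
    grid: np.ndarray,
    n_curves: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Marginal effect of one predictor on the µmol h⁻¹ scale.

    Other predictors sit at their data means (on the transformed scale),
    the family effect at zero.  Returns the grid, the posterior-mean curve
    and ``n_curves`` sampled posterior curves as columns ``draw_j``.
    """
    spec = fit.spec
    if predictor not in spec.location_terms:
        raise DomainError(f"{predictor!r} is not in the fitted model")
    grid = np.asarray(grid, dtype=float)
    p = fit.stacked_params()
    info = fit.model.design_info
    means = dict(zip(info.terms, info.means))
    j = spec.location_terms.index(predictor)
    eta0 = p["gamma0"].copy()
    for t_i, term in enumerate(spec.location_terms):
        if t_i != j:
            eta0 = eta0 + p["beta"][:, t_i] * means[term]
    gx = np.array([_term_value(predictor, v) for v in grid])
    ln_curves = eta0[:, None] + np.outer(p["beta"][:, j], gx)
    curves = np.exp(ln_curves)
    out = pd.DataFrame({predictor: grid, "mean": curves.mean(axis=0)})
    rng = np.random.default_rng(seed)
    S = curves.shape[0]
    take = rng.choice(S, size=min(n_curves, S), replace=False)
    for c, s in enumerate(take):
        out[f"draw_{c}"] = curves[s]
    return out


def prediction_surface(
    fit: ExcretionFit,
    ar_levels: np.ndarray,
    ril_levels: np.ndarray,
    temperature: float,
    mass_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Population-level expected rates over mass for (AR, RIL) combinations.

    Average predictions: the family effect is zeroed, so surfaces describe
    a typical fish of unknown family.  Returns long-format rows
    (ar, ril, body_mass_kg, mean, q2.5, q97.5).
    """
    spec = fit.spec
    for needed in ("ln_mass",):
        if needed not in spec.location_terms:
            raise DomainError("model must include ln_mass")
    if mass_grid is None:
        mass_grid = np.geomspace(0.001, 11.0, 25)
    p = fit.stacked_params()
    rows = []
    terms = spec.location_terms
    for ar in np.asarray(ar_levels, dtype=float):
        for ril in np.asarray(ril_levels, dtype=float):
            vals = {
                "sqrt_ar": _term_value("sqrt_ar", ar),
                "ln_ril": _term_value("ln_ril", ril),
                "temperature": float(temperature),
            }
            eta0 = p["gamma0"].copy()
            for t_i, term in enumerate(terms):
                if term == "ln_mass":
                    continue
                if term not in vals:
                    info = fit.model.design_info
                    vals[term] = float(
                        dict(zip(info.terms, info.means))[term]
                    )
                eta0 = eta0 + p["beta"][:, t_i] * vals[term]
            j = terms.index("ln_mass")
            ln_pred = eta0[:, None] + np.outer(
                p["beta"][:, j], np.log(mass_grid)
            )
            pred = np.exp(ln_pred)
            for g, mkg in enumerate(mass_grid):
                rows.append(
                    {
                        "ar": ar,
                        "ril": ril,
                        "body_mass_kg": float(mkg),
                        "mean": float(pred[:, g].mean()),
                        "q2.5": float(np.quantile(pred[:, g], 0.025)),
                        "q97.5": float(np.quantile(pred[:, g], 0.975)),
                    }
                )
    return pd.DataFrame(rows)
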