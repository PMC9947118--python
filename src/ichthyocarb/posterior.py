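"""Posterior draw container with convergence diagnostics and serialisation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd


@dataclass
class PosteriorDraws:
    """Named posterior draws, indexed (chain, iteration, *shape).

    Diagnostics (split R-hat, bulk effective sample size) are computed
    lazily with arviz.  ``divergences`` counts post-warm-up divergent
    transitions across all chains.
    """

    params: dict[str, np.ndarray]
    divergences: int = 0
    accept_rate: float = float("nan")
    _summary_cache: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """(chain*draw, *shape) view of one parameter."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(posterior=self.params)

    def summary(self) -> pd.DataFrame:
        """Mean, SD, quantiles, split R-hat and bulk ESS per scalar entry."""
        if self._summary_cache is not None:
            return self._summary_cache
        idata = self.to_inference_data()
        rhat = az.rhat(idata)
        ess = az.ess(idata, method="bulk")
        rows = []
        for name, a in self.params.items():
            flat = a.reshape(a.shape[0] * a.shape[1], -1)
            r = np.atleast_1d(np.asarray(rhat[name]).reshape(-1))
            e = np.atleast_1d(np.asarray(ess[name]).reshape(-1))
            for j in range(flat.shape[1]):
                label = name if flat.shape[1] == 1 else f"{name}[{j}]"
                col = flat[:, j]
                rows.append(
                    {
                        "parameter": label,
                        "mean": col.mean(),
                        "sd": col.std(ddof=1),
                        "q2.5": np.quantile(col, 0.025),
                        "q50": np.quantile(col, 0.5),
                        "q97.5": np.quantile(col, 0.975),
                        "rhat": float(r[j]),
                        "ess_bulk": float(e[j]),
                    }
                )
        self._summary_cache = pd.DataFrame(rows).set_index("parameter")
        return self._summary_cache

    def converged(
        self,
        rhat_max: float = 1.01,
        min_ess: float = 400.0,
        allow_divergences: int = 0,
    ) -> bool:
        """Default acceptance contract for a fit."""
        s = self.summary()
        return (
            bool((s["rhat"] < rhat_max).all())
            and bool((s["ess_bulk"] > min_ess).all())
            and self.divergences <= allow_divergences
        )

    # ---- serialisation -------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Columnar draws CSV plus a JSON summary sidecar."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cols = {}
        for name, a in self.params.items():
            flat = a.reshape(a.shape[0] * a.shape[1], -1)
            for j in range(flat.shape[1]):
                label = name if flat.shape[1] == 1 else f"{name}[{j}]"
                cols[label] = flat[:, j]
        pd.DataFrame(cols).to_csv(d / "draws.csv", index=False)
        summary = self.summary().reset_index().to_dict(orient="records")
        meta = {
            "n_chains": self.n_chains,
            "n_draws": self.n_draws,
            "divergences": self.divergences,
            "accept_rate": self.accept_rate,
            "shapes": {k: list(v.shape[2:]) for k, v in self.params.items()},
            "summary": summary,
        }
        (d / "summary.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorDraws":
        d = Path(directory)
        meta = json.loads((d / "summary.json").read_text())
        df = pd.read_csv(d / "draws.csv")
        nc, nd = meta["n_chains"], meta["n_draws"]
        params: dict[str, np.ndarray] = {}
        for name, shape in meta["shapes"].items():
            size = int(np.prod(shape)) if shape else 1
            labels = (
                [name]
                if size == 1 and not shape
                else [f"{name}[{j}]" for j in range(size)]
            )
            flat = np.column_stack([df[c].to_numpy() for c in labels])
            params[name] = flat.reshape(nc, nd, *shape)
        return cls(
            params=params,
            divergences=meta["divergences"],
            accept_rate=meta["accept_rate"],
        )
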