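"""Core data layer: schema, titration chemistry, rate aggregation, filtering
and predictor transforms.

Everything between a raw carbonate titration and a model-ready design matrix
lives here.  The central container is :class:`Dataset`, which couples
per-tank-group observations of intestinal carbonate excretion (one row per
independent group of fish) with species-level mineralogical composition
profiles over the five carbonate polymorphs excreted by teleosts.

Units follow the field conventions throughout: body mass in kg, excretion
rates in µmol CaCO3-equivalents per hour per individual, temperature in °C,
sampling periods in hours.  Relative intestinal length (RIL, intestine length
over standard length) and caudal fin aspect ratio (AR) are dimensionless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The five carbonate polymorphs, in order of increasing expected solubility.
POLYMORPHS: tuple[str, ...] = ("LMC", "HMC", "aragonite", "MHC", "ACMC")

#: Titration protocols.  ``double`` is the reference back-titration;
#: ``single_endpoint`` is the colorimetric end-point protocol, which reads
#: systematically high by a factor of ~1.08.
TITRATION_METHODS: tuple[str, str] = ("double", "single_endpoint")

#: Default single-endpoint / double-titration calibration ratio.
DEFAULT_METHOD_RATIO: float = 1.08

#: Covariate transforms used in all linear predictors.  Keys are the term
#: names accepted by model specs; values are (source column, function).
TERM_TRANSFORMS: dict[str, tuple[str, str]] = {
    "ln_mass": ("body_mass_kg", "ln"),
    "ln_ril": ("ril", "ln"),
    "sqrt_ar": ("ar", "sqrt"),
    "temperature": ("temperature_C", "identity"),
    "salinity": ("salinity", "identity"),
    "period": ("sampling_period_h", "identity"),
}

OBSERVATION_COLUMNS = [
    "obs_id",
    "family",
    "species",
    "region",
    "n_individuals",
    "body_mass_kg",
    "ril",
    "ar",
    "temperature_C",
    "salinity",
    "sampling_period_h",
    "titration_method",
    "excretion_rate_umol_h",
    "weight",
]


class DomainError(ValueError):
    """Raised when an input violates a physical or schema precondition."""


def weight_for_group(n_individuals: int) -> float:
    """Regression weight for a tank group.

    Singleton tanks get weight 1; groups of two or more get weight 2.  Group
    observations average out intra-tank variability and are therefore more
    reliable, but weighting by group size would overweight the few large
    groups, hence the cap at 2.
    """
    if n_individuals < 1:
        raise DomainError(f"n_individuals must be >= 1, got {n_individuals}")
    return 1.0 if int(n_individuals) == 1 else 2.0


@dataclass(frozen=True)
class FishObservation:
    """One independent observation: a tank holding one fish or a small
    monospecific group, with its traits, environment and measured rate."""

    obs_id: str
    family: str
    species: str
    region: str
    n_individuals: int
    body_mass_kg: float
    ril: float
    ar: float
    temperature_C: float
    salinity: float
    sampling_period_h: float
    titration_method: str
    excretion_rate_umol_h: float
    weight: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise DomainError("n_individuals must be >= 1")
        for name in ("body_mass_kg", "ril", "ar", "sampling_period_h"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        if self.excretion_rate_umol_h < 0:
            raise DomainError("excretion_rate_umol_h must be non-negative")
        if self.titration_method not in TITRATION_METHODS:
            raise DomainError(
                f"titration_method must be one of {TITRATION_METHODS}"
            )
        expected = weight_for_group(self.n_individuals)
        if self.weight is None:
            object.__setattr__(self, "weight", expected)
        elif float(self.weight) != expected:
            raise DomainError(
                "weight must be 1 for singletons and 2 for groups"
            )


@dataclass(frozen=True)
class PolymorphProfile:
    """Species-level relative abundances of the five polymorphs (a point on
    the 4-simplex)."""

    species: str
    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        fr = {m: float(self.fractions.get(m, 0.0)) for m in POLYMORPHS}
        object.__setattr__(self, "fractions", fr)
        vals = np.array([fr[m] for m in POLYMORPHS])
        if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
            raise DomainError("polymorph fractions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise DomainError(
                f"polymorph fractions must sum to 1, got {vals.sum():.12f}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[m] for m in POLYMORPHS], dtype=float)


@dataclass
class Dataset:
    """Observations plus species composition profiles."""

    observations: list[FishObservation]
    profiles: list[PolymorphProfile] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [o.obs_id for o in self.observations]
        if len(set(ids)) != len(ids):
            raise DomainError("obs_ids must be unique")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def families(self) -> list[str]:
        return sorted({o.family for o in self.observations})

    @property
    def species(self) -> list[str]:
        return sorted({o.species for o in self.observations})

    def profile_for(self, species: str) -> PolymorphProfile:
        for p in self.profiles:
            if p.species == species:
                return p
        raise KeyError(f"no polymorph profile for species {species!r}")

    # ---- tabular views -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {c: getattr(o, c) for c in OBSERVATION_COLUMNS}
            for o in self.observations
        ]
        return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)

    def profiles_frame(self) -> pd.DataFrame:
        rows = [{"species": p.species, **p.fractions} for p in self.profiles]
        return pd.DataFrame(rows, columns=["species", *POLYMORPHS])

    @classmethod
    def from_frames(
        cls,
        observations: pd.DataFrame,
        profiles: pd.DataFrame | None = None,
        provenance: str = "",
    ) -> "Dataset":
        model_cols = [c for c in OBSERVATION_COLUMNS if c not in ("weight",)]
        if observations[model_cols].isna().any().any():
            bad = observations[model_cols].isna().any()
            raise DomainError(
                f"missing values in model covariates: {list(bad[bad].index)}"
            )
        obs = []
        for _, r in observations.iterrows():
            kwargs = {c: r[c] for c in OBSERVATION_COLUMNS if c in r.index}
            kwargs["n_individuals"] = int(kwargs["n_individuals"])
            if "weight" in kwargs and pd.isna(kwargs["weight"]):
                kwargs.pop("weight")
            obs.append(FishObservation(**kwargs))
        profs = []
        if profiles is not None:
            for _, r in profiles.iterrows():
                profs.append(
                    PolymorphProfile(
                        species=r["species"],
                        fractions={m: float(r[m]) for m in POLYMORPHS},
                    )
                )
        return cls(observations=obs, profiles=profs, provenance=provenance)

    # ---- disk round-trip ----------------------------------------------

    def write(self, directory: str | Path) -> None:
        """Write observations.csv, profiles.csv and a provenance sidecar."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(d / "observations.csv", index=False)
        self.profiles_frame().to_csv(d / "profiles.csv", index=False)
        (d / "provenance.json").write_text(
            json.dumps({"provenance": self.provenance}, indent=2)
        )

    @classmethod
    def read(cls, directory: str | Path) -> "Dataset":
        d = Path(directory)
        obs = pd.read_csv(d / "observations.csv")
        prof_path = d / "profiles.csv"
        profiles = pd.read_csv(prof_path) if prof_path.exists() else None
        if profiles is not None and profiles.empty:
            profiles = None
        prov_path = d / "provenance.json"
        prov = ""
        if prov_path.exists():
            prov = json.loads(prov_path.read_text()).get("provenance", "")
        return cls.from_frames(obs, profiles, provenance=prov)


# ---------------------------------------------------------------------------
# Titration chemistry
# ---------------------------------------------------------------------------

def carbonate_from_titration(
    n_hcl_umol: float, n_naoh_umol: float
) -> float:
    """Molar amount of (Ca,Mg)CO3 from a double titration.

    The acid consumed minus the base needed to return to the starting pH
    measures the bicarbonate equivalents in the sample; each carbonate
    molecule yields two, so the carbonate amount is half the difference::

        n[(Ca,Mg)CO3] = 0.5 * (n(HCl) - n(NaOH))

    Parameters are in µmol; the result is in µmol carbonate.
    """
    if n_hcl_umol < 0 or n_naoh_umol < 0:
        raise DomainError("titrant amounts must be non-negative")
    if n_naoh_umol > n_hcl_umol:
        raise DomainError(
            "NaOH exceeds HCl: over-titration was not back-corrected"
        )
    return 0.5 * (n_hcl_umol - n_naoh_umol)


def apply_titration_correction(
    rate: float, method: str, factor: float = DEFAULT_METHOD_RATIO
) -> float:
    """Convert a rate to double-titration equivalents.

    Single-end-point titration reads systematically high by a calibration
    factor (1.08 from paired measurements of the same samples), so rates
    measured that way are divided by the factor; double-titration rates pass
    through unchanged.
    """
    if rate < 0:
        raise DomainError("rate must be non-negative")
    if factor <= 0:
        raise DomainError("correction factor must be positive")
    if method not in TITRATION_METHODS:
        raise DomainError(f"unknown titration method {method!r}")
    return rate / factor if method == "single_endpoint" else rate


def aggregate_excretion_rate(
    sample_amounts_umol: Sequence[float],
    total_period_h: float,
    n_individuals: int,
) -> float:
    """Per-individual excretion rate for a tank group.

    All carbonate samples collected from a tank over the sampling period are
    summed, averaged over the period and divided by the number of individuals
    so the result is µmol h⁻¹ per individual of average biomass.
    """
    if len(sample_amounts_umol) == 0:
        raise DomainError("at least one carbonate sample is required")
    if total_period_h <= 0:
        raise DomainError("total sampling period must be positive")
    if n_individuals < 1:
        raise DomainError("n_individuals must be >= 1")
    return float(np.sum(sample_amounts_umol)) / total_period_h / n_individuals


# ---------------------------------------------------------------------------
# Filtering and family handling
# ---------------------------------------------------------------------------

def filter_min_observations(dataset: Dataset, k: int = 3) -> Dataset:
    """Retain only families with at least ``k`` independent observations.

    Families represented by fewer tank groups than ``k`` carry too little
    information for a family-level effect; idempotent by construction.
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    counts: dict[str, int] = {}
    for o in dataset.observations:
        counts[o.family] = counts.get(o.family, 0) + 1
    keep = {f for f, c in counts.items() if c >= k}
    obs = [o for o in dataset.observations if o.family in keep]
    kept_species = {o.species for o in obs}
    profiles = [p for p in dataset.profiles if p.species in kept_species]
    return Dataset(
        observations=obs, profiles=profiles, provenance=dataset.provenance
    )


def split_families_by_tribe(
    dataset: Dataset,
    tribe_of_species: Mapping[str, str],
    rules: Mapping[str, Mapping[str, str]],
) -> Dataset:
    """Relabel members of given tribes as pseudo-families.

    ``rules`` maps family -> {tribe -> new family label}.  The canonical use
    is splitting the parrotfishes (tribe Scarini) from the rest of the
    Labridae, which excrete distinct carbonate products; the mapping is a
    plain table so other splits can be configured the same way.
    """
    obs = []
    for o in dataset.observations:
        tribe = tribe_of_species.get(o.species)
        new_family = rules.get(o.family, {}).get(tribe) if tribe else None
        obs.append(replace(o, family=new_family) if new_family else o)
    return Dataset(
        observations=obs,
        profiles=list(dataset.profiles),
        provenance=dataset.provenance,
    )


# ---------------------------------------------------------------------------
# Polymorph composition
# ---------------------------------------------------------------------------

def species_profile_from_samples(
    species: str, sample_fractions: Iterable[Mapping[str, float]]
) -> PolymorphProfile:
    """Average per-sample visual composition estimates into a species profile.

    Unweighted mean per polymorph, renormalised to the simplex afterwards
    (per-sample estimates are themselves approximate, so their mean need not
    sum exactly to 1).
    """
    rows = [
        np.array([float(s.get(m, 0.0)) for m in POLYMORPHS])
        for s in sample_fractions
    ]
    if not rows:
        raise DomainError("at least one sample composition is required")
    mean = np.mean(rows, axis=0)
    total = mean.sum()
    if total <= 0:
        raise DomainError("sample compositions sum to zero")
    mean = mean / total
    return PolymorphProfile(
        species=species, fractions=dict(zip(POLYMORPHS, mean))
    )


def polymorph_rates(
    total_rate_umol_h: float, profile: PolymorphProfile
) -> np.ndarray:
    """Split a total excretion rate into the five polymorph-specific rates.

    Elementwise product of the total rate with the species composition;
    outputs sum exactly to the input rate.
    """
    if total_rate_umol_h < 0:
        raise DomainError("total rate must be non-negative")
    fr = profile.as_array()
    out = total_rate_umol_h * fr
    # exact sum preservation: push float round-off into the largest share
    if total_rate_umol_h > 0:
        j = int(np.argmax(fr))
        out[j] += total_rate_umol_h - out.sum()
    return out


def polymorph_response_matrix(dataset: Dataset) -> np.ndarray:
    """(n_obs, 5) matrix of polymorph rates from totals and species profiles."""
    rows = []
    for o in dataset.observations:
        profile = dataset.profile_for(o.species)
        rows.append(polymorph_rates(o.excretion_rate_umol_h, profile))
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignInfo:
    """Transform metadata needed to map standardised coefficients back to
    the natural covariate scale."""

    terms: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    standardised: bool


def build_design(
    dataset: Dataset | pd.DataFrame,
    terms: Sequence[str],
    standardise: bool = False,
) -> tuple[pd.DataFrame, DesignInfo]:
    """Model-ready covariate table.

    Applies the canonical transforms (natural log to body mass and RIL,
    square root to AR, identity to temperature, salinity and sampling
    period).  With ``standardise`` each column is mean-centred and scaled to
    unit SD, and the means/SDs are returned so fitted coefficients can be
    back-transformed to natural scale.
    """
    df = dataset.to_frame() if isinstance(dataset, Dataset) else dataset
    cols = {}
    for t in terms:
        if t not in TERM_TRANSFORMS:
            raise DomainError(f"unknown design term {t!r}")
        src, fn = TERM_TRANSFORMS[t]
        x = df[src].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise DomainError(f"non-finite values in covariate {src!r}")
        if fn in ("ln", "sqrt") and (x <= 0).any():
            raise DomainError(f"{src!r} must be positive for {fn} transform")
        cols[t] = np.log(x) if fn == "ln" else np.sqrt(x) if fn == "sqrt" else x
    X = pd.DataFrame(cols, columns=list(terms))
    means = X.mean().to_numpy() if len(X) else np.zeros(len(terms))
    sds = X.std(ddof=0).to_numpy() if len(X) else np.ones(len(terms))
    if standardise:
        safe_sds = np.where(sds > 0, sds, 1.0)
        X = (X - means) / safe_sds
        sds = safe_sds
    info = DesignInfo(
        terms=tuple(terms), means=means, sds=sds, standardised=standardise
    )
    return X, info
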