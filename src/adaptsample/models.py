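"""Species vocalization models: declarative logistic specs and prediction.

Each species' hourly probability of vocalizing at least once (``p_v``,
conditional on presence) is a logistic regression over site-hour
covariates.  Models are declarative — an intercept plus (covariate,
transform, coefficient) terms — rather than fitted objects, because they
encode literature-based phenology, not data fits.  Circular covariates
(day of year, hour of day, lunar phase) enter through explicit-period sine
and cosine transforms; polynomial transforms act on the raw covariate
scale.

The linear predictor is

    M = intercept + sum_j  coef_j * transform_j(x_j)

and ``p_v = exp(M) / (1 + exp(M))``.

``predict_grid`` evaluates every model over a complete covariate lattice
and returns a :class:`PvGrid`, a dense species x site x date x hour array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .covariates import COVARIATE_COLUMNS

__all__ = [
    "ModelTerm",
    "VocalizationModelSpec",
    "PvGrid",
    "ModelSpecificationError",
    "build_model",
    "load_model_specs",
    "default_models",
    "linear_predictor",
    "predict_pv",
    "predict_grid",
]

#: Covariates a model term may reference.
MODEL_COVARIATES = frozenset(COVARIATE_COLUMNS) - {"site_id", "date"}

#: Transforms needing an explicit period.
_PERIODIC = {"sin_period", "cos_period"}

TRANSFORMS = frozenset({"identity", "square", "cube", "cos_lunar"}) | _PERIODIC


class ModelSpecificationError(ValueError):
    """A model spec references an unknown covariate or transform."""


@dataclass(frozen=True)
class ModelTerm:
    """One additive term of a logistic vocalization model."""

    covariate: str
    transform: str = "identity"
    coefficient: float = 0.0
    period: float | None = None

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ModelSpecificationError(
                f"unknown transform {self.transform!r} on covariate "
                f"{self.covariate!r} (choose from {sorted(TRANSFORMS)})"
            )
        if self.covariate not in MODEL_COVARIATES:
            raise ModelSpecificationError(
                f"unknown covariate {self.covariate!r} "
                f"(choose from {sorted(MODEL_COVARIATES)})"
            )
        if self.transform in _PERIODIC:
            if self.period is None or self.period <= 0:
                raise ModelSpecificationError(
                    f"{self.transform} on {self.covariate!r} needs a period > 0"
                )
        elif self.period is not None:
            raise ModelSpecificationError(
                f"transform {self.transform!r} takes no period"
            )

    def evaluate(self, x):
        """coefficient * transform(x), vectorized."""
        x = np.asarray(x, dtype=float)
        t = self.transform
        if t == "identity":
            v = x
        elif t == "square":
            v = x**2
        elif t == "cube":
            v = x**3
        elif t == "sin_period":
            v = np.sin(2.0 * np.pi * x / self.period)
        elif t == "cos_period":
            v = np.cos(2.0 * np.pi * x / self.period)
        else:  # cos_lunar: the phase is already a fraction of the lunation
            v = np.cos(2.0 * np.pi * x)
        return self.coefficient * v


@dataclass(frozen=True)
class VocalizationModelSpec:
    """A species' logistic vocalization model."""

    species_code: str
    intercept: float = 0.0
    terms: tuple[ModelTerm, ...] = field(default_factory=tuple)

    @property
    def covariates(self) -> set[str]:
        return {t.covariate for t in self.terms}


def build_model(record: Mapping) -> VocalizationModelSpec:
    """Validate a mapping with keys species_code, intercept, terms.

    ``terms`` entries are mappings with covariate / transform / coefficient
    (and period where the transform is periodic).  Raises
    :class:`ModelSpecificationError` naming any offending term.
    """
    terms = tuple(
        t if isinstance(t, ModelTerm) else ModelTerm(**t)
        for t in record.get("terms", ())
    )
    return VocalizationModelSpec(
        species_code=str(record["species_code"]),
        intercept=float(record.get("intercept", 0.0)),
        terms=terms,
    )


def load_model_specs(source) -> list[VocalizationModelSpec]:
    """Read model specs from CSV (one term per row; intercept rows distinguished).

    Columns: species_code, covariate, transform, period, coefficient.  The
    intercept row has transform ``intercept`` and an empty covariate.
    Species order follows first appearance.
    """
    df = pd.read_csv(source)
    specs = []
    for code, grp in df.groupby("species_code", sort=False):
        intercept = 0.0
        terms = []
        for row in grp.itertuples(index=False):
            if str(row.transform) == "intercept":
                intercept = float(row.coefficient)
                continue
            period = None if pd.isna(row.period) else float(row.period)
            kwargs = {"covariate": str(row.covariate),
                      "transform": str(row.transform),
                      "coefficient": float(row.coefficient)}
            if period is not None:
                kwargs["period"] = period
            terms.append(ModelTerm(**kwargs))
        specs.append(
            VocalizationModelSpec(str(code), intercept, tuple(terms))
        )
    return specs


def default_models() -> list[VocalizationModelSpec]:
    """The nine shipped desert focal-species models (BTGN .. VERD)."""
    ref = resources.files("adaptsample.data") / "vocalization_models.csv"
    with ref.open("r") as fh:
        return load_model_specs(fh)


def linear_predictor(model: VocalizationModelSpec, row) -> float:
    """Evaluate M for one covariate row (mapping or DataFrame row)."""
    m = model.intercept
    for term in model.terms:
        try:
            x = row[term.covariate]
        except (KeyError, IndexError) as exc:
            raise KeyError(
                f"covariate {term.covariate!r} missing from row"
            ) from exc
        if pd.isna(x):
            raise ValueError(f"covariate {term.covariate!r} is missing (NaN)")
        m += float(term.evaluate(x))
    if not np.isfinite(m):
        raise ValueError(f"non-finite linear predictor for {model.species_code}")
    return float(m)


def _logistic(m):
    # Numerically stable on both tails.
    out = np.empty_like(m, dtype=float)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-m[pos]))
    e = np.exp(m[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def predict_pv(model: VocalizationModelSpec, row) -> float:
    """Hourly vocalization probability p_v = logistic(M) for one row."""
    return float(_logistic(np.array([linear_predictor(model, row)]))[0])


class PvGrid:
    """Dense hourly vocalization probabilities over species x site x date x hour.

    ``values[k, r, d, h]`` is p_v for species ``species[k]`` at site
    ``sites[r]`` on ``dates[d]`` during hour ``h``.
    """

    def __init__(self, values: np.ndarray, species: Sequence[str],
                 sites: Sequence[str], dates) -> None:
        values = np.asarray(values, dtype=float)
        dates = pd.DatetimeIndex(dates)
        if values.shape != (len(species), len(sites), len(dates), 24):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(species)}, {len(sites)}, {len(dates)}, 24)"
            )
        if values.min() < 0.0 or values.max() > 1.0:
            raise ValueError("p_v values must lie in [0, 1]")
        self.values = values
        self.species = list(species)
        self.sites = list(sites)
        self.dates = dates

    @property
    def n_records(self) -> int:
        """Total number of p_v records (= K * R * D * 24)."""
        return self.values.size

    def sel(self, species: str, site: str, date) -> np.ndarray:
        """The 24-hour p_v vector for one species, site and date."""
        k = self.species.index(species)
        r = self.sites.index(site)
        d = self.dates.get_loc(pd.Timestamp(date))
        return self.values[k, r, d]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PvGrid":
        """Rebuild a grid from long format (inverse of :meth:`to_frame`)."""
        species = list(pd.unique(df["species_code"]))
        sites = list(pd.unique(df["site_id"]))
        dates = pd.DatetimeIndex(
            pd.unique(pd.DatetimeIndex(df["date"]).normalize())
        ).sort_values()
        shape = (len(species), len(sites), len(dates), 24)
        if len(df) != int(np.prod(shape)):
            raise ValueError(
                f"expected {int(np.prod(shape))} rows for a complete lattice, "
                f"got {len(df)}"
            )
        k = pd.Categorical(df["species_code"], categories=species).codes
        r = pd.Categorical(df["site_id"], categories=sites).codes
        d = dates.get_indexer(pd.DatetimeIndex(df["date"]).normalize())
        h = df["hour_of_day"].to_numpy()
        values = np.full(shape, np.nan)
        values[k, r, d, h] = df["p_v"].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("incomplete or duplicated (species, site, date, hour) keys")
        return cls(values, species, sites, dates)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: species_code, site_id, date, hour_of_day, p_v."""
        k, r, d, h = np.unravel_index(
            np.arange(self.values.size), self.values.shape
        )
        return pd.DataFrame(
            {
                "species_code": pd.Categorical.from_codes(k, self.species),
                "site_id": pd.Categorical.from_codes(r, self.sites),
                "date": self.dates.values[d],
                "hour_of_day": h.astype(np.int64),
                "p_v": self.values.ravel(),
            }
        )


def predict_grid(
    models: Sequence[VocalizationModelSpec], covariates: pd.DataFrame
) -> PvGrid:
    """Vectorized p_v prediction for every model over a covariate lattice.

    The covariate table must be complete: exactly 24 hours per site-date
    over a full site x date rectangle.  Raises ``ValueError`` listing the
    missing (site, date) keys otherwise.
    """
    sites = list(pd.unique(covariates["site_id"]))
    dates = pd.DatetimeIndex(pd.unique(pd.DatetimeIndex(covariates["date"]).normalize()))
    dates = dates.sort_values()

    counts = covariates.groupby(
        [covariates["site_id"], pd.DatetimeIndex(covariates["date"]).normalize()],
        observed=True,
    ).size()
    expected = {(s, d) for s in sites for d in dates}
    seen = dict(counts.items())
    bad = sorted(
        str(key)
        for key in expected - set(seen)
        | {k for k, v in seen.items() if v != 24}
    )
    if len(seen) != len(expected) or bad:
        missing = sorted(str(k) for k in expected - set(seen))
        raise ValueError(
            f"incomplete covariate lattice; missing or short site-dates: "
            f"{(missing + bad)[:20]}"
        )

    site_codes = pd.Categorical(covariates["site_id"], categories=sites).codes
    order = np.lexsort(
        (
            covariates["hour_of_day"].to_numpy(),
            pd.DatetimeIndex(covariates["date"]).normalize().to_numpy(),
            site_codes,
        )
    )
    df = covariates.iloc[order]

    shape = (len(sites), len(dates), 24)
    values = np.empty((len(models),) + shape, dtype=float)
    for k, model in enumerate(models):
        m = np.full(len(df), model.intercept, dtype=float)
        for term in model.terms:
            if term.covariate not in df.columns:
                raise KeyError(
                    f"covariate {term.covariate!r} missing from table "
                    f"(model {model.species_code})"
                )
            m += term.evaluate(df[term.covariate].to_numpy())
        values[k] = _logistic(m).reshape(shape)

    return PvGrid(values, [mo.species_code for mo in models], sites, dates)
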