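"""Extrinsic-variability distributions over single-cell parameters.

Cell-to-cell variability is modelled by independent log-normal marginals,
one per heterogeneous parameter.  Each marginal is parameterized the way
experimentalists report protein abundances: a location (either the mean or
the median, both in model units) and a dimensionless coefficient of
variation (CV = standard deviation / mean).  On the log scale this maps to

    sigma^2 = ln(1 + CV^2)
    mu      = ln(median)                  (location given as median)
    mu      = ln(mean) - sigma^2 / 2      (location given as mean)

``cv = 0`` degenerates to a point mass at the location value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .ensemble import SingleCellModel

__all__ = [
    "LogNormalSpec",
    "PopulationSpec",
    "ParameterMatrix",
    "lognormal_logscale",
    "sample_parameters",
    "region_probability",
]


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal marginal for one heterogeneous parameter.

    Parameters
    ----------
    name
        Parameter identifier (must match a model parameter name).
    location_value
        Positive location in model units (e.g. molecules/cell, 1/h).
    cv
        Coefficient of variation; ``0`` means a point mass.
    location_kind
        Whether ``location_value`` is the distribution ``"mean"`` or
        ``"median"``.
    """

    name: str
    location_value: float
    cv: float
    location_kind: str = "median"

    def __post_init__(self) -> None:
        if self.location_kind not in ("mean", "median"):
            raise ValueError(
                f"location_kind must be 'mean' or 'median', got {self.location_kind!r}"
            )
        if not self.location_value > 0:
            raise ValueError(f"{self.name}: location_value must be > 0")
        if self.cv < 0:
            raise ValueError(f"{self.name}: cv must be >= 0")

    @property
    def logscale(self) -> tuple[float, float]:
        """``(mu, sigma)`` of the underlying normal distribution."""
        return lognormal_logscale(self)

    @property
    def median(self) -> float:
        mu, _ = self.logscale
        return math.exp(mu)

    @property
    def mean(self) -> float:
        mu, sigma = self.logscale
        return math.exp(mu + sigma**2 / 2)

    def frozen(self):
        """The scipy frozen distribution (undefined for ``cv == 0``)."""
        mu, sigma = self.logscale
        if sigma == 0:
            raise ValueError("cv=0 is a point mass; no continuous distribution")
        return stats.lognorm(s=sigma, scale=math.exp(mu))


def lognormal_logscale(spec: LogNormalSpec) -> tuple[float, float]:
    """Map a (location, CV) parameterization to log-scale ``(mu, sigma)``."""
    sigma = math.sqrt(math.log1p(spec.cv**2))
    if spec.location_kind == "median":
        mu = math.log(spec.location_value)
    else:
        mu = math.log(spec.location_value) - sigma**2 / 2
    return mu, sigma


def region_probability(spec: LogNormalSpec, lower: float, upper: float) -> float:
    """Probability that the parameter lies in the open interval (lower, upper).

    Exact CDF difference of the log-normal; a point mass (``cv = 0``) gives
    an indicator on whether the location value lies inside.
    """
    if not lower < upper:
        raise ValueError(f"require lower < upper, got ({lower}, {upper})")
    mu, sigma = spec.logscale
    if sigma == 0:
        return float(lower < spec.location_value < upper)
    dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    lo = dist.cdf(lower) if lower > 0 else 0.0
    hi = dist.cdf(upper) if np.isfinite(upper) else 1.0
    return float(hi - lo)


@dataclass
class ParameterMatrix:
    """Sampled parameter vectors, one row per cell.

    ``values`` is an ``(N, q)`` array with strictly positive entries whose
    columns follow the order of the generating specs.
    """

    values: np.ndarray
    parameter_names: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x parameters)")
        if self.values.shape[1] != len(self.parameter_names):
            raise ValueError("column count does not match parameter_names")
        if self.values.size and not np.all(self.values > 0):
            raise ValueError("parameter values must be strictly positive")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.parameter_names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.parameter_names)

    # -- round trips ----------------------------------------------------

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            if self.seed is not None:
                fh.write(f"# seed={self.seed}\n")
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ParameterMatrix":
        seed = None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for token in first[1:].split():
                    if token.startswith("seed="):
                        seed = int(token[5:])
                frame = pd.read_csv(fh)
            else:
                fh.seek(0)
                frame = pd.read_csv(fh)
        return cls(frame.to_numpy(float), list(frame.columns), seed=seed)

    def to_npz(self, path) -> None:
        np.savez(
            path,
            values=self.values,
            parameter_names=np.array(self.parameter_names),
            seed=np.array(-1 if self.seed is None else self.seed),
        )

    @classmethod
    def from_npz(cls, path) -> "ParameterMatrix":
        with np.load(path, allow_pickle=False) as data:
            seed = int(data["seed"])
            return cls(
                data["values"],
                [str(n) for n in data["parameter_names"]],
                seed=None if seed < 0 else seed,
            )


@dataclass
class PopulationSpec:
    """A single-cell model plus the heterogeneity of its parameters.

    ``varying`` lists the log-normal marginals of the heterogeneous
    parameters (order defines the sample's column order); every remaining
    model parameter must appear in ``fixed``.
    """

    model: "SingleCellModel"
    varying: Sequence[LogNormalSpec]
    fixed: Mapping[str, float] = field(default_factory=dict)
    ensemble_size: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        var_names = [s.name for s in self.varying]
        if len(set(var_names)) != len(var_names):
            raise ValueError("duplicate names in varying specs")
        overlap = set(var_names) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both varying and fixed: {sorted(overlap)}")
        model_names = set(self.model.parameter_names)
        covered = set(var_names) | set(self.fixed)
        if covered != model_names:
            missing = sorted(model_names - covered)
            extra = sorted(covered - model_names)
            raise ValueError(
                f"varying+fixed must cover the model parameters exactly; "
                f"missing={missing}, unknown={extra}"
            )
        if self.ensemble_size < 0:
            raise ValueError("ensemble_size must be >= 0")

    @property
    def varying_names(self) -> list[str]:
        return [s.name for s in self.varying]

    def sample(self, n: int | None = None, seed: int | None = None) -> ParameterMatrix:
        return sample_parameters(self, n=n, seed=seed)

    def full_matrix(self, sampled: ParameterMatrix) -> np.ndarray:
        """Merge sampled varying columns with fixed values.

        Returns an ``(N, P)`` array ordered like ``model.parameter_names``.
        """
        if sampled.parameter_names != self.varying_names:
            raise ValueError("sampled columns do not match the varying specs")
        n = len(sampled)
        full = np.empty((n, len(self.model.parameter_names)))
        for j, name in enumerate(self.model.parameter_names):
            if name in self.fixed:
                full[:, j] = self.fixed[name]
            else:
                full[:, j] = sampled.column(name)
        return full


def sample_parameters(
    pop: PopulationSpec, n: int | None = None, seed: int | None = None
) -> ParameterMatrix:
    """Draw ``n`` independent parameter vectors from the population density.

    The generator consumes one stream column by column, so appending a new
    varying parameter leaves the draws of the existing columns unchanged.
    Sampling is a pure function of ``(specs, n, seed)``.
    """
    n = pop.ensemble_size if n is None else n
    seed = pop.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    values = np.empty((n, len(pop.varying)))
    for j, spec in enumerate(pop.varying):
        mu, sigma = spec.logscale
        values[:, j] = np.exp(mu + sigma * rng.standard_normal(n))
    return ParameterMatrix(values, pop.varying_names, seed=seed)
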