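"""Synthetic environmental covariates, length samples, and test fixtures.

Stands in for the historical covariate record driving the life cycle
model: May PDO and May/September coastal upwelling as standardized AR(1)
indices, late-summer water temperature (degC), and the wild-fish fraction
on the spawning grounds.  Each covariate is an independent stationary
AR(1) process with configurable mean, marginal standard deviation and
lag-1 autocorrelation; a 100-step burn-in precedes every emitted series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .lifecycle import EnvironmentYear
from .params import ScenarioSpec, ValidationError, default_parameters

__all__ = [
    "CovariateSpec",
    "CovariateModel",
    "generate_env_series",
    "generate_length_sample",
    "make_fixture",
]

_BURN_IN = 100


@dataclass(frozen=True)
class CovariateSpec:
    """Mean, marginal sd and lag-1 autocorrelation of one AR(1) covariate."""

    mean: float
    sd: float
    autocorrelation: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd!r}")
        if not abs(self.autocorrelation) < 1:
            raise ValidationError(
                f"|autocorrelation| must be < 1, got {self.autocorrelation!r}"
            )


@dataclass(frozen=True)
class CovariateModel:
    """The five covariate processes used by one projection.

    Defaults: standardized ocean indices (mean 0, sd 1) with interannual
    persistence for PDO; temperature around 16 degC; wild fraction around
    0.8, clipped to [0, 1] after simulation.
    """

    pdo_may: CovariateSpec = field(default_factory=lambda: CovariateSpec(0.0, 1.0, 0.7))
    upwelling_may: CovariateSpec = field(default_factory=lambda: CovariateSpec(0.0, 1.0, 0.5))
    upwelling_sept: CovariateSpec = field(default_factory=lambda: CovariateSpec(0.0, 1.0, 0.5))
    late_summer_temp: CovariateSpec = field(default_factory=lambda: CovariateSpec(16.0, 1.0, 0.5))
    wild_fraction: CovariateSpec = field(default_factory=lambda: CovariateSpec(0.80, 0.08, 0.3))

    def fields(self) -> dict[str, CovariateSpec]:
        return {
            "pdo_may": self.pdo_may,
            "upwelling_may": self.upwelling_may,
            "upwelling_sept": self.upwelling_sept,
            "late_summer_temp": self.late_summer_temp,
            "wild_fraction": self.wild_fraction,
        }


def _ar1(spec: CovariateSpec, years: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path with the requested marginal mean/sd."""
    phi = spec.autocorrelation
    innov_sd = spec.sd * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, 1.0, _BURN_IN + years)
    x = np.empty(_BURN_IN + years)
    # start at the stationary marginal so burn-in is belt-and-braces
    x[0] = spec.mean + spec.sd * eps[0]
    for t in range(1, len(x)):
        x[t] = spec.mean + phi * (x[t - 1] - spec.mean) + innov_sd * eps[t]
    return x[_BURN_IN:]


def generate_env_series(
    model: CovariateModel | None = None,
    years: int = 100,
    n_series: int = 1,
    seed: int | np.random.SeedSequence | None = None,
) -> list[list[EnvironmentYear]]:
    """Generate ``n_series`` independent covariate series of ``years`` years.

    Returns a list of series, each a list of :class:`EnvironmentYear`.
    The wild fraction is clipped to [0, 1]; everything else is unbounded.
    Reproducible from the seed.
    """
    if years < 1:
        raise ValidationError(f"years must be >= 1, got {years!r}")
    if n_series < 1:
        raise ValidationError(f"n_series must be >= 1, got {n_series!r}")
    model = model or CovariateModel()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_series):
        columns = {}
        for name, spec in model.fields().items():
            path = _ar1(spec, years, rng)
            if name == "wild_fraction":
                path = np.clip(path, 0.0, 1.0)
            columns[name] = path
        out.append(
            [
                EnvironmentYear(**{k: float(v[t]) for k, v in columns.items()})
                for t in range(years)
            ]
        )
    return out


def generate_length_sample(
    n: int, seed: int | np.random.SeedSequence | None = None
) -> np.ndarray:
    """Fork lengths (mm) of subyearlings in the harbor reach: uniform on
    [50, 80] mm, mean 65 mm."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n!r}")
    rng = np.random.default_rng(seed)
    return rng.uniform(50.0, 80.0, n)


def make_fixture(name: str, seed: int = 0) -> dict:
    """Deterministic, small test bundles with known structure.

    * ``baseline-small`` / ``cleanup-small``: a 50-run x 50-year
      configuration (multiplier 1.0 / 1.54) with its covariate model.
    * ``linear-sensitivity``: a sampled design whose response is an exact
      known linear function of the first input, for influence-recovery
      tests.
    """
    if name in {"baseline-small", "cleanup-small"}:
        params = default_parameters().evolve(n_runs=50, horizon_years=50)
        mult = 1.54 if name == "cleanup-small" else 1.0
        return {
            "name": name,
            "params": params,
            "scenario": ScenarioSpec(name=name, subyearling_survival_multiplier=mult, seed=seed),
            "covariate_model": CovariateModel(),
            "seed": seed,
        }
    if name == "linear-sensitivity":
        rng = np.random.default_rng(seed)
        n_draws, names = 200, ["driver", "idle_a", "idle_b"]
        ranges = {"driver": (0.0, 1.0), "idle_a": (0.0, 1.0), "idle_b": (0.0, 1.0)}
        draws = rng.uniform(0.0, 1.0, size=(n_draws, 3))
        responses = 5.0 * draws[:, 0]  # exact linear ground truth
        return {
            "name": name,
            "parameter_names": names,
            "ranges": ranges,
            "draws": draws,
            "responses": responses,
            "seed": seed,
        }
    raise ValueError(f"unknown fixture {name!r}")
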