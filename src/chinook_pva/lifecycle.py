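"""Stage-structured life cycle engine for McKenzie River spring Chinook.

One annual time step takes a population through: Beverton-Holt fry
recruitment (with an above/below Cougar Dam split), allocation of fry to
the three juvenile life-history pathways, pathway-specific lower-river
survival (where the contaminant-mitigation multiplier acts on spring
subyearlings), covariate-driven estuary/early-ocean survival, advancement
through ocean ages 1-5 with annual survival and a maturation schedule, and
prespawn survival of returning adults driven by late-summer temperature
and the wild-fish fraction.  Spawning is semelparous.

Demographic stochasticity uses Poisson recruitment, binomial survival and
multinomial pathway allocation.  Every draw is generated by inverse-CDF
sampling from a fixed number of uniforms per year, so two projections run
with the same seed but different survival multipliers are coupled: the
higher-survival run is pathwise at least as large at every stage (common
random numbers).  Passing ``rng=None`` gives the deterministic
expected-value model on continuous counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import binom as _binom, poisson as _poisson

from .params import ModelParameters, ScenarioSpec, ValidationError

__all__ = [
    "EnvironmentYear",
    "PopulationState",
    "beverton_holt",
    "allocate_pathways",
    "prespawn_survival",
    "estuary_ocean_survival",
    "initial_state",
    "step_year",
    "project",
]

# Uniform variates consumed by one stochastic year (fixed so that common
# random numbers stay aligned across scenarios).
_DRAWS_PER_YEAR = 18


@dataclass(frozen=True)
class EnvironmentYear:
    """Environmental covariates for one year.

    PDO and upwelling enter as standardized indices (default 0 = average
    conditions); temperature in degC and wild fraction as a proportion.
    """

    pdo_may: float = 0.0
    upwelling_may: float = 0.0
    upwelling_sept: float = 0.0
    late_summer_temp: float = 16.0
    wild_fraction: float = 0.80

    def __post_init__(self) -> None:
        if not (0.0 <= self.wild_fraction <= 1.0):
            raise ValidationError(
                f"wild_fraction must be in [0, 1], got {self.wild_fraction!r}"
            )


@dataclass(frozen=True)
class PopulationState:
    """Abundance over life stages for one year of one run."""

    year: int = 0
    fry: float = 0.0
    pathway_cohorts: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ocean_abundance: tuple[float, float, float, float, float] = (0.0,) * 5
    returning_adults: float = 0.0
    spawners: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fry", "returning_adults", "spawners"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
        for label, seq in (("pathway_cohorts", self.pathway_cohorts),
                           ("ocean_abundance", self.ocean_abundance)):
            for v in seq:
                if not (math.isfinite(v) and v >= 0):
                    raise ValidationError(f"{label} entries must be finite and >= 0")


# -- elementary transitions -----------------------------------------------

def beverton_holt(spawners: float, productivity: float, capacity: float) -> float:
    """Beverton-Holt recruitment ``p*S / (1 + p*S/c)``.

    ``capacity`` is in the units of the output (the asymptote); the curve is
    approximately ``p*S`` for small ``S``.
    """
    if not capacity > 0:
        raise ValueError(f"capacity must be > 0, got {capacity!r}")
    if not productivity > 0:
        raise ValueError(f"productivity must be > 0, got {productivity!r}")
    if spawners < 0:
        raise ValueError(f"spawners must be >= 0, got {spawners!r}")
    return productivity * spawners / (1.0 + productivity * spawners / capacity)


def allocate_pathways(
    fry: float, proportions: Sequence[float], rng: np.random.Generator | None = None
) -> tuple[float, float, float]:
    """Split fry among the three juvenile pathways.

    Expected-value mode multiplies; stochastic mode draws a multinomial.
    The three cohorts always sum to the fry input.
    """
    props = np.asarray(proportions, dtype=float)
    if props.shape != (3,) or np.any(props < 0) or not math.isclose(
        props.sum(), 1.0, abs_tol=1e-9
    ):
        raise ValidationError(f"proportions must be 3 nonnegative values summing to 1, got {proportions!r}")
    if rng is None:
        return tuple(float(fry) * props)
    u = rng.random(2)
    return tuple(float(c) for c in _multinomial_icdf(u, int(fry), props))


def prespawn_survival(env: EnvironmentYear, coefficients: Mapping[str, float]) -> float:
    """Prespawn survival of returning adults: logistic in late-summer
    temperature and the wild fraction on the spawning grounds."""
    eta = (
        coefficients["intercept"]
        + coefficients["late_summer_temp"] * env.late_summer_temp
        + coefficients["wild_fraction"] * env.wild_fraction
    )
    return float(expit(eta))


def estuary_ocean_survival(
    env: EnvironmentYear,
    coefficients: Mapping[str, float],
    delta_length: float = 0.0,
) -> float:
    """Estuary/early-ocean survival: logistic in May PDO, May and September
    coastal upwelling, plus the length-change term of the growth-survival
    link (slope ``coefficients['delta_length']``, default 0.0329 per mm)."""
    eta = (
        coefficients["intercept"]
        + coefficients["pdo_may"] * env.pdo_may
        + coefficients["upwelling_may"] * env.upwelling_may
        + coefficients["upwelling_sept"] * env.upwelling_sept
        + coefficients.get("delta_length", 0.0329) * delta_length
    )
    return float(expit(eta))


# -- monotone-coupled stochastic draws ------------------------------------

def _binomial_icdf(u: float, n: int, p: float) -> int:
    """Binomial sample by inverse CDF; monotone in u, n and p, which makes
    common-random-number comparisons pathwise monotone."""
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    return int(_binom.ppf(u, n, p))


def _poisson_icdf(u: float, lam: float) -> int:
    """Poisson sample by inverse CDF; monotone in u and the mean."""
    if lam <= 0.0:
        return 0
    return int(_poisson.ppf(u, lam))


def _multinomial_icdf(u: np.ndarray, n: int, props: np.ndarray) -> list[int]:
    """Multinomial sample via sequential conditional binomials."""
    counts: list[int] = []
    remaining = n
    mass = 1.0
    for i in range(len(props) - 1):
        p_cond = min(1.0, props[i] / mass) if mass > 0 else 0.0
        c = _binomial_icdf(float(u[i]), remaining, p_cond)
        counts.append(c)
        remaining -= c
        mass -= props[i]
    counts.append(remaining)
    return counts


# -- annual step and projection -------------------------------------------

def _check_finite(value: float, stage: str) -> None:
    if not math.isfinite(value):
        raise ArithmeticError(f"non-finite abundance produced at stage {stage!r}")


def initial_state(params: ModelParameters, env: EnvironmentYear | None = None) -> PopulationState:
    """Population state with a filled ocean pipeline.

    Ocean ages are seeded at the deterministic stationary age structure
    implied by ``initial_spawners`` under reference environmental
    conditions, so projections do not start with an artificial gap in adult
    returns while the first cohorts age at sea.
    """
    env = env or EnvironmentYear()
    s_o = params.ocean_annual_survival
    m3, m4, m5 = params.maturation_schedule
    fry = beverton_holt(
        params.initial_spawners, params.productivity,
        params.productivity * params.capacity_above_dam,
    )
    fresh = (
        params.fraction_above_dam * params.dam_passage_proportion * params.reservoir_survival
        + (1.0 - params.fraction_above_dam) * params.fry_survival_below_dam
    )
    juveniles = fry * fresh
    cohorts = tuple(juveniles * p for p in params.pathway_proportions)
    smolts = sum(c * s for c, s in zip(cohorts, params.lower_river_survival))
    p_est = estuary_ocean_survival(env, params.estuary_coefficients)
    n1 = smolts * p_est
    n2 = n1 * s_o
    n3 = n2 * s_o * (1.0 - m3)
    n4 = n3 * s_o * (1.0 - m4)
    n5 = n4 * s_o * (1.0 - m5)
    returns = s_o * (n2 * m3 + n3 * m4 + n4 * m5)
    return PopulationState(
        year=0,
        fry=fry,
        pathway_cohorts=cohorts,
        ocean_abundance=(n1, n2, n3, n4, n5),
        returning_adults=returns,
        spawners=float(params.initial_spawners),
    )


def step_year(
    state: PopulationState,
    params: ModelParameters,
    env: EnvironmentYear,
    scenario: ScenarioSpec | None = None,
    rng: np.random.Generator | None = None,
) -> PopulationState:
    """Advance the population one year.

    With ``rng`` the transitions are demographic draws (integer counts);
    without it the expected-value model runs on continuous counts.  A
    stochastic year always consumes exactly the same number of uniforms,
    so identical seeds give common random numbers across scenarios.
    """
    scenario = scenario or ScenarioSpec()
    u = rng.random(_DRAWS_PER_YEAR) if rng is not None else None
    stochastic = rng is not None

    s_above = params.dam_passage_proportion * params.reservoir_survival
    s_below = params.fry_survival_below_dam

    # spawners -> fry (density-dependent egg-to-fry production)
    fry_mean = beverton_holt(
        state.spawners, params.productivity,
        params.productivity * params.capacity_above_dam,
    )
    if stochastic:
        fry = _poisson_icdf(float(u[0]), fry_mean)
        above = _binomial_icdf(float(u[1]), fry, params.fraction_above_dam)
        below = fry - above
        juveniles = (
            _binomial_icdf(float(u[2]), above, s_above)
            + _binomial_icdf(float(u[3]), below, s_below)
        )
    else:
        fry = fry_mean
        juveniles = fry * (
            params.fraction_above_dam * s_above
            + (1.0 - params.fraction_above_dam) * s_below
        )
    _check_finite(juveniles, "freshwater rearing")

    # fry -> pathway cohorts
    if stochastic:
        cohorts = _multinomial_icdf(
            u[4:6], int(juveniles), np.asarray(params.pathway_proportions)
        )
    else:
        cohorts = [juveniles * p for p in params.pathway_proportions]

    # lower-river survival; the mitigation multiplier acts on spring
    # subyearlings only, clipped to a valid probability
    lr = list(params.lower_river_survival)
    lr[0] = min(1.0, lr[0] * scenario.subyearling_survival_multiplier)
    if stochastic:
        survivors = [
            _binomial_icdf(float(u[6 + i]), int(cohorts[i]), lr[i]) for i in range(3)
        ]
    else:
        survivors = [cohorts[i] * lr[i] for i in range(3)]
    smolts = sum(survivors)
    _check_finite(smolts, "lower river")

    # estuary / early ocean entry
    p_est = estuary_ocean_survival(env, params.estuary_coefficients)
    if stochastic:
        ocean_recruits = _binomial_icdf(float(u[7 + 2]), int(smolts), p_est)
    else:
        ocean_recruits = smolts * p_est
    _check_finite(ocean_recruits, "estuary")

    # ocean ageing, survival and maturation
    s_o = params.ocean_annual_survival
    n = list(state.ocean_abundance)
    new_ocean = [0.0] * 5
    new_ocean[0] = ocean_recruits
    for a in range(4):  # age a+1 survives to age a+2
        if stochastic:
            new_ocean[a + 1] = _binomial_icdf(float(u[10 + a]), int(n[a]), s_o)
        else:
            new_ocean[a + 1] = n[a] * s_o
    returns = 0.0
    for j, age_idx in enumerate((2, 3, 4)):  # ocean ages 3, 4, 5
        m = params.maturation_schedule[j]
        if stochastic:
            matured = _binomial_icdf(float(u[14 + j]), int(new_ocean[age_idx]), m)
        else:
            matured = new_ocean[age_idx] * m
        new_ocean[age_idx] -= matured
        returns += matured
    _check_finite(returns, "ocean return")

    # prespawn survival of returning adults
    p_pre = prespawn_survival(env, params.prespawn_coefficients)
    if stochastic:
        spawners = _binomial_icdf(float(u[17]), int(returns), p_pre)
    else:
        spawners = returns * p_pre
    _check_finite(spawners, "prespawn")

    return PopulationState(
        year=state.year + 1,
        fry=float(fry),
        pathway_cohorts=tuple(float(c) for c in cohorts),
        ocean_abundance=tuple(float(x) for x in new_ocean),
        returning_adults=float(returns),
        spawners=float(spawners),
    )


def project(
    params: ModelParameters,
    scenario: ScenarioSpec | None = None,
    env_series: Sequence[EnvironmentYear] | None = None,
    seed: int | np.random.SeedSequence | None = None,
    stochastic: bool = True,
    start: PopulationState | None = None,
) -> np.ndarray:
    """Project spawner abundance over the configured horizon.

    Returns one spawner count per year (length ``params.horizon_years``).
    ``env_series`` must cover the horizon; ``None`` holds the environment at
    reference conditions.  Deterministic given ``seed`` (or with
    ``stochastic=False``).
    """
    horizon = params.horizon_years
    if env_series is None:
        env_series = [EnvironmentYear()] * horizon
    if len(env_series) < horizon:
        raise ValueError(
            f"env_series has {len(env_series)} years but the horizon is {horizon}"
        )
    rng = np.random.default_rng(seed) if stochastic else None
    state = start or initial_state(params)
    if stochastic:
        state = replace(
            state,
            fry=round(state.fry),
            pathway_cohorts=tuple(round(c) for c in state.pathway_cohorts),
            ocean_abundance=tuple(round(x) for x in state.ocean_abundance),
            returning_adults=round(state.returning_adults),
            spawners=round(state.spawners),
        )
    out = np.empty(horizon)
    for t in range(horizon):
        state = step_year(state, params, env_series[t], scenario, rng)
        out[t] = state.spawners
    return out
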