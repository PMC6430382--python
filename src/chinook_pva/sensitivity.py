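"""Global sensitivity analysis by standardized-regression influence.

Each of ``n_draws`` model iterations receives an independent uniform draw
of every perturbed parameter; a single stochastic projection per draw
yields a mean-spawner-abundance response.  The three compositional pathway
proportions are renormalized to sum to one and enter the regression as
additive log-ratio (alr) coordinates so the predictors stay independent.
Relative influence of a parameter is its standardized OLS coefficient
(estimate / standard error) divided by the largest absolute standardized
coefficient, so the most influential parameter scores exactly +/-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .params import ModelParameters, ScenarioSpec, ValidationError
from .lifecycle import project
from .synth import CovariateModel, generate_env_series

__all__ = [
    "DEFAULT_RANGES",
    "PATHWAY_PARAMS",
    "SensitivityDesign",
    "sample_design",
    "logratio_transform",
    "inverse_logratio",
    "apply_draw",
    "evaluate_design",
    "relative_influence",
]

#: The three compositional parameters (order matches pathway tuples).
PATHWAY_PARAMS = (
    "pathway_spring_subyearling",
    "pathway_fall_subyearling",
    "pathway_spring_yearling",
)

#: Plausible ranges for the perturbed parameters.  The mitigation
#: multiplier spans no-effect (1.00) to full remediation (1.54); the
#: pathway-composition ranges are per-component bounds applied before
#: renormalization; the rest are the baseline demographic rates bracketed
#: by plausibility intervals.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "subyearling_survival_multiplier": (1.00, 1.54),
    "prespawn_intercept": (3.94, 5.94),
    "capacity_above_dam": (750.0, 1800.0),
    "fry_survival_below_dam": (0.50, 0.80),
    "dam_passage_proportion": (0.40, 0.80),
    "reservoir_survival": (0.40, 0.70),
    "pathway_spring_subyearling": (0.10, 0.33),
    "pathway_fall_subyearling": (0.40, 0.65),
    "pathway_spring_yearling": (0.10, 0.30),
    "estuary_intercept": (-2.40, -1.60),
}


@dataclass(frozen=True)
class SensitivityDesign:
    """Sampled parameter draws and (once evaluated) per-draw responses."""

    parameter_ranges: dict[str, tuple[float, float]]
    n_draws: int
    seed: int
    parameter_names: tuple[str, ...]
    draws: np.ndarray  # (n_draws, n_params), raw parameter scale
    responses: np.ndarray | None = None  # per-draw mean spawner abundance

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.parameter_names.index(name)]

    def compositions(self) -> np.ndarray:
        """Pathway proportions per draw, renormalized to sum to 1."""
        raw = np.column_stack([self.column(n) for n in PATHWAY_PARAMS])
        return raw / raw.sum(axis=1, keepdims=True)

    def with_responses(self, responses: np.ndarray) -> "SensitivityDesign":
        responses = np.asarray(responses, dtype=float)
        if responses.shape != (self.n_draws,):
            raise ValueError(f"responses must have shape ({self.n_draws},)")
        return replace(self, responses=responses)


def sample_design(
    ranges: Mapping[str, tuple[float, float]] | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> SensitivityDesign:
    """Independent uniform draws of every parameter for every iteration."""
    ranges = dict(ranges or DEFAULT_RANGES)
    for name, (low, high) in ranges.items():
        if not low < high:
            raise ValidationError(f"degenerate range for {name!r}: ({low}, {high})")
    if n_draws < 2:
        raise ValidationError(f"n_draws must be >= 2, got {n_draws!r}")
    rng = np.random.default_rng(seed)
    names = tuple(ranges)
    draws = np.column_stack(
        [rng.uniform(*ranges[name], size=n_draws) for name in names]
    )
    return SensitivityDesign(
        parameter_ranges=ranges, n_draws=n_draws, seed=seed,
        parameter_names=names, draws=draws,
    )


def logratio_transform(p1: float, p2: float, p3: float) -> tuple[float, float]:
    """Additive log-ratio coordinates of a 3-part composition, third
    component (spring yearling) as reference: ``(ln(p1/p3), ln(p2/p3))``."""
    parts = np.array([p1, p2, p3], dtype=float)
    if np.any(parts <= 0):
        raise ValueError(f"composition parts must be > 0, got {parts.tolist()}")
    total = parts.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"composition must sum to 1 within 1e-6, got {total}")
    parts = parts / total
    return float(np.log(parts[0] / parts[2])), float(np.log(parts[1] / parts[2]))


def inverse_logratio(x1: float, x2: float) -> tuple[float, float, float]:
    """Composition recovered from alr coordinates; always sums to 1."""
    e = np.array([math.exp(x1), math.exp(x2), 1.0])
    p = e / e.sum()
    return float(p[0]), float(p[1]), float(p[2])


def apply_draw(base: ModelParameters, design: SensitivityDesign, i: int) -> tuple[ModelParameters, ScenarioSpec]:
    """Materialize draw ``i`` as a model configuration and scenario."""
    values = dict(zip(design.parameter_names, design.draws[i]))
    changes: dict = {}
    if all(name in design.parameter_names for name in PATHWAY_PARAMS):
        changes["pathway_proportions"] = tuple(design.compositions()[i])
    estuary = dict(base.estuary_coefficients)
    prespawn = dict(base.prespawn_coefficients)
    if "estuary_intercept" in values:
        estuary["intercept"] = values["estuary_intercept"]
    if "prespawn_intercept" in values:
        prespawn["intercept"] = values["prespawn_intercept"]
    changes["estuary_coefficients"] = estuary
    changes["prespawn_coefficients"] = prespawn
    for name in ("capacity_above_dam", "fry_survival_below_dam",
                 "dam_passage_proportion", "reservoir_survival"):
        if name in values:
            changes[name] = values[name]
    params = base.evolve(**changes)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # draws may graze the range edge
        scenario = ScenarioSpec(
            name=f"draw-{i}",
            subyearling_survival_multiplier=values.get("subyearling_survival_multiplier", 1.0),
            seed=design.seed,
        )
    return params, scenario


def evaluate_design(
    design: SensitivityDesign,
    base: ModelParameters | None = None,
    covariate_model: CovariateModel | None = None,
) -> SensitivityDesign:
    """Run one stochastic projection per draw and record its mean spawner
    abundance as the response."""
    from .params import default_parameters

    base = base or default_parameters()
    master = np.random.SeedSequence(design.seed).spawn(design.n_draws)
    responses = np.empty(design.n_draws)
    for i, child in enumerate(master):
        env_seq, demo_seq = child.spawn(2)
        params, scenario = apply_draw(base, design, i)
        env = generate_env_series(
            covariate_model, years=params.horizon_years, n_series=1, seed=env_seq
        )[0]
        responses[i] = project(params, scenario, env, seed=demo_seq).mean()
    return design.with_responses(responses)


def _regression_matrix(design: SensitivityDesign) -> pd.DataFrame:
    """Predictors for the influence regression: raw columns for scalar
    parameters, alr coordinates for the pathway composition."""
    cols: dict[str, np.ndarray] = {}
    for name in design.parameter_names:
        if name in PATHWAY_PARAMS:
            continue
        cols[name] = design.column(name)
    if all(name in design.parameter_names for name in PATHWAY_PARAMS):
        comp = design.compositions()
        cols["alr_spring_subyearling_vs_yearling"] = np.log(comp[:, 0] / comp[:, 2])
        cols["alr_fall_subyearling_vs_yearling"] = np.log(comp[:, 1] / comp[:, 2])
    return pd.DataFrame(cols)


def relative_influence(design: SensitivityDesign) -> pd.DataFrame:
    """Standardized-regression influence table.

    OLS of the response on all (transformed) inputs; standardized
    coefficient is estimate/SE; relative influence rescales by the largest
    absolute standardized coefficient.  Sorted by descending influence
    magnitude.
    """
    if design.responses is None:
        raise ValueError("design has no responses; run evaluate_design first")
    X = _regression_matrix(design)
    if design.n_draws <= X.shape[1] + 2:
        raise ValueError(
            f"need more than {X.shape[1] + 2} draws for {X.shape[1]} predictors"
        )
    exog = sm.add_constant(X)
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        cond = np.linalg.cond(exog.to_numpy())
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {exog.shape[1]}, "
            f"condition number {cond:.3g})"
        )
    fit = sm.OLS(design.responses, exog).fit()
    table = pd.DataFrame(
        {
            "coefficient": fit.params.drop("const"),
            "std_error": fit.bse.drop("const"),
        }
    )
    table["standardized"] = table["coefficient"] / table["std_error"]
    table["relative_influence"] = (
        table["standardized"] / table["standardized"].abs().max()
    )
    table["sign"] = np.sign(table["coefficient"]).astype(int)
    table.index.name = "parameter"
    return table.sort_values("relative_influence", key=abs, ascending=False)
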