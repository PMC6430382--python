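"""Model parameterization and scenario configuration.

A :class:`ModelParameters` instance is one complete configuration of the
McKenzie River spring Chinook life cycle model: freshwater demography
(Beverton-Holt productivity and capacity, dam passage, reservoir and
below-dam fry survival), the three-way juvenile life-history pathway split,
pathway-specific lower-river survival, covariate-driven estuary/early-ocean
and prespawn survival coefficients, the ocean maturation schedule, and the
projection settings (horizon, number of Monte Carlo runs, quasi-extinction
threshold).

Configurations are plain frozen dataclasses; they round-trip losslessly
through YAML, JSON, and a flat CSV parameter table.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "ModelParameters",
    "ScenarioSpec",
    "PATHWAY_NAMES",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]

#: Juvenile life-history pathways, in the fixed order used by every
#: tuple-valued field (migration-timing cohorts through the lower river).
PATHWAY_NAMES = ("spring_subyearling", "fall_subyearling", "spring_yearling")


class ConfigurationError(ValueError):
    """A configuration file is missing a required field or cannot be parsed."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValidationError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class ModelParameters:
    """One full parameterization of the life cycle model.

    Defaults are the baseline McKenzie River configuration.  Dimensionless
    covariate coefficients act on the logit scale; survival fields are
    annual probabilities unless noted.
    """

    #: Expected fry produced per spawner at low density (dimensionless > 0).
    productivity: float = 215.0
    #: Adult-equivalent spawning/rearing capacity above Cougar Dam (fish).
    capacity_above_dam: float = 900.0
    #: Fraction of fry production originating above Cougar Dam.
    fraction_above_dam: float = 0.30
    #: Survival of fry rearing below the dam to the smolt migration.
    fry_survival_below_dam: float = 0.65
    #: Survival of above-dam juveniles through the reservoir.
    reservoir_survival: float = 0.55
    #: Proportion of above-dam juveniles available to pass the dam.
    dam_passage_proportion: float = 0.60
    #: Proportion of fry entering each pathway (spring subyearling,
    #: fall subyearling, spring yearling); sums to 1.
    pathway_proportions: tuple[float, float, float] = (0.18, 0.13, 0.69)
    #: Lower-river (Willamette mainstem + Portland Harbor) survival for each
    #: pathway, same order as :data:`PATHWAY_NAMES`.
    lower_river_survival: tuple[float, float, float] = (0.52, 0.50, 0.52)
    #: Logit-scale coefficients for estuary/early-ocean survival:
    #: intercept plus slopes on May PDO, May and September coastal upwelling,
    #: and contaminant-driven change in fork length (mm).
    estuary_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": -2.003,
            "pdo_may": -1.12,
            "upwelling_may": 0.70,
            "upwelling_sept": 0.56,
            "delta_length": 0.0329,
        }
    )
    #: Logit-scale coefficients for prespawn survival of returning adults:
    #: intercept plus slopes on late-summer water temperature (degC) and the
    #: wild fraction on the spawning grounds.
    prespawn_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": 4.935,
            "late_summer_temp": -0.45,
            "wild_fraction": 2.00,
        }
    )
    #: Proportion of fish maturing at ocean ages 3, 4, 5 (of those alive and
    #: still at sea at that age); the age-5 entry of 1 makes the schedule
    #: exhaustive.
    maturation_schedule: tuple[float, float, float] = (0.30, 0.60, 1.00)
    #: Annual survival while at sea.
    ocean_annual_survival: float = 0.80
    #: Adult abundance below which a run counts as quasi-extinct.
    quasi_extinction_threshold: int = 250
    #: Projection horizon in years.
    horizon_years: int = 100
    #: Monte Carlo replicate runs per ensemble.
    n_runs: int = 1000
    #: Spawner abundance used to initialize each projection.
    initial_spawners: int = 650

    def __post_init__(self) -> None:
        _check_positive("productivity", self.productivity)
        _check_positive("capacity_above_dam", self.capacity_above_dam)
        for name in (
            "fraction_above_dam",
            "fry_survival_below_dam",
            "reservoir_survival",
            "dam_passage_proportion",
            "ocean_annual_survival",
        ):
            _check_prob(name, getattr(self, name))
        object.__setattr__(
            self, "pathway_proportions", tuple(float(p) for p in self.pathway_proportions)
        )
        object.__setattr__(
            self, "lower_river_survival", tuple(float(s) for s in self.lower_river_survival)
        )
        object.__setattr__(
            self, "maturation_schedule", tuple(float(m) for m in self.maturation_schedule)
        )
        if len(self.pathway_proportions) != 3:
            raise ValidationError("pathway_proportions must have exactly 3 entries")
        for i, p in enumerate(self.pathway_proportions):
            _check_prob(f"pathway_proportions[{i}]", p)
        if not math.isclose(sum(self.pathway_proportions), 1.0, abs_tol=1e-9):
            raise ValidationError(
                "pathway_proportions must sum to 1 within 1e-9, got "
                f"{sum(self.pathway_proportions)!r}"
            )
        if len(self.lower_river_survival) != 3:
            raise ValidationError("lower_river_survival must have exactly 3 entries")
        for i, s in enumerate(self.lower_river_survival):
            _check_prob(f"lower_river_survival[{i}]", s)
        if len(self.maturation_schedule) != 3:
            raise ValidationError("maturation_schedule must have exactly 3 entries")
        for i, m in enumerate(self.maturation_schedule):
            _check_prob(f"maturation_schedule[{i}]", m)
        for cname, coeffs, required in (
            ("estuary_coefficients", self.estuary_coefficients,
             ("intercept", "pdo_may", "upwelling_may", "upwelling_sept")),
            ("prespawn_coefficients", self.prespawn_coefficients,
             ("intercept", "late_summer_temp", "wild_fraction")),
        ):
            for key in required:
                if key not in coeffs:
                    raise ConfigurationError(f"{cname} is missing required key {key!r}")
            for key, val in coeffs.items():
                if not math.isfinite(val):
                    raise ValidationError(f"{cname}[{key!r}] must be finite, got {val!r}")
        for name in ("quasi_extinction_threshold", "horizon_years", "n_runs",
                     "initial_spawners"):
            value = getattr(self, name)
            if not (isinstance(value, (int,)) and value > 0):
                raise ValidationError(f"{name} must be a positive integer, got {value!r}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pathway_proportions"] = list(self.pathway_proportions)
        d["lower_river_survival"] = list(self.lower_river_survival)
        d["maturation_schedule"] = list(self.maturation_schedule)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelParameters":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            warnings.warn(
                f"ignoring unknown parameter keys: {sorted(unknown)}", stacklevel=2
            )
        missing = known - set(data)
        if missing:
            raise ConfigurationError(
                f"configuration is missing required fields: {sorted(missing)}"
            )
        kwargs = {k: data[k] for k in known}
        for tup in ("pathway_proportions", "lower_river_survival", "maturation_schedule"):
            kwargs[tup] = tuple(kwargs[tup])
        for dct in ("estuary_coefficients", "prespawn_coefficients"):
            kwargs[dct] = {k: float(v) for k, v in dict(kwargs[dct]).items()}
        return cls(**kwargs)

    def evolve(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ScenarioSpec:
    """A contaminant-mitigation scenario applied to a projection.

    The multiplier scales spring-subyearling lower-river survival; 1.0 is
    the pre-cleanup baseline and 1.54 the full-remediation case (a 54%
    survival increase).  Values outside [1.00, 1.54] are allowed but warned
    about, since they fall outside the range the loss calculus supports.
    """

    name: str = "baseline"
    subyearling_survival_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.subyearling_survival_multiplier
        if not (math.isfinite(m) and m >= 0):
            raise ValidationError(
                f"subyearling_survival_multiplier must be finite and >= 0, got {m!r}"
            )
        if not (1.0 <= m <= 1.54):
            warnings.warn(
                "subyearling_survival_multiplier "
                f"{m} outside the supported range [1.00, 1.54]",
                stacklevel=2,
            )


def default_parameters() -> ModelParameters:
    """Baseline McKenzie River configuration.

    Point values reproduce the quantities fixed by the study design: a
    three-way pathway split of (0.18, 0.13, 0.69), an estuary-survival
    intercept of -2.003 (survival 0.1188 at average ocean conditions), a
    quasi-extinction threshold of 250 adults, a 100-year horizon, and
    1000-run ensembles.  Remaining demographic rates are calibrated
    McKenzie-plausible values; see the methods note.
    """
    return ModelParameters()


def load_parameters(path: str | Path, format: str | None = None) -> ModelParameters:
    """Load and validate a configuration from YAML, JSON, or flat CSV.

    The CSV form is the flat parameter table with columns
    (name, value, low, high, units, source); tuple- and dict-valued fields
    use dotted names (e.g. ``pathway_proportions.spring_subyearling``,
    ``estuary_coefficients.pdo_may``).
    """
    path = Path(path)
    if format is None:
        format = {".yaml": "yaml", ".yml": "yaml", ".json": "json", ".csv": "csv"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ConfigurationError(f"cannot infer format from suffix of {path}")
    if format not in {"yaml", "json", "csv"}:
        raise ConfigurationError(f"unsupported format {format!r}")
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigurationError(f"cannot read {path}: {exc}") from exc
    if format == "yaml":
        data = yaml.safe_load(text)
    elif format == "json":
        data = json.loads(text)
    else:
        data = _csv_to_dict(text, path)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path} does not contain a parameter mapping")
    return ModelParameters.from_dict(data)


def _csv_to_dict(text: str, path: Path) -> dict:
    flat: dict[str, float] = {}
    reader = csv.DictReader(text.splitlines())
    if reader.fieldnames is None or "name" not in reader.fieldnames:
        raise ConfigurationError(f"{path} lacks a 'name' column")
    for row in reader:
        try:
            flat[row["name"]] = float(row["value"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(
                f"{path}, row {reader.line_num}: bad value {row.get('value')!r}"
            ) from exc
    nested: dict = {}
    for key, value in flat.items():
        if "." in key:
            head, tail = key.split(".", 1)
            nested.setdefault(head, {})[tail] = value
        else:
            nested[key] = value
    for tup in ("pathway_proportions", "lower_river_survival", "maturation_schedule"):
        if tup in nested and isinstance(nested[tup], dict):
            sub = nested[tup]
            order = PATHWAY_NAMES if tup != "maturation_schedule" else ("age3", "age4", "age5")
            try:
                nested[tup] = tuple(sub[name] for name in order)
            except KeyError as exc:
                raise ConfigurationError(f"{tup} is missing component {exc}") from exc
    for name in ("quasi_extinction_threshold", "horizon_years", "n_runs", "initial_spawners"):
        if name in nested:
            nested[name] = int(nested[name])
    return nested


def save_parameters(params: ModelParameters, path: str | Path) -> Path:
    """Serialize a configuration to YAML or JSON (by suffix)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    elif path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        raise ConfigurationError(f"unsupported output suffix for {path}")
    return path
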