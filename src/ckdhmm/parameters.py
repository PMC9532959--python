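"""Parameter containers: covariate profiles, multipliers, model parameters.

The progression model is parametrised by nine baseline intensities per year
(four stage-to-next-stage rates and five stage-to-death rates) for a
reference profile — a woman aged 60 without heart failure or a previous
diagnosis of cancer — together with multiplicative covariate effects
(hazard ratios) shared across transitions: one progression multiplier and
one death multiplier per covariate, and a per-year age multiplier applied as
``m ** (age - 60)``.  Misclassification of the observed eGFR stage is a
row-stochastic emission matrix supported on a +/- 2 stage band among living
stages; death is always classified correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .states import (ALL_STATES, DEATH_INDEX, LIVING_STAGES, N_LIVING,
                     N_STATES, STATE_SPACE)

#: Binary covariates in canonical order (reference level = 0 for each;
#: sex is coded as ``male`` with female as reference).
BINARY_COVARIATES: tuple[str, ...] = (
    "male", "heart_failure", "cancer", "hypertension", "diabetes")

#: Albuminuria strata labels (cohort stratifier, not a model covariate).
STRATA: tuple[str, ...] = ("unmeasured", "normo", "micro", "macro")

REFERENCE_AGE = 60.0


@dataclass(frozen=True)
class CovariateProfile:
    """Fixed covariates of a patient plus age at study entry."""

    male: int = 0
    heart_failure: int = 0
    cancer: int = 0
    hypertension: int = 0
    diabetes: int = 0
    age_at_entry: float = REFERENCE_AGE
    albuminuria_stratum: str = "unmeasured"

    def __post_init__(self) -> None:
        for name in BINARY_COVARIATES:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"covariate {name} must be 0/1, got {v!r}")
        if self.age_at_entry < 18:
            raise ValueError("age_at_entry must be >= 18")
        if self.albuminuria_stratum not in STRATA:
            raise ValueError(
                f"unknown albuminuria stratum {self.albuminuria_stratum!r}; "
                f"expected one of {STRATA}")

    def age_at(self, elapsed_years: float) -> float:
        """Age after *elapsed_years* of follow-up (annually updated age)."""
        return self.age_at_entry + elapsed_years

    def value(self, covariate: str) -> int:
        return int(getattr(self, covariate))


REFERENCE_PROFILE = CovariateProfile()


@dataclass(frozen=True)
class Multiplier:
    """Covariate effect: hazard ratios on progression and death intensities."""

    progression: float
    death: float
    progression_ci: tuple[float, float] | None = None
    death_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.progression <= 0 or self.death <= 0:
            raise ValueError("multipliers must be positive")
        for point, ci in ((self.progression, self.progression_ci),
                          (self.death, self.death_ci)):
            if ci is not None and not (ci[0] <= point <= ci[1]):
                raise ValueError(f"CI {ci} does not bracket point {point}")


#: A full multiplier set maps covariate name (including "age") -> Multiplier.
MultiplierSet = dict[str, Multiplier]

UNIT_MULTIPLIER = Multiplier(1.0, 1.0)


def emission_support(band_width: int = 2) -> np.ndarray:
    """Boolean (6, 6) support mask of the misclassification matrix.

    A living stage may be observed as any living stage within *band_width*
    stages of the truth; death is observed exactly.
    """
    if band_width < 0:
        raise ValueError("band_width must be non-negative")
    mask = np.zeros((N_STATES, N_STATES), dtype=bool)
    for r in range(N_LIVING):
        for s in range(N_LIVING):
            if abs(r - s) <= band_width:
                mask[r, s] = True
    mask[DEATH_INDEX, DEATH_INDEX] = True
    return mask


@dataclass(frozen=True)
class ModelParameters:
    """Baseline intensities, covariate multipliers and misclassification.

    Parameters
    ----------
    progression_rates
        Four rates/year: G1/2->G3a, G3a->G3b, G3b->G4, G4->G5 for the
        reference profile (woman aged 60, no comorbidities).
    death_rates
        Five rates/year: each living stage -> death, reference profile.
    multipliers
        Mapping of covariate name -> :class:`Multiplier`.  The special key
        ``"age"`` holds the per-year-of-age multipliers applied as
        ``m ** (age - 60)``; binary covariates apply their multiplier when
        the indicator is 1.  Missing covariates default to no effect.
    emission
        Row-stochastic (6, 6) misclassification matrix
        ``E[r, s] = P(observed stage s | true stage r)``.
    band_width
        Half-width of the permitted misclassification band (default 2).
    """

    progression_rates: np.ndarray
    death_rates: np.ndarray
    multipliers: MultiplierSet = field(default_factory=dict)
    emission: np.ndarray | None = None
    band_width: int = 2
    cohort: str = "unmeasured"

    def __post_init__(self) -> None:
        prog = np.asarray(self.progression_rates, dtype=float)
        death = np.asarray(self.death_rates, dtype=float)
        object.__setattr__(self, "progression_rates", prog)
        object.__setattr__(self, "death_rates", death)
        if prog.shape != (N_LIVING - 1,):
            raise ValueError("expected 4 progression rates")
        if death.shape != (N_LIVING,):
            raise ValueError("expected 5 death rates")
        if (prog < 0).any() or (death < 0).any():
            raise ValueError("baseline rates must be non-negative")
        for name in self.multipliers:
            if name != "age" and name not in BINARY_COVARIATES:
                raise ValueError(f"unknown covariate {name!r}")
        if self.emission is None:
            object.__setattr__(self, "emission", np.eye(N_STATES))
        else:
            E = np.asarray(self.emission, dtype=float)
            object.__setattr__(self, "emission", E)
            validate_emission(E, self.band_width)

    def multiplier(self, covariate: str) -> Multiplier:
        return self.multipliers.get(covariate, UNIT_MULTIPLIER)

    def rate_scale(self, profile: CovariateProfile, age: float) -> tuple[float, float]:
        """Joint multiplicative factors (progression, death) for a profile."""
        age_m = self.multiplier("age")
        fp = age_m.progression ** (age - REFERENCE_AGE)
        fd = age_m.death ** (age - REFERENCE_AGE)
        for name in BINARY_COVARIATES:
            if profile.value(name):
                m = self.multiplier(name)
                fp *= m.progression
                fd *= m.death
        return fp, fd

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


def validate_emission(E: np.ndarray, band_width: int = 2,
                      atol: float = 1e-10) -> None:
    """Raise ``ValueError`` unless *E* is a valid misclassification matrix."""
    E = np.asarray(E, dtype=float)
    if E.shape != (N_STATES, N_STATES):
        raise ValueError(f"emission matrix must be {N_STATES}x{N_STATES}")
    if (E < -atol).any() or (E > 1 + atol).any():
        raise ValueError("emission entries must lie in [0, 1]")
    if not np.allclose(E.sum(axis=1), 1.0, atol=atol):
        raise ValueError("emission rows must sum to 1")
    support = emission_support(band_width)
    bad = (~support) & (np.abs(E) > atol)
    if bad.any():
        r, s = np.argwhere(bad)[0]
        raise ValueError(
            f"emission support violation: P(observed {ALL_STATES[s]} | "
            f"true {ALL_STATES[r]}) must be 0 (band width {band_width})")


# ---------------------------------------------------------------------------
# Flat key-value (YAML) serialisation
# ---------------------------------------------------------------------------

_PROG_KEYS = [f"rate.{LIVING_STAGES[r]}.{LIVING_STAGES[r + 1]}"
              for r in range(N_LIVING - 1)]
_DEATH_KEYS = [f"rate.{s}.DEATH" for s in LIVING_STAGES]


def parameters_to_dict(params: ModelParameters) -> dict:
    """Flatten :class:`ModelParameters` to a plain key-value mapping."""
    out: dict[str, float | int | str] = {
        "cohort": params.cohort,
        "band_width": int(params.band_width),
    }
    for key, v in zip(_PROG_KEYS, params.progression_rates):
        out[key] = float(v)
    for key, v in zip(_DEATH_KEYS, params.death_rates):
        out[key] = float(v)
    for name, m in sorted(params.multipliers.items()):
        out[f"mult.{name}.progression"] = float(m.progression)
        out[f"mult.{name}.death"] = float(m.death)
    support = emission_support(params.band_width)
    for r in range(N_LIVING):
        for s in range(N_LIVING):
            if support[r, s]:
                out[f"emission.{ALL_STATES[r]}.{ALL_STATES[s]}"] = float(
                    params.emission[r, s])
    return out


def parameters_from_dict(data: dict) -> ModelParameters:
    """Inverse of :func:`parameters_to_dict`."""
    band = int(data.get("band_width", 2))
    prog = np.array([float(data[k]) for k in _PROG_KEYS])
    death = np.array([float(data[k]) for k in _DEATH_KEYS])
    mults: MultiplierSet = {}
    names = {k.split(".")[1] for k in data if k.startswith("mult.")}
    for name in names:
        mults[name] = Multiplier(
            progression=float(data[f"mult.{name}.progression"]),
            death=float(data[f"mult.{name}.death"]))
    E = np.zeros((N_STATES, N_STATES))
    E[DEATH_INDEX, DEATH_INDEX] = 1.0
    for key, value in data.items():
        if key.startswith("emission."):
            _, true_s, obs_s = key.split(".")
            E[STATE_SPACE.index(true_s), STATE_SPACE.index(obs_s)] = float(value)
    # rows not mentioned at all default to exact classification
    for r in range(N_LIVING):
        if E[r].sum() == 0:
            E[r, r] = 1.0
    return ModelParameters(progression_rates=prog, death_rates=death,
                           multipliers=mults, emission=E, band_width=band,
                           cohort=str(data.get("cohort", "unmeasured")))


def save_parameters(params: ModelParameters, path) -> None:
    """Write parameters to a flat YAML key-value file (UTF-8 text)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(parameters_to_dict(params), fh, sort_keys=True)


def load_parameters(path) -> ModelParameters:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return parameters_from_dict(data)
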