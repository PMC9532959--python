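"""Default parameter presets and population mixes per albuminuria stratum.

The synthetic-cohort generator needs a complete set of "true" model
parameters and a population composition for each of the four albuminuria
strata (unmeasured, normo-, micro-, macroalbuminuria).  Published anchors
pin part of each preset: reference-profile one-year probabilities for the
unmeasured cohort (G1/2 -> G3a 1.1%, G1/2 -> death 0.7%, G3b -> G4 1.0%,
correct classification of true G1/2 97.1% with 2.9% read as G3a), per-year
age multipliers 1.08 (kidney function) and 1.09 (death), and per-stratum
one-year progression probabilities inside the ranges 0.75-1.3%, 1.5-2.5%,
3.4-5.4% and 3.1-11.9%.  Values the source material does not pin (remaining
death rates, the other emission rows, binary-covariate multipliers) are
stated modelling assumptions, documented in docs/methods.md, chosen once
for realism — e.g. under-grading mass exceeding over-grading mass, and
sojourn times shrinking with stage severity.

Baseline *intensities* are calibrated by root-finding so that the one-year
transition *probabilities* of the reference profile equal the preset annual
targets exactly (probabilities, not rates, are what the model diagrams
print).

Population mixes (age bands, covariate prevalences, initial stage
distribution) follow the printed baseline characteristics of each cohort.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import root

from .matrices import build_intensity_matrix, transition_probability_matrix
from .parameters import ModelParameters, Multiplier
from .states import DEATH_INDEX, N_LIVING

#: One-year reference-profile target probabilities (fractions) per stratum:
#: four progression entries and five death entries of P(1).
ANNUAL_TARGETS: dict[str, dict[str, list[float]]] = {
    "unmeasured": {
        "progression": [0.011, 0.0125, 0.010, 0.008],
        "death": [0.007, 0.010, 0.016, 0.028, 0.065],
    },
    "normo": {
        "progression": [0.022, 0.025, 0.020, 0.016],
        "death": [0.008, 0.012, 0.019, 0.032, 0.080],
    },
    "micro": {
        "progression": [0.034, 0.042, 0.050, 0.036],
        "death": [0.010, 0.015, 0.025, 0.040, 0.100],
    },
    "macro": {
        "progression": [0.031, 0.055, 0.090, 0.115],
        "death": [0.012, 0.020, 0.035, 0.060, 0.120],
    },
}

#: Shared covariate multipliers (progression, death).  Age per year of age;
#: hypertension and diabetes have no independent effect.
DEFAULT_MULTIPLIERS: dict[str, tuple[float, float]] = {
    "age": (1.08, 1.09),
    "male": (1.20, 1.40),
    "heart_failure": (1.40, 2.00),
    "cancer": (1.15, 1.90),
    "hypertension": (1.00, 1.00),
    "diabetes": (1.00, 1.00),
}

#: Misclassification rows (living 5x5 block); each row sums to 1 and is
#: supported on the +/-2 stage band.
EMISSION_ROWS: dict[str, list[list[float]]] = {
    "unmeasured": [
        [0.971, 0.029, 0.000, 0.000, 0.000],
        [0.280, 0.655, 0.060, 0.005, 0.000],
        [0.010, 0.170, 0.750, 0.065, 0.005],
        [0.000, 0.010, 0.120, 0.820, 0.050],
        [0.000, 0.000, 0.010, 0.130, 0.860],
    ],
    "normo": [
        [0.965, 0.033, 0.002, 0.000, 0.000],
        [0.290, 0.640, 0.065, 0.005, 0.000],
        [0.010, 0.170, 0.740, 0.070, 0.010],
        [0.000, 0.010, 0.120, 0.810, 0.060],
        [0.000, 0.000, 0.010, 0.130, 0.860],
    ],
    "micro": [
        [0.955, 0.040, 0.005, 0.000, 0.000],
        [0.270, 0.640, 0.080, 0.010, 0.000],
        [0.015, 0.160, 0.720, 0.090, 0.015],
        [0.000, 0.010, 0.120, 0.800, 0.070],
        [0.000, 0.000, 0.010, 0.130, 0.860],
    ],
    "macro": [
        [0.955, 0.040, 0.005, 0.000, 0.000],
        [0.250, 0.660, 0.080, 0.010, 0.000],
        [0.015, 0.160, 0.730, 0.085, 0.010],
        [0.000, 0.010, 0.110, 0.820, 0.060],
        [0.000, 0.000, 0.010, 0.120, 0.870],
    ],
}

#: Baseline observed-stage mix used as the initial true-stage distribution.
INITIAL_STAGE_DISTRIBUTION: dict[str, list[float]] = {
    "unmeasured": [0.793, 0.154, 0.044, 0.008, 0.001],
    "normo": [0.731, 0.181, 0.072, 0.016, 0.001],
    "micro": [0.597, 0.210, 0.141, 0.051, 0.003],
    "macro": [0.557, 0.195, 0.155, 0.084, 0.009],
}

#: Baseline covariate prevalences per stratum.
COVARIATE_PREVALENCE: dict[str, dict[str, float]] = {
    "unmeasured": {"male": 0.449, "heart_failure": 0.008, "cancer": 0.020,
                   "hypertension": 0.213, "diabetes": 0.029},
    "normo": {"male": 0.517, "heart_failure": 0.004, "cancer": 0.007,
              "hypertension": 0.095, "diabetes": 0.055},
    "micro": {"male": 0.537, "heart_failure": 0.004, "cancer": 0.004,
              "hypertension": 0.069, "diabetes": 0.057},
    "macro": {"male": 0.538, "heart_failure": 0.003, "cancer": 0.004,
              "hypertension": 0.060, "diabetes": 0.039},
}

#: Age bands (lower, upper) and per-stratum weights (%).
AGE_BANDS: list[tuple[float, float]] = [
    (18, 40), (40, 50), (50, 60), (60, 70), (70, 80), (80, 90), (90, 100)]
AGE_BAND_WEIGHTS: dict[str, list[float]] = {
    "unmeasured": [13.2, 16.9, 21.8, 21.9, 16.7, 8.1, 1.3],
    "normo": [7.1, 12.7, 19.4, 26.2, 22.7, 10.4, 1.6],
    "micro": [4.9, 9.1, 15.1, 21.4, 25.1, 19.6, 4.9],
    "macro": [9.1, 12.0, 17.6, 21.8, 20.6, 15.2, 3.7],
}


def calibrate_rates(annual_progression: np.ndarray,
                    annual_death: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve for baseline intensities hitting one-year target probabilities.

    Finds the nine rates/year such that the one-year transition matrix of
    the reference profile satisfies ``P(1)[r, r+1] = annual_progression[r]``
    and ``P(1)[r, DEATH] = annual_death[r]``.  Deterministic; for the small
    probabilities involved the map is near-identity and the solve is exact
    to root-finder precision.
    """
    targets = np.concatenate([annual_progression, annual_death])

    def residual(log_rates: np.ndarray) -> np.ndarray:
        rates = np.exp(log_rates)
        params = ModelParameters(progression_rates=rates[:4],
                                 death_rates=rates[4:])
        P1 = transition_probability_matrix(
            build_intensity_matrix(params), 1.0)
        got = np.concatenate([
            [P1[r, r + 1] for r in range(N_LIVING - 1)],
            [P1[r, DEATH_INDEX] for r in range(N_LIVING)]])
        return got - targets

    x0 = np.log(-np.log1p(-targets))  # exact for an isolated transition
    sol = root(residual, x0, method="hybr", tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"rate calibration failed: {sol.message}")
    rates = np.exp(sol.x)
    return rates[:4], rates[4:]


@lru_cache(maxsize=None)
def preset_parameters(stratum: str) -> ModelParameters:
    """Full generating :class:`ModelParameters` for a stratum preset."""
    if stratum not in ANNUAL_TARGETS:
        raise ValueError(f"unknown stratum {stratum!r}")
    t = ANNUAL_TARGETS[stratum]
    prog, death = calibrate_rates(np.array(t["progression"]),
                                  np.array(t["death"]))
    E = np.zeros((6, 6))
    E[:N_LIVING, :N_LIVING] = np.array(EMISSION_ROWS[stratum])
    E[DEATH_INDEX, DEATH_INDEX] = 1.0
    mults = {name: Multiplier(*pd_) for name, pd_ in
             DEFAULT_MULTIPLIERS.items()}
    return ModelParameters(progression_rates=prog, death_rates=death,
                           multipliers=mults, emission=E, band_width=2,
                           cohort=stratum)


def preset_population(stratum: str) -> dict:
    """Population composition (sampling mix) for a stratum preset."""
    if stratum not in ANNUAL_TARGETS:
        raise ValueError(f"unknown stratum {stratum!r}")
    w = np.asarray(AGE_BAND_WEIGHTS[stratum], dtype=float)
    pi0 = np.asarray(INITIAL_STAGE_DISTRIBUTION[stratum], dtype=float)
    return {
        "prevalence": dict(COVARIATE_PREVALENCE[stratum]),
        "age_bands": list(AGE_BANDS),
        "age_band_weights": (w / w.sum()).tolist(),
        "initial_distribution": (pi0 / pi0.sum()).tolist(),
    }
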