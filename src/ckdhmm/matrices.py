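"""Intensity, transition and misclassification matrices.

The true stage process is a continuous-time Markov chain on the six states
G1/2 < G3a < G3b < G4 < G5 < DEATH with permitted instantaneous transitions
stage k -> stage k+1 (progression) and stage k -> DEATH only: the chain is
uni-directional with an absorbing death state, so the intensity matrix Q is
upper triangular.  Interval transition probabilities are P(t) = expm(t Q).

The public :func:`transition_probability_matrix` uses scipy's
scaling-and-squaring matrix exponential.  Because Q is triangular its
exponential also has a closed eigendecomposition form, implemented here in a
batched variant (`tri_eig_living` / `p_living`) that the likelihood engine
uses for speed; the two routes are cross-checked in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .parameters import (CovariateProfile, ModelParameters, emission_support,
                         validate_emission)
from .states import (ALL_STATES, DEATH_INDEX, DISPLAY_LABELS, LIVING_STAGES,
                     N_LIVING, N_STATES, STATE_SPACE)

# boolean mask of permitted off-diagonal intensities
PERMITTED_TRANSITIONS = np.zeros((N_STATES, N_STATES), dtype=bool)
for _r in range(N_LIVING - 1):
    PERMITTED_TRANSITIONS[_r, _r + 1] = True
for _r in range(N_LIVING):
    PERMITTED_TRANSITIONS[_r, DEATH_INDEX] = True


@dataclass(frozen=True)
class IntensityMatrix:
    """Validated 6x6 intensity matrix (rates/year) of the stage process."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", Q)
        validate_intensity(Q)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.matrix, dtype=dtype)

    @property
    def progression_rates(self) -> np.ndarray:
        return np.array([self.matrix[r, r + 1] for r in range(N_LIVING - 1)])

    @property
    def death_rates(self) -> np.ndarray:
        return self.matrix[:N_LIVING, DEATH_INDEX].copy()

    @property
    def living_block(self) -> np.ndarray:
        """Top-left 5x5 block; its exponential gives living->living mass."""
        return self.matrix[:N_LIVING, :N_LIVING]


@dataclass(frozen=True)
class EmissionMatrix:
    """Row-stochastic misclassification matrix with banded support."""

    matrix: np.ndarray
    band_width: int = 2

    def __post_init__(self) -> None:
        E = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", E)
        validate_emission(E, self.band_width)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.matrix, dtype=dtype)


def validate_intensity(Q: np.ndarray, atol: float = 1e-10) -> None:
    """Raise ``ValueError`` unless *Q* is a valid intensity matrix."""
    if Q.shape != (N_STATES, N_STATES):
        raise ValueError(f"intensity matrix must be {N_STATES}x{N_STATES}")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < -atol).any():
        raise ValueError("off-diagonal intensities must be non-negative")
    if (np.abs(off[~PERMITTED_TRANSITIONS]) > atol).any():
        raise ValueError("non-zero intensity on a forbidden transition")
    if not np.allclose(Q.sum(axis=1), 0.0, atol=atol):
        raise ValueError("intensity rows must sum to 0")
    if (np.abs(Q[DEATH_INDEX]) > atol).any():
        raise ValueError("death row must be zero (absorbing state)")


def build_intensity_matrix(params: ModelParameters,
                           profile: CovariateProfile | None = None,
                           age: float | None = None) -> IntensityMatrix:
    """Intensity matrix for a covariate profile at a given (current) age.

    Permitted entries are ``baseline_rate * prod(covariate multipliers) *
    age_multiplier ** (age - 60)``; the diagonal is minus the row sum and the
    death row is zero.
    """
    if profile is None:
        profile = CovariateProfile()
    if age is None:
        age = profile.age_at_entry
    # annually updated age is floored, so allow the floored entry age
    if age < np.floor(profile.age_at_entry) - 1e-9:
        raise ValueError("age must not precede the age at entry")
    fp, fd = params.rate_scale(profile, age)
    Q = np.zeros((N_STATES, N_STATES))
    for r in range(N_LIVING - 1):
        Q[r, r + 1] = params.progression_rates[r] * fp
    for r in range(N_LIVING):
        Q[r, DEATH_INDEX] = params.death_rates[r] * fd
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return IntensityMatrix(Q)


def transition_probability_matrix(Q: IntensityMatrix | np.ndarray,
                                  t: float) -> np.ndarray:
    """Row-stochastic interval transition matrix ``P(t) = expm(t Q)``."""
    if t < 0:
        raise ValueError("time must be non-negative")
    Qm = np.asarray(Q, dtype=float)
    P = expm(t * Qm)
    # clean numerical noise: clamp into [0, 1]
    P = np.clip(P, 0.0, 1.0)
    return P


def build_emission_matrix(misclass_params: dict[tuple[str, str], float],
                          band_width: int = 2) -> EmissionMatrix:
    """Misclassification matrix from off-diagonal probabilities.

    Parameters
    ----------
    misclass_params
        Mapping ``(true stage, observed stage) -> probability`` for the
        off-diagonal entries; diagonal entries are the complements.  Entries
        outside the permitted band, or rows whose off-diagonal mass exceeds
        1, are rejected.
    """
    support = emission_support(band_width)
    E = np.zeros((N_STATES, N_STATES))
    E[DEATH_INDEX, DEATH_INDEX] = 1.0
    for (true_s, obs_s), p in misclass_params.items():
        r, s = STATE_SPACE.index(true_s), STATE_SPACE.index(obs_s)
        if r == s:
            raise ValueError("only off-diagonal probabilities may be given")
        if not support[r, s]:
            raise ValueError(
                f"P(observed {obs_s} | true {true_s}) is outside the "
                f"permitted +/-{band_width} stage band")
        if not 0 <= p <= 1:
            raise ValueError("misclassification probabilities must be in [0, 1]")
        E[r, s] = p
    for r in range(N_LIVING):
        off = E[r].sum()
        if off > 1 + 1e-12:
            raise ValueError(
                f"misclassification mass for true {ALL_STATES[r]} exceeds 1")
        E[r, r] = 1.0 - off
    return EmissionMatrix(E, band_width)


def mean_sojourn(Q: IntensityMatrix | np.ndarray) -> np.ndarray:
    """Mean years spent in each living stage before leaving it.

    The sojourn time in stage r is ``-1 / q_rr``; a stage with zero total
    exit rate has infinite sojourn, reported as ``inf`` rather than raising.
    """
    Qm = np.asarray(Q, dtype=float)
    exit_rates = -np.diag(Qm)[:N_LIVING]
    with np.errstate(divide="ignore"):
        out = np.where(exit_rates > 0, 1.0 / np.where(exit_rates > 0,
                                                      exit_rates, 1.0),
                       np.inf)
    return out


def apply_age_multiplier(annual_prob: float, multiplier: float,
                         years: int) -> float:
    """Scale an annual transition probability by an age multiplier.

    Returns ``annual_prob * multiplier ** years`` capped at 1.  This is the
    presentation-level convention of quoting annual probabilities at older
    ages; it is an approximation valid for small probabilities — the
    rigorous covariate effect acts multiplicatively on the intensities.
    """
    if not 0 <= annual_prob <= 1:
        raise ValueError("annual_prob must be a probability")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if years < 0:
        raise ValueError("years must be non-negative")
    out = annual_prob * multiplier ** years
    if out > 1:
        warnings.warn("scaled probability exceeds 1; capped", RuntimeWarning,
                      stacklevel=2)
        out = 1.0
    return out


def annual_transition_diagram(params: ModelParameters,
                              profile: CovariateProfile | None = None,
                              age: float | None = None) -> pd.DataFrame:
    """One-year transition and misclassification probabilities per stage.

    One row per living stage with the one-year probabilities of staying,
    moving to the next stage, and dying (entries of ``P(1)``), followed by
    the misclassification probabilities ``P(observed s | true r)``.  Stay,
    next-stage and death probabilities sum to 1 up to the (small) mass of
    multi-step transitions within the year.
    """
    Q = build_intensity_matrix(params, profile, age)
    P1 = transition_probability_matrix(Q, 1.0)
    rows = []
    for r, stage in enumerate(LIVING_STAGES):
        row = {
            "stage": DISPLAY_LABELS[stage],
            "stay": P1[r, r],
            "progress": P1[r, r + 1] if r < N_LIVING - 1 else 0.0,
            "death": P1[r, DEATH_INDEX],
        }
        for s, obs in enumerate(LIVING_STAGES):
            row[f"observed_{obs}"] = params.emission[r, s]
        rows.append(row)
    return pd.DataFrame(rows).set_index("stage")


# ---------------------------------------------------------------------------
# Closed-form exponential of the (triangular) living block, batched.
# ---------------------------------------------------------------------------

def tri_eig_living(q_prog: np.ndarray, q_death: np.ndarray,
                   jitter: float = 1e-9):
    """Eigendecomposition of the 5x5 living block of Q, batched.

    Parameters are arrays ``q_prog (..., 4)`` and ``q_death (..., 5)`` of
    positive-scaled rates.  Returns ``(lam, V, W)`` with ``Q_LL = V diag(lam)
    W`` and ``W = V^{-1}``; all triangular.  Coinciding eigenvalues (exit
    rates) are separated by a tiny deterministic jitter, which perturbs P(t)
    by O(jitter * t) — far below the accuracy that matters here.
    """
    q_prog = np.asarray(q_prog, dtype=float)
    q_death = np.asarray(q_death, dtype=float)
    batch = q_death.shape[:-1]
    exit_rates = q_death.copy()
    exit_rates[..., :-1] += q_prog
    lam = -exit_rates
    # separate tied eigenvalues deterministically
    scale = np.maximum(1.0, np.abs(lam).max(axis=-1, keepdims=True))
    tol = jitter * scale
    d = np.abs(lam[..., :, None] - lam[..., None, :])
    d += np.eye(N_LIVING) * 1e30
    tied = (d < tol[..., None]).any(axis=(-1, -2))
    if np.any(tied):
        offsets = np.arange(N_LIVING) * tol
        lam = np.where(tied[..., None], lam + offsets, lam)
    V = np.zeros(batch + (N_LIVING, N_LIVING))
    W = np.zeros(batch + (N_LIVING, N_LIVING))
    for j in range(N_LIVING):
        V[..., j, j] = 1.0
        for r in range(j - 1, -1, -1):
            V[..., r, j] = (q_prog[..., r] * V[..., r + 1, j]
                            / (lam[..., j] - lam[..., r]))
    for j in range(N_LIVING):
        W[..., j, j] = 1.0
        for r in range(j - 1, -1, -1):
            acc = np.zeros(batch)
            for m in range(r + 1, j + 1):
                acc = acc + V[..., r, m] * W[..., m, j]
            W[..., r, j] = -acc
    return lam, V, W


def p_living(lam: np.ndarray, V: np.ndarray, W: np.ndarray,
             dt: np.ndarray) -> np.ndarray:
    """Living-to-living transition probabilities exp(dt * Q_LL), batched.

    ``lam, V, W`` as returned by :func:`tri_eig_living`; ``dt`` broadcasts
    against their batch shape.  Row deficits from 1 are the probabilities of
    having died.
    """
    dt = np.asarray(dt, dtype=float)
    edt = np.exp(lam * dt[..., None])
    P = (V * edt[..., None, :]) @ W
    return np.clip(P, 0.0, 1.0)


def min_eigen_gap(lam: np.ndarray) -> np.ndarray:
    """Smallest relative pairwise eigenvalue separation per batch element.

    The closed eigen form of the exponential loses accuracy when exit rates
    (nearly) coincide; batches below ~1e-3 here should use the series route.
    """
    d = np.abs(lam[..., :, None] - lam[..., None, :])
    d = np.where(np.eye(N_LIVING, dtype=bool), np.inf, d)
    scale = np.maximum(1.0, np.abs(lam).max(axis=-1))
    return d.min(axis=(-1, -2)) / scale


def expm_taylor_batch(A: np.ndarray, order: int = 12) -> np.ndarray:
    """Batched matrix exponential by scaling, Taylor series and squaring.

    Robust for any (small) batch of square matrices; used as the fallback
    when the triangular eigendecomposition is ill-conditioned (nearly tied
    exit rates).
    """
    A = np.asarray(A, dtype=float)
    norm = np.abs(A).sum(axis=-1).max(axis=-1)
    maxn = float(norm.max()) if A.size else 0.0
    s = max(0, int(np.ceil(np.log2(max(maxn, 1e-300) / 0.5))))
    As = A / (2 ** s)
    n = A.shape[-1]
    eye = np.broadcast_to(np.eye(n), A.shape).copy()
    P = eye.copy()
    term = eye.copy()
    for k in range(1, order + 1):
        term = term @ As / k
        P = P + term
    for _ in range(s):
        P = P @ P
    return P
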