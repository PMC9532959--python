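"""Viterbi decoding of true stage sequences and grading of observations.

Given fitted parameters, the Viterbi dynamic programme finds the most
probable non-decreasing sequence of true stages behind each patient's
observed sequence.  Taking the decoded states as the truth, each eGFR test
is graded: *under-graded* if the observed stage is less severe than the
decoded one, *over-graded* if more severe.  Pooled over a cohort this gives
the probability that any test is misclassified, with Wilson score
intervals (within-patient correlation ignored in the default presentation;
a patient-level bootstrap is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord
from .likelihood import OBS_DEATH, OBS_PROP, LikelihoodOptions, \
    _record_segments
from .matrices import build_intensity_matrix, transition_probability_matrix
from .parameters import ModelParameters
from .states import DEATH_INDEX, LIVING_STAGES, N_LIVING

_Z95 = 1.959963984540054


@dataclass
class DecodedRecord:
    """Observed and decoded stages of one patient, with per-test grading."""

    patient_id: str
    times: np.ndarray
    observed: np.ndarray
    decoded: np.ndarray
    grading: np.ndarray  # "correct" | "under" | "over"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.patient_id, "time_years": self.times,
            "observed_stage": [LIVING_STAGES[s] for s in self.observed],
            "decoded_stage": [LIVING_STAGES[s] for s in self.decoded],
            "grading": self.grading})


def _interval_kernels(rec: PatientRecord, params: ModelParameters,
                      options: LikelihoodOptions):
    """Per-observation-interval transition kernels and the death vector.

    Returns ``(mats, death_vec)`` where ``mats[k]`` propagates the living
    distribution from observation k to observation k+1 (sub-intervals at
    integer age anniversaries are composed when the exact age-update
    convention is selected) and ``death_vec`` is ``P(dt) q_death`` for an
    exactly observed death, or None.
    """
    prof = rec.profile
    mats: list[np.ndarray] = []
    death_vec = None
    acc = np.eye(N_LIVING)
    for t0, dt, obs in _record_segments(rec, options.age_update == "exact"):
        age = math.floor(prof.age_at(t0) + 1e-9)
        Q = build_intensity_matrix(params, prof, age).matrix
        P = transition_probability_matrix(Q, dt)
        acc = acc @ P[:N_LIVING, :N_LIVING]
        if obs == OBS_PROP:
            continue
        if obs == OBS_DEATH:
            death_vec = acc @ Q[:N_LIVING, DEATH_INDEX]
        else:
            mats.append(acc)
        acc = np.eye(N_LIVING)
    if death_vec is None:
        # survival weight over the trailing censored window (identity row
        # sums, i.e. weight one, when the record ends at its last test)
        death_vec = None if np.allclose(acc, np.eye(N_LIVING)) \
            else acc.sum(axis=1)
    return mats, death_vec


def viterbi(record: PatientRecord, params: ModelParameters,
            options: LikelihoodOptions | None = None) -> DecodedRecord:
    """Most probable true stage sequence given the observed sequence.

    Maximises the joint probability of the hidden non-decreasing stage
    sequence and the observations (including the death density when the
    record ends in death).  Ties are broken toward the less severe stage.
    A record with no consistent hidden path raises a ``ValueError`` naming
    the offending observation.
    """
    options = options or LikelihoodOptions()
    E = np.asarray(params.emission, dtype=float)
    mats, death_vec = _interval_kernels(record, params, options)
    obs = record.stages
    K = len(obs)
    with np.errstate(divide="ignore"):
        logE = np.log(E[:N_LIVING, :N_LIVING])
    delta = np.full(N_LIVING, -np.inf)
    if options.initial == "first_obs_exact":
        delta[obs[0]] = 0.0
    else:
        pi0 = options.initial_distribution
        if pi0 is None:
            pi0 = np.full(N_LIVING, 1.0 / N_LIVING)
        with np.errstate(divide="ignore"):
            delta = np.log(pi0) + logE[:, obs[0]]
    if not np.isfinite(delta).any():
        raise ValueError(f"patient {record.patient_id}: observation 1 "
                         f"({LIVING_STAGES[obs[0]]}) admits no hidden state")
    back = np.zeros((K, N_LIVING), dtype=int)
    for k in range(1, K):
        with np.errstate(divide="ignore"):
            logP = np.log(np.maximum(mats[k - 1], 0.0))
        cand = delta[:, None] + logP            # (from, to)
        best_from = np.argmax(cand, axis=0)     # first max -> least severe
        delta = cand[best_from, np.arange(N_LIVING)] + logE[:, obs[k]]
        back[k] = best_from
        if not np.isfinite(delta).any():
            raise ValueError(
                f"patient {record.patient_id}: observation {k + 1} "
                f"({LIVING_STAGES[obs[k]]}) is inconsistent with every "
                "non-decreasing hidden path")
    if death_vec is not None:
        # terminal weight: death density, or survival over the censored tail
        with np.errstate(divide="ignore"):
            delta = delta + np.log(np.maximum(death_vec, 0.0))
        if not np.isfinite(delta).any():
            raise ValueError(f"patient {record.patient_id}: the terminal "
                             "event is inconsistent with every hidden path")
    states = np.empty(K, dtype=int)
    states[-1] = int(np.argmax(delta))
    for k in range(K - 1, 0, -1):
        states[k - 1] = back[k, states[k]]
    grading = np.where(obs < states, "under",
                       np.where(obs > states, "over", "correct"))
    return DecodedRecord(patient_id=record.patient_id,
                         times=record.times.copy(), observed=obs.copy(),
                         decoded=states, grading=grading)


def decode_cohort(cohort: Cohort, params: ModelParameters,
                  options: LikelihoodOptions | None = None
                  ) -> list[DecodedRecord]:
    return [viterbi(rec, params, options) for rec in cohort]


@dataclass
class GradingReport:
    """Pooled under-/over-grading percentages with 95% CIs."""

    n_tests: int
    n_under: int
    n_over: int
    under_pct: float
    under_ci: tuple[float, float]
    over_pct: float
    over_ci: tuple[float, float]
    total_pct: float
    total_ci: tuple[float, float]

    @property
    def n_total(self) -> int:
        return self.n_under + self.n_over

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [("under", self.n_under, self.under_pct, *self.under_ci),
             ("over", self.n_over, self.over_pct, *self.over_ci),
             ("total", self.n_total, self.total_pct, *self.total_ci)],
            columns=["grading", "count", "percent", "lower", "upper"])


def _wilson(k: int, n: int, z: float = _Z95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (as fractions)."""
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def grading_rates(cohort: Cohort, params: ModelParameters,
                  options: LikelihoodOptions | None = None,
                  bootstrap: int | None = None,
                  seed: int = 0) -> GradingReport:
    """Cohort-level misclassification accounting from Viterbi decoding.

    All eGFR tests are pooled across patients (death is excluded from the
    denominator: it is always classified correctly and is not a test).
    With ``bootstrap`` set, CIs come from a patient-level bootstrap with
    that many replicates instead of the Wilson interval.
    """
    if len(cohort) == 0:
        raise ValueError("cannot grade an empty cohort")
    decoded = decode_cohort(cohort, params, options)
    per_pat = [(int((d.grading == "under").sum()),
                int((d.grading == "over").sum()), len(d.grading))
               for d in decoded]
    n_under = sum(u for u, _o, _n in per_pat)
    n_over = sum(o for _u, o, _n in per_pat)
    n = sum(nn for _u, _o, nn in per_pat)
    pct = lambda k: 100.0 * k / n
    if bootstrap:
        rng = np.random.default_rng(seed)
        arr = np.asarray(per_pat, dtype=float)
        reps = np.empty((bootstrap, 3))
        for b in range(bootstrap):
            take = arr[rng.integers(0, len(arr), len(arr))]
            tot = take[:, 2].sum()
            reps[b] = [100 * take[:, 0].sum() / tot,
                       100 * take[:, 1].sum() / tot,
                       100 * (take[:, 0] + take[:, 1]).sum() / tot]
        ci = lambda j: tuple(np.percentile(reps[:, j], [2.5, 97.5]))
        under_ci, over_ci, total_ci = ci(0), ci(1), ci(2)
    else:
        scale = lambda ci: (100 * ci[0], 100 * ci[1])
        under_ci = scale(_wilson(n_under, n))
        over_ci = scale(_wilson(n_over, n))
        total_ci = scale(_wilson(n_under + n_over, n))
    return GradingReport(
        n_tests=n, n_under=n_under, n_over=n_over,
        under_pct=pct(n_under), under_ci=under_ci,
        over_pct=pct(n_over), over_ci=over_ci,
        total_pct=pct(n_under + n_over), total_ci=total_ci)
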