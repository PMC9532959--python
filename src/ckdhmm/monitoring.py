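"""Monitoring-policy metrics and split-sample calibration.

Monitoring metrics answer: if a patient currently in stage G3a or G3b is
re-tested after 6, 12 or 36 months, how likely has true kidney function
progressed, how likely does the test detect a true progression (true
positive), and how likely does it signal a change when nothing changed
(false positive, driven entirely by misclassification)?

Calibration compares, on a held-out cohort, the model-predicted
distribution of each test's eGFR category (conditional on the patient's
prior observations and on being alive at the test) with the category
actually recorded, aggregated in time bins.
"""

from __future__ import annotations

import math
from collections import namedtuple

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord
from .likelihood import LikelihoodOptions
from .matrices import build_intensity_matrix, transition_probability_matrix
from .parameters import CovariateProfile, ModelParameters
from .states import DEATH_INDEX, LIVING_STAGES, N_LIVING, STATE_SPACE

_EPS = 1e-9


def _stage_index(stage) -> int:
    if isinstance(stage, str):
        idx = STATE_SPACE.index(stage)
    else:
        idx = int(stage)
    if idx >= N_LIVING:
        raise ValueError("baseline stage must be a living stage")
    return idx


def _kernel(params: ModelParameters, profile: CovariateProfile,
            t0: float, t1: float, age_update: str) -> np.ndarray:
    """Full 6x6 transition kernel from time t0 to t1 of a profile."""
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    cuts = [t0]
    if age_update == "exact":
        a0 = profile.age_at(t0)
        b = t0 + (math.floor(a0 + _EPS) + 1.0 - a0)
        while b < t1 - _EPS:
            cuts.append(b)
            b += 1.0
    cuts.append(t1)
    P = np.eye(N_LIVING + 1)
    for a, b in zip(cuts[:-1], cuts[1:]):
        age = math.floor(profile.age_at(a) + _EPS)
        Q = build_intensity_matrix(params, profile, age)
        P = P @ transition_probability_matrix(Q, b - a)
    return P


def progression_probability(params: ModelParameters, stage,
                            profile: CovariateProfile | None = None,
                            horizon_years: float = 1.0,
                            include_death: bool = False,
                            age_update: str = "interval_start") -> float:
    """P(true stage at the horizon is strictly more severe than *stage*).

    By default death is excluded (reported separately via
    :func:`death_probability`); ``include_death`` folds it in as the most
    severe outcome.
    """
    r = _stage_index(stage)
    if horizon_years < 0:
        raise ValueError("horizon must be non-negative")
    profile = profile or CovariateProfile()
    P = _kernel(params, profile, 0.0, horizon_years, age_update)
    prob = float(P[r, r + 1:N_LIVING].sum())
    if include_death:
        prob += float(P[r, DEATH_INDEX])
    return prob


def death_probability(params: ModelParameters, stage,
                      profile: CovariateProfile | None = None,
                      horizon_years: float = 1.0,
                      age_update: str = "interval_start") -> float:
    r = _stage_index(stage)
    profile = profile or CovariateProfile()
    P = _kernel(params, profile, 0.0, horizon_years, age_update)
    return float(P[r, DEATH_INDEX])


DetectionProbabilities = namedtuple("DetectionProbabilities",
                                    ["true_positive", "false_positive"])


def detection_probabilities(params: ModelParameters, stage,
                            profile: CovariateProfile | None = None,
                            horizon_years: float = 1.0,
                            fp_any_change: bool = True,
                            age_update: str = "interval_start"
                            ) -> DetectionProbabilities:
    """True/false positive probabilities of a single test at the horizon.

    true positive: P(observed stage more severe than baseline | true stage
    progressed to a more severe living stage).  false positive: P(observed
    stage differs from baseline | true stage unchanged) — any observed
    change by default; with ``fp_any_change=False`` only observed changes
    in the progression direction count.
    """
    r = _stage_index(stage)
    profile = profile or CovariateProfile()
    E = np.asarray(params.emission, dtype=float)
    P = _kernel(params, profile, 0.0, horizon_years, age_update)
    w = P[r, r + 1:N_LIVING]            # occupancy of more severe living stages
    denom = w.sum()
    if denom > 0:
        detect = np.array([E[s, r + 1:N_LIVING].sum()
                           for s in range(r + 1, N_LIVING)])
        tp = float(w @ detect / denom)
    else:
        tp = float("nan")
    if fp_any_change:
        fp = float(E[r, :N_LIVING].sum() - E[r, r])
    else:
        fp = float(E[r, r + 1:N_LIVING].sum())
    return DetectionProbabilities(true_positive=tp, false_positive=fp)


def monitoring_report(params: ModelParameters,
                      profile: CovariateProfile | None = None,
                      stages=("G3A", "G3B"),
                      horizons_months=(6, 12, 36),
                      age_update: str = "interval_start") -> pd.DataFrame:
    """Progression/detection metrics per baseline stage and horizon."""
    profile = profile or CovariateProfile()
    rows = []
    for stage in stages:
        for months in horizons_months:
            h = months / 12.0
            prog = progression_probability(params, stage, profile, h,
                                           age_update=age_update)
            dp = death_probability(params, stage, profile, h,
                                   age_update=age_update)
            det = detection_probabilities(params, stage, profile, h,
                                          age_update=age_update)
            det_dir = detection_probabilities(params, stage, profile, h,
                                              fp_any_change=False,
                                              age_update=age_update)
            rows.append({
                "cohort": params.cohort, "stage": stage,
                "horizon_months": months, "progression": prog,
                "death": dp, "true_positive": det.true_positive,
                "false_positive": det.false_positive,
                "false_positive_directional": det_dir.false_positive})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Filtering, forecasting, calibration
# ---------------------------------------------------------------------------

def _filtered_distribution(record: PatientRecord, params: ModelParameters,
                           options: LikelihoodOptions, upto: int
                           ) -> np.ndarray:
    """Filtered living-stage distribution after observations 1..*upto*.

    Normalised over living stages (conditional on being alive at the last
    used observation).
    """
    E = np.asarray(params.emission, dtype=float)
    obs = record.stages
    if options.initial == "first_obs_exact":
        alpha = np.zeros(N_LIVING)
        alpha[obs[0]] = 1.0
    else:
        pi0 = options.initial_distribution
        if pi0 is None:
            pi0 = np.full(N_LIVING, 1.0 / N_LIVING)
        alpha = pi0 * E[:N_LIVING, obs[0]]
        if alpha.sum() <= 0:
            raise ValueError("first observation impossible under the model")
        alpha = alpha / alpha.sum()
    for k in range(1, upto):
        P = _kernel(params, record.profile, record.times[k - 1],
                    record.times[k], options.age_update)
        alpha = (alpha @ P[:N_LIVING, :N_LIVING]) * E[:N_LIVING, obs[k]]
        s = alpha.sum()
        if s <= 0:
            raise ValueError(
                f"patient {record.patient_id}: observation {k + 1} is "
                "impossible under the model")
        alpha = alpha / s
    return alpha


def occupancy_forecast(params: ModelParameters, record_prefix: PatientRecord,
                       query_times, options: LikelihoodOptions | None = None
                       ) -> pd.DataFrame:
    """Predicted stage distributions at future times given a record prefix.

    The filtered distribution at the last prefix observation is propagated
    to each query time.  Columns ``state_*`` give the unconditional true
    state occupancy (including death); ``pred_*`` give the predicted
    distribution of an eGFR test's observed category at that time,
    conditional on the patient being alive (mapped through the
    misclassification matrix).
    """
    options = options or LikelihoodOptions()
    E = np.asarray(params.emission, dtype=float)
    t_last = float(record_prefix.times[-1])
    query_times = np.atleast_1d(np.asarray(query_times, dtype=float))
    if (query_times < t_last - _EPS).any():
        raise ValueError("query times must not precede the last prefix "
                         "observation")
    alpha = _filtered_distribution(record_prefix, params, options,
                                   upto=record_prefix.n_obs)
    rows = []
    for t in query_times:
        P = _kernel(params, record_prefix.profile, t_last, t,
                    options.age_update)
        occ_living = alpha @ P[:N_LIVING, :N_LIVING]
        p_death = 1.0 - occ_living.sum()
        alive = occ_living / occ_living.sum() if occ_living.sum() > 0 \
            else occ_living
        pred = alive @ E[:N_LIVING, :N_LIVING]
        row = {"time_years": float(t), "state_DEATH": max(p_death, 0.0)}
        for s, label in enumerate(LIVING_STAGES):
            row[f"state_{label}"] = occ_living[s]
            row[f"pred_{label}"] = pred[s]
        rows.append(row)
    return pd.DataFrame(rows)


def calibration_table(params: ModelParameters, test_cohort: Cohort,
                      bin_width_years: float = 1.0,
                      options: LikelihoodOptions | None = None,
                      condition_on: str = "all_prior") -> pd.DataFrame:
    """Predicted vs observed proportions of tests per eGFR category.

    For every held-out test beyond a patient's first, the predicted
    category distribution comes from the filtered distribution of the
    patient's prior observations propagated to the test time and mapped
    through the misclassification matrix (conditional on being alive,
    which the existence of the test implies).  Proportions are aggregated
    in time bins from entry.  ``condition_on="first_only"`` conditions on
    the first observation alone.  Bins up to the latest test are reported
    even when empty.
    """
    if bin_width_years <= 0:
        raise ValueError("bin width must be positive")
    if condition_on not in ("all_prior", "first_only"):
        raise ValueError("condition_on must be all_prior or first_only")
    options = options or LikelihoodOptions()
    E = np.asarray(params.emission, dtype=float)
    pred_sums: dict[int, np.ndarray] = {}
    obs_counts: dict[int, np.ndarray] = {}
    max_bin = 0
    for rec in test_cohort:
        if rec.n_obs < 2:
            continue
        alpha = _filtered_distribution(rec, params, options, upto=1)
        for k in range(1, rec.n_obs):
            t_prev = rec.times[k - 1] if condition_on == "all_prior" \
                else rec.times[0]
            base = alpha
            P = _kernel(params, rec.profile, t_prev, rec.times[k],
                        options.age_update)
            occ = base @ P[:N_LIVING, :N_LIVING]
            if occ.sum() <= 0:
                raise ValueError(
                    f"patient {rec.patient_id}: zero predicted living mass")
            alive = occ / occ.sum()
            pred = alive @ E[:N_LIVING, :N_LIVING]
            b = int(rec.times[k] // bin_width_years)
            max_bin = max(max_bin, b)
            pred_sums.setdefault(b, np.zeros(N_LIVING))
            obs_counts.setdefault(b, np.zeros(N_LIVING))
            pred_sums[b] += pred
            obs_counts[b][rec.stages[k]] += 1
            if condition_on == "all_prior":
                # advance the filter with the observation just scored
                alpha = occ * E[:N_LIVING, rec.stages[k]]
                alpha = alpha / alpha.sum()
    rows = []
    for b in range(max_bin + 1):
        n = int(obs_counts.get(b, np.zeros(N_LIVING)).sum())
        for s, label in enumerate(LIVING_STAGES):
            rows.append({
                "bin_start_years": b * bin_width_years,
                "category": label,
                "predicted": (pred_sums[b][s] / n) if n else 0.0,
                "observed": (obs_counts[b][s] / n) if n else 0.0,
                "n_tests": n})
    return pd.DataFrame(rows)


def calibration_mae(table: pd.DataFrame, min_tests: int = 1) -> float:
    """Mean absolute predicted-minus-observed proportion per bin-category."""
    use = table[table["n_tests"] >= min_tests]
    if use.empty:
        raise ValueError("no populated calibration bins")
    return float((use["predicted"] - use["observed"]).abs().mean())


def plot_calibration(table: pd.DataFrame, path=None):
    """Calibration plot: predicted vs observed category proportions by bin."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, N_LIVING, figsize=(15, 3), sharey=False)
    for s, (ax, label) in enumerate(zip(axes, LIVING_STAGES)):
        sub = table[(table["category"] == label) & (table["n_tests"] > 0)]
        ax.plot(sub["bin_start_years"], sub["observed"], "o-",
                label="observed")
        ax.plot(sub["bin_start_years"], sub["predicted"], "s--",
                label="predicted")
        ax.set_title(label)
        ax.set_xlabel("years since entry")
        if s == 0:
            ax.set_ylabel("proportion of tests")
            ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120, metadata={"Software": None})
        plt.close(fig)
    return fig
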