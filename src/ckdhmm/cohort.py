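"""Patient records and cohorts of panel-observed eGFR stages.

A record is one patient's irregularly timed sequence of observed eGFR
stages, with fixed covariates, an optional exactly-dated death and an
administrative censoring time.  The on-disk format is a long CSV, one row
per observation, with death encoded as a final row whose observed stage is
``DEATH`` at the death time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import STRATA, CovariateProfile
from .states import ALL_STATES, DEATH, LIVING_STAGES, STATE_SPACE

CSV_COLUMNS = ["patient_id", "time_years", "age_years", "observed_stage",
               "sex", "heart_failure", "cancer", "hypertension", "diabetes",
               "albuminuria_stratum", "censor_years"]

#: columns a cohort CSV must provide; censor_years is optional (defaults to
#: the last event time, i.e. no censored follow-up tail)
REQUIRED_COLUMNS = CSV_COLUMNS[:-1]


@dataclass
class PatientRecord:
    """One patient's observation history.

    ``times``/``stages`` hold the living eGFR observations (stage indices
    0..4); death, if any, is carried separately as an exactly observed time.
    """

    patient_id: str
    profile: CovariateProfile
    times: np.ndarray
    stages: np.ndarray
    censor_time: float
    death_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.stages = np.asarray(self.stages, dtype=int)
        if self.times.shape != self.stages.shape:
            raise ValueError("times and stages must have equal length")
        if len(self.times) == 0:
            raise ValueError("a record needs at least one observation")
        if (np.diff(self.times) <= 0).any():
            raise ValueError(
                f"patient {self.patient_id}: observation times must be "
                "strictly increasing")
        if self.times[0] < 0:
            raise ValueError("observation times must be non-negative")
        if ((self.stages < 0) | (self.stages > 4)).any():
            raise ValueError("observed stages must be living stage indices 0..4")
        if self.death_time is not None and self.death_time <= self.times[-1]:
            raise ValueError(
                f"patient {self.patient_id}: death must follow the last "
                "eGFR observation")
        end = self.death_time if self.death_time is not None else self.times[-1]
        if end > self.censor_time + 1e-9:
            raise ValueError(
                f"patient {self.patient_id}: events exceed the censoring time")

    @property
    def n_obs(self) -> int:
        """Number of eGFR tests (death is not an eGFR test)."""
        return len(self.times)

    @property
    def died(self) -> bool:
        return self.death_time is not None


@dataclass
class Cohort:
    """A set of patient records sharing an albuminuria stratum."""

    records: list[PatientRecord]
    stratum: str = "unmeasured"
    generating_params: object | None = None  # truth, retained for testing
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")
        for r in self.records:
            if r.profile.albuminuria_stratum != self.stratum:
                raise ValueError(
                    f"patient {r.patient_id} has stratum "
                    f"{r.profile.albuminuria_stratum!r}, cohort is "
                    f"{self.stratum!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_observations(self) -> int:
        return sum(r.n_obs for r in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            p = rec.profile
            base = {
                "patient_id": rec.patient_id,
                "sex": p.male,
                "heart_failure": p.heart_failure,
                "cancer": p.cancer,
                "hypertension": p.hypertension,
                "diabetes": p.diabetes,
                "albuminuria_stratum": p.albuminuria_stratum,
                "censor_years": rec.censor_time,
            }
            for t, s in zip(rec.times, rec.stages):
                rows.append({**base, "time_years": t,
                             "age_years": p.age_at(t),
                             "observed_stage": LIVING_STAGES[s]})
            if rec.died:
                rows.append({**base, "time_years": rec.death_time,
                             "age_years": p.age_at(rec.death_time),
                             "observed_stage": DEATH})
        if not rows:
            return pd.DataFrame(columns=CSV_COLUMNS)
        return pd.DataFrame(rows)[CSV_COLUMNS]


def cohort_from_dataframe(df: pd.DataFrame, stratum: str | None = None,
                          censor_times: dict | None = None) -> Cohort:
    """Assemble a :class:`Cohort` from a long-format observation table.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    df = df.reset_index(drop=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    records: list[PatientRecord] = []
    strata_seen = set()
    for pid, g in df.groupby("patient_id", sort=True):
        diffs = g["time_years"].diff().fillna(1.0)
        if (diffs <= 0).any():
            row = int(g.index[diffs <= 0][0]) + 1
            raise ValueError(
                f"row {row}: non-increasing times for patient {pid}")
        stages = []
        death_time = None
        for idx, obs in zip(g.index, g.itertuples()):
            label = str(obs.observed_stage)
            if label not in ALL_STATES:
                raise ValueError(
                    f"row {int(idx) + 1}, column observed_stage: unknown "
                    f"stage label {label!r}")
            if death_time is not None:
                raise ValueError(
                    f"row {int(idx) + 1}: observation after DEATH for "
                    f"patient {pid} (DEATH must be the final row)")
            if label == DEATH:
                death_time = float(obs.time_years)
            else:
                stages.append(STATE_SPACE.index(label))
        n_living = len(stages)
        first = g.iloc[0]
        entry_age = float(first["age_years"]) - float(first["time_years"])
        profile = CovariateProfile(
            male=int(first["sex"]), heart_failure=int(first["heart_failure"]),
            cancer=int(first["cancer"]), hypertension=int(first["hypertension"]),
            diabetes=int(first["diabetes"]), age_at_entry=entry_age,
            albuminuria_stratum=str(first["albuminuria_stratum"]))
        strata_seen.add(profile.albuminuria_stratum)
        times = g["time_years"].to_numpy(dtype=float)[:n_living]
        end = death_time if death_time is not None else float(times[-1])
        censor = end
        if "censor_years" in g.columns and pd.notna(first.get("censor_years")):
            censor = max(end, float(first["censor_years"]))
        if censor_times is not None and pid in censor_times:
            censor = float(censor_times[pid])
        records.append(PatientRecord(
            patient_id=str(pid), profile=profile, times=times,
            stages=np.asarray(stages), censor_time=censor,
            death_time=death_time))
    if stratum is None:
        stratum = strata_seen.pop() if len(strata_seen) == 1 else "unmeasured"
    return Cohort(records=records, stratum=stratum)


def read_cohort_csv(path, stratum: str | None = None) -> Cohort:
    """Read a cohort from the documented long CSV format."""
    df = pd.read_csv(path, dtype={"patient_id": str},
                     float_precision="round_trip")
    if df.empty:
        return Cohort(records=[], stratum=stratum or "unmeasured")
    return cohort_from_dataframe(df, stratum=stratum)


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort to CSV; ``read_cohort_csv`` round-trips it exactly.

    Floats are written at full precision so write-read-write is
    byte-stable.
    """
    df = cohort.to_dataframe()
    df.to_csv(path, index=False)


def split_sample(cohort: Cohort, seed: int) -> "SampleSplit":
    """Pseudo-random split into equal-size training and testing cohorts.

    Patients are partitioned (no overlap, union is the whole cohort); the
    halves differ in size by at most one, with the extra patient going to
    the training set.  Deterministic under *seed*.
    """
    n = len(cohort)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = (n + 1) // 2
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    mk = lambda idx: Cohort(records=[cohort.records[i] for i in idx],
                            stratum=cohort.stratum,
                            generating_params=cohort.generating_params)
    return SampleSplit(train=mk(train_idx), test=mk(test_idx), seed=seed)


@dataclass
class SampleSplit:
    train: Cohort
    test: Cohort
    seed: int


def subsample_patients(cohort: Cohort, n: int, seed: int) -> Cohort:
    """Uniform without-replacement sample of *n* patients."""
    if n > len(cohort):
        raise ValueError(f"cannot sample {n} of {len(cohort)} patients")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(cohort), size=n, replace=False))
    return Cohort(records=[cohort.records[i] for i in idx],
                  stratum=cohort.stratum,
                  generating_params=cohort.generating_params)
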