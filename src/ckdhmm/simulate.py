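"""Synthetic panel-data cohorts with the structure the model assumes.

The generator draws true stage trajectories from the uni-directional
continuous-time Markov chain (intensities refreshed at each integer age
anniversary — annually updated age), schedules eGFR tests under either a
state-independent renewal scheme ("random") or a scheme whose next test gap
depends on the last *observed* stage ("doctor's care"), and emits observed
stages through the misclassification matrix.  Death is recorded exactly;
follow-up is censored administratively at the end of the study window;
patients with fewer than three eGFR tests are dropped, mirroring the
eligibility rule of the source cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .cohort import Cohort, PatientRecord, write_cohort_csv
from .parameters import (BINARY_COVARIATES, CovariateProfile, ModelParameters)
from .presets import preset_parameters, preset_population
from .states import DEATH_INDEX, LIVING_STAGES, N_LIVING

_EPS = 1e-9


@dataclass(frozen=True)
class TruePath:
    """A realised true-stage trajectory.

    ``states[0]`` is the stage at entry; ``jump_times[k]`` is when the
    process moved into ``states[k + 1]``.  The path ends at death or at the
    censoring horizon.
    """

    jump_times: np.ndarray
    states: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        jt = np.asarray(self.jump_times, dtype=float)
        st = np.asarray(self.states, dtype=int)
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "states", st)
        if len(st) != len(jt) + 1:
            raise ValueError("need one more state than jump times")
        if len(jt) and ((np.diff(jt) <= 0).any() or jt[0] <= 0):
            raise ValueError("jump times must be strictly increasing and > 0")
        if (np.diff(st) <= 0).any():
            raise ValueError("true stages can only increase in severity")
        if len(jt) > N_LIVING:
            raise ValueError("too many jumps for a uni-directional path")

    @property
    def death_time(self) -> float | None:
        if len(self.states) and self.states[-1] == DEATH_INDEX:
            return float(self.jump_times[-1])
        return None

    def state_at(self, t: float) -> int:
        """Stage in effect at time *t* (right-continuous at jumps)."""
        if t < 0 or t > self.horizon + _EPS:
            raise ValueError("time outside the path support")
        return int(self.states[np.searchsorted(self.jump_times, t,
                                               side="right")])


@dataclass(frozen=True)
class ObservationScheme:
    """Timing mechanism of eGFR tests.

    kind "random": renewal process with the stated mean gap, independent of
    disease state.  kind "doctors_care": the next gap is looked up by the
    last observed stage (more severe observed disease -> more frequent
    testing) and multiplied by a uniform jitter on
    ``[1 - gap_jitter, 1 + gap_jitter]``.
    """

    kind: str = "random"
    mean_gap: float = 1.0
    distribution: str = "exponential"  # or "fixed"
    gap_by_stage: dict[str, float] = field(default_factory=lambda: {
        "G1_2": 1.0, "G3A": 1.0, "G3B": 0.5, "G4": 0.25, "G5": 0.25})
    gap_jitter: float = 0.2
    include_baseline: bool | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("random", "doctors_care"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "random":
            if self.mean_gap <= 0:
                raise ValueError("mean gap must be positive")
            if self.distribution not in ("exponential", "fixed"):
                raise ValueError("distribution must be exponential or fixed")
        else:
            gaps = [self.gap_by_stage[s] for s in LIVING_STAGES]
            if min(gaps) <= 0:
                raise ValueError("gaps must be positive")
            if (np.diff(gaps) > 0).any():
                raise ValueError(
                    "doctors_care gaps must be non-increasing in severity")
            if not 0 <= self.gap_jitter < 1:
                raise ValueError("gap_jitter must be in [0, 1)")

    @property
    def baseline(self) -> bool:
        if self.include_baseline is None:
            # a doctor's-care schedule is keyed on an observed stage, so it
            # starts from a baseline test; the random scheme need not.
            return self.kind == "doctors_care"
        return self.include_baseline


def simulate_true_path(params: ModelParameters, profile: CovariateProfile,
                       horizon: float, rng, initial_stage: int = 0) -> TruePath:
    """Forward-simulate the true stage process over ``[0, horizon]``.

    Piecewise-constant-rate CTMC simulation: the intensity matrix is
    refreshed whenever the patient's (floored) age increments, i.e. at each
    integer age anniversary.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if not 0 <= initial_stage < N_LIVING:
        raise ValueError("initial stage must be a living stage index")
    rng = _as_rng(rng)
    state = int(initial_stage)
    t = 0.0
    jump_times: list[float] = []
    states = [state]
    while state != DEATH_INDEX and t < horizon - _EPS:
        age = np.floor(profile.age_at(t) + _EPS)
        fp, fd = params.rate_scale(profile, age)
        r_prog = params.progression_rates[state] * fp if state < N_LIVING - 1 \
            else 0.0
        r_death = params.death_rates[state] * fd
        total = r_prog + r_death
        # next intensity refresh: the coming integer age anniversary
        next_refresh = min(horizon, t + (age + 1.0 - profile.age_at(t)))
        if total <= 0:
            t = next_refresh
            continue
        wait = rng.exponential(1.0 / total)
        if t + wait >= next_refresh - _EPS:
            # no jump before the refresh; memorylessness lets us redraw
            t = next_refresh
            continue
        t = t + wait
        state = state + 1 if rng.random() < r_prog / total else DEATH_INDEX
        jump_times.append(t)
        states.append(state)
    return TruePath(jump_times=np.array(jump_times),
                    states=np.array(states), horizon=float(horizon))


def schedule_observations(scheme: ObservationScheme, horizon: float, rng,
                          observe=None) -> np.ndarray:
    """Draw eGFR test times over ``[0, horizon]`` under a scheme.

    ``observe`` is a callable ``time -> observed stage index`` consulted at
    each test under the doctor's-care scheme to key the next gap (tests and
    their timing are interleaved in that scheme).  An empty schedule (first
    gap beyond the horizon) is allowed and flagged with a warning.
    """
    rng = _as_rng(rng)
    times: list[float] = []
    if scheme.kind == "random":
        t = 0.0 if scheme.baseline else _draw_gap(scheme, rng)
        while t <= horizon + _EPS:
            times.append(min(t, horizon))
            t += _draw_gap(scheme, rng)
    else:
        if observe is None:
            raise ValueError("doctors_care scheduling needs an observe callback")
        t = 0.0
        if not scheme.baseline:
            # key the first gap on the stage a baseline assessment would show
            t = _dc_gap(scheme, int(observe(0.0)), rng)
        while t <= horizon + _EPS:
            t = min(t, horizon)
            times.append(t)
            stage = int(observe(t))
            t += _dc_gap(scheme, stage, rng)
    if not times:
        warnings.warn("empty observation schedule (horizon shorter than the "
                      "first test gap)", RuntimeWarning, stacklevel=2)
    return np.asarray(times, dtype=float)


def _draw_gap(scheme: ObservationScheme, rng) -> float:
    if scheme.distribution == "fixed":
        return scheme.mean_gap
    return rng.exponential(scheme.mean_gap)


def _dc_gap(scheme: ObservationScheme, stage: int, rng) -> float:
    gap = scheme.gap_by_stage[LIVING_STAGES[stage]]
    if scheme.gap_jitter > 0:
        gap *= rng.uniform(1 - scheme.gap_jitter, 1 + scheme.gap_jitter)
    return gap


def emit_observations(path: TruePath, times: np.ndarray, E: np.ndarray,
                      rng) -> np.ndarray:
    """Draw observed stages at *times* from the misclassification matrix.

    Each observation is a categorical draw from the emission row of the true
    stage at that time; a request at or after the death time is rejected
    (dead patients are not tested).
    """
    rng = _as_rng(rng)
    E = np.asarray(E, dtype=float)
    times = np.asarray(times, dtype=float)
    death = path.death_time
    out = np.empty(len(times), dtype=int)
    for i, t in enumerate(times):
        if death is not None and t >= death - _EPS:
            raise ValueError(f"observation at t={t:.3f} requested at or "
                             f"after death (t={death:.3f})")
        true = path.state_at(t)
        out[i] = rng.choice(N_LIVING, p=E[true, :N_LIVING]
                            / E[true, :N_LIVING].sum())
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of :func:`generate_cohort`.

    ``n_patients`` is the number of *retained* patients (those surviving the
    minimum-observations rule).  The study window is ``window`` years; with
    ``stagger_entry`` patients enter uniformly over the window (an open
    cohort) and are censored at its end, otherwise everyone is followed for
    the full window.  ``params``, ``prevalence``, ``age_bands`` and
    ``initial_distribution`` default to the stratum preset.
    """

    n_patients: int = 1000
    stratum: str = "unmeasured"
    params: ModelParameters | None = None
    scheme: ObservationScheme = field(
        default_factory=lambda: ObservationScheme(include_baseline=True))
    window: float = 9.0
    stagger_entry: bool = True
    min_obs: int = 3
    prevalence: dict[str, float] | None = None
    age_bands: list[tuple[float, float]] | None = None
    age_band_weights: list[float] | None = None
    initial_distribution: list[float] | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.window <= 0:
            raise ValueError("window must be positive")
        prev = self.prevalence
        if prev is not None:
            for name, p in prev.items():
                if name not in BINARY_COVARIATES:
                    raise ValueError(f"unknown covariate {name!r}")
                if not 0 <= p <= 1:
                    raise ValueError(
                        f"prevalence of {name} must be in [0, 1], got {p}")
        pi0 = self.initial_distribution
        if pi0 is not None:
            pi0 = np.asarray(pi0, dtype=float)
            if pi0.shape != (N_LIVING,) or (pi0 < 0).any() or \
                    not np.isclose(pi0.sum(), 1.0):
                raise ValueError("initial_distribution must be a probability "
                                 "vector over the 5 living stages")

    def resolved(self) -> "GeneratorConfig":
        """Fill preset-dependent defaults."""
        pop = preset_population(self.stratum)
        return replace(
            self,
            params=self.params or preset_parameters(self.stratum),
            prevalence=self.prevalence or pop["prevalence"],
            age_bands=self.age_bands or pop["age_bands"],
            age_band_weights=self.age_band_weights or pop["age_band_weights"],
            initial_distribution=(self.initial_distribution
                                  or pop["initial_distribution"]),
        )


def _sample_profile(cfg: GeneratorConfig, rng) -> CovariateProfile:
    bands = cfg.age_bands
    b = rng.choice(len(bands), p=cfg.age_band_weights)
    lo, hi = bands[b]
    age = rng.uniform(lo, hi)
    cov = {name: int(rng.random() < cfg.prevalence.get(name, 0.0))
           for name in BINARY_COVARIATES}
    return CovariateProfile(age_at_entry=age, albuminuria_stratum=cfg.stratum,
                            **cov)


def _simulate_patient(cfg: GeneratorConfig, pid: str, rng):
    """One candidate patient; returns a record or ``None`` if filtered."""
    profile = _sample_profile(cfg, rng)
    censor = cfg.window
    if cfg.stagger_entry:
        censor = cfg.window * (1.0 - rng.random())
    if censor < _EPS:
        return None
    init = rng.choice(N_LIVING, p=cfg.initial_distribution)
    path = simulate_true_path(cfg.params, profile, censor, rng,
                              initial_stage=int(init))
    death = path.death_time
    E = cfg.params.emission
    obs_horizon = censor if death is None else max(0.0, death - 1e-6)
    obs_times: list[float] = []
    obs_stages: list[int] = []

    def observe(t: float) -> int:
        true = path.state_at(t)
        p = E[true, :N_LIVING]
        stage = rng.choice(N_LIVING, p=p / p.sum())
        obs_times.append(t)
        obs_stages.append(int(stage))
        return int(stage)

    scheme = cfg.scheme
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if scheme.kind == "doctors_care":
            schedule_observations(scheme, obs_horizon, rng, observe=observe)
        else:
            times = schedule_observations(scheme, obs_horizon, rng)
            for t in times:
                observe(float(t))
    if len(obs_times) < cfg.min_obs:
        return None
    return PatientRecord(patient_id=pid, profile=profile,
                         times=np.asarray(obs_times),
                         stages=np.asarray(obs_stages),
                         censor_time=censor, death_time=death)


def generate_cohort(config: GeneratorConfig, seed: int,
                    csv_path=None) -> Cohort:
    """Generate a synthetic cohort; optionally also write it to CSV.

    Deterministic under ``seed`` (per-patient substreams are spawned from a
    single master seed).  Candidates failing the minimum-observation rule
    are dropped and counted in ``Cohort.n_dropped``.
    """
    cfg = config.resolved()
    master = np.random.SeedSequence(seed)
    records: list[PatientRecord] = []
    n_dropped = 0
    attempt = 0
    max_attempts = 60 * max(cfg.n_patients, 1) + 1000
    while len(records) < cfg.n_patients:
        if attempt >= max_attempts:
            raise RuntimeError(
                "generator retention too low; check scheme/min_obs settings")
        rng = np.random.default_rng(master.spawn(1)[0])
        rec = _simulate_patient(cfg, f"P{attempt:07d}", rng)
        attempt += 1
        if rec is None:
            n_dropped += 1
        else:
            records.append(rec)
    cohort = Cohort(records=records, stratum=cfg.stratum,
                    generating_params=cfg.params, n_dropped=n_dropped)
    if csv_path is not None:
        write_cohort_csv(cohort, csv_path)
    return cohort


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# -- generator config file round-trip (flat key-value YAML) -----------------

def save_generator_config(cfg: GeneratorConfig, path) -> None:
    out = {
        "n_patients": cfg.n_patients, "stratum": cfg.stratum,
        "window": cfg.window, "stagger_entry": cfg.stagger_entry,
        "min_obs": cfg.min_obs,
        "scheme.kind": cfg.scheme.kind,
        "scheme.mean_gap": cfg.scheme.mean_gap,
        "scheme.distribution": cfg.scheme.distribution,
        "scheme.gap_jitter": cfg.scheme.gap_jitter,
    }
    for stage, gap in cfg.scheme.gap_by_stage.items():
        out[f"scheme.gap.{stage}"] = gap
    if cfg.scheme.include_baseline is not None:
        out["scheme.include_baseline"] = cfg.scheme.include_baseline
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)


def load_generator_config(path) -> GeneratorConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    gaps = {k.split(".")[-1]: float(v) for k, v in data.items()
            if k.startswith("scheme.gap.")}
    scheme = ObservationScheme(
        kind=data.get("scheme.kind", "random"),
        mean_gap=float(data.get("scheme.mean_gap", 1.0)),
        distribution=data.get("scheme.distribution", "exponential"),
        gap_by_stage=gaps or ObservationScheme().gap_by_stage,
        gap_jitter=float(data.get("scheme.gap_jitter", 0.2)),
        include_baseline=data.get("scheme.include_baseline", True),
    )
    return GeneratorConfig(
        n_patients=int(data.get("n_patients", 1000)),
        stratum=data.get("stratum", "unmeasured"),
        scheme=scheme,
        window=float(data.get("window", 9.0)),
        stagger_entry=bool(data.get("stagger_entry", True)),
        min_obs=int(data.get("min_obs", 3)),
    )
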