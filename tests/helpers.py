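"""Independent reference implementations used as test oracles.

Everything here recomputes quantities by brute force (exhaustive hidden-path
enumeration, scipy's matrix exponential, direct vectorised CTMC simulation)
without touching the package's forward algorithm, Viterbi programme or
eigendecomposition engine.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm

from ckdhmm.cohort import PatientRecord
from ckdhmm.likelihood import LikelihoodOptions
from ckdhmm.matrices import build_intensity_matrix
from ckdhmm.parameters import ModelParameters

N_LIVING = 5
DEATH = 5


def _kern(params: ModelParameters, profile, t0: float, t1: float,
          exact_age: bool) -> np.ndarray:
    """6x6 kernel from t0 to t1 composed over integer age anniversaries."""
    cuts = [t0]
    if exact_age:
        a0 = profile.age_at(t0)
        b = t0 + (math.floor(a0 + 1e-9) + 1.0 - a0)
        while b < t1 - 1e-9:
            cuts.append(b)
            b += 1.0
    cuts.append(t1)
    P = np.eye(6)
    for a, b in zip(cuts[:-1], cuts[1:]):
        age = math.floor(profile.age_at(a) + 1e-9)
        Q = build_intensity_matrix(params, profile, age).matrix
        P = P @ expm((b - a) * Q)
    return P


def _terminal_weight(rec: PatientRecord, params: ModelParameters,
                     exact_age: bool) -> np.ndarray | None:
    """Death density vector or censored-survival vector (per last state)."""
    prof = rec.profile
    t_last = float(rec.times[-1])
    if rec.died:
        td = float(rec.death_time)
        P = _kern(params, prof, t_last, td, exact_age)
        # death intensity at the age in force when death occurs
        t_rate = t_last
        if exact_age:
            a0 = prof.age_at(t_last)
            b = t_last + (math.floor(a0 + 1e-9) + 1.0 - a0)
            while b < td - 1e-9:
                t_rate = b
                b += 1.0
        age = math.floor(prof.age_at(t_rate) + 1e-9)
        Q = build_intensity_matrix(params, prof, age).matrix
        return P[:N_LIVING, :N_LIVING] @ Q[:N_LIVING, DEATH]
    if rec.censor_time > t_last + 1e-9:
        P = _kern(params, prof, t_last, float(rec.censor_time), exact_age)
        return P[:N_LIVING, :N_LIVING].sum(axis=1)
    return None


def _path_weights(rec: PatientRecord, params: ModelParameters,
                  options: LikelihoodOptions):
    """Kernels, emission and terminal pieces shared by the oracles."""
    exact = options.age_update == "exact"
    mats = [_kern(params, rec.profile, rec.times[k - 1], rec.times[k],
                  exact)[:N_LIVING, :N_LIVING]
            for k in range(1, rec.n_obs)]
    term = _terminal_weight(rec, params, exact)
    E = np.asarray(params.emission)
    if options.initial == "first_obs_exact":
        init = None
    else:
        pi0 = options.initial_distribution
        if pi0 is None:
            pi0 = np.full(N_LIVING, 1.0 / N_LIVING)
        init = pi0
    return mats, term, E, init


def iter_hidden_paths(K: int):
    """All non-decreasing living-stage sequences of length K."""
    for path in itertools.combinations_with_replacement(range(N_LIVING), K):
        yield path


def brute_record_loglik(rec: PatientRecord, params: ModelParameters,
                        options: LikelihoodOptions) -> float:
    """Exhaustive hidden-path sum of the record likelihood."""
    mats, term, E, init = _path_weights(rec, params, options)
    obs = rec.stages
    total = 0.0
    for path in iter_hidden_paths(rec.n_obs):
        if init is None:
            if path[0] != obs[0]:
                continue
            p = 1.0
        else:
            p = init[path[0]] * E[path[0], obs[0]]
        for k in range(1, rec.n_obs):
            p *= mats[k - 1][path[k - 1], path[k]] * E[path[k], obs[k]]
        if term is not None:
            p *= term[path[-1]]
        total += p
    return math.log(total) if total > 0 else -math.inf


def brute_viterbi(rec: PatientRecord, params: ModelParameters,
                  options: LikelihoodOptions):
    """Exhaustive argmax over hidden paths; returns (path, log joint)."""
    mats, term, E, init = _path_weights(rec, params, options)
    obs = rec.stages
    best, best_p = None, -1.0
    for path in iter_hidden_paths(rec.n_obs):
        if init is None:
            if path[0] != obs[0]:
                continue
            p = 1.0
        else:
            p = init[path[0]] * E[path[0], obs[0]]
        for k in range(1, rec.n_obs):
            p *= mats[k - 1][path[k - 1], path[k]] * E[path[k], obs[k]]
        if term is not None:
            p *= term[path[-1]]
        if p > best_p:
            best, best_p = path, p
    return best, (math.log(best_p) if best_p > 0 else -math.inf)


def simulate_fixed_q_states(Q: np.ndarray, start: int, horizons,
                            n: int, rng) -> np.ndarray:
    """Vectorised CTMC simulation at a fixed intensity matrix.

    Simulates *n* independent trajectories once (uni-directional chain, at
    most five jumps each) and returns an ``(n, len(horizons))`` array of the
    state occupied at each horizon.
    """
    Q = np.asarray(Q, dtype=float)
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    h_max = float(horizons.max())
    state = np.full(n, start, dtype=int)
    t = np.zeros(n)
    out = np.full((n, len(horizons)), start, dtype=int)
    recorded = np.zeros((n, len(horizons)), dtype=bool)
    for _ in range(N_LIVING + 1):
        active = (state != DEATH) & (t < h_max)
        if not active.any():
            break
        s = state[active]
        prog = np.where(s < N_LIVING - 1, Q[s, np.minimum(s + 1, 4)], 0.0)
        death = Q[s, DEATH]
        exit_rate = prog + death
        with np.errstate(divide="ignore"):
            wait = rng.exponential(1.0 / np.where(exit_rate > 0, exit_rate,
                                                  1.0))
        wait = np.where(exit_rate > 0, wait, np.inf)
        tt = np.minimum(t[active] + wait, h_max + 1e-9)
        # record the pre-jump state at every horizon passed during the wait
        upd = np.flatnonzero(active)
        for j, h in enumerate(horizons):
            hit = (t[upd] <= h) & (tt > h) & ~recorded[upd, j]
            out[upd[hit], j] = s[hit]
            recorded[upd[hit], j] = True
        jumped = tt <= h_max
        to_death = rng.random(len(s)) < death / np.where(exit_rate > 0,
                                                         exit_rate, 1.0)
        new_state = np.where(to_death, DEATH, s + 1)
        t[upd] = tt
        state[upd] = np.where(jumped, new_state, s)
    for j, h in enumerate(horizons):
        rem = ~recorded[:, j]
        out[rem, j] = state[rem]
    return out


def simulate_fixed_q_paths(Q: np.ndarray, start: int, horizon: float,
                           n: int, rng) -> np.ndarray:
    """State of *n* independent fixed-Q trajectories at a single horizon."""
    return simulate_fixed_q_states(Q, start, [horizon], n, rng)[:, 0]


def sample_emission(states: np.ndarray, E: np.ndarray, rng) -> np.ndarray:
    """Vectorised categorical draws of observed stages for living states."""
    u = rng.random(len(states))
    cdf = np.cumsum(E[states, :N_LIVING], axis=1)
    return (u[:, None] < cdf).argmax(axis=1)
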