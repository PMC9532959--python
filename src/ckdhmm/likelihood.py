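"""Forward-algorithm likelihood and analytic score for the panel HMM.

Each patient contributes a hidden-Markov likelihood over the living stages:
between consecutive observation times the true stage evolves by
``P(dt) = expm(dt * Q)`` with covariates (annually updated age) taken at the
start of the interval — optionally with exact splitting of intervals at
integer age anniversaries — and each observed stage multiplies in the
corresponding misclassification column.  An exactly observed death adds the
density term ``sum_s P(dt)[., s] * q_{s, death}``.

Implementation notes.  Because the intensity matrix is upper triangular the
exponential of its living block has the closed eigen form of
:func:`ckdhmm.matrices.tri_eig_living`; intervals are grouped by (floored
age, covariate pattern) so the decomposition is shared, and the forward
recursion runs "wave by wave" across all patients at once.  The score is
computed analytically by a scaled backward recursion plus the
Daleckii-Krein directional-derivative identity for the matrix exponential;
it is validated against finite differences in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, PatientRecord
from .matrices import (expm_taylor_batch, min_eigen_gap, p_living,
                       tri_eig_living)
from .parameters import (BINARY_COVARIATES, ModelParameters, Multiplier,
                         emission_support)
from .states import DEATH_INDEX, N_LIVING, N_STATES

_EPS = 1e-12

#: design features: the five binary covariates plus the age exponent
FEATURES: tuple[str, ...] = BINARY_COVARIATES + ("age",)
N_FEATURES = len(FEATURES)

OBS_PROP = -1   # pure propagation step (interval split at an anniversary)
OBS_DEATH = -2  # exactly observed death step


@dataclass(frozen=True)
class LikelihoodOptions:
    """Conventions of the likelihood evaluation.

    covariates
        Binary covariates whose multipliers are *fitted*; may also contain
        ``"age"`` (fitted per-year multipliers).  Covariates left out are
        held at no effect.
    age_update
        ``"interval_start"`` freezes the intensity over each observation
        interval at its start (standard panel-data convention);
        ``"exact"`` splits intervals at integer age anniversaries.
    initial
        ``"first_obs_exact"``: the true state at the first observation is
        its observed stage (no emission factor).  ``"distribution"``: the
        first observation is misclassified like any other, with prior
        ``initial_distribution`` over living stages (uniform if not given).
    emission
        ``"free"``: fit all entries on the permitted band;
        ``"fixed"``: keep the supplied emission matrix.
    """

    covariates: tuple[str, ...] = ("age", "male", "heart_failure", "cancer")
    age_update: str = "interval_start"
    initial: str = "first_obs_exact"
    initial_distribution: np.ndarray | None = None
    emission: str = "free"
    band_width: int = 2

    def __post_init__(self) -> None:
        for c in self.covariates:
            if c != "age" and c not in BINARY_COVARIATES:
                raise ValueError(f"unknown covariate {c!r}")
        if self.age_update not in ("interval_start", "exact"):
            raise ValueError("age_update must be interval_start or exact")
        if self.initial not in ("first_obs_exact", "distribution"):
            raise ValueError("initial must be first_obs_exact or distribution")
        if self.emission not in ("free", "fixed"):
            raise ValueError("emission must be free or fixed")
        if self.initial_distribution is not None:
            pi0 = np.asarray(self.initial_distribution, dtype=float)
            if pi0.shape != (N_LIVING,) or (pi0 < 0).any():
                raise ValueError("initial_distribution must be a length-5 "
                                 "non-negative vector")
            object.__setattr__(self, "initial_distribution", pi0 / pi0.sum())

    @property
    def fitted_binaries(self) -> tuple[str, ...]:
        return tuple(c for c in self.covariates if c != "age")

    @property
    def fit_age(self) -> bool:
        return "age" in self.covariates


class ParamLayout:
    """Mapping between the unconstrained vector and natural parameters.

    Order: 4 log progression rates, 5 log death rates, per fitted covariate
    (age first when fitted) a pair (log progression multiplier, log death
    multiplier), then the free emission logits row by row (diagonal entry is
    the reference with logit 0).
    """

    def __init__(self, options: LikelihoodOptions):
        self.options = options
        names = [f"log_rate[{r}->{r + 1}]" for r in range(N_LIVING - 1)]
        names += [f"log_rate[{r}->death]" for r in range(N_LIVING)]
        self.mult_covs: list[str] = []
        if options.fit_age:
            self.mult_covs.append("age")
        self.mult_covs += list(options.fitted_binaries)
        for c in self.mult_covs:
            names += [f"log_mult[{c}.progression]", f"log_mult[{c}.death]"]
        self.emission_entries: list[tuple[int, int]] = []
        if options.emission == "free":
            support = emission_support(options.band_width)
            for r in range(N_LIVING):
                for s in range(N_LIVING):
                    if support[r, s] and r != s:
                        self.emission_entries.append((r, s))
                        names.append(f"logit_e[{r}->{s}]")
        self.names = names
        self.n_rates = N_LIVING - 1 + N_LIVING
        self.n_mults = 2 * len(self.mult_covs)
        self.i_emission = self.n_rates + self.n_mults
        self.n_params = len(names)

    # -- decoding ----------------------------------------------------------
    def split(self, theta: np.ndarray):
        """theta -> (log rates (9,), logm_prog (6,), logm_death (6,), E)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters")
        log_rates = theta[:self.n_rates]
        lmp = np.zeros(N_FEATURES)
        lmd = np.zeros(N_FEATURES)
        pos = self.n_rates
        for c in self.mult_covs:
            f = FEATURES.index(c)
            lmp[f] = theta[pos]
            lmd[f] = theta[pos + 1]
            pos += 2
        E = self.emission_matrix(theta)
        return log_rates, lmp, lmd, E

    def emission_matrix(self, theta: np.ndarray) -> np.ndarray:
        if self.options.emission == "fixed":
            raise ValueError("emission is fixed; no logits in the vector")
        E = np.zeros((N_STATES, N_STATES))
        E[DEATH_INDEX, DEATH_INDEX] = 1.0
        z = theta[self.i_emission:]
        rows: dict[int, list[tuple[int, float]]] = {}
        for (r, s), v in zip(self.emission_entries, z):
            rows.setdefault(r, []).append((s, v))
        for r in range(N_LIVING):
            entries = rows.get(r, [])
            denom = 1.0 + sum(math.exp(v) for _, v in entries)
            E[r, r] = 1.0 / denom
            for s, v in entries:
                E[r, s] = math.exp(v) / denom
        return E

    # -- encoding ----------------------------------------------------------
    def encode(self, params: ModelParameters) -> np.ndarray:
        """Natural parameters -> unconstrained vector (for starts / truth).

        Requires strictly positive rates; free emission entries equal to 0
        map to a large negative logit.
        """
        theta = np.empty(self.n_params)
        rates = np.concatenate([params.progression_rates, params.death_rates])
        if (rates <= 0).any():
            raise ValueError("cannot encode zero rates on the log scale")
        theta[:self.n_rates] = np.log(rates)
        pos = self.n_rates
        for c in self.mult_covs:
            m = params.multiplier(c)
            theta[pos] = math.log(m.progression)
            theta[pos + 1] = math.log(m.death)
            pos += 2
        for i, (r, s) in enumerate(self.emission_entries):
            p_off, p_diag = params.emission[r, s], params.emission[r, r]
            theta[self.i_emission + i] = (math.log(p_off / p_diag)
                                          if p_off > 0 else -25.0)
        return theta

    def to_parameters(self, theta: np.ndarray,
                      fixed_emission: np.ndarray | None = None,
                      cohort: str = "unmeasured") -> ModelParameters:
        log_rates, lmp, lmd, E = (
            self.split(theta) if self.options.emission == "free"
            else (*self._split_no_e(theta), fixed_emission))
        rates = np.exp(log_rates)
        mults = {}
        pos = self.n_rates
        for c in self.mult_covs:
            mults[c] = Multiplier(math.exp(theta[pos]),
                                  math.exp(theta[pos + 1]))
            pos += 2
        return ModelParameters(
            progression_rates=rates[:N_LIVING - 1],
            death_rates=rates[N_LIVING - 1:],
            multipliers=mults, emission=E,
            band_width=self.options.band_width, cohort=cohort)

    def _split_no_e(self, theta):
        log_rates = theta[:self.n_rates]
        lmp = np.zeros(N_FEATURES)
        lmd = np.zeros(N_FEATURES)
        pos = self.n_rates
        for c in self.mult_covs:
            f = FEATURES.index(c)
            lmp[f] = theta[pos]
            lmd[f] = theta[pos + 1]
            pos += 2
        return log_rates, lmp, lmd


# ---------------------------------------------------------------------------
# Design: flattened steps, interval groups, wave schedule
# ---------------------------------------------------------------------------

@dataclass
class _Design:
    """Flattened step arrays of a cohort, ordered wave-major.

    Steps are sorted by (position within patient, patient), so the k-th
    "wave" — the k-th step of every patient that has one — is a contiguous
    slice, letting the forward/backward recursions run batched across
    patients with no gathers on the step arrays.
    """

    n_pat: int
    X: np.ndarray            # (G, 6) feature values per group
    step_dt: np.ndarray      # (S,)
    step_gid: np.ndarray     # (S,)
    step_obs: np.ndarray     # (S,) observed stage, OBS_PROP or OBS_DEATH
    wave_bounds: list[tuple[int, int]]
    wave_pats: list[np.ndarray]
    init_stage: np.ndarray   # (n_pat,)
    record_ids: list[str] = field(default_factory=list)
    # steps sorted by group for fast segment reductions
    gid_perm: np.ndarray | None = None
    gid_starts: np.ndarray | None = None
    gid_order: np.ndarray | None = None
    # per-wave emission/death index caches
    wave_obs_idx: list = field(default_factory=list)
    wave_death_idx: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.step_gid):
            self.gid_perm = np.argsort(self.step_gid, kind="stable")
            sorted_gid = self.step_gid[self.gid_perm]
            self.gid_order, self.gid_starts = np.unique(sorted_gid,
                                                        return_index=True)
        else:
            self.gid_perm = np.empty(0, dtype=int)
            self.gid_order = np.empty(0, dtype=int)
            self.gid_starts = np.empty(0, dtype=int)
        self.wave_obs_idx = []
        self.wave_death_idx = []
        for lo, hi in self.wave_bounds:
            obs = self.step_obs[lo:hi]
            oi = np.flatnonzero(obs >= 0)
            di = np.flatnonzero(obs == OBS_DEATH)
            self.wave_obs_idx.append((oi, obs[oi]))
            self.wave_death_idx.append((di, self.step_gid[lo:hi][di]))


def _record_segments(rec: PatientRecord, exact_age: bool):
    """Yield (t_start, dt, obs_code) steps of one record.

    Death contributes an exact-time density step; for censored patients a
    final pure-propagation step carries the survival probability from the
    last test to the administrative censoring time (the patient is known
    not to have died in that window).
    """
    entry_age = rec.profile.age_at_entry
    events = [(t, int(s)) for t, s in zip(rec.times, rec.stages)]
    if rec.died:
        events.append((float(rec.death_time), OBS_DEATH))
    elif rec.censor_time > rec.times[-1] + 1e-9:
        events.append((float(rec.censor_time), OBS_PROP))
    for (t0, _), (t1, obs) in zip(events[:-1], events[1:]):
        if not exact_age:
            yield t0, t1 - t0, obs
            continue
        cuts = [t0]
        a0 = entry_age + t0
        b = t0 + (math.floor(a0 + 1e-9) + 1.0 - a0)
        while b < t1 - 1e-9:
            cuts.append(b)
            b += 1.0
        cuts.append(t1)
        for i in range(len(cuts) - 1):
            yield (cuts[i], cuts[i + 1] - cuts[i],
                   obs if i == len(cuts) - 2 else OBS_PROP)


def build_design(cohort: Cohort, options: LikelihoodOptions) -> _Design:
    groups: dict[tuple, int] = {}
    X_rows: list[tuple] = []
    dts: list[float] = []
    gids: list[int] = []
    obss: list[int] = []
    counts: list[int] = []
    init = []
    ids = []
    exact = options.age_update == "exact"
    for rec in cohort:
        prof = rec.profile
        xbin = tuple(prof.value(c) for c in BINARY_COVARIATES)
        n_steps = 0
        for t0, dt, obs in _record_segments(rec, exact):
            agex = math.floor(prof.age_at(t0) + 1e-9) - 60.0
            key = xbin + (agex,)
            gid = groups.setdefault(key, len(groups))
            if gid == len(X_rows):
                X_rows.append(key)
            dts.append(dt)
            gids.append(gid)
            obss.append(obs)
            n_steps += 1
        counts.append(n_steps)
        init.append(int(rec.stages[0]))
        ids.append(rec.patient_id)
    n_pat = len(counts)
    counts = np.asarray(counts) if n_pat else np.zeros(0, dtype=int)
    step_pat = np.repeat(np.arange(n_pat), counts)
    pos_in_pat = np.arange(len(dts)) - np.repeat(
        np.concatenate([[0], np.cumsum(counts)[:-1]]) if n_pat else [],
        counts)
    order = np.lexsort((step_pat, pos_in_pat))
    step_dt = np.asarray(dts)[order]
    step_gid = np.asarray(gids, dtype=int)[order]
    step_obs = np.asarray(obss, dtype=int)[order]
    step_pat = step_pat[order]
    pos_sorted = pos_in_pat[order]
    max_steps = int(counts.max()) if n_pat and len(counts) else 0
    wave_bounds, wave_pats = [], []
    starts = np.searchsorted(pos_sorted, np.arange(max_steps + 1))
    for w in range(max_steps):
        lo, hi = int(starts[w]), int(starts[w + 1])
        wave_bounds.append((lo, hi))
        wave_pats.append(step_pat[lo:hi])
    return _Design(
        n_pat=n_pat,
        X=np.asarray(X_rows, dtype=float).reshape(len(X_rows), N_FEATURES),
        step_dt=step_dt, step_gid=step_gid, step_obs=step_obs,
        wave_bounds=wave_bounds, wave_pats=wave_pats,
        init_stage=np.asarray(init, dtype=int), record_ids=ids)


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Cohort log-likelihood and score under fixed conventions."""

    def __init__(self, cohort: Cohort, options: LikelihoodOptions
                 | None = None, fixed_emission: np.ndarray | None = None):
        self.options = options or LikelihoodOptions()
        self.layout = ParamLayout(self.options)
        self.design = build_design(cohort, self.options)
        if self.options.emission == "fixed":
            if fixed_emission is None:
                fixed_emission = np.eye(N_STATES)
            self.fixed_emission = np.asarray(fixed_emission, dtype=float)
        else:
            self.fixed_emission = None
        pi0 = self.options.initial_distribution
        if self.options.initial == "distribution" and pi0 is None:
            pi0 = np.full(N_LIVING, 1.0 / N_LIVING)
        self.pi0 = pi0

    # -- natural-parameter ingredients -------------------------------------
    def _group_rates(self, log_rates, lmp, lmd):
        """Per-group scaled rates qp (G, 4) and qd (G, 5)."""
        X = self.design.X
        fp = np.exp(X @ lmp)
        fd = np.exp(X @ lmd)
        a = np.exp(log_rates)
        qp = a[:N_LIVING - 1][None, :] * fp[:, None]
        qd = a[N_LIVING - 1:][None, :] * fd[:, None]
        return qp, qd

    def _parts_from_theta(self, theta):
        if self.options.emission == "free":
            log_rates, lmp, lmd, E = self.layout.split(theta)
        else:
            log_rates, lmp, lmd = self.layout._split_no_e(
                np.asarray(theta, dtype=float))
            E = self.fixed_emission
        qp, qd = self._group_rates(log_rates, lmp, lmd)
        return qp, qd, E

    def parts_from_parameters(self, params: ModelParameters):
        lmp = np.zeros(N_FEATURES)
        lmd = np.zeros(N_FEATURES)
        for f, name in enumerate(FEATURES):
            m = params.multiplier(name)
            lmp[f] = math.log(m.progression)
            lmd[f] = math.log(m.death)
        with np.errstate(divide="ignore"):
            log_rates = np.log(np.concatenate(
                [params.progression_rates, params.death_rates]))
        X = self.design.X
        fp = np.exp(X @ lmp)
        fd = np.exp(X @ lmd)
        qp = params.progression_rates[None, :] * fp[:, None]
        qd = params.death_rates[None, :] * fd[:, None]
        del log_rates
        return qp, qd, np.asarray(params.emission, dtype=float)

    # -- forward pass -------------------------------------------------------
    def _forward(self, qp, qd, E, keep: bool = False,
                 floor_c: float = 0.0):
        d = self.design
        lam, V, W = tri_eig_living(qp, qd)
        P = _p_steps(lam, V, W, qp, qd, d.step_gid, d.step_dt)
        ET = E[:N_LIVING, :N_LIVING].T.copy()  # (obs, true)
        alpha = np.zeros((d.n_pat, N_LIVING))
        ll = np.zeros(d.n_pat)
        if self.options.initial == "first_obs_exact":
            alpha[np.arange(d.n_pat), d.init_stage] = 1.0
            c0 = np.ones(d.n_pat)
        else:
            alpha = self.pi0[None, :] * ET[d.init_stage]
            c0 = alpha.sum(axis=1)
            ok = c0 > 0
            ll = np.where(ok, np.log(np.where(ok, c0, 1.0)), -np.inf)
            alpha = alpha / np.where(ok, c0, 1.0)[:, None]
        S = len(d.step_dt)
        alpha_prev = np.empty((S, N_LIVING)) if keep else None
        c_step = np.empty(S) if keep else None
        for w, ((lo, hi), pat) in enumerate(zip(d.wave_bounds, d.wave_pats)):
            A = alpha[pat]
            if keep:
                alpha_prev[lo:hi] = A
            Anew = np.matmul(A[:, None, :], P[lo:hi])[:, 0, :]
            oi, ostage = d.wave_obs_idx[w]
            di, dgid = d.wave_death_idx[w]
            if len(oi):
                Anew[oi] *= ET[ostage]
            if len(di):
                Anew[di] *= qd[dgid]
            c = Anew.sum(axis=1)
            ok = c > floor_c
            if keep:
                c_step[lo:hi] = np.where(ok, c, max(floor_c, 1.0))
            # floor_c > 0 keeps the fitting surface finite (a steep but
            # smooth penalty) instead of a -inf cliff; floor_c == 0 yields
            # the exact -inf for genuinely impossible sequences.
            ll[pat] += np.where(ok, np.log(np.where(ok, c, 1.0)),
                                math.log(floor_c) if floor_c > 0 else -np.inf)
            alpha[pat] = Anew / np.where(ok, c, 1.0)[:, None]
        state = dict(lam=lam, V=V, W=W, P=P, ET=ET, qp=qp, qd=qd, E=E,
                     alpha=alpha, alpha_prev=alpha_prev, c_step=c_step,
                     c0=c0)
        return ll, state

    #: per-step floor of the forward normaliser during fitting: keeps the
    #: objective finite (a steep smooth penalty) in absurd parameter regions
    FIT_FLOOR = 1e-290

    def loglike_per_record(self, theta) -> np.ndarray:
        ll, _ = self._forward(*self._parts_from_theta(theta),
                              floor_c=self.FIT_FLOOR)
        return ll

    def loglike(self, theta) -> float:
        return float(self.loglike_per_record(theta).sum())

    def loglike_parameters(self, params: ModelParameters,
                           per_record: bool = False):
        """Log-likelihood at the given natural parameters."""
        ll, _ = self._forward(*self.parts_from_parameters(params))
        return ll if per_record else float(ll.sum())

    # -- score --------------------------------------------------------------
    def score(self, theta):
        """Return ``(loglike, gradient)`` — analytic forward/backward."""
        qp, qd, E = self._parts_from_theta(theta)
        ll, st = self._forward(qp, qd, E, keep=True,
                               floor_c=self.FIT_FLOOR)
        total = ll.sum()
        if not np.isfinite(total):
            raise FloatingPointError(
                "log-likelihood is -inf; the observed data are impossible "
                "under the current parameters")
        d = self.design
        lam, V, W, P, ET = st["lam"], st["V"], st["W"], st["P"], st["ET"]
        S = len(d.step_dt)
        dP = np.zeros((S, N_LIVING, N_LIVING))
        dEL = np.zeros((N_LIVING, N_LIVING))   # (obs, true) accumulation
        G = len(d.X)
        dqd_direct = np.zeros((G, N_LIVING))
        beta = np.ones((d.n_pat, N_LIVING))
        waves = list(enumerate(zip(d.wave_bounds, d.wave_pats)))
        for w, ((lo, hi), pat) in reversed(waves):
            A = st["alpha_prev"][lo:hi]
            c = st["c_step"][lo:hi]
            B = beta[pat]
            oi, ostage = d.wave_obs_idx[w]
            di, dgid = d.wave_death_idx[w]
            eb = B.copy()
            if len(oi):
                eb[oi] *= ET[ostage]
            if len(di):
                eb[di] *= qd[dgid]
            Pw = P[lo:hi]
            dP[lo:hi] = A[:, :, None] * eb[:, None, :] / c[:, None, None]
            AP = np.matmul(A[:, None, :], Pw)[:, 0, :]
            de = AP * B / c[:, None]
            if len(oi):
                np.add.at(dEL, ostage, de[oi])
            if len(di):
                np.add.at(dqd_direct, dgid, de[di])
            beta[pat] = np.matmul(Pw, eb[:, :, None])[:, :, 0] / c[:, None]
        # initial-state contribution (misclassified first observation)
        if self.options.initial == "distribution":
            contrib = self.pi0[None, :] * beta / st["c0"][:, None]
            np.add.at(dEL, d.init_stage, contrib)
        dQ = _dp_to_dq(dP, lam, V, W, qp, qd, d, G)
        # chain rule into rates and multipliers
        gq_prog = np.empty((G, N_LIVING - 1))
        for r in range(N_LIVING - 1):
            gq_prog[:, r] = dQ[:, r, r + 1] - dQ[:, r, r]
        gq_death = -dQ[:, np.arange(N_LIVING), np.arange(N_LIVING)] \
            + dqd_direct
        wp = qp * gq_prog    # (G, 4) sensitivities to log rates via groups
        wd = qd * gq_death   # (G, 5)
        grad = np.zeros(self.layout.n_params)
        grad[:N_LIVING - 1] = wp.sum(axis=0)
        grad[N_LIVING - 1:self.layout.n_rates] = wd.sum(axis=0)
        pos = self.layout.n_rates
        X = d.X
        sp = wp.sum(axis=1)
        sd = wd.sum(axis=1)
        for cov in self.layout.mult_covs:
            f = FEATURES.index(cov)
            grad[pos] = X[:, f] @ sp
            grad[pos + 1] = X[:, f] @ sd
            pos += 2
        if self.options.emission == "free":
            dE_true_obs = dEL.T  # (true, obs)
            z_grad = np.empty(len(self.layout.emission_entries))
            row_dot = {}
            for r in range(N_LIVING):
                p = E[r, :N_LIVING]
                row_dot[r] = float(p @ dE_true_obs[r])
            for i, (r, s) in enumerate(self.layout.emission_entries):
                z_grad[i] = E[r, s] * (dE_true_obs[r, s] - row_dot[r])
            grad[self.layout.i_emission:] = z_grad
        return total, grad


def _p_steps(lam, V, W, qp, qd, gid, dt):
    """Transition matrices of all steps from the group decomposition.

    Groups whose exit rates nearly coincide make the eigen form
    ill-conditioned; their steps fall back to a batched series/squaring
    exponential.  (The analytic score keeps the eigen identity for those
    rare groups — adequate for line searches passing through such points.)
    """
    P = p_living(lam[gid], V[gid], W[gid], dt)
    unsafe = min_eigen_gap(lam) < 1e-3
    if unsafe.any():
        mask = unsafe[gid]
        if mask.any():
            Q = _q_living_batch(qp, qd)
            A = Q[gid[mask]] * dt[mask][:, None, None]
            P[mask] = np.clip(expm_taylor_batch(A), 0.0, 1.0)
    return P


def _q_living_batch(qp, qd):
    """(G, 5, 5) living blocks of the intensity matrices."""
    G = qd.shape[0]
    Q = np.zeros((G, N_LIVING, N_LIVING))
    rows = np.arange(N_LIVING - 1)
    Q[:, rows, rows + 1] = qp
    exits = qd.copy()
    exits[:, :-1] += qp
    Q[:, np.arange(N_LIVING), np.arange(N_LIVING)] = -exits
    return Q


def _dp_to_dq(dP, lam, V, W, qp, qd, design: _Design, G):
    """Backpropagate step-level dL/dP into group-level dL/dQ (living block).

    Uses the Daleckii-Krein identity dexpm(tQ)[dQ] =
    V (Phi(t) o (V^-1 dQ V)) V^-1 with Phi_ij = (e^{l_i t} - e^{l_j t}) /
    (l_i - l_j) off the diagonal and t e^{l_i t} on it.  Steps are
    pre-sorted by group so the per-group sum is a contiguous reduction.

    Groups with nearly tied exit rates (ill-conditioned eigenvectors) are
    redone exactly with the block-matrix Frechet identity: the adjoint of
    expm at A in direction Gbar is the top-right block of
    expm([[A^T, Gbar], [0, A^T]]).
    """
    perm = design.gid_perm
    gid = design.step_gid[perm]
    dt = design.step_dt[perm]
    lam_s = lam[gid]
    edt = np.exp(lam_s * dt[:, None])
    num = edt[:, :, None] - edt[:, None, :]
    den = lam_s[:, :, None] - lam_s[:, None, :]
    eye = np.eye(N_LIVING, dtype=bool)
    den[:, eye] = 1.0
    phi = num / den
    phi[:, eye] = dt[:, None] * edt
    Vt = np.swapaxes(V[gid], -1, -2)
    Wt = np.swapaxes(W[gid], -1, -2)
    X = np.matmul(np.matmul(Vt, dP[perm]), Wt)
    Y = phi * X
    Ysum = np.zeros((G, N_LIVING, N_LIVING))
    Ysum[design.gid_order] = np.add.reduceat(Y, design.gid_starts, axis=0)
    WtG = np.swapaxes(W, -1, -2)
    VtG = np.swapaxes(V, -1, -2)
    dQ = np.matmul(np.matmul(WtG, Ysum), VtG)
    unsafe = min_eigen_gap(lam) < 1e-3
    if unsafe.any():
        mask = unsafe[design.step_gid]
        if mask.any():
            sgid = design.step_gid[mask]
            sdt = design.step_dt[mask]
            Qb = _q_living_batch(qp, qd)
            A = Qb[sgid] * sdt[:, None, None]
            n = N_LIVING
            M = np.zeros((mask.sum(), 2 * n, 2 * n))
            At = np.swapaxes(A, -1, -2)
            M[:, :n, :n] = At
            M[:, n:, n:] = At
            M[:, :n, n:] = dP[mask]
            dA = expm_taylor_batch(M)[:, :n, n:]
            dQ[unsafe] = 0.0
            np.add.at(dQ, sgid, dA * sdt[:, None, None])
    return dQ


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def record_log_likelihood(record: PatientRecord, params: ModelParameters,
                          options: LikelihoodOptions | None = None) -> float:
    """Forward-algorithm log-likelihood of a single patient record.

    Returns ``-inf`` for sequences impossible under the parameters (e.g. an
    observed regression with an identity misclassification matrix).
    """
    cohort = Cohort(records=[record],
                    stratum=record.profile.albuminuria_stratum)
    engine = LikelihoodEngine(cohort, options)
    return float(engine.loglike_parameters(params, per_record=True)[0])


def cohort_log_likelihood(cohort: Cohort, params: ModelParameters,
                          options: LikelihoodOptions | None = None) -> float:
    """Sum of record log-likelihoods; order-independent."""
    if len(cohort) == 0:
        warnings.warn("empty cohort: log-likelihood is 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    engine = LikelihoodEngine(cohort, options)
    return engine.loglike_parameters(params)
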