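"""Model / Results interface for fitting the progression HMM.

:class:`CKDProgressionModel` wraps a cohort plus the likelihood conventions
(covariate set, misclassification band, age-updating and initial-state
rules); ``fit()`` maximises the forward-algorithm likelihood over
unconstrained transforms (log rates, log multipliers, multinomial-logit
emission rows) by quasi-Newton ascent with the analytic score, and returns
a :class:`CKDProgressionResults` carrying estimates, Wald confidence
intervals from the observed information (numerically differentiated
Hessian of the score), and reporting tables.  Confidence intervals are only
reported when the observed information is positive definite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.optimize import minimize

from .cohort import Cohort, cohort_from_dataframe, read_cohort_csv
from .likelihood import LikelihoodEngine, LikelihoodOptions
from .parameters import ModelParameters, Multiplier
from .states import DISPLAY_LABELS, LIVING_STAGES, N_LIVING

_Z95 = 1.959963984540054

#: canonical covariate ordering for reproducible parameter vectors
COVARIATE_ORDER = ("age", "male", "heart_failure", "cancer",
                   "hypertension", "diabetes")


class CKDProgressionModel:
    """Hidden Markov model of eGFR-stage progression with misclassification.

    Parameters
    ----------
    cohort
        A :class:`~ckdhmm.cohort.Cohort` of panel-observed records.
    options
        :class:`~ckdhmm.likelihood.LikelihoodOptions`; defaults fit the
        covariates sex, heart failure, cancer and annually updated age with
        a free emission matrix on the +/-2 band.
    fixed_emission
        Misclassification matrix to hold fixed when
        ``options.emission == "fixed"`` (identity if omitted).
    """

    def __init__(self, cohort: Cohort,
                 options: LikelihoodOptions | None = None,
                 fixed_emission: np.ndarray | None = None):
        if len(cohort) == 0:
            raise ValueError("cannot build a model from an empty cohort")
        self.cohort = cohort
        self.options = options or LikelihoodOptions()
        self.engine = LikelihoodEngine(cohort, self.options, fixed_emission)
        self.layout = self.engine.layout

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, stratum: str | None = None,
                       **kwargs) -> "CKDProgressionModel":
        return cls(cohort_from_dataframe(df, stratum=stratum), **kwargs)

    @classmethod
    def from_csv(cls, path, stratum: str | None = None,
                 **kwargs) -> "CKDProgressionModel":
        return cls(read_cohort_csv(path, stratum=stratum), **kwargs)

    # -- likelihood surface --------------------------------------------------
    def loglike(self, theta: np.ndarray) -> float:
        return self.engine.loglike(theta)

    def score(self, theta: np.ndarray) -> np.ndarray:
        return self.engine.score(theta)[1]

    # -- starting values -----------------------------------------------------
    def crude_start(self) -> np.ndarray:
        """Deterministic feasible start.

        Rates are crude event counts over observed person-time (treating
        observed stages as true); multipliers start at no effect; free
        emission off-diagonals start at 0.05.
        """
        time_in = np.zeros(N_LIVING)
        prog_events = np.zeros(N_LIVING - 1)
        death_events = np.zeros(N_LIVING)
        for rec in self.cohort:
            for k in range(1, rec.n_obs):
                r = rec.stages[k - 1]
                time_in[r] += rec.times[k] - rec.times[k - 1]
                if rec.stages[k] > r:
                    prog_events[min(r, N_LIVING - 2)] += 1
            if rec.died:
                r = rec.stages[-1]
                time_in[r] += rec.death_time - rec.times[-1]
                death_events[r] += 1
        with np.errstate(divide="ignore", invalid="ignore"):
            pr = np.where(time_in[:-1] > 0, prog_events
                          / np.maximum(time_in[:-1], 1e-12), 0.0)
            dr = np.where(time_in > 0, death_events
                          / np.maximum(time_in, 1e-12), 0.0)
        pr = np.clip(pr, 1e-4, 2.0)
        dr = np.clip(dr, 1e-4, 2.0)
        theta = np.zeros(self.layout.n_params)
        theta[:N_LIVING - 1] = np.log(pr)
        theta[N_LIVING - 1:self.layout.n_rates] = np.log(dr)
        # tiny deterministic spread keeps exit rates distinct at the start
        # (coinciding exit rates are a degenerate point of the eigen form)
        theta[:self.layout.n_rates] += 0.02 * np.arange(self.layout.n_rates)
        # multipliers start at log 1 = 0
        if self.options.emission == "free":
            n_off = np.zeros(N_LIVING)
            for r, _s in self.layout.emission_entries:
                n_off[r] += 1
            for i, (r, _s) in enumerate(self.layout.emission_entries):
                diag = 1.0 - 0.05 * n_off[r]
                theta[self.layout.i_emission + i] = math.log(0.05 / diag)
        return theta

    # -- fitting -------------------------------------------------------------
    def parameter_bounds(self) -> list[tuple[float, float]]:
        """Box bounds keeping the optimizer in a numerically sane region.

        Baseline rates within [1e-6, 10]/year; per-year age multipliers in
        [0.8, 1.25] (an exponent reaching +/-40 years makes larger values
        astronomically implausible); binary multipliers in [0.05, 20];
        emission logits in [-25, 3].  All far outside clinically plausible
        estimates, so the bounds never bind at a sensible optimum.
        """
        layout = self.layout
        bounds: list[tuple[float, float]] = []
        bounds += [(math.log(1e-6), math.log(10.0))] * layout.n_rates
        for c in layout.mult_covs:
            if c == "age":
                bounds += [(math.log(0.8), math.log(1.25))] * 2
            else:
                bounds += [(math.log(0.05), math.log(20.0))] * 2
        bounds += [(-25.0, 3.0)] * len(layout.emission_entries)
        return bounds

    def fit(self, start: np.ndarray | None = None, maxiter: int = 500,
            n_starts: int = 1, seed: int = 0, compute_hessian: bool = True,
            hessian_step: float = 1e-4) -> "CKDProgressionResults":
        """Maximum-likelihood fit.

        ``n_starts > 1`` adds jittered restarts around the crude start as a
        guard against local maxima (the deterministic start is always the
        first).  Non-convergence is flagged on the results, never silent.
        """
        theta0 = np.asarray(start, dtype=float) if start is not None \
            else self.crude_start()
        rng = np.random.default_rng(seed)
        bounds = self.parameter_bounds()
        lob = np.array([b[0] for b in bounds])
        upb = np.array([b[1] for b in bounds])
        theta0 = np.clip(theta0, lob, upb)
        # precondition: the age-multiplier coordinates act through an
        # exponent spanning roughly +/- 40 years, so their curvature is
        # ~40^2 times that of the other log parameters; rescaling them
        # equalises the geometry for the quasi-Newton line search
        scale = np.ones_like(theta0)
        pos = self.layout.n_rates
        for c in self.layout.mult_covs:
            if c == "age":
                scale[pos:pos + 2] = 30.0
            pos += 2

        def neg_x(x):
            theta = x / scale
            try:
                ll, g = self.engine.score(theta)
            except FloatingPointError:
                return 1e30, np.zeros_like(x)
            if not np.isfinite(ll):
                return 1e30, np.zeros_like(x)
            return -ll, -g / scale

        xbounds = list(zip(lob * scale, upb * scale))

        def run(x_init):
            res = minimize(neg_x, x_init, jac=True, method="L-BFGS-B",
                           bounds=xbounds,
                           options={"maxiter": maxiter, "maxcor": 25})
            # restart with cleared quasi-Newton memory while it helps:
            # recovers from occasional line-search stalls far from optimum
            for _ in range(6):
                res2 = minimize(neg_x, res.x, jac=True, method="L-BFGS-B",
                                bounds=xbounds,
                                options={"maxiter": maxiter, "maxcor": 25})
                improved = res2.fun < res.fun - 1e-6 * (1 + abs(res.fun))
                res2.nit += res.nit
                res = res2 if res2.fun <= res.fun else res
                if not improved:
                    break
            return res

        best = None
        for i in range(max(1, n_starts)):
            x0 = theta0 * scale if i == 0 else np.clip(
                theta0 + rng.normal(0.0, 0.2, len(theta0)), lob, upb) * scale
            res = run(x0)
            if best is None or res.fun < best.fun:
                best = res
        theta_hat = best.x / scale
        converged = bool(best.success)
        if not converged:
            warnings.warn(f"optimizer did not report convergence: "
                          f"{best.message}", RuntimeWarning, stacklevel=2)
        hessian = None
        cov = None
        hessian_pd = False
        if compute_hessian:
            hessian = self._score_hessian(theta_hat, hessian_step)
            try:
                cf = cho_factor(-hessian)
                cov = cho_solve(cf, np.eye(len(theta_hat)))
                hessian_pd = True
            except LinAlgError:
                warnings.warn(
                    "observed information is not positive definite; "
                    "confidence intervals are not reported",
                    RuntimeWarning, stacklevel=2)
        return CKDProgressionResults(
            model=self, theta=theta_hat, llf=float(-best.fun),
            converged=converged, n_iter=int(best.nit), hessian=hessian,
            hessian_pd=hessian_pd, cov=cov)

    def _score_hessian(self, theta: np.ndarray, step: float) -> np.ndarray:
        """Central differences of the analytic score."""
        p = len(theta)
        H = np.empty((p, p))
        for i in range(p):
            h = step * (1.0 + abs(theta[i]))
            tp = theta.copy()
            tp[i] += h
            tm = theta.copy()
            tm[i] -= h
            H[:, i] = (self.engine.score(tp)[1]
                       - self.engine.score(tm)[1]) / (2 * h)
        return 0.5 * (H + H.T)


class CKDProgressionResults:
    """Fitted progression model: estimates, uncertainty, reporting."""

    def __init__(self, model: CKDProgressionModel, theta: np.ndarray,
                 llf: float, converged: bool, n_iter: int,
                 hessian: np.ndarray | None, hessian_pd: bool,
                 cov: np.ndarray | None):
        self.model = model
        self.theta = np.asarray(theta, dtype=float)
        self.llf = llf
        self.converged = converged
        self.n_iter = n_iter
        self.hessian = hessian
        self.hessian_pd = hessian_pd
        self._cov = cov

    # -- basic accessors -----------------------------------------------------
    @property
    def param_names(self) -> list[str]:
        return list(self.model.layout.names)

    def cov_params(self) -> np.ndarray:
        if not self.hessian_pd:
            raise ValueError("no covariance: observed information is not "
                             "positive definite")
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        """Standard errors on the unconstrained (log / logit) scale."""
        return np.sqrt(np.diag(self.cov_params()))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald intervals on the unconstrained scale."""
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        se = self.bse
        lo = self.theta - z * se
        hi = self.theta + z * se
        return pd.DataFrame({"estimate": self.theta, "se": se,
                             "lower": lo, "upper": hi},
                            index=self.param_names)

    @property
    def params(self) -> ModelParameters:
        """Estimates as :class:`ModelParameters` (CIs attached when available)."""
        layout = self.model.layout
        params = layout.to_parameters(
            self.theta, fixed_emission=self.model.engine.fixed_emission,
            cohort=self.model.cohort.stratum)
        if not self.hessian_pd:
            return params
        ci = self.conf_int()
        mults = {}
        pos = layout.n_rates
        for c in layout.mult_covs:
            mults[c] = Multiplier(
                progression=math.exp(self.theta[pos]),
                death=math.exp(self.theta[pos + 1]),
                progression_ci=(math.exp(ci["lower"].iloc[pos]),
                                math.exp(ci["upper"].iloc[pos])),
                death_ci=(math.exp(ci["lower"].iloc[pos + 1]),
                          math.exp(ci["upper"].iloc[pos + 1])))
            pos += 2
        return params.replace(multipliers=mults)

    # -- natural-scale tables -------------------------------------------------
    def rate_table(self) -> pd.DataFrame:
        """Baseline intensities (rates/year) with back-transformed CIs."""
        names = ([f"{LIVING_STAGES[r]}->{LIVING_STAGES[r + 1]}"
                  for r in range(N_LIVING - 1)]
                 + [f"{s}->DEATH" for s in LIVING_STAGES])
        est = np.exp(self.theta[:self.model.layout.n_rates])
        out = pd.DataFrame({"rate": est}, index=names)
        if self.hessian_pd:
            ci = self.conf_int().iloc[:self.model.layout.n_rates]
            out["lower"] = np.exp(np.minimum(ci["lower"].to_numpy(), 700))
            out["upper"] = np.exp(np.minimum(ci["upper"].to_numpy(), 700))
        return out

    def multiplier_table(self) -> pd.DataFrame:
        """Covariate multipliers with the display convention applied.

        The displayed value is set to 1.00 whenever the confidence interval
        overlaps no effect (the estimates themselves are retained); without
        a CI the display is blank and flagged.
        """
        layout = self.model.layout
        rows = []
        pos = layout.n_rates
        ci = self.conf_int() if self.hessian_pd else None
        for c in layout.mult_covs:
            for j, kind in enumerate(("progression", "death")):
                est = math.exp(self.theta[pos + j])
                row = {"covariate": c, "transition": kind, "estimate": est,
                       "has_ci": self.hessian_pd}
                if ci is not None:
                    lo = math.exp(ci["lower"].iloc[pos + j])
                    hi = math.exp(ci["upper"].iloc[pos + j])
                    row.update(lower=lo, upper=hi,
                               display=("1.00" if lo <= 1.0 <= hi
                                        else f"{est:.2f}"))
                else:
                    row.update(lower=np.nan, upper=np.nan, display="")
                rows.append(row)
            pos += 2
        return pd.DataFrame(rows)

    def emission_table(self) -> pd.DataFrame:
        """Misclassification probabilities with delta-method CIs."""
        layout = self.model.layout
        E = self.params.emission
        rows = []
        if layout.options.emission == "fixed":
            for r in range(N_LIVING):
                for s in range(N_LIVING):
                    if E[r, s] > 0:
                        rows.append({"true": LIVING_STAGES[r],
                                     "observed": LIVING_STAGES[s],
                                     "probability": E[r, s]})
            return pd.DataFrame(rows)
        cov = self._cov if self.hessian_pd else None
        by_row: dict[int, list[tuple[int, int]]] = {}
        for i, (r, s) in enumerate(layout.emission_entries):
            by_row.setdefault(r, []).append((i + layout.i_emission, s))
        for r in range(N_LIVING):
            idx = by_row.get(r, [])
            cols = [s for _i, s in idx] + [r]
            for s in sorted(cols):
                entry = {"true": LIVING_STAGES[r],
                         "observed": LIVING_STAGES[s],
                         "probability": E[r, s]}
                if cov is not None and idx:
                    ii = [i for i, _s in idx]
                    # d p_s / d z_u = p_s (1{s=u} - p_u)
                    grad = np.array([
                        E[r, s] * ((1.0 if s == su else 0.0) - E[r, su])
                        for _i, su in idx])
                    var = float(grad @ cov[np.ix_(ii, ii)] @ grad)
                    half = _Z95 * math.sqrt(max(var, 0.0))
                    entry["lower"] = max(0.0, E[r, s] - half)
                    entry["upper"] = min(1.0, E[r, s] + half)
                rows.append(entry)
        return pd.DataFrame(rows)

    def sojourn_table(self) -> pd.DataFrame:
        """Reference-profile mean sojourn times (years) with delta CIs.

        The sojourn in stage r is the inverse of the total exit rate
        (progression plus death); the CI comes from the delta method on the
        log sojourn using the covariance of the log rates.
        """
        layout = self.model.layout
        a = np.exp(self.theta[:layout.n_rates])
        prog = np.append(a[:N_LIVING - 1], 0.0)
        death = a[N_LIVING - 1:]
        exit_rate = prog + death
        sojourn = 1.0 / exit_rate
        out = pd.DataFrame({"stage": [DISPLAY_LABELS[s]
                                      for s in LIVING_STAGES],
                            "sojourn_years": sojourn})
        if self.hessian_pd:
            cov = self._cov
            lo, hi = [], []
            for r in range(N_LIVING):
                grad = np.zeros(layout.n_params)
                if r < N_LIVING - 1:
                    grad[r] = -prog[r] / exit_rate[r]
                grad[N_LIVING - 1 + r] = -death[r] / exit_rate[r]
                se = math.sqrt(max(float(grad @ cov @ grad), 0.0))
                lo.append(sojourn[r] * math.exp(-_Z95 * se))
                hi.append(sojourn[r] * math.exp(_Z95 * se))
            out["lower"] = lo
            out["upper"] = hi
        return out.set_index("stage")

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fit."""
        n_obs = self.model.cohort.n_observations
        lines = [
            "CKD progression hidden Markov model",
            "=" * 52,
            f"cohort stratum:        {self.model.cohort.stratum}",
            f"patients / eGFR tests: {len(self.model.cohort)} / {n_obs}",
            f"log-likelihood:        {self.llf:.3f}",
            f"converged:             {self.converged} "
            f"({self.n_iter} iterations)",
            f"observed information positive definite: {self.hessian_pd}",
            "",
            "Baseline intensities (per year, reference profile):",
            self.rate_table().to_string(float_format=lambda v: f"{v:.5f}"),
            "",
            "Covariate multipliers:",
            self.multiplier_table().to_string(
                index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            "Mean sojourn times (years):",
            self.sojourn_table().to_string(
                float_format=lambda v: f"{v:.1f}"),
        ]
        return "\n".join(lines)

    def save_tables(self, directory) -> dict[str, str]:
        """Write parameter/report CSVs; returns {name: path}."""
        import os
        out = {}
        for name, df in (("rates", self.rate_table()),
                         ("multipliers", self.multiplier_table()),
                         ("emission", self.emission_table()),
                         ("sojourn", self.sojourn_table())):
            path = os.path.join(directory, f"fit_{name}.csv")
            df.to_csv(path, float_format="%.8g")
            out[name] = path
        return out

    # -- downstream analyses ---------------------------------------------------
    def decode(self, cohort: Cohort | None = None):
        from .decoding import decode_cohort
        return decode_cohort(cohort or self.model.cohort, self.params,
                             self.model.options)

    def grading_rates(self, cohort: Cohort | None = None):
        from .decoding import grading_rates
        return grading_rates(cohort or self.model.cohort, self.params,
                             self.model.options)

    def calibration_table(self, test_cohort: Cohort,
                          bin_width_years: float = 1.0):
        from .monitoring import calibration_table
        return calibration_table(self.params, test_cohort,
                                 bin_width_years=bin_width_years,
                                 options=self.model.options)


def fit_with_covariate_selection(
        cohort: Cohort, options: LikelihoodOptions | None = None,
        candidates: tuple[str, ...] = ("hypertension", "diabetes"),
        fixed_emission: np.ndarray | None = None,
        **fit_kwargs):
    """Fit with candidate covariates, dropping them if uninformative.

    The model is first fitted including *candidates*; if no candidate
    multiplier's confidence interval excludes no effect (for either
    progression or death), the candidates are removed and the model
    refitted.  Returns ``(results, dropped)``.
    """
    base = options or LikelihoodOptions()
    covs = tuple(c for c in COVARIATE_ORDER
                 if c in set(base.covariates) | set(candidates))
    full_opts = replace(base, covariates=covs)
    full = CKDProgressionModel(cohort, full_opts,
                               fixed_emission=fixed_emission).fit(**fit_kwargs)
    if not full.hessian_pd:
        return full, ()
    table = full.multiplier_table()
    droppable = []
    for c in candidates:
        sub = table[table["covariate"] == c]
        informative = ((sub["lower"] > 1.0) | (sub["upper"] < 1.0)).any()
        if not informative:
            droppable.append(c)
    if len(droppable) < len(candidates):
        return full, ()
    reduced_covs = tuple(c for c in covs if c not in candidates)
    reduced_opts = replace(base, covariates=reduced_covs)
    reduced = CKDProgressionModel(
        cohort, reduced_opts, fixed_emission=fixed_emission).fit(**fit_kwargs)
    return reduced, tuple(droppable)
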