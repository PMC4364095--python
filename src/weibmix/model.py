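"""Model and results classes for the four Weibull event-history models.

Usage follows the fit-and-inspect idiom of statsmodels::

    from weibmix import WeibullEventModel

    model = WeibullEventModel.from_event_table(table, kind="m2",
                                               covariates=["diabetes", "male"])
    res = model.fit()
    print(res.summary())
    res.hazard_ratios()          # conditional HRs with Wald CIs
    res.marginalized_hr("diabetes")   # population-averaged HR

Model kinds
-----------
``m1``
    Time to first event of any type; plain Weibull regression.
``m2``
    Recurrent events pooled over types with a shared subject-level normal
    random effect (log-normal frailty) of SD sigma.
``m3``
    First event of each type with type-specific Weibull shapes and a shared
    subject-level random effect of SD tau.
``m4``
    Joint recurrent + multi-type model: type-specific shapes plus two
    independent normal random effects — subject-by-type (SD chi) and subject
    (SD delta).

Estimation maximizes the Gauss-Hermite marginal likelihood with analytic
scores; standard errors come from the observed information (central-difference
Hessian of the analytic score at the optimum).
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import EventTable, ModelFrame, build_model_frame
from .likelihood import WeibullLikelihood
from .params import ParameterSet

__all__ = ["WeibullEventModel", "WeibullEventResults", "hazard_ratios"]

logger = logging.getLogger(__name__)

KIND_LABELS = {
    "m1": "time-to-first-event",
    "m2": "recurrent events (shared frailty)",
    "m3": "multivariate event types",
    "m4": "joint recurrent + multivariate",
}


class WeibullEventModel:
    """Weibull event-history model bound to one analysis frame.

    Parameters
    ----------
    frame : ModelFrame
        Frame built by :func:`weibmix.data.build_model_frame` (its ``kind``
        selects the model).
    quadrature_nodes : int
        Gauss-Hermite nodes per random-effect dimension; default 15.
    """

    def __init__(self, frame: ModelFrame, quadrature_nodes: int = 15):
        self.frame = frame
        self.kind = frame.kind
        self.nodes = quadrature_nodes
        self.engine = WeibullLikelihood(frame, nodes=quadrature_nodes)
        self.exog_names = frame.covariate_names
        self.param_names = self.engine.param_names

    @classmethod
    def from_event_table(
        cls,
        table: EventTable,
        kind: str,
        covariates: list[str] | None = None,
        event_types: list[str] | None = None,
        timescale: str = "total",
        quadrature_nodes: int = 15,
    ) -> "WeibullEventModel":
        frame = build_model_frame(
            table, kind, covariates=covariates, event_types=event_types, timescale=timescale
        )
        return cls(frame, quadrature_nodes=quadrature_nodes)

    # ------------------------------------------------------------------
    def loglike(self, params) -> float:
        """Marginal log-likelihood at a ParameterSet or internal vector."""
        if isinstance(params, ParameterSet):
            return self.engine.from_params(params)
        return self.engine.value(np.asarray(params, dtype=float))

    def score(self, theta) -> np.ndarray:
        return self.engine.value_and_grad(np.asarray(theta, dtype=float))[1]

    # ------------------------------------------------------------------
    def _start_theta(self, init) -> np.ndarray:
        if isinstance(init, ParameterSet):
            return init.to_internal(self.kind)
        if isinstance(init, np.ndarray):
            return np.asarray(init, dtype=float)
        if init != "auto":
            raise ValueError("init must be 'auto', a ParameterSet, or a vector")
        eng = self.engine
        exposure = float(np.sum(eng.t - eng.entry))
        events = float(np.sum(eng.status))
        n_stream_per_subj = eng.n_streams / eng.n_subjects
        rate = max(events, 0.5) / max(exposure * n_stream_per_subj, 1e-8)
        p = len(self.exog_names)
        theta0 = np.concatenate(
            [
                [np.log(rate)],
                np.zeros(p),
                np.zeros(eng.n_shapes),                   # log rho = 0
                np.log(0.3) * np.ones(eng.n_params - 1 - p - eng.n_shapes),
            ]
        )
        if self.kind == "m1":
            return theta0
        # warm start: pooled (zero random effect) fit seeds beta and rho
        n_fixed = 1 + p + eng.n_shapes
        def pooled(th_red):
            th = theta0.copy()
            th[:n_fixed] = th_red
            # force degenerate random effects for the warm-start objective
            ll, g = eng._compute(
                float(th[0]), th[1 : 1 + p], np.exp(th[1 + p : n_fixed]), 0.0, 0.0, True
            )
            if not np.isfinite(ll) or not np.all(np.isfinite(g)):
                return 1e12, np.zeros(n_fixed)
            return -ll, -g[:n_fixed]
        res = optimize.minimize(pooled, theta0[:n_fixed], jac=True, method="BFGS",
                                options={"maxiter": 200})
        theta0[:n_fixed] = res.x
        return theta0

    def fit(
        self,
        init="auto",
        maxiter: int = 500,
        gtol: float = 1e-5,
        method: str = "BFGS",
    ) -> "WeibullEventResults":
        """Maximize the marginal likelihood and return a results object.

        Non-convergence does not raise: the returned results carry
        ``converged=False`` and the optimizer message.  A singular Hessian
        leaves ``cov_ok=False`` (Wald inference unavailable).
        """
        if float(np.sum(self.engine.status)) == 0:
            raise ValueError("frame contains no observed events")
        theta0 = self._start_theta(init)
        res = optimize.minimize(
            self.engine.neg_value_and_grad,
            theta0,
            jac=True,
            method=method,
            options={"maxiter": maxiter, "gtol": gtol},
        )
        theta = res.x
        ll, grad = self.engine.value_and_grad(theta)
        gnorm = float(np.max(np.abs(grad)))
        converged = bool(res.success) or gnorm < 1e-3 * max(1.0, abs(ll)) * 1e-2
        if not res.success:
            # one polishing pass sometimes rescues a flat line search
            res2 = optimize.minimize(
                self.engine.neg_value_and_grad, theta, jac=True, method="L-BFGS-B",
                options={"maxiter": maxiter},
            )
            if -res2.fun > ll:
                theta = res2.x
                ll, grad = self.engine.value_and_grad(theta)
                gnorm = float(np.max(np.abs(grad)))
                converged = bool(res2.success)
        hess = self._hessian(theta)
        cov, cov_ok = self._covariance(hess)
        return WeibullEventResults(
            model=self,
            theta=theta,
            cov_theta=cov,
            cov_ok=cov_ok,
            llf=float(ll),
            converged=converged,
            niter=int(res.nit),
            message=str(res.message),
            grad_norm=gnorm,
        )

    # ------------------------------------------------------------------
    def _hessian(self, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
        """Central finite differences of the analytic score."""
        n = len(theta)
        H = np.empty((n, n))
        for j in range(n):
            h = rel_step * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            gp = self.engine.value_and_grad(tp)[1]
            gm = self.engine.value_and_grad(tm)[1]
            H[:, j] = (gp - gm) / (2 * h)
        return 0.5 * (H + H.T)

    @staticmethod
    def _covariance(hess: np.ndarray) -> tuple[np.ndarray, bool]:
        neg = -hess
        try:
            cov = np.linalg.inv(neg)
            if np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0):
                return cov, True
        except np.linalg.LinAlgError:
            pass
        logger.warning("observed information singular or indefinite; using pseudo-inverse")
        cov = np.linalg.pinv(neg)
        return cov, False


class WeibullEventResults:
    """Maximum-likelihood results for a :class:`WeibullEventModel`.

    ``params`` reports natural-scale estimates (shapes and random-effect SDs
    back-transformed from the log scale); ``cov_params()`` is the covariance
    of the internal (log-transformed) parameter vector, whose names carry the
    transform, e.g. ``log(shape)``.
    """

    def __init__(self, model, theta, cov_theta, cov_ok, llf, converged,
                 niter, message, grad_norm):
        self.model = model
        self._theta = np.asarray(theta, dtype=float)
        self._cov_theta = np.asarray(cov_theta, dtype=float)
        self.cov_ok = bool(cov_ok)
        self.llf = llf
        self.converged = converged
        self.niter = niter
        self.message = message
        self.grad_norm = grad_norm
        self.nobs = model.frame.n_rows
        self.n_subjects = model.frame.n_subjects

    # -- parameter views ------------------------------------------------
    @property
    def parameter_set(self) -> ParameterSet:
        return ParameterSet.from_internal(
            self._theta, self.model.kind, self.model.exog_names, self.model.engine.n_shapes
        )

    def _natural_names(self) -> list[str]:
        eng = self.model.engine
        names = ["intercept"] + list(self.model.exog_names)
        if eng.n_shapes == 1:
            names.append("shape")
        else:
            names += [f"shape[{t}]" for t in self.model.frame.event_types]
        names += {
            "m1": [],
            "m2": ["sd_recurrent"],
            "m3": ["sd_type"],
            "m4": ["sd_subject_type", "sd_subject"],
        }[self.model.kind]
        return names

    def _log_scale_mask(self) -> np.ndarray:
        p = len(self.model.exog_names)
        mask = np.zeros(len(self._theta), dtype=bool)
        mask[1 + p :] = True
        return mask

    @property
    def params(self) -> pd.Series:
        mask = self._log_scale_mask()
        vals = np.where(mask, np.exp(self._theta), self._theta)
        return pd.Series(vals, index=self._natural_names())

    @property
    def bse(self) -> pd.Series:
        se_int = np.sqrt(np.clip(np.diag(self._cov_theta), 0, None))
        mask = self._log_scale_mask()
        nat = self.params.to_numpy()
        se = np.where(mask, nat * se_int, se_int)   # delta method for exp()
        return pd.Series(se, index=self._natural_names())

    def cov_params(self) -> pd.DataFrame:
        names = self.model.param_names
        return pd.DataFrame(self._cov_theta, index=names, columns=names)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        se_int = np.sqrt(np.clip(np.diag(self._cov_theta), 0, None))
        lo_int = self._theta - z * se_int
        hi_int = self._theta + z * se_int
        mask = self._log_scale_mask()
        lo = np.where(mask, np.exp(lo_int), lo_int)
        hi = np.where(mask, np.exp(hi_int), hi_int)
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self._natural_names())

    # -- inference ------------------------------------------------------
    def hazard_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """Conditional hazard ratios ``exp(beta)`` with Wald intervals."""
        return hazard_ratios(self, level=level)

    def marginal_survival(self, t, x=None, nodes: int | None = None):
        from .marginal import marginal_survival

        return marginal_survival(t, x, self, nodes=nodes or self.model.nodes)

    def marginalized_hr(self, covariate: str, contrast=(0.0, 1.0), time_grid=None,
                        reference_x=None, level: float = 0.95):
        from .marginal import marginalized_hr

        return marginalized_hr(self, covariate, contrast=contrast, time_grid=time_grid,
                               reference_x=reference_x, level=level)

    # -- reporting ------------------------------------------------------
    def summary(self, level: float = 0.95) -> str:
        p = self.params
        se = self.bse
        ci = self.conf_int(level)
        kind = self.model.kind
        lines = [
            f"Weibull event-history model [{kind}: {KIND_LABELS[kind]}]",
            f"subjects: {self.n_subjects}    rows: {self.nobs}    "
            f"events: {int(self.model.engine.status.sum())}",
            f"log-likelihood: {self.llf:.3f}    converged: {self.converged}"
            + ("" if self.cov_ok else "    [covariance unavailable]"),
            "-" * 72,
            f"{'parameter':<24}{'estimate':>10}{'std err':>10}"
            f"{'[' + format(level, '.0%'):>12}{']':>14}",
        ]
        for name in p.index:
            lines.append(
                f"{name:<24}{p[name]:>10.4f}{se[name]:>10.4f}"
                f"{ci.loc[name, 'lower']:>12.4f}{ci.loc[name, 'upper']:>14.4f}"
            )
        lines.append("-" * 72)
        hr = self.hazard_ratios(level)
        if len(hr):
            lines.append(f"{'covariate':<24}{'HR':>10}{'lower':>12}{'upper':>14}")
            for _, row in hr.iterrows():
                lines.append(
                    f"{row['covariate']:<24}{row['hr']:>10.4f}"
                    f"{row['lower']:>12.4f}{row['upper']:>14.4f}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        hr = self.hazard_ratios()
        return {
            "kind": self.model.kind,
            "loglik": self.llf,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "n_rows": self.nobs,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "hazard_ratios": hr.to_dict(orient="records"),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def hazard_ratios(result: WeibullEventResults, level: float = 0.95) -> pd.DataFrame:
    """Wald hazard-ratio table for every covariate in a fitted model.

    HR = exp(beta_hat); bounds = exp(beta_hat +/- z * SE).  Requires a usable
    covariance (``result.cov_ok``).
    """
    if not result.cov_ok:
        raise ValueError("covariance unavailable; cannot form Wald intervals")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    names = result.model.exog_names
    p = len(names)
    beta = result._theta[1 : 1 + p]
    se = np.sqrt(np.clip(np.diag(result._cov_theta)[1 : 1 + p], 0, None))
    return pd.DataFrame(
        {
            "covariate": names,
            "hr": np.exp(beta),
            "lower": np.exp(beta - z * se),
            "upper": np.exp(beta + z * se),
            "se_log": se,
        }
    )
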