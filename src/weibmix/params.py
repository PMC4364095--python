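"""Parameter containers and the mapping to the unconstrained optimizer scale.

Positivity-constrained quantities (Weibull shapes, random-effect standard
deviations) are estimated on the log scale and reported on the natural
scale.  The internal ("theta") layout per model kind is::

    m1: [beta0, beta_1..p, log rho]
    m2: [beta0, beta_1..p, log rho, log sigma]
    m3: [beta0, beta_1..p, log rho_1..K, log tau]
    m4: [beta0, beta_1..p, log rho_1..K, log chi, log delta]

where sigma is the recurrent-event frailty SD, tau the shared event-type
frailty SD, chi the subject-by-type SD and delta the subject SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ParameterSet", "RandomEffectDraw"]

_SD_FIELD = {"m2": "sd_recurrent", "m3": "sd_type"}


@dataclass
class ParameterSet:
    """Natural-scale parameters of any of the four Weibull event models.

    Only the variance components relevant to a model kind are used by it:
    ``sd_recurrent`` (sigma) for the recurrent model, ``sd_type`` (tau) for
    the multivariate model, ``sd_subject_type`` (chi) and ``sd_subject``
    (delta) for the joint model.
    """

    beta0: float
    beta: pd.Series
    shape: float | np.ndarray = 1.0
    sd_recurrent: float = 0.0
    sd_type: float = 0.0
    sd_subject_type: float = 0.0
    sd_subject: float = 0.0

    def __post_init__(self) -> None:
        self.beta = pd.Series(self.beta, dtype=float)
        shp = np.atleast_1d(np.asarray(self.shape, dtype=float))
        if np.any(shp <= 0):
            raise ValueError("shape parameters must be positive")
        for name in ("sd_recurrent", "sd_type", "sd_subject_type", "sd_subject"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    # ------------------------------------------------------------------
    @property
    def shapes(self) -> np.ndarray:
        """Shape(s) as a 1-d array (length K for m3/m4, length 1 otherwise)."""
        return np.atleast_1d(np.asarray(self.shape, dtype=float))

    def total_random_variance(self, kind: str) -> float:
        """Variance of the total random offset entering the log scale."""
        if kind == "m1":
            return 0.0
        if kind == "m2":
            return self.sd_recurrent**2
        if kind == "m3":
            return self.sd_type**2
        if kind == "m4":
            return self.sd_subject_type**2 + self.sd_subject**2
        raise ValueError(f"unknown model kind {kind!r}")

    # -- theta packing --------------------------------------------------
    def to_internal(self, kind: str) -> np.ndarray:
        parts = [np.array([self.beta0]), self.beta.to_numpy(dtype=float),
                 np.log(self.shapes)]
        if kind in ("m2", "m3"):
            parts.append(np.log([max(getattr(self, _SD_FIELD[kind]), 1e-8)]))
        elif kind == "m4":
            parts.append(np.log([max(self.sd_subject_type, 1e-8),
                                 max(self.sd_subject, 1e-8)]))
        elif kind != "m1":
            raise ValueError(f"unknown model kind {kind!r}")
        return np.concatenate(parts)

    @staticmethod
    def from_internal(theta: np.ndarray, kind: str, covariate_names: list[str],
                      n_shapes: int = 1) -> "ParameterSet":
        theta = np.asarray(theta, dtype=float)
        p = len(covariate_names)
        beta0 = float(theta[0])
        beta = pd.Series(theta[1 : 1 + p], index=list(covariate_names))
        shapes = np.exp(theta[1 + p : 1 + p + n_shapes])
        shape = float(shapes[0]) if n_shapes == 1 else shapes
        rest = theta[1 + p + n_shapes :]
        kw = {}
        if kind == "m2":
            kw["sd_recurrent"] = float(np.exp(rest[0]))
        elif kind == "m3":
            kw["sd_type"] = float(np.exp(rest[0]))
        elif kind == "m4":
            kw["sd_subject_type"] = float(np.exp(rest[0]))
            kw["sd_subject"] = float(np.exp(rest[1]))
        return ParameterSet(beta0=beta0, beta=beta, shape=shape, **kw)

    @staticmethod
    def internal_names(kind: str, covariate_names: list[str], n_shapes: int = 1) -> list[str]:
        names = ["intercept"] + list(covariate_names)
        if n_shapes == 1:
            names.append("log(shape)")
        else:
            names += [f"log(shape[{k}])" for k in range(n_shapes)]
        if kind == "m2":
            names.append("log(sd_recurrent)")
        elif kind == "m3":
            names.append("log(sd_type)")
        elif kind == "m4":
            names += ["log(sd_subject_type)", "log(sd_subject)"]
        return names


@dataclass
class RandomEffectDraw:
    """One realization of the random effects for a single subject.

    ``subject_effect`` is a_i (recurrent model), b_i (multivariate model) or
    d_i (joint model); ``type_effects`` holds the K subject-by-type effects
    c_ik of the joint model and is ignored elsewhere.
    """

    subject_effect: float = 0.0
    type_effects: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.type_effects = np.asarray(self.type_effects, dtype=float)
        if not np.isfinite(self.subject_effect) or not np.all(np.isfinite(self.type_effects)):
            raise ValueError("random-effect draws must be finite")
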