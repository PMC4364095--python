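"""Conditional and marginal log-likelihoods for the four Weibull event models.

Given a row with entry time ``e``, exit time ``t``, event indicator ``s`` and
log-scale linear predictor ``eta = beta0 + beta.x + u`` (with ``u`` the row's
total random-effect offset), its log-likelihood contribution is

    s * [log rho + (rho - 1) log t + eta]  -  exp(eta) * (t**rho - e**rho),

i.e. the log hazard at the event time plus the survival increment over the
at-risk interval.  For first-event rows (``e = 0``) this is exactly
``s * logpdf + (1 - s) * logsurv``; for recurrent rows it is the correct
left-truncated (total-time counting process) contribution.

Because covariates are baseline-fixed and the offset is shared within a
(subject, type) stream, each stream's contribution collapses to

    LL_stream(u) = A + S u - G exp(u)

with per-stream aggregates A (events' log-hazard terms at u=0), S (event
count) and G (cumulative baseline hazard mass).  Marginalizing the normal
random effects by Gauss-Hermite quadrature then costs O(streams x nodes)
per likelihood evaluation, and the score is available analytically, which is
what makes the joint model practical at cohort scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp, roots_hermite

from .data import NO_EVENT, ModelFrame
from .params import ParameterSet, RandomEffectDraw

__all__ = ["WeibullLikelihood", "conditional_loglik", "marginal_loglik"]

_SQRT2 = np.sqrt(2.0)
_BIG = 1e12


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Standardized Gauss-Hermite rule: integrates g against N(0,1) exactly
    for polynomials; offsets are ``sd * sqrt(2) * z`` with weights ``w/sqrt(pi)``."""
    z, w = roots_hermite(n)
    return z, np.log(w) - 0.5 * np.log(np.pi)


class WeibullLikelihood:
    """Precompiled likelihood for one :class:`~weibmix.data.ModelFrame`.

    Parameters
    ----------
    frame : ModelFrame
        Analysis frame (kind m1..m4) with an ``entry`` column.
    nodes : int
        Gauss-Hermite nodes per random-effect dimension (ignored for m1).
    """

    def __init__(self, frame: ModelFrame, nodes: int = 15):
        if nodes < 1:
            raise ValueError("nodes must be >= 1")
        self.frame = frame
        self.kind = frame.kind
        self.nodes = int(nodes)
        self.covariate_names = frame.covariate_names

        d = frame.data
        bad = (d["status"] == 1) & (d["time"] <= 0)
        if bad.any():
            raise ValueError("event rows must have strictly positive time")
        if (d["entry"] >= d["time"]).any() and not np.allclose(
            d.loc[d["entry"] >= d["time"], "entry"], d.loc[d["entry"] >= d["time"], "time"]
        ):
            raise ValueError("entry must not exceed time")

        self.t = d["time"].to_numpy(dtype=float)
        self.entry = d["entry"].to_numpy(dtype=float)
        self.status = d["status"].to_numpy(dtype=float)

        subj_index = frame.covariates.index
        pos = pd.Series(np.arange(len(subj_index)), index=subj_index)
        self.row_subject = pos.loc[d["subject_id"]].to_numpy()
        self.n_subjects = len(subj_index)
        self.X = frame.covariates.to_numpy(dtype=float)

        if self.kind in ("m3", "m4"):
            self.K = len(frame.event_types)
            tmap = {t: i for i, t in enumerate(frame.event_types)}
            self.row_type = d["event_type"].map(tmap).to_numpy(dtype=int)
            self.n_shapes = self.K
        else:
            self.K = max(len(frame.event_types), 1)
            self.row_type = np.zeros(len(d), dtype=int)
            self.n_shapes = 1

        # streams: per-(subject, type) groups.  m4 needs them because each
        # stream has its own c_ik; m3 because each stream has its own rho_k.
        if self.kind in ("m3", "m4"):
            codes = self.row_subject * self.K + self.row_type
            uniq, self.row_stream = np.unique(codes, return_inverse=True)
            self.stream_subject = uniq // self.K
            self.stream_type = (uniq % self.K).astype(int)
        else:
            self.row_stream = self.row_subject
            self.stream_subject = np.arange(self.n_subjects)
            self.stream_type = np.zeros(self.n_subjects, dtype=int)
        self.n_streams = len(self.stream_subject)

        with np.errstate(divide="ignore"):
            self.logt = np.where(self.t > 0, np.log(np.maximum(self.t, 1e-300)), 0.0)
            self.logentry = np.where(self.entry > 0, np.log(np.maximum(self.entry, 1e-300)), 0.0)

        self.param_names = ParameterSet.internal_names(
            self.kind, self.covariate_names, self.n_shapes
        )
        self.n_params = len(self.param_names)
        self._z, self._lw = _gh_nodes(self.nodes)

    # ------------------------------------------------------------------
    def _row_pieces(self, beta0: float, beta: np.ndarray, rho: np.ndarray):
        """Per-stream aggregates A, S, G and score helpers R, H."""
        eta_subj = beta0 + self.X @ beta
        base = eta_subj[self.row_subject]
        rho_row = rho[self.row_type] if self.n_shapes > 1 else rho[0]
        t_r = self.t**rho_row
        e_r = np.where(self.entry > 0, self.entry**rho_row, 0.0)
        ebase = np.exp(base)
        a = self.status * (np.log(rho_row) + (rho_row - 1.0) * self.logt + base)
        E = ebase * (t_r - e_r)
        R = self.status * (1.0 + rho_row * self.logt)
        H = ebase * rho_row * (t_r * self.logt - e_r * self.logentry)
        n = self.n_streams
        A = np.bincount(self.row_stream, weights=a, minlength=n)
        S = np.bincount(self.row_stream, weights=self.status, minlength=n)
        G = np.bincount(self.row_stream, weights=E, minlength=n)
        Rs = np.bincount(self.row_stream, weights=R, minlength=n)
        Hs = np.bincount(self.row_stream, weights=H, minlength=n)
        return A, S, G, Rs, Hs

    def _unpack(self, theta: np.ndarray):
        p = len(self.covariate_names)
        beta0 = float(theta[0])
        beta = np.asarray(theta[1 : 1 + p], dtype=float)
        rho = np.exp(theta[1 + p : 1 + p + self.n_shapes])
        rest = np.exp(theta[1 + p + self.n_shapes :])
        sd1 = float(rest[0]) if len(rest) >= 1 else 0.0
        sd2 = float(rest[1]) if len(rest) >= 2 else 0.0
        return beta0, beta, rho, sd1, sd2

    # ------------------------------------------------------------------
    def value(self, theta: np.ndarray) -> float:
        return self._compute(*self._unpack(theta), want_grad=False)[0]

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        return self._compute(*self._unpack(theta), want_grad=True)

    def neg_value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, g = self.value_and_grad(theta)
        if not np.isfinite(ll) or not np.all(np.isfinite(g)):
            return _BIG, np.zeros_like(np.asarray(theta, dtype=float))
        return -ll, -g

    def from_params(self, params: ParameterSet) -> float:
        """Marginal log-likelihood at natural-scale parameters (sd = 0 handled
        exactly: the quadrature degenerates to a point mass at zero)."""
        beta0, beta, rho, sd1, sd2 = self._natural(params)
        return self._compute(beta0, beta, rho, sd1, sd2, want_grad=False)[0]

    def _natural(self, params: ParameterSet):
        beta = params.beta.reindex(self.covariate_names)
        if beta.isna().any():
            raise KeyError(
                f"params.beta missing coefficients for {list(beta.index[beta.isna()])}"
            )
        rho = params.shapes
        if len(rho) != self.n_shapes:
            if len(rho) == 1:
                rho = np.repeat(rho, self.n_shapes)
            else:
                raise ValueError(
                    f"expected {self.n_shapes} shape(s), got {len(rho)}"
                )
        if self.kind == "m2":
            sd1, sd2 = params.sd_recurrent, 0.0
        elif self.kind == "m3":
            sd1, sd2 = params.sd_type, 0.0
        elif self.kind == "m4":
            sd1, sd2 = params.sd_subject_type, params.sd_subject
        else:
            sd1 = sd2 = 0.0
        return params.beta0, beta.to_numpy(dtype=float), rho, sd1, sd2

    # ------------------------------------------------------------------
    def _compute(self, beta0, beta, rho, sd1, sd2, want_grad: bool):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            out = self._compute_inner(beta0, beta, rho, sd1, sd2, want_grad)
        return out

    def _compute_inner(self, beta0, beta, rho, sd1, sd2, want_grad: bool):
        A, S, G, R, H = self._row_pieces(beta0, beta, rho)
        zeros = np.zeros(self.n_params)
        if self.kind == "m1":
            ll = float(np.sum(A) - np.sum(G))
            if not want_grad:
                return ll, None
            D = S - G
            grad = self._assemble_grad(D, R - H, None, None)
            return ll, grad
        if self.kind in ("m2", "m3"):
            return self._compute_single(A, S, G, R, H, sd1, want_grad)
        return self._compute_joint(A, S, G, R, H, sd1, sd2, want_grad)

    def _assemble_grad(self, D_stream, T_stream, g_sd1, g_sd2):
        """Stitch the internal-scale gradient from stream-level pieces.

        ``D_stream`` is d LL / d eta summed within stream (drives beta0/beta);
        ``T_stream`` the per-stream d LL / d log rho_k contribution.
        """
        D_subj = np.bincount(self.stream_subject, weights=D_stream, minlength=self.n_subjects)
        g = [np.array([D_subj.sum()]), self.X.T @ D_subj]
        if self.n_shapes == 1:
            g.append(np.array([T_stream.sum()]))
        else:
            g.append(np.bincount(self.stream_type, weights=T_stream, minlength=self.n_shapes))
        if g_sd1 is not None:
            g.append(np.array([g_sd1]))
        if g_sd2 is not None:
            g.append(np.array([g_sd2]))
        return np.concatenate(g)

    def _compute_single(self, A, S, G, R, H, sd, want_grad):
        """m2/m3: one shared normal offset per subject."""
        u = sd * _SQRT2 * self._z                       # (Q,)
        eu = np.exp(u)
        # subject-level aggregates (streams share the subject's offset)
        ns = self.n_subjects
        A_i = np.bincount(self.stream_subject, weights=A, minlength=ns)
        S_i = np.bincount(self.stream_subject, weights=S, minlength=ns)
        G_i = np.bincount(self.stream_subject, weights=G, minlength=ns)
        LL = A_i[:, None] + S_i[:, None] * u[None, :] - G_i[:, None] * eu[None, :]
        M = LL + self._lw[None, :]
        ll_i = logsumexp(M, axis=1)
        ll = float(ll_i.sum())
        if not want_grad:
            return ll, None
        P = np.exp(M - ll_i[:, None])                   # (n_sub, Q) posterior weights
        PE = P @ eu
        PU = P @ u
        PUE = P @ (u * eu)
        # stream-level score pieces (streams may be finer than subjects: m3)
        PE_st = PE[self.stream_subject]
        D_stream = S - PE_st * G
        T_stream = R - PE_st * H
        g_sd = float(np.sum(S_i * PU - G_i * PUE))
        grad = self._assemble_grad(D_stream, T_stream, g_sd, None)
        return ll, grad

    def _compute_joint(self, A, S, G, R, H, chi, delta, want_grad):
        """m4: outer quadrature over the subject effect d, inner over each
        independent subject-by-type effect c (independence across types lets
        the (K+1)-dim integral factor into nested one-dimensional rules)."""
        Q = self.nodes
        c = chi * _SQRT2 * self._z
        d = delta * _SQRT2 * self._z
        lw = self._lw
        ns, nst = self.n_subjects, self.n_streams

        B = np.zeros((ns, Q))            # per-subject inner-integrated loglik at d_q
        Ain = np.empty((nst, Q))
        if want_grad:
            I1 = np.empty((nst, Q))      # E[e^{c+d} | data-ish weights]
            Ic = np.empty((nst, Q))      # E[c]
            Ice = np.empty((nst, Q))     # E[c e^{c+d}]
        for q in range(Q):
            off = c + d[q]               # (Q,)
            eoff = np.exp(off)
            LL = A[:, None] + S[:, None] * off[None, :] - G[:, None] * eoff[None, :]
            M = LL + lw[None, :]
            aq = logsumexp(M, axis=1)
            Ain[:, q] = aq
            if want_grad:
                w = np.exp(M - aq[:, None])
                I1[:, q] = w @ eoff
                Ic[:, q] = w @ c
                Ice[:, q] = w @ (c * eoff)
        np.add.at(B, self.stream_subject, Ain)
        MB = B + lw[None, :]
        ll_i = logsumexp(MB, axis=1)
        ll = float(ll_i.sum())
        if not want_grad:
            return ll, None
        P = np.exp(MB - ll_i[:, None])   # (n_sub, Q) outer weights
        Pst = P[self.stream_subject]     # (n_st, Q)
        Dmat = S[:, None] - G[:, None] * I1
        D_stream = np.sum(Pst * Dmat, axis=1)
        T_stream = np.sum(Pst * (R[:, None] - H[:, None] * I1), axis=1)
        g_chi = float(np.sum(Pst * (S[:, None] * Ic - G[:, None] * Ice)))
        g_delta = float(np.sum(Pst * Dmat * d[None, :]))
        grad = self._assemble_grad(D_stream, T_stream, g_chi, g_delta)
        return ll, grad

    # ------------------------------------------------------------------
    def conditional(self, params: ParameterSet, draws=None) -> float:
        """Conditional log-likelihood with the random effects held fixed.

        ``draws`` maps ``subject_id`` to a :class:`RandomEffectDraw`; omitted
        subjects (or ``draws=None``) get zero offsets, in which case the
        mixed models collapse to their pooled fixed-effect counterparts.
        """
        beta0, beta, rho, _, _ = self._natural(params)
        offsets = np.zeros(len(self.t))
        if draws:
            subj_index = self.frame.covariates.index
            per_subj = np.zeros(self.n_subjects)
            per_type = np.zeros((self.n_subjects, self.K))
            for sid, draw in draws.items():
                if sid not in subj_index:
                    raise KeyError(f"unknown subject {sid!r} in draws")
                i = subj_index.get_loc(sid)
                per_subj[i] = draw.subject_effect
                if self.kind == "m4" and len(draw.type_effects):
                    if len(draw.type_effects) != self.K:
                        raise ValueError("type_effects length must equal K")
                    per_type[i] = draw.type_effects
            offsets = per_subj[self.row_subject]
            if self.kind == "m4":
                offsets = offsets + per_type[self.row_subject, self.row_type]
            if self.kind == "m1":
                offsets = np.zeros(len(self.t))
        eta = beta0 + (self.X @ beta)[self.row_subject] + offsets
        rho_row = rho[self.row_type] if self.n_shapes > 1 else rho[0]
        t_r = self.t**rho_row
        e_r = np.where(self.entry > 0, self.entry**rho_row, 0.0)
        contrib = self.status * (
            np.log(rho_row) + (rho_row - 1.0) * self.logt + eta
        ) - np.exp(eta) * (t_r - e_r)
        return float(np.sum(contrib))


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def conditional_loglik(frame: ModelFrame, params: ParameterSet, draws=None) -> float:
    """Sum of per-row contributions with random effects fixed at ``draws``."""
    return WeibullLikelihood(frame, nodes=1).conditional(params, draws)


def marginal_loglik(frame: ModelFrame, params: ParameterSet, nodes: int = 15) -> float:
    """Random-effects-integrated log-likelihood by Gauss-Hermite quadrature.

    For m1 this equals the conditional log-likelihood; for the mixed models a
    zero variance component degenerates exactly to the pooled likelihood.
    """
    return WeibullLikelihood(frame, nodes=nodes).from_params(params)
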