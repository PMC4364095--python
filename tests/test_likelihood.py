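"""Likelihood correctness: row-sum oracles, quadrature vs brute-force
integration, degenerate collapses, and quadrature-node convergence."""

import numpy as np
import pandas as pd
import pytest
from _oracles import dense_marginal_oracle
from weibmix import (
    ParameterSet,
    RandomEffectDraw,
    WeibullLikelihood,
    conditional_loglik,
    marginal_loglik,
    weibull_loghazard,
    weibull_logsurv,
)


def row_sum_oracle(frame, params, offset_fn):
    """Independent per-row evaluation via the public Weibull primitives:
    status * log h(t) + [log S(t) - log S(entry)], scale from the row's
    covariates and random-effect offset."""
    shapes = params.shapes
    tmap = {t: i for i, t in enumerate(frame.event_types)}
    total = 0.0
    for _, row in frame.data.iterrows():
        x = frame.covariates.loc[row["subject_id"]]
        k = tmap.get(row["event_type"], 0)
        rho = shapes[k] if len(shapes) > 1 else shapes[0]
        eta = params.beta0 + float((params.beta * x[params.beta.index]).sum())
        lam = np.exp(eta + offset_fn(row["subject_id"], k))
        term = weibull_logsurv(row["time"], lam, rho)
        if row["entry"] > 0:
            term -= weibull_logsurv(row["entry"], lam, rho)
        if row["status"] == 1:
            term += weibull_loghazard(row["time"], lam, rho)
        total += float(term)
    return total


class TestConditional:
    def test_m1_single_unit_subject_reduces_to_logpdf(self):
        """y=1, status=1, beta0=0, beta=0, rho=1 -> log f = -1."""
        from weibmix import EventTable, build_model_frame

        rec = pd.DataFrame(
            [("a", "mi", 1, 1.0, 1)],
            columns=["subject_id", "event_type", "occurrence_index", "time", "status"],
        )
        cov = pd.DataFrame({"x": [0.0]}, index=pd.Index(["a"], name="subject_id"))
        table = EventTable(records=rec, covariates=cov,
                           followup_end=pd.Series(1.0, index=cov.index))
        fr = build_model_frame(table, "m1")
        params = ParameterSet(beta0=0.0, beta=pd.Series({"x": 0.0}), shape=1.0)
        assert conditional_loglik(fr, params) == pytest.approx(-1.0)

    def test_matches_row_by_row_oracle(self, three_subject_frames, fixture_params):
        rng = np.random.default_rng(42)
        for kind in ("m1", "m2", "m3", "m4"):
            fr = three_subject_frames[kind]
            draws = {
                sid: RandomEffectDraw(
                    subject_effect=rng.normal(0, 0.5),
                    type_effects=rng.normal(0, 0.5, size=len(fr.event_types)),
                )
                for sid in fr.covariates.index
            }

            def offset(sid, k, kind=kind, draws=draws):
                if kind == "m1":
                    return 0.0
                base = draws[sid].subject_effect
                if kind == "m4":
                    base += draws[sid].type_effects[k]
                return base

            got = conditional_loglik(fr, fixture_params[kind], draws)
            want = row_sum_oracle(fr, fixture_params[kind], offset)
            assert got == pytest.approx(want, rel=1e-10)

    def test_zero_offsets_collapse_m2_to_pooled(self, three_subject_frames, fixture_params):
        fr = three_subject_frames["m2"]
        p = fixture_params["m2"]
        with_zero = conditional_loglik(
            fr, p, {sid: RandomEffectDraw() for sid in fr.covariates.index}
        )
        assert with_zero == pytest.approx(conditional_loglik(fr, p))

    def test_invariant_to_row_order(self, three_subject_frames, fixture_params):
        fr = three_subject_frames["m4"]
        base = conditional_loglik(fr, fixture_params["m4"])
        shuffled = fr.__class__(
            kind=fr.kind,
            data=fr.data.sample(frac=1.0, random_state=1).reset_index(drop=True),
            covariates=fr.covariates,
            event_types=fr.event_types,
            followup=fr.followup,
        )
        assert conditional_loglik(shuffled, fixture_params["m4"]) == pytest.approx(base)

    def test_zero_time_event_is_domain_error(self, three_subject_frames):
        fr = three_subject_frames["m1"]
        bad = fr.data.copy()
        bad.loc[bad.index[0], "time"] = 0.0
        bad.loc[bad.index[0], "status"] = 1
        bad.loc[bad.index[0], "entry"] = 0.0
        broken = fr.__class__(kind="m1", data=bad, covariates=fr.covariates,
                              event_types=fr.event_types, followup=fr.followup)
        with pytest.raises(ValueError, match="positive"):
            WeibullLikelihood(broken)


class TestMarginal:
    def test_sigma_zero_equals_pooled_exactly(self, three_subject_frames, fixture_params):
        fr = three_subject_frames["m2"]
        p0 = ParameterSet(beta0=-1.0, beta=fixture_params["m2"].beta,
                          shape=1.1, sd_recurrent=0.0)
        assert marginal_loglik(fr, p0) == pytest.approx(conditional_loglik(fr, p0), abs=1e-12)

    def test_m4_zero_variances_equal_pooled(self, three_subject_frames, fixture_params):
        fr = three_subject_frames["m4"]
        p0 = ParameterSet(beta0=-1.0, beta=fixture_params["m4"].beta,
                          shape=np.array([1.1, 1.1]),
                          sd_subject_type=0.0, sd_subject=0.0)
        assert marginal_loglik(fr, p0) == pytest.approx(conditional_loglik(fr, p0), abs=1e-12)

    @pytest.mark.parametrize("kind", ["m2", "m3", "m4"])
    def test_quadrature_matches_dense_integration(self, kind, three_subject_frames,
                                                  fixture_params):
        fr = three_subject_frames[kind]
        got = marginal_loglik(fr, fixture_params[kind], nodes=31)
        want = dense_marginal_oracle(fr, fixture_params[kind], kind)
        assert got == pytest.approx(want, abs=1e-6)

    def test_continuity_in_sigma_at_zero(self, three_subject_frames, fixture_params):
        fr = three_subject_frames["m2"]
        beta = fixture_params["m2"].beta
        base = conditional_loglik(fr, ParameterSet(beta0=-1.0, beta=beta, shape=1.1))
        gaps = []
        for sd in (1e-3, 1e-5):
            p = ParameterSet(beta0=-1.0, beta=beta, shape=1.1, sd_recurrent=sd)
            gaps.append(abs(marginal_loglik(fr, p) - base))
        assert gaps[1] < gaps[0] < 1e-3

    def test_node_convergence(self, three_subject_frames, fixture_params):
        fr = three_subject_frames["m4"]
        p = fixture_params["m4"]
        l7 = marginal_loglik(fr, p, nodes=7)
        l15 = marginal_loglik(fr, p, nodes=15)
        l31 = marginal_loglik(fr, p, nodes=31)
        assert abs(l31 - l15) < abs(l15 - l7)
        assert abs(l31 - l15) < 1e-5

    def test_negative_sd_is_domain_error(self):
        with pytest.raises(ValueError):
            ParameterSet(beta0=0.0, beta=pd.Series(dtype=float), shape=1.0,
                         sd_recurrent=-0.1)

    def test_analytic_score_matches_finite_differences(self, three_subject_frames):
        for kind in ("m1", "m2", "m3", "m4"):
            eng = WeibullLikelihood(three_subject_frames[kind], nodes=9)
            rng = np.random.default_rng(kind.encode()[1])
            th = rng.normal(0, 0.4, eng.n_params)
            _, g = eng.value_and_grad(th)
            for j in range(eng.n_params):
                h = 1e-6
                tp, tm = th.copy(), th.copy()
                tp[j] += h
                tm[j] -= h
                num = (eng.value(tp) - eng.value(tm)) / (2 * h)
                assert g[j] == pytest.approx(num, rel=1e-4, abs=1e-6)
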