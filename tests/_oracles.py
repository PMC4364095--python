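"""Independent brute-force oracles shared by likelihood and acceptance tests."""

import numpy as np
from scipy.stats import norm

def _rows_ll_on_grid(rows, eta, rho_of, offsets):
    """Sum of truncated Weibull row contributions at each offset in ``offsets``
    (any-dimensional array), written out directly from the closed forms."""
    total = np.zeros_like(offsets, dtype=float)
    lam = np.exp(eta + offsets)
    for _, row in rows.iterrows():
        rho = rho_of(row["event_type"])
        t, entry, s = row["time"], row["entry"], row["status"]
        total += -lam * (t**rho - (entry**rho if entry > 0 else 0.0))
        if s == 1:
            total += np.log(lam) + np.log(rho) + (rho - 1.0) * np.log(t)
    return total


def dense_marginal_oracle(frame, params, kind):
    """Brute-force random-effects integral: trapezoid over +/- 8 sd grids."""
    shapes = params.shapes
    tmap = {t: i for i, t in enumerate(frame.event_types)}

    def rho_of(etype):
        return shapes[tmap.get(etype, 0)] if len(shapes) > 1 else shapes[0]

    def eta_of(sid):
        x = frame.covariates.loc[sid]
        return params.beta0 + float((params.beta * x[params.beta.index]).sum())

    if kind in ("m2", "m3"):
        sd = params.sd_recurrent if kind == "m2" else params.sd_type
        grid = np.linspace(-8 * sd, 8 * sd, 4001)
        total = 0.0
        for sid in frame.covariates.index:
            rows = frame.data[frame.data["subject_id"] == sid]
            vals = _rows_ll_on_grid(rows, eta_of(sid), rho_of, grid)
            total += np.log(np.trapezoid(np.exp(vals) * norm.pdf(grid, 0, sd), grid))
        return total
    # m4: outer d-grid, inner independent c-grid per event type
    chi, delta = params.sd_subject_type, params.sd_subject
    dgrid = np.linspace(-8 * delta, 8 * delta, 1201)
    cgrid = np.linspace(-8 * chi, 8 * chi, 1201)
    offsets = dgrid[:, None] + cgrid[None, :]
    total = 0.0
    for sid in frame.covariates.index:
        outer = np.zeros(len(dgrid))
        for etype in frame.event_types:
            rows = frame.data[
                (frame.data["subject_id"] == sid) & (frame.data["event_type"] == etype)
            ]
            inner_vals = _rows_ll_on_grid(rows, eta_of(sid), rho_of, offsets)
            inner = np.trapezoid(
                np.exp(inner_vals) * norm.pdf(cgrid, 0, chi)[None, :], cgrid, axis=1
            )
            outer += np.log(inner)
        total += np.log(np.trapezoid(np.exp(outer) * norm.pdf(dgrid, 0, delta), dgrid))
    return total
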