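"""Four-model comparison: fit m1-m4 on one cohort and tabulate hazard ratios.

The output table mirrors the forest-plot summary a comparison study reports:
one row per (covariate, model), with the conditional HR for the plain
time-to-first-event model and the marginalized (population-averaged) HR for
the three mixed models, so the columns are directly comparable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import EventTable, build_model_frame
from .marginal import marginalized_hr
from .model import WeibullEventModel

__all__ = ["run_comparison", "percent_excess", "forest_plot"]

logger = logging.getLogger(__name__)

ALL_KINDS = ("m1", "m2", "m3", "m4")


def percent_excess(hr_numerator: float, hr_denominator: float) -> float:
    """How much higher (in %) one hazard ratio is than another.

    E.g. ``percent_excess(1.93, 1.44) -> 34.0``: the first HR is 34% higher.
    """
    if hr_numerator <= 0 or hr_denominator <= 0:
        raise ValueError("hazard ratios must be positive")
    return round(100.0 * (hr_numerator / hr_denominator - 1.0), 1)


def run_comparison(
    table: EventTable,
    covariates: list[str] | None = None,
    kinds=ALL_KINDS,
    level: float = 0.95,
    quadrature_nodes: int = 15,
    timescale: str = "total",
    output_dir=None,
) -> pd.DataFrame:
    """Fit the requested models and assemble the comparison table.

    A failure of any single model is logged and reported as NaN rows without
    aborting the others; if every fit fails, raises with per-model
    diagnostics.  Columns: covariate, model, hr, lower, upper, estimate_kind
    (``conditional`` for m1, ``marginalized`` for m2-m4), loglik, converged.
    """
    rows = []
    results = {}
    failures = {}
    for kind in kinds:
        try:
            model = WeibullEventModel.from_event_table(
                table, kind, covariates=covariates, timescale=timescale,
                quadrature_nodes=quadrature_nodes,
            )
            res = model.fit()
            results[kind] = res
            logger.info("%s: loglik=%.2f converged=%s", kind, res.llf, res.converged)
        except Exception as exc:  # noqa: BLE001 - per-model isolation is the contract
            failures[kind] = str(exc)
            logger.error("model %s failed: %s", kind, exc)
            continue
        names = model.exog_names
        if kind == "m1":
            hr = res.hazard_ratios(level)
            for _, r in hr.iterrows():
                rows.append(
                    {"covariate": r["covariate"], "model": kind, "hr": r["hr"],
                     "lower": r["lower"], "upper": r["upper"],
                     "estimate_kind": "conditional",
                     "loglik": res.llf, "converged": res.converged}
                )
        else:
            for name in names:
                try:
                    eff = marginalized_hr(res, name, level=level, nodes=quadrature_nodes)
                    lo, hi = eff.marginal_hr_ci
                    rows.append(
                        {"covariate": name, "model": kind, "hr": eff.marginal_hr,
                         "lower": lo, "upper": hi, "estimate_kind": "marginalized",
                         "loglik": res.llf, "converged": res.converged}
                    )
                except Exception as exc:  # noqa: BLE001
                    logger.error("marginalization of %s under %s failed: %s", name, kind, exc)
                    rows.append(
                        {"covariate": name, "model": kind, "hr": np.nan,
                         "lower": np.nan, "upper": np.nan,
                         "estimate_kind": "marginalized",
                         "loglik": res.llf, "converged": res.converged}
                    )
    if not results:
        raise RuntimeError(f"all model fits failed: {failures}")

    out = pd.DataFrame(rows)
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "comparison.csv", index=False)
        for kind, res in results.items():
            res.save(outdir / f"fit_{kind}.json")
        logger.info("wrote comparison outputs to %s", outdir)
    out.attrs["results"] = results
    out.attrs["failures"] = failures
    return out


def forest_plot(comparison: pd.DataFrame, path=None):
    """Optional forest-style rendering of a comparison table (cosmetic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    covs = list(dict.fromkeys(comparison["covariate"]))
    kinds = list(dict.fromkeys(comparison["model"]))
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(covs) * len(kinds) + 1.5))
    offsets = np.linspace(-0.3, 0.3, len(kinds))
    colors = plt.get_cmap("tab10")
    for j, kind in enumerate(kinds):
        sub = comparison[comparison["model"] == kind].set_index("covariate")
        y = np.array([covs.index(c) for c in sub.index]) + offsets[j]
        ax.errorbar(
            sub["hr"], y,
            xerr=[sub["hr"] - sub["lower"], sub["upper"] - sub["hr"]],
            fmt="o", ms=4, lw=1.2, color=colors(j), label=kind,
        )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(range(len(covs)))
    ax.set_yticklabels(covs)
    ax.set_xlabel("hazard ratio")
    ax.legend(title="model", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
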