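"""Long-format event-history containers and per-model analysis frames.

The central container is :class:`EventTable`: one row per observed event
occurrence (subject, event type, occurrence index, time from baseline in
years, status), a subject-level table of baseline covariates, and a
per-subject administrative censoring time (``followup_end``).  Subjects with
no events are represented either by a sentinel ``"none"`` record with
``status = 0`` or simply by their presence in the covariate/follow-up tables.

Four analysis layouts ("model frames") are derived from it:

* ``m1`` — time to first event of any type: exactly one row per subject.
* ``m2`` — recurrent events pooled over types: every occurrence plus one
  terminal censoring row per subject.
* ``m3`` — first occurrence of each event type: one row per (subject, type),
  censoring at ``followup_end`` for types never observed.
* ``m4`` — every (type, occurrence) plus one terminal censoring row per
  (subject, type) stream.

Rows carry an ``entry`` column (time at which the subject became at risk for
that row on the total-time clock: 0 for first rows, the previous same-stream
event time for later ones) so likelihood code can form the correct
left-truncated contribution for recurrent rows.  Under the ``gap`` timescale
the clock restarts after each event and ``entry`` is identically 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NO_EVENT = "none"

MODEL_KINDS = ("m1", "m2", "m3", "m4")

#: canonical record columns, in storage order
RECORD_COLUMNS = ["subject_id", "event_type", "occurrence_index", "time", "status"]


class ValidationError(ValueError):
    """An event table violates a structural invariant."""


@dataclass
class EventTable:
    """Validated long-format event history.

    Attributes
    ----------
    records : pandas.DataFrame
        Columns ``subject_id, event_type, occurrence_index, time, status``.
        ``status = 1`` marks an observed event; ``status = 0`` rows are
        explicit censoring markers (optional — administrative censoring is
        always derivable from ``followup_end``).
    covariates : pandas.DataFrame
        One row per subject, indexed by ``subject_id``; baseline values only.
    followup_end : pandas.Series
        Administrative censoring time (years) per subject, same index.
    """

    records: pd.DataFrame
    covariates: pd.DataFrame
    followup_end: pd.Series

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        self.covariates = self.covariates.sort_index()
        self.followup_end = self.followup_end.sort_index().astype(float)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        rec = self.records
        missing = [c for c in RECORD_COLUMNS if c not in rec.columns]
        if missing:
            raise ValidationError(f"records missing columns {missing}")
        if len(self.covariates) == 0:
            raise ValidationError("no subjects present")
        if not self.covariates.index.equals(self.followup_end.index):
            raise ValidationError("covariates and followup_end must index the same subjects")
        if self.covariates.index.has_duplicates:
            raise ValidationError("duplicate subject in covariate table")
        bad_time = rec.index[rec["time"].astype(float) < 0]
        if len(bad_time):
            raise ValidationError(f"negative time in records at rows {list(bad_time[:5])}")
        if not rec["status"].isin([0, 1]).all():
            raise ValidationError("status must be 0 or 1")
        if (rec["occurrence_index"] < 1).any():
            raise ValidationError("occurrence_index must be >= 1")
        unknown = set(rec["subject_id"]) - set(self.covariates.index)
        if unknown:
            raise ValidationError(f"records reference subjects without covariates: {sorted(unknown)[:5]}")
        dup = rec.duplicated(subset=["subject_id", "event_type", "occurrence_index"])
        if dup.any():
            raise ValidationError(f"duplicate (subject, type, occurrence) at rows {list(rec.index[dup][:5])}")
        fu = self.followup_end.reindex(rec["subject_id"]).to_numpy()
        over = rec["time"].to_numpy(dtype=float) > fu + 1e-12
        if over.any():
            raise ValidationError(
                f"event time exceeds followup_end for rows {list(rec.index[over][:5])}"
            )
        # per-stream ordering: times strictly increase with occurrence_index,
        # and a censoring marker can only terminate its stream
        ev = rec[rec["event_type"] != NO_EVENT]
        if len(ev):
            srt = ev.sort_values(["subject_id", "event_type", "occurrence_index"], kind="stable")
            grp = srt.groupby(["subject_id", "event_type"], sort=False)
            dt = grp["time"].diff()
            bad = dt.notna() & (dt <= 0)
            if bad.any():
                sid, etype = srt.loc[bad.idxmax(), ["subject_id", "event_type"]]
                raise ValidationError(
                    f"times not strictly increasing within stream ({sid!r}, {etype!r})"
                )
            not_last = grp.cumcount(ascending=False) > 0
            bad = (srt["status"] == 0) & not_last
            if bad.any():
                sid, etype = srt.loc[bad.idxmax(), ["subject_id", "event_type"]]
                raise ValidationError(
                    f"censoring record not last in stream ({sid!r}, {etype!r})"
                )

    # -- convenience -------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def event_types(self) -> list[str]:
        ev = self.records.loc[self.records["status"] == 1, "event_type"]
        return sorted(set(ev) - {NO_EVENT})

    def events(self) -> pd.DataFrame:
        """Observed events only (``status == 1``), sorted by subject and time."""
        ev = self.records[self.records["status"] == 1]
        return ev.sort_values(["subject_id", "time"]).reset_index(drop=True)

    def subjects_with_no_events(self) -> pd.Index:
        ev = set(self.records.loc[self.records["status"] == 1, "subject_id"])
        return self.covariates.index[~self.covariates.index.isin(ev)]


@dataclass
class ModelFrame:
    """Analysis-ready layout for one of the four model kinds."""

    kind: str
    data: pd.DataFrame        # subject_id, event_type, entry, time, status
    covariates: pd.DataFrame  # subject-indexed design columns
    event_types: list[str]
    followup: pd.Series       # per-subject administrative censor time

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def to_dataframe(self) -> pd.DataFrame:
        """Rows merged with their subject's covariates (for display/export)."""
        return self.data.join(self.covariates, on="subject_id")


# ---------------------------------------------------------------------------
# reading / writing the delimited long format
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {
    "subject_id": "subject_id",
    "event_type": "event_type",
    "occurrence_index": "occurrence_index",
    "time": "time",
    "status": "status",
    "followup_end": "followup_end",
}


def read_event_table(
    path,
    schema: dict | None = None,
    covariate_path=None,
    sep: str = ",",
    time_divisor: float = 1.0,
) -> EventTable:
    """Read a delimited long-format event file into a validated EventTable.

    Parameters
    ----------
    path : path-like
        Event-level file.  Required columns (after applying ``schema``):
        ``subject_id, event_type, time, status``.  ``occurrence_index`` is
        derived from within-stream time order when absent.  Covariates may be
        repeated per row here, or supplied separately.
    schema : dict, optional
        Mapping from canonical field name to the column name in the file.
    covariate_path : path-like, optional
        Separate subject-level covariate file (one row per ``subject_id``).
    time_divisor : float
        Divide times by this on input (e.g. 365.25 to convert days to years).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path, sep=sep)
    for canon in ("subject_id", "event_type", "time", "status"):
        if schema[canon] not in raw.columns:
            raise ValidationError(f"missing mapped column {schema[canon]!r} for field {canon!r}")
    rename = {v: k for k, v in schema.items() if v in raw.columns}
    raw = raw.rename(columns=rename)

    raw["time"] = pd.to_numeric(raw["time"], errors="raise") / time_divisor
    raw["status"] = pd.to_numeric(raw["status"], errors="raise").astype(int)
    raw["event_type"] = raw["event_type"].astype(str)
    neg = raw.index[raw["time"] < 0]
    if len(neg):
        raise ValidationError(f"negative time at row(s) {list(neg + 2)[:5]} of {path}")

    if "occurrence_index" not in raw.columns:
        raw = raw.sort_values(["subject_id", "event_type", "time"], kind="stable")
        raw["occurrence_index"] = raw.groupby(["subject_id", "event_type"]).cumcount() + 1
    raw["occurrence_index"] = raw["occurrence_index"].astype(int)

    if "followup_end" in raw.columns:
        followup = raw.groupby("subject_id")["followup_end"].first().astype(float) / time_divisor
    else:
        followup = raw.groupby("subject_id")["time"].max().astype(float)

    if covariate_path is not None:
        cov = pd.read_csv(covariate_path, sep=sep).set_index(schema["subject_id"])
        cov.index.name = "subject_id"
    else:
        aux = {"followup_end"}
        cov_cols = [c for c in raw.columns if c not in set(RECORD_COLUMNS) | aux]
        cov = raw.groupby("subject_id")[cov_cols].first() if cov_cols else pd.DataFrame(
            index=pd.Index(sorted(raw["subject_id"].unique()), name="subject_id")
        )

    followup = followup.reindex(cov.index)
    if followup.isna().any():
        followup = followup.fillna(raw.groupby("subject_id")["time"].max().reindex(cov.index))

    records = raw[RECORD_COLUMNS].reset_index(drop=True)
    return EventTable(records=records, covariates=cov, followup_end=followup)


def write_event_table(table: EventTable, path, sep: str = ",") -> None:
    """Write the long format back out (covariates repeated per row).

    A subject with no records still gets one sentinel ``"none"`` row so that
    the file round-trips without losing subjects.
    """
    rec = table.records.copy()
    silent = table.covariates.index.difference(rec["subject_id"].unique())
    if len(silent):
        pad = pd.DataFrame(
            {
                "subject_id": silent,
                "event_type": NO_EVENT,
                "occurrence_index": 1,
                "time": table.followup_end.reindex(silent).to_numpy(),
                "status": 0,
            }
        )
        rec = pd.concat([rec, pad], ignore_index=True)
    rec["followup_end"] = table.followup_end.reindex(rec["subject_id"]).to_numpy()
    out = rec.join(table.covariates, on="subject_id")
    out.sort_values(["subject_id", "event_type", "occurrence_index"]).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# model frames
# ---------------------------------------------------------------------------

def build_model_frame(
    table: EventTable,
    kind: str,
    covariates: list[str] | None = None,
    event_types: list[str] | None = None,
    timescale: str = "total",
) -> ModelFrame:
    """Reshape an EventTable into the analysis frame for one model kind.

    Subjects with a missing value in any modelled covariate are dropped
    (complete-case) with a logged count.  ``event_types`` fixes the type
    universe for m3/m4 (defaults to the types observed in the table).
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    if timescale not in ("total", "gap"):
        raise ValueError("timescale must be 'total' or 'gap'")
    if table.n_subjects == 0:
        raise ValidationError("empty table")

    cov = table.covariates
    if covariates is not None:
        missing_cols = set(covariates) - set(cov.columns)
        if missing_cols:
            raise KeyError(f"unknown covariates {sorted(missing_cols)}")
        cov = cov[list(covariates)]
    keep = cov.dropna().index
    dropped = len(cov) - len(keep)
    if dropped:
        logger.info("build_model_frame: dropped %d subject(s) with missing covariates", dropped)
    if len(keep) == 0:
        raise ValidationError("no subjects remain after complete-case filtering")
    cov = cov.loc[keep]
    followup = table.followup_end.loc[keep]

    ev = table.events()
    ev = ev[ev["subject_id"].isin(keep)]
    types = list(event_types) if event_types is not None else sorted(set(ev["event_type"]))
    ev = ev[ev["event_type"].isin(types)] if types else ev.iloc[0:0]

    rows: list[pd.DataFrame] = []
    if kind == "m1":
        first = ev.sort_values("time", kind="stable").groupby("subject_id").first()
        out = pd.DataFrame(index=keep)
        out["subject_id"] = keep
        out["event_type"] = first["event_type"].reindex(keep).fillna(NO_EVENT)
        out["time"] = first["time"].reindex(keep).fillna(followup)
        out["status"] = first["time"].reindex(keep).notna().astype(int)
        out["entry"] = 0.0
        rows.append(out.reset_index(drop=True))
    elif kind == "m2":
        e = ev.sort_values(["subject_id", "time"], kind="stable").copy()
        e["entry"] = e.groupby("subject_id")["time"].shift(1).fillna(0.0)
        rows.append(e[["subject_id", "event_type", "entry", "time", "status"]])
        last = e.groupby("subject_id")["time"].max()
        cens = pd.DataFrame(
            {
                "subject_id": keep,
                "event_type": NO_EVENT,
                "entry": last.reindex(keep).fillna(0.0).to_numpy(),
                "time": followup.to_numpy(),
                "status": 0,
            }
        )
        rows.append(cens)
    elif kind == "m3":
        first = (
            ev.sort_values("time", kind="stable")
            .groupby(["subject_id", "event_type"])
            .first()
            .reset_index()
        )
        grid = pd.MultiIndex.from_product([keep, types], names=["subject_id", "event_type"])
        out = first.set_index(["subject_id", "event_type"]).reindex(grid).reset_index()
        out["status"] = out["time"].notna().astype(int)
        fu_rows = followup.reindex(out["subject_id"]).to_numpy()
        out["time"] = np.where(out["time"].notna(), out["time"], fu_rows)
        out["entry"] = 0.0
        rows.append(out[["subject_id", "event_type", "entry", "time", "status"]])
    else:  # m4
        e = ev.sort_values(["subject_id", "event_type", "time"], kind="stable").copy()
        e["entry"] = e.groupby(["subject_id", "event_type"])["time"].shift(1).fillna(0.0)
        rows.append(e[["subject_id", "event_type", "entry", "time", "status"]])
        last = e.groupby(["subject_id", "event_type"])["time"].max()
        grid = pd.MultiIndex.from_product([keep, types], names=["subject_id", "event_type"])
        cens = pd.DataFrame(index=grid).reset_index()
        cens["entry"] = last.reindex(grid).fillna(0.0).to_numpy()
        cens["time"] = followup.reindex(cens["subject_id"]).to_numpy()
        cens["status"] = 0
        rows.append(cens[["subject_id", "event_type", "entry", "time", "status"]])

    data = pd.concat(rows, ignore_index=True)
    data = data.sort_values(["subject_id", "event_type", "time"], kind="stable").reset_index(drop=True)

    if timescale == "gap":
        data["time"] = data["time"] - data["entry"]
        data["entry"] = 0.0

    # events recorded at t == 0 break log t at rho != 1; shift them slightly
    zero_ev = (data["status"] == 1) & (data["time"] <= 0)
    if zero_ev.any():
        pos = data.loc[data["time"] > 0, "time"]
        eps = 0.5 * float(pos.min()) if len(pos) else 1e-6
        logger.warning("shifting %d zero event time(s) to %.3g", int(zero_ev.sum()), eps)
        data.loc[zero_ev, "time"] = eps

    frame_types = types if kind in ("m3", "m4") else types or []
    return ModelFrame(kind=kind, data=data, covariates=cov,
                      event_types=frame_types, followup=followup)


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def describe_events(table: EventTable) -> pd.DataFrame:
    """Per-event-type counts and percentages of the grand total.

    The grand total counts every observed event record plus each subject with
    no events once (the "no event" row), so the percentage column sums to
    100 up to rounding.  Percentages are rounded to one decimal.
    """
    ev = table.events()
    counts = ev["event_type"].value_counts().sort_index()
    n_no_event = len(table.subjects_with_no_events())
    rows = [("no event", n_no_event)] + list(counts.items())
    total = n_no_event + int(counts.sum())
    out = pd.DataFrame(rows, columns=["event_type", "count"])
    if total > 0:
        out["percent"] = (100.0 * out["count"] / total).round(1)
    else:
        out = out.iloc[0:0]
        out["percent"] = []
    out.attrs["grand_total"] = total
    return out


def _is_indicator(col: pd.Series) -> bool:
    vals = set(col.dropna().unique().tolist())
    return vals <= {0, 1, 0.0, 1.0, True, False}


def describe_covariates(table: EventTable) -> pd.DataFrame:
    """Baseline-covariate summary: count/percent for indicators, mean/SD otherwise.

    Denominators are the non-missing counts per covariate (complete-case per
    column), so percentages match tables built on varying denominators.
    """
    rows = []
    for name, col in table.covariates.items():
        nonmiss = col.dropna()
        n = len(nonmiss)
        if n and _is_indicator(col):
            count = int(nonmiss.astype(float).sum())
            rows.append(
                {"covariate": name, "kind": "indicator", "n": n,
                 "count": count, "percent": round(100.0 * count / n, 1),
                 "mean": np.nan, "sd": np.nan}
            )
        else:
            vals = nonmiss.astype(float)
            rows.append(
                {"covariate": name, "kind": "continuous", "n": n,
                 "count": np.nan, "percent": np.nan,
                 "mean": float(vals.mean()) if n else np.nan,
                 "sd": float(vals.std(ddof=1)) if n > 1 else 0.0}
            )
    return pd.DataFrame(rows)
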