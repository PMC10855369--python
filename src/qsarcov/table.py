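"""Data model and I/O for the per-model benchmark results table.

One row per prediction model per challenge round/phase.  A model name that
recurs in different phases or projects denotes a distinct (possibly
retrained) model and always gets its own record and ``model_uid``;
deduplication is never performed.  Reported metrics may arrive either as
fractions (0-1) or percentages (0-100); the reader detects the scale per
column and canonicalizes to percent, except MCC which is always raw in
[-1, 1].  Missing values are explicit ``None``, never 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from .confusion import ConfusionMatrix, compute_metrics, f1_from_ppv_sensitivity
from .errors import SchemaError, ValidationError

__all__ = [
    "ModelRecord",
    "ModelTable",
    "read_model_table",
    "write_model_table",
    "backfill_f1",
    "PERCENT_METRICS",
    "METRIC_FIELDS",
]

PERCENT_METRICS = ("sensitivity", "specificity", "accuracy", "ba", "ppv", "npv", "f1")
METRIC_FIELDS = PERCENT_METRICS + ("mcc",)
COUNT_FIELDS = ("tp", "fp", "fn", "tn")

#: tolerance for agreement between reported metrics and metrics recomputed
#: from counts: one-decimal rounding of a percent value.
_AGREEMENT_TOL = 0.05


@dataclass(frozen=True)
class ModelRecord:
    """One prediction model's identity, reported metrics, and coverage."""

    model_uid: int
    cov: float
    project: int | None = None
    phase: int | None = None
    team: str = ""
    tool_name: str = ""
    confusion: ConfusionMatrix | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    ba: float | None = None
    ppv: float | None = None
    npv: float | None = None
    f1: float | None = None
    mcc: float | None = None
    pc1: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.cov <= 100):
            raise ValidationError(f"model_uid={self.model_uid}: cov must lie in (0, 100], got {self.cov}")
        for name in PERCENT_METRICS:
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise ValidationError(f"model_uid={self.model_uid}: {name}={v} outside [0, 100]")
        if self.mcc is not None and not (-1 <= self.mcc <= 1):
            raise ValidationError(f"model_uid={self.model_uid}: mcc={self.mcc} outside [-1, 1]")
        if self.confusion is not None:
            derived = compute_metrics(self.confusion)
            for name in METRIC_FIELDS:
                reported, computed = getattr(self, name), getattr(derived, name)
                if reported is None or computed is None:
                    continue
                tol = _AGREEMENT_TOL if name in PERCENT_METRICS else 0.005
                if abs(reported - computed) > tol:
                    raise ValidationError(
                        f"model_uid={self.model_uid}: reported {name}={reported} disagrees with "
                        f"value {computed:.4f} derived from counts (tolerance {tol})"
                    )

    def metric(self, name: str) -> float | None:
        if name not in METRIC_FIELDS + ("pc1", "cov"):
            raise KeyError(f"unknown metric {name!r}")
        return getattr(self, name)


@dataclass
class ModelTable:
    """Ordered collection of :class:`ModelRecord` with provenance."""

    records: list[ModelRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        uids = [r.model_uid for r in self.records]
        if len(set(uids)) != len(uids):
            dupes = sorted({u for u in uids if uids.count(u) > 1})
            raise ValidationError(f"duplicate model_uid(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ModelRecord]:
        return iter(self.records)

    def get(self, model_uid: int) -> ModelRecord:
        for r in self.records:
            if r.model_uid == model_uid:
                return r
        raise KeyError(f"no record with model_uid={model_uid}")

    def log(self, message: str) -> None:
        self.provenance.setdefault("parse_log", []).append(message)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict = {
                "model_uid": r.model_uid,
                "project": r.project,
                "phase": r.phase,
                "team": r.team,
                "tool_name": r.tool_name,
                "cov": r.cov,
            }
            for name in METRIC_FIELDS + ("pc1",):
                row[name] = getattr(r, name)
            if r.confusion is not None:
                row.update({k: getattr(r.confusion, k) for k in COUNT_FIELDS})
            else:
                row.update({k: None for k in COUNT_FIELDS})
            rows.append(row)
        return pd.DataFrame(rows)

    def with_records(self, records: list[ModelRecord], note: str | None = None) -> "ModelTable":
        out = ModelTable(records=records, provenance=dict(self.provenance))
        out.provenance["parse_log"] = list(self.provenance.get("parse_log", []))
        if note:
            out.log(note)
        return out

    def to_json(self) -> str:
        df = self.to_dataframe()
        return json.dumps(
            {"records": json.loads(df.to_json(orient="records")), "provenance": self.provenance},
            indent=2,
        )


def _detect_percent_scale(values: pd.Series) -> bool:
    """True if a metric column looks like 0-1 fractions needing rescale."""
    finite = values.dropna().astype(float)
    if finite.empty:
        return False
    return bool((finite.abs() <= 1.0).all())


def read_model_table(
    path: str | Path,
    schema_config: Mapping[str, str] | str | Path | None = None,
    *,
    recompute_from_counts: bool = False,
) -> ModelTable:
    """Read a per-model results CSV into a :class:`ModelTable`.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row; must provide ``cov`` plus either the
        confusion counts (tp/fp/fn/tn) or at least one reported metric.
    schema_config : mapping or path, optional
        Column-name mapping, canonical field -> source column.  A path is
        read as a JSON object.  Unmapped canonical names are looked up
        case-insensitively in the header.
    recompute_from_counts : bool
        When counts are present, overwrite reported metrics with values
        recomputed from the counts (the path used is recorded in provenance).
    """
    path = Path(path)
    if isinstance(schema_config, (str, Path)):
        schema_config = json.loads(Path(schema_config).read_text())
    mapping = dict(schema_config or {})

    df = pd.read_csv(path)
    colmap: dict[str, str] = {}
    lowered = {c.lower(): c for c in df.columns}
    for canonical in ("model_uid", "project", "phase", "team", "tool_name", "cov") + METRIC_FIELDS + COUNT_FIELDS:
        source = mapping.get(canonical, canonical)
        if source in df.columns:
            colmap[canonical] = source
        elif source.lower() in lowered:
            colmap[canonical] = lowered[source.lower()]

    if "cov" not in colmap:
        raise SchemaError("required column 'cov' not found (map it via schema_config)")
    has_counts = all(c in colmap for c in COUNT_FIELDS)
    has_metrics = any(m in colmap for m in METRIC_FIELDS)
    if not has_counts and not has_metrics:
        raise SchemaError(
            "need either confusion-count columns (tp, fp, fn, tn) or at least one metric column"
        )

    log: list[str] = [f"read {len(df)} rows from {path.name}"]

    # per-column scale detection: fractions are rescaled to percent
    rescaled: dict[str, bool] = {}
    for name in PERCENT_METRICS + ("cov",):
        if name in colmap:
            frac = _detect_percent_scale(df[colmap[name]])
            rescaled[name] = frac
            if frac:
                log.append(f"column {colmap[name]!r} detected as 0-1 fractions; rescaled to percent")

    records: list[ModelRecord] = []
    for idx, row in df.iterrows():
        def val(name: str, scale: bool = True) -> float | None:
            if name not in colmap:
                return None
            v = row[colmap[name]]
            if pd.isna(v):
                return None
            v = float(v)
            return v * 100.0 if scale and rescaled.get(name, False) else v

        cov = val("cov")
        if cov is None or not (0 < cov <= 100):
            raise ValidationError(f"row {idx}: cov={cov} outside (0, 100]")

        confusion = None
        if has_counts and not any(pd.isna(row[colmap[c]]) for c in COUNT_FIELDS):
            confusion = ConfusionMatrix(**{c: int(row[colmap[c]]) for c in COUNT_FIELDS})

        fields: dict = {name: val(name) for name in PERCENT_METRICS}
        fields["mcc"] = val("mcc", scale=False)  # mcc is always raw
        if confusion is not None and (recompute_from_counts or not any(v is not None for v in fields.values())):
            derived = compute_metrics(confusion)
            fields = {k: getattr(derived, k) for k in METRIC_FIELDS}

        uid = row[colmap["model_uid"]] if "model_uid" in colmap else None
        records.append(
            ModelRecord(
                model_uid=int(uid) if uid is not None and not pd.isna(uid) else idx + 1,
                cov=cov,
                project=int(row[colmap["project"]]) if "project" in colmap and not pd.isna(row[colmap["project"]]) else None,
                phase=int(row[colmap["phase"]]) if "phase" in colmap and not pd.isna(row[colmap["phase"]]) else None,
                team=str(row[colmap["team"]]) if "team" in colmap and not pd.isna(row[colmap["team"]]) else "",
                tool_name=str(row[colmap["tool_name"]]) if "tool_name" in colmap and not pd.isna(row[colmap["tool_name"]]) else "",
                confusion=confusion,
                **fields,
            )
        )

    log.append(
        "metrics taken from counts" if (has_counts and (recompute_from_counts or not has_metrics))
        else "metrics taken as reported"
    )
    return ModelTable(records=records, provenance={"source": str(path), "parse_log": log})


def write_model_table(table: ModelTable, path: str | Path) -> None:
    """Write the table as CSV with canonical column names."""
    df = table.to_dataframe()
    df.to_csv(path, index=False)


def backfill_f1(table: ModelTable) -> ModelTable:
    """Fill missing F1 from PPV and sensitivity (harmonic mean, percent).

    Existing F1 values are left untouched, so the operation is idempotent.
    Records where the backfill is impossible (PPV or sensitivity missing)
    are listed in the returned table's parse log.
    """
    out_records: list[ModelRecord] = []
    impossible: list[int] = []
    n_filled = 0
    for r in table:
        if r.f1 is not None:
            out_records.append(r)
        elif r.ppv is not None and r.sensitivity is not None:
            out_records.append(replace(r, f1=f1_from_ppv_sensitivity(r.ppv, r.sensitivity)))
            n_filled += 1
        else:
            impossible.append(r.model_uid)
            out_records.append(r)
    note = f"backfill_f1: filled {n_filled} record(s)"
    if impossible:
        note += f"; impossible for model_uid(s) {impossible} (missing ppv or sensitivity)"
    return table.with_records(out_records, note)
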