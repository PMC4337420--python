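"""CSV reading/writing for cohort tables and flat JSON serialization of estimates.

Tables are UTF-8 CSV with a header row and "." decimal separator.  Each
reader takes an optional ``schema`` mapping from logical field names to the
file's column names; unspecified fields fall back to the defaults below.
Validation never silently drops a row: records that fail a domain invariant
raise :class:`~critweight.exceptions.RowParseError` naming the row, and
non-pupariating larvae are retained (flagged) rather than removed.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .estimates import CriticalWeightEstimate
from .exceptions import InvariantError, RowParseError, SchemaError
from .records import CtRecord, GrowthRecord, StarvationRecord, TimecourseSample

__all__ = [
    "STARVATION_SCHEMA",
    "GROWTH_SCHEMA",
    "CT_SCHEMA",
    "TIMECOURSE_SCHEMA",
    "read_starvation_table",
    "write_starvation_table",
    "read_growth_table",
    "write_growth_table",
    "read_ct_table",
    "read_timecourse_table",
    "write_timecourse_table",
    "write_estimate",
    "read_estimate",
]

# Default logical-name -> column-name maps.  The deposited tables' headers
# are not standardized, hence the user-overridable schema.
STARVATION_SCHEMA = {
    "larva_id": "larva_id",
    "group": "group",
    "age_at_starvation": "age_at_starvation",
    "time_to_pupariation": "time_to_pupariation",
    "pupariated": "pupariated",  # optional column
}
GROWTH_SCHEMA = {
    "larva_id": "larva_id",
    "group": "group",
    "age": "age",
    "mass": "mass",
}
CT_SCHEMA = {
    "gene": "gene",
    "group": "group",
    "time": "time",
    "replicate": "replicate",
    "ct_target": "ct_target",
    "ct_reference": "ct_reference",
}
TIMECOURSE_SCHEMA = {
    "group": "group",
    "time": "time",
    "replicate": "replicate",
    "value": "value",
}

#: Values in a time/mass column read as "not applicable".
_NA_SENTINELS = {"", "na", "n/a", "nan", "none", "."}


def _resolve_schema(defaults: Mapping[str, str], schema: Mapping[str, str] | None):
    merged = dict(defaults)
    if schema:
        unknown = set(schema) - set(defaults)
        if unknown:
            raise SchemaError(f"unknown schema field(s): {sorted(unknown)}")
        merged.update(schema)
    return merged

def _read_csv(path, columns: Sequence[str], optional: Sequence[str] = ()):
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns and c not in optional]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return df

def _num(raw: str, row: int, col: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise RowParseError(row, f"non-numeric value {raw!r} in column {col!r}") from None

def _is_na(raw: str) -> bool:
    return raw.strip().lower() in _NA_SENTINELS


def read_starvation_table(
    path, schema: Mapping[str, str] | None = None
) -> list[StarvationRecord]:
    """Read a per-larva starvation-response table.

    A missing ``pupariated`` column is inferred: rows whose
    time-to-pupariation field is an NA sentinel ("NA", empty, ...) become
    ``pupariated=False`` records (the larva died before pupariating).
    """
    cols = _resolve_schema(STARVATION_SCHEMA, schema)
    df = _read_csv(path, list(cols.values()), optional=[cols["pupariated"]])
    has_flag = cols["pupariated"] in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row = dict(zip(df.columns, row))
        raw_ttp = row[cols["time_to_pupariation"]]
        if has_flag:
            pupariated = row[cols["pupariated"]].strip().lower() in {"true", "1", "yes", "t"}
        else:
            pupariated = not _is_na(raw_ttp)
        age = _num(row[cols["age_at_starvation"]], i, cols["age_at_starvation"])
        ttp = float("nan")
        if pupariated:
            ttp = _num(raw_ttp, i, cols["time_to_pupariation"])
        try:
            rec = StarvationRecord(
                larva_id=row[cols["larva_id"]],
                group=row[cols["group"]],
                age_at_starvation=age,
                time_to_pupariation=ttp,
                pupariated=pupariated,
            )
        except InvariantError as exc:
            raise RowParseError(i, str(exc)) from exc
        records.append(rec)
    return records


def write_starvation_table(records: Iterable[StarvationRecord], path) -> None:
    rows = [
        {
            "larva_id": r.larva_id,
            "group": r.group,
            "age_at_starvation": r.age_at_starvation,
            "time_to_pupariation": r.time_to_pupariation if r.pupariated else "NA",
            "pupariated": r.pupariated,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(STARVATION_SCHEMA)).to_csv(path, index=False)


def read_growth_table(path, schema: Mapping[str, str] | None = None) -> list[GrowthRecord]:
    cols = _resolve_schema(GROWTH_SCHEMA, schema)
    df = _read_csv(path, list(cols.values()))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            rec = GrowthRecord(
                larva_id=row[cols["larva_id"]],
                group=row[cols["group"]],
                age=_num(row[cols["age"]], i, cols["age"]),
                mass=_num(row[cols["mass"]], i, cols["mass"]),
            )
        except InvariantError as exc:
            raise RowParseError(i, str(exc)) from exc
        records.append(rec)
    return records


def write_growth_table(records: Iterable[GrowthRecord], path) -> None:
    rows = [
        {"larva_id": r.larva_id, "group": r.group, "age": r.age, "mass": r.mass}
        for r in records
    ]
    pd.DataFrame(rows, columns=list(GROWTH_SCHEMA)).to_csv(path, index=False)


def read_ct_table(path, schema: Mapping[str, str] | None = None) -> list[CtRecord]:
    cols = _resolve_schema(CT_SCHEMA, schema)
    df = _read_csv(path, list(cols.values()))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        if _is_na(row[cols["ct_reference"]]):
            raise RowParseError(i, "missing reference Ct")
        try:
            rec = CtRecord(
                gene=row[cols["gene"]],
                group=row[cols["group"]],
                time=_num(row[cols["time"]], i, cols["time"]),
                replicate=int(_num(row[cols["replicate"]], i, cols["replicate"])),
                ct_target=_num(row[cols["ct_target"]], i, cols["ct_target"]),
                ct_reference=_num(row[cols["ct_reference"]], i, cols["ct_reference"]),
            )
        except InvariantError as exc:
            raise RowParseError(i, str(exc)) from exc
        records.append(rec)
    return records


def write_ct_table(records: Iterable[CtRecord], path) -> None:
    rows = [
        {
            "gene": r.gene,
            "group": r.group,
            "time": r.time,
            "replicate": r.replicate,
            "ct_target": r.ct_target,
            "ct_reference": r.ct_reference,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(CT_SCHEMA)).to_csv(path, index=False)


def read_timecourse_table(
    path, schema: Mapping[str, str] | None = None
) -> list[TimecourseSample]:
    cols = _resolve_schema(TIMECOURSE_SCHEMA, schema)
    df = _read_csv(path, list(cols.values()))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            rec = TimecourseSample(
                group=row[cols["group"]],
                time=_num(row[cols["time"]], i, cols["time"]),
                replicate=int(_num(row[cols["replicate"]], i, cols["replicate"])),
                value=_num(row[cols["value"]], i, cols["value"]),
            )
        except InvariantError as exc:
            raise RowParseError(i, str(exc)) from exc
        records.append(rec)
    return records


def write_timecourse_table(samples: Iterable[TimecourseSample], path) -> None:
    rows = [
        {"group": s.group, "time": s.time, "replicate": s.replicate, "value": s.value}
        for s in samples
    ]
    pd.DataFrame(rows, columns=list(TIMECOURSE_SCHEMA)).to_csv(path, index=False)


def write_estimate(estimate: CriticalWeightEstimate, path) -> None:
    """Write an estimate as flat JSON key-value text; round-trips losslessly."""
    if not estimate.is_finite():
        raise InvariantError("refusing to write a non-finite estimate")
    if estimate.age_ci_low > estimate.age_ci_high or estimate.mass_ci_low > estimate.mass_ci_high:
        raise InvariantError("refusing to write reversed CI bounds")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(estimate.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_estimate(path) -> CriticalWeightEstimate:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return CriticalWeightEstimate(**payload)
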