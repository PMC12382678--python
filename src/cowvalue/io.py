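"""Reading and writing herdbook files, economic configuration and reports.

A herdbook lives in one directory of delimited-text tables (one per record
type): ``farm.csv``, ``cows.csv``, ``calvings.csv``, ``testdays.csv``,
``inseminations.csv`` and ``cullings.csv``.  Column names are remappable
via a schema dictionary.  Row-level problems (bad dates, invariant
violations) are collected into an error log and the offending cow is
dropped; the read aborts only if more than 10% of rows fail, since real
herdbook exports are dirty but silently dropping a majority would bias any
audit built on them.

Economic configuration is a flat YAML key-value file whose keys are the
:class:`~cowvalue.economics.EconomicParams` field names; farm values
override the dataset averages field by field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .economics import EconomicParams
from .records import (CowRecord, CullingEvent, Herdbook, RecordError, TestDay,
                      as_period, normalize_reason)

ROW_ERROR_TOLERANCE = 0.10

TABLES = ("farm", "cows", "calvings", "testdays", "inseminations", "cullings")

#: Default column names per table; a schema maps these standard names to
#: the names actually present in the files.
DEFAULT_COLUMNS = {
    "farm": ("farm_id", "period_start", "period_end"),
    "cows": ("cow_id", "breed"),
    "calvings": ("cow_id", "month"),
    "testdays": ("cow_id", "month", "milk_kg", "fat_pct", "protein_pct"),
    "inseminations": ("cow_id", "month"),
    "cullings": ("cow_id", "month", "reason"),
}


class SchemaError(ValueError):
    """A mandatory column is missing from a herdbook table."""


class HerdbookReadError(ValueError):
    """Too many rows failed validation for the herdbook to be trusted."""


@dataclass
class RowError:
    table: str
    row: int
    message: str


@dataclass
class ReadReport:
    """Per-row error log produced while reading a herdbook."""

    errors: list[RowError] = field(default_factory=list)
    n_rows: int = 0
    excluded_cows: list[str] = field(default_factory=list)

    def add(self, table: str, row: int, message: str) -> None:
        self.errors.append(RowError(table, row, message))


def _load_table(directory: Path, table: str, schema: dict | None,
                delimiter: str) -> pd.DataFrame:
    path = directory / f"{table}.csv"
    if not path.exists():
        if table in ("farm", "calvings"):
            raise SchemaError(f"missing mandatory table {path}")
        return pd.DataFrame(columns=DEFAULT_COLUMNS[table])
    frame = pd.read_csv(path, sep=delimiter, dtype=str, comment="#")
    mapping = (schema or {}).get(table, {})
    rename = {v: k for k, v in mapping.items()}
    frame = frame.rename(columns=rename)
    missing = [c for c in DEFAULT_COLUMNS[table] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return frame


def read_herdbook(path, schema: dict | None = None, delimiter: str = ","
                  ) -> tuple[Herdbook, ReadReport]:
    """Read and validate a herdbook directory.

    Parameters
    ----------
    path : path-like
        Directory holding the per-record-type tables.
    schema : dict, optional
        ``{table: {standard_name: file_column_name}}`` column remapping.
    delimiter : str
        Field delimiter (comma by default).

    Returns
    -------
    (Herdbook, ReadReport)
        The validated herdbook and the per-row error log.

    Raises
    ------
    SchemaError
        A mandatory table or column is missing.
    HerdbookReadError
        More than 10% of data rows failed validation.
    """
    directory = Path(path)
    report = ReadReport()
    farm = _load_table(directory, "farm", schema, delimiter)
    if len(farm) != 1:
        raise SchemaError(f"{directory / 'farm.csv'} must contain exactly one row")
    farm_id = str(farm.iloc[0]["farm_id"])
    period = (as_period(farm.iloc[0]["period_start"]),
              as_period(farm.iloc[0]["period_end"]))

    cows_tbl = _load_table(directory, "cows", schema, delimiter)
    breeds = {str(r.cow_id): str(r.breed) for r in cows_tbl.itertuples()}
    records: dict[str, CowRecord] = {}
    for cow_id, breed in breeds.items():
        records[cow_id] = CowRecord(cow_id=cow_id, breed=breed)

    def get_record(cow_id: str) -> CowRecord:
        return records.setdefault(str(cow_id), CowRecord(cow_id=str(cow_id)))

    bad_cows: set[str] = set()

    def parse_rows(table: str, handler) -> None:
        frame = _load_table(directory, table, schema, delimiter)
        for i, row in enumerate(frame.itertuples(index=False)):
            report.n_rows += 1
            try:
                handler(row)
            except (ValueError, RecordError) as exc:
                report.add(table, i, str(exc))
                if hasattr(row, "cow_id"):
                    bad_cows.add(str(row.cow_id))

    parse_rows("calvings",
               lambda r: get_record(r.cow_id).calvings.append(as_period(r.month)))
    parse_rows("testdays",
               lambda r: get_record(r.cow_id).testdays.append(TestDay(
                   month=as_period(r.month), milk_kg=float(r.milk_kg),
                   fat_pct=float(r.fat_pct), protein_pct=float(r.protein_pct))))
    parse_rows("inseminations",
               lambda r: get_record(r.cow_id).inseminations.append(
                   as_period(r.month)))

    def handle_cull(r):
        reason, recognized = normalize_reason(r.reason)
        if not recognized:
            warnings.warn(f"unknown culling reason {r.reason!r} mapped to 'others'",
                          stacklevel=4)
        get_record(r.cow_id).culling = CullingEvent(month=as_period(r.month),
                                                    reason=reason)

    parse_rows("cullings", handle_cull)

    # cow-level invariant validation; offending cows are excluded
    valid: list[CowRecord] = []
    for cow_id, record in records.items():
        if cow_id in bad_cows:
            report.excluded_cows.append(cow_id)
            continue
        record.calvings.sort()
        record.inseminations.sort()
        record.testdays.sort(key=lambda td: td.month)
        try:
            record.validate()
            start, end = period
            for month in record.event_months():
                if not (start <= month <= end):
                    raise RecordError(
                        f"cow {cow_id}: event {month} outside period {start}..{end}")
        except RecordError as exc:
            report.add("cows", -1, str(exc))
            report.excluded_cows.append(cow_id)
            continue
        valid.append(record)

    if report.n_rows > 0 and len(report.errors) > ROW_ERROR_TOLERANCE * report.n_rows:
        raise HerdbookReadError(
            f"{len(report.errors)} of {report.n_rows} rows failed validation "
            f"(tolerance {ROW_ERROR_TOLERANCE:.0%}); first error: "
            f"{report.errors[0].message}")

    herdbook = Herdbook(farm_id=farm_id, cows=valid, period=period)
    herdbook.validate()
    return herdbook, report


def write_herdbook(herdbook: Herdbook, path, delimiter: str = ",") -> None:
    """Write a herdbook to a directory in the standard table schema.

    A write followed by :func:`read_herdbook` reproduces every event
    exactly (dates are year-month, yields carry two decimals).
    """
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    start, end = herdbook.period
    pd.DataFrame([{"farm_id": herdbook.farm_id, "period_start": str(start),
                   "period_end": str(end)}]).to_csv(
        directory / "farm.csv", index=False, sep=delimiter)
    cows, calvings, testdays, inseminations, cullings = [], [], [], [], []
    for cow in herdbook.cows:
        cows.append({"cow_id": cow.cow_id, "breed": cow.breed})
        for c in cow.calvings:
            calvings.append({"cow_id": cow.cow_id, "month": str(c)})
        for td in cow.testdays:
            testdays.append({"cow_id": cow.cow_id, "month": str(td.month),
                             "milk_kg": td.milk_kg, "fat_pct": td.fat_pct,
                             "protein_pct": td.protein_pct})
        for ins in cow.inseminations:
            inseminations.append({"cow_id": cow.cow_id, "month": str(ins)})
        if cow.culling is not None:
            cullings.append({"cow_id": cow.cow_id,
                             "month": str(cow.culling.month),
                             "reason": cow.culling.reason})
    for name, rows, cols in (
            ("cows", cows, DEFAULT_COLUMNS["cows"]),
            ("calvings", calvings, DEFAULT_COLUMNS["calvings"]),
            ("testdays", testdays, DEFAULT_COLUMNS["testdays"]),
            ("inseminations", inseminations, DEFAULT_COLUMNS["inseminations"]),
            ("cullings", cullings, DEFAULT_COLUMNS["cullings"])):
        pd.DataFrame(rows, columns=list(cols)).to_csv(
            directory / f"{name}.csv", index=False, sep=delimiter)


def read_econ_config(path, dataset_averages: EconomicParams | None = None
                     ) -> EconomicParams:
    """Read a farm economic configuration with field-wise fallback.

    Keys present in the YAML file override the corresponding field of
    ``dataset_averages`` (the Swiss dataset averages by default); absent
    fields keep the average.  Invalid values (e.g. negative prices) raise a
    validation error.
    """
    base = dataset_averages or EconomicParams()
    raw = yaml.safe_load(Path(path).read_text()) if Path(path).exists() else None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    unknown = set(raw) - set(EconomicParams.model_fields)
    if unknown:
        raise ValueError(f"{path}: unknown economic parameter(s) {sorted(unknown)}")
    merged = base.model_dump()
    merged.update(raw)
    return EconomicParams(**merged)


def write_audit_report(farm_audits, decision_records, reason_grid, path,
                       delimiter: str = ",", header_lines: list[str] | None = None
                       ) -> dict[str, Path]:
    """Write audit results as delimited-text report tables.

    Emits ``farm_summary.csv`` (one row per farm: losses, herd size,
    replacement rate; farm id ascending), ``reasons_by_parity.csv`` (the
    reason x parity grid with totals and shares) and ``decisions.csv``
    (per-cow decision records).  Empty inputs produce header-only files.
    """
    from .audit import farm_audit_frame, decision_frame  # local: avoid cycle

    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = "".join(f"# {line}\n" for line in (header_lines or []))

    def emit(name: str, frame: pd.DataFrame, index=False) -> Path:
        out = directory / name
        with open(out, "w") as fh:
            fh.write(prefix)
            frame.to_csv(fh, index=index, sep=delimiter)
        return out

    paths = {
        "farm_summary": emit("farm_summary.csv", farm_audit_frame(farm_audits)),
        "decisions": emit("decisions.csv", decision_frame(decision_records)),
        "reasons_by_parity": emit("reasons_by_parity.csv", reason_grid,
                                  index=True),
    }
    return paths
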