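"""Reading, writing and validating ED extract files.

Extracts are comma-separated UTF-8 files with a mandatory header row. A single
transfer specification (:class:`FormatSpec`) covers every trust: fixed column
titles and order, a literal ``"XXXX"`` sentinel for absent values, and a named
date/time dialect. Validation reports every violation with its locus so a data
provider can fix the extract and resend — the revision loop that dominates
real multi-site transfers.
"""

from __future__ import annotations

import csv
import io
import warnings
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import pandas as pd

from .errors import ExtractFormatError, ExtractIOError

#: The 18 ED variables requested from every trust, in transfer order.
ED_VARIABLES: tuple[str, ...] = (
    "hospital_site",
    "ed_arrival_datetime",
    "ethnicity",
    "age",
    "gender",
    "gp_practice_id",
    "first_ed_location",
    "blue_light_journey",
    "pathology",
    "imaging",
    "treatment",
    "diagnosis",
    "specialty_referral",
    "outcome",
    "outcome_destination",
    "departure_datetime",
    "cad_number",
    "call_sign",
)

#: strptime formats for the supported date/time dialects.
DATETIME_DIALECTS: dict[str, str] = {
    "iso8601": "%Y-%m-%d %H:%M:%S",
    "uk_dmy": "%d/%m/%Y %H:%M",
}

#: Tokens providers commonly use instead of the required missing sentinel.
BAD_SENTINELS = frozenset({"null", "n/a", "na", ""})


@dataclass(frozen=True)
class FormatSpec:
    """The transfer specification an extract must adhere to exactly."""

    column_titles: tuple[str, ...] = ("ed_row_id",) + ED_VARIABLES
    missing_sentinel: str = "XXXX"
    datetime_convention: str = "iso8601"
    delimiter: str = ","
    filename_pattern: str = "{trust}_{extract_date}.csv"
    datetime_columns: tuple[str, ...] = ("ed_arrival_datetime", "departure_datetime")

    def __post_init__(self):
        if len(set(self.column_titles)) != len(self.column_titles):
            raise ValueError("column titles must be unique")
        if not self.missing_sentinel:
            raise ValueError("missing_sentinel must be non-empty")
        if self.datetime_convention not in DATETIME_DIALECTS:
            raise ValueError(f"unknown datetime dialect {self.datetime_convention!r}")

    @property
    def datetime_format(self) -> str:
        return DATETIME_DIALECTS[self.datetime_convention]


@dataclass(frozen=True)
class Violation:
    rule: str          # one of: delimiter, column_title, column_order, structure,
                       #         missing_sentinel, datetime_format
    locus: str         # "header", "col <name>", or "row <i>, col <name>"
    detail: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def file_ok(self) -> bool:
        return not self.violations

    @property
    def counts(self) -> dict[str, int]:
        return dict(Counter(v.rule for v in self.violations))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.rule, v.locus, v.detail) for v in self.violations],
            columns=["rule", "locus", "detail"],
        )


_ALTERNATE_DELIMITERS = (";", "\t", "|")


def _read_raw(path) -> list[list[str]]:
    p = Path(path)
    if not p.exists():
        raise ExtractIOError(f"extract file not found: {p}")
    text = p.read_text(encoding="utf-8")
    if not text.strip():
        raise ExtractIOError(f"extract file is empty: {p}")
    return text


def validate_extract(path, spec: FormatSpec = None) -> ValidationReport:
    """Check an extract file against the transfer specification.

    Pure: the file is never mutated and the same file + spec always yields the
    same report. Every title, order, structure, sentinel and datetime-dialect
    violation is reported with its locus.
    """
    spec = spec or FormatSpec()
    text = _read_raw(path)
    rows = list(csv.reader(io.StringIO(text), delimiter=spec.delimiter))
    report = ValidationReport()

    header = rows[0]
    expected = list(spec.column_titles)

    # Wrong delimiter: the header collapses to one field but an alternate
    # delimiter recovers the expected titles.
    if len(header) == 1 and len(expected) > 1:
        for alt in _ALTERNATE_DELIMITERS:
            if header[0].split(alt) == expected:
                report.violations.append(Violation(
                    "delimiter", "header",
                    f"file appears to use {alt!r} instead of {spec.delimiter!r}"))
                return report

    missing = [c for c in expected if c not in header]
    unknown = [c for c in header if c not in expected]
    for m, u in zip(missing, unknown):
        report.violations.append(Violation(
            "column_title", f"col {u}", f"unrecognised title {u!r}; expected {m!r}"))
    for m in missing[len(unknown):]:
        report.violations.append(Violation("column_title", f"col {m}", f"missing column {m!r}"))
    for u in unknown[len(missing):]:
        report.violations.append(Violation("column_title", f"col {u}", f"unexpected column {u!r}"))
    if not missing and not unknown and header != expected:
        for i, (got, want) in enumerate(zip(header, expected)):
            if got != want:
                report.violations.append(Violation(
                    "column_order", f"col {got}",
                    f"position {i}: found {got!r}, expected {want!r}"))

    # Cell-level checks use the *provided* header names so they stay meaningful
    # even when columns were re-ordered or a title is wrong.
    dt_cols = {c for c in spec.datetime_columns if c in header}
    fmt = spec.datetime_format
    for r, row in enumerate(rows[1:], start=2):  # 1-based file line numbers
        if len(row) != len(header):
            report.violations.append(Violation(
                "structure", f"row {r}",
                f"{len(row)} fields, header has {len(header)}"))
            continue
        for col, cell in zip(header, row):
            if cell != spec.missing_sentinel and cell.lower() in BAD_SENTINELS:
                report.violations.append(Violation(
                    "missing_sentinel", f"row {r}, col {col}",
                    f"{cell!r} used instead of {spec.missing_sentinel!r}"))
            elif col in dt_cols and cell != spec.missing_sentinel:
                try:
                    datetime.strptime(cell, fmt)
                except ValueError:
                    report.violations.append(Violation(
                        "datetime_format", f"row {r}, col {col}",
                        f"{cell!r} does not match dialect {spec.datetime_convention!r}"))
    return report


def read_extract(path, spec: FormatSpec = None, strict: bool = False) -> pd.DataFrame:
    """Read an extract into a DataFrame, mapping the sentinel to missing values.

    When ``strict``, any validation violation rejects the file with an
    :class:`ExtractFormatError` carrying the report. Otherwise the read is
    best-effort: one warning is emitted per violation, bad sentinels are
    treated as missing and unparseable timestamps become NaT. Row order is
    preserved and the validation report is attached as
    ``df.attrs["validation_report"]``.
    """
    spec = spec or FormatSpec()
    report = validate_extract(path, spec)
    if strict and not report.file_ok:
        raise ExtractFormatError(
            f"extract rejected: {len(report.violations)} violation(s) "
            f"({', '.join(sorted(report.counts))})", report=report)
    for v in report.violations:
        warnings.warn(f"extract violation [{v.rule}] at {v.locus}: {v.detail}",
                      stacklevel=2)

    df = pd.read_csv(path, sep=spec.delimiter, dtype=str, keep_default_na=False)
    df = df.replace(spec.missing_sentinel, pd.NA)
    df = df.map(lambda x: pd.NA if isinstance(x, str) and x.lower() in BAD_SENTINELS else x)
    for col in spec.datetime_columns:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format=spec.datetime_format,
                                     errors="coerce")
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce").astype("Int64")
    df.attrs["validation_report"] = report
    return df


def write_extract(rows: pd.DataFrame, spec: FormatSpec = None, path=None) -> Path:
    """Write rows as a spec-conformant extract file.

    Columns are emitted in spec order; absent values (NA/NaT) are serialised
    as the missing sentinel; timestamps use the spec dialect. Round-trips with
    :func:`read_extract` losslessly under the iso8601 dialect.
    """
    spec = spec or FormatSpec()
    missing_cols = [c for c in spec.column_titles if c not in rows.columns]
    if missing_cols:
        raise ValueError(f"rows are missing required column(s): {missing_cols}")
    out = rows.loc[:, list(spec.column_titles)].copy()
    fmt = spec.datetime_format
    for col in spec.datetime_columns:
        out[col] = pd.to_datetime(out[col]).dt.strftime(fmt)
    for col in out.columns:
        out[col] = out[col].map(
            lambda x: spec.missing_sentinel if pd.isna(x) else str(x))
    path = Path(path)
    out.to_csv(path, sep=spec.delimiter, index=False, encoding="utf-8")
    return path
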