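"""Canonicalising CAD and call-sign identifiers from raw ED fields.

The two event identifiers arrive in wildly inconsistent shapes: separate
fields, or one unformatted free-text box holding both in any order
(``'CAD123, Q987'``, ``'123, Call sign Q987'``, ``'Q987/123'``). Cleaning
scans the raw text for

* a CAD candidate — a 1–4 digit numeric token with value under 7000 (the
  dispatch system's daily range), never taken from inside a call-sign token;
* a call-sign candidate — a letters-then-digits token that, after
  uppercasing and stripping punctuation, is an exact member of the service's
  call-sign registry.

Label words ("CAD", "Call sign") are stripped case-insensitively before
scanning. Unparseable content is reported, never raised.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

CALLSIGN_PATTERN = re.compile(r"^[A-Z]+\d+$")
_LABEL_RE = re.compile(r"call[\s_\-]*sign|cad(?=[\s:#\-]*\d)", re.IGNORECASE)
_TOKEN_RE = re.compile(r"[A-Za-z]+\d+|\d+|[A-Za-z]+")

#: Upper bound (exclusive) for a genuine CAD number.
CAD_LIMIT = 7000

_MISSING_TOKENS = frozenset({"", "xxxx", "null", "n/a", "na"})


@dataclass(frozen=True)
class CallSignRegistry:
    """The list of all possible call signs, used to verify parsed candidates."""

    valid_signs: frozenset[str]

    def __post_init__(self):
        if not self.valid_signs:
            raise ValueError("registry must be non-empty")
        bad = [s for s in self.valid_signs if not CALLSIGN_PATTERN.match(s)]
        if bad:
            raise ValueError(f"invalid call signs in registry: {sorted(bad)[:5]}")

    def __contains__(self, sign: str) -> bool:
        return sign in self.valid_signs

    @classmethod
    def from_iterable(cls, signs: Iterable[str]) -> "CallSignRegistry":
        return cls(frozenset(s.strip().upper() for s in signs))

    @classmethod
    def from_csv(cls, path) -> "CallSignRegistry":
        df = pd.read_csv(path, dtype=str)
        col = "call_sign" if "call_sign" in df.columns else df.columns[0]
        return cls.from_iterable(df[col].dropna())


@dataclass(frozen=True)
class ParsedIdentifiers:
    cad: Optional[int]
    call_sign: Optional[str]
    parse_status: str  # both | cad_only | callsign_only | none
    raw: str
    n_cad_candidates: int = 0
    callsign_rejected: bool = False  # pattern token seen but not in registry

    def __post_init__(self):
        expected = {(True, True): "both", (True, False): "cad_only",
                    (False, True): "callsign_only", (False, False): "none"}[
                        (self.cad is not None, self.call_sign is not None)]
        assert self.parse_status == expected


@dataclass
class CleaningReport:
    n_rows_in: int = 0
    n_duplicates_removed: int = 0
    n_parsed_cad: int = 0
    n_parsed_callsign: int = 0
    n_callsigns_rejected_by_registry: int = 0
    n_neither: int = 0
    n_multi_cad_candidates: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _is_missing(value) -> bool:
    if value is None or (not isinstance(value, str) and pd.isna(value)):
        return True
    return str(value).strip().lower() in _MISSING_TOKENS


def _tokens(text: str) -> list[str]:
    return _TOKEN_RE.findall(_LABEL_RE.sub(" ", text))


def parse_identifiers(raw_cad_field, raw_callsign_field=None,
                      registry: Optional[CallSignRegistry] = None) -> ParsedIdentifiers:
    """Extract a (CAD, call sign) pair from one or two raw identifier fields.

    Tokens are scanned in field order (CAD field first), so the function
    handles both separate fields and a single combined free-text field. The
    first 1–4 digit token under 7000 becomes the CAD; the first
    letters-then-digits token accepted by the registry (exact match after
    canonicalisation) becomes the call sign. Digits inside a call-sign token
    are never also claimed as a CAD. Idempotent and total: any input yields a
    result, ``parse_status="none"`` at worst.
    """
    parts = [str(f) for f in (raw_cad_field, raw_callsign_field)
             if not _is_missing(f)]
    raw = " | ".join(parts)
    cad: Optional[int] = None
    call_sign: Optional[str] = None
    n_cad_candidates = 0
    rejected = False
    for text in parts:
        for token in _tokens(text):
            if token.isdigit():
                if 1 <= len(token) <= 4 and 1 <= int(token) < CAD_LIMIT:
                    n_cad_candidates += 1
                    if cad is None:
                        cad = int(token)
            else:
                canon = token.upper()
                if CALLSIGN_PATTERN.match(canon) and call_sign is None:
                    if registry is None or canon in registry:
                        call_sign = canon
                    else:
                        rejected = True
    status = {(True, True): "both", (True, False): "cad_only",
              (False, True): "callsign_only", (False, False): "none"}[
                  (cad is not None, call_sign is not None)]
    return ParsedIdentifiers(cad=cad, call_sign=call_sign, parse_status=status,
                             raw=raw, n_cad_candidates=n_cad_candidates,
                             callsign_rejected=rejected and call_sign is None)


def deduplicate(rows: pd.DataFrame, id_column: str = "ed_row_id"
                ) -> tuple[pd.DataFrame, int]:
    """Collapse rows identical on every non-id column to the first occurrence."""
    cols = [c for c in rows.columns if c != id_column]
    kept = rows.drop_duplicates(subset=cols, keep="first")
    return kept, len(rows) - len(kept)


def clean_extract(rows: pd.DataFrame, registry: Optional[CallSignRegistry] = None
                  ) -> tuple[pd.DataFrame, CleaningReport]:
    """Deduplicate and attach parsed identifiers to every row.

    Returns the cleaned frame with ``parsed_cad`` (nullable Int64),
    ``parsed_call_sign`` and ``parse_status`` columns, plus a count report.
    Empty input yields an empty frame and a zeroed report.
    """
    report = CleaningReport(n_rows_in=len(rows))
    if rows.empty:
        out = rows.copy()
        out["parsed_cad"] = pd.Series(dtype="Int64")
        out["parsed_call_sign"] = pd.Series(dtype=object)
        out["parse_status"] = pd.Series(dtype=object)
        return out, report

    deduped, n_removed = deduplicate(rows)
    report.n_duplicates_removed = n_removed
    out = deduped.copy()

    cads, signs, statuses = [], [], []
    for cad_raw, cs_raw in zip(out["cad_number"], out["call_sign"]):
        p = parse_identifiers(cad_raw, cs_raw, registry)
        cads.append(p.cad)
        signs.append(p.call_sign)
        statuses.append(p.parse_status)
        if p.cad is not None:
            report.n_parsed_cad += 1
        if p.call_sign is not None:
            report.n_parsed_callsign += 1
        if p.callsign_rejected:
            report.n_callsigns_rejected_by_registry += 1
        if p.parse_status == "none":
            report.n_neither += 1
        if p.n_cad_candidates > 1:
            report.n_multi_cad_candidates += 1
    out["parsed_cad"] = pd.array(cads, dtype="Int64")
    out["parsed_call_sign"] = signs
    out["parse_status"] = statuses
    return out, report
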