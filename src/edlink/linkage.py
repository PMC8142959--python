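"""Two-pathway deterministic linkage of cleaned ED rows to ambulance records.

An ED row must carry at least one event identifier to be linkable. With both
available, agreement on either suffices and the CAD pathway is tried first:

* **CAD + date** — the CAD number resets at midnight, so (CAD, incident
  date) is unique within the service per day. A row matches on its arrival
  date or, for journeys that crossed midnight, the preceding date. No time
  window is applied. When *both* dates hold a candidate (the CAD was
  reissued the next day), the default tie-break prefers the candidate whose
  ambulance-recorded ED arrival is nearest the row's arrival — time used
  only to break a date tie, never as a standalone matcher.
* **Call sign + date + arrival time** — a call sign is unique to a crew's
  shift but one crew can convey several patients to the same ED, so the
  match additionally requires the nearest ambulance-recorded arrival within
  a configurable tolerance (and, by default, the same site). Two candidates
  equidistant within the window are ambiguous and yield no match.

Matching is exact throughout: no fuzzy repair, no demographic variables.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import NamedTuple, Optional

import pandas as pd

from .errors import ConfigurationError


@dataclass(frozen=True)
class LinkConfig:
    """Tunable rules of the deterministic matcher."""

    time_tolerance_minutes: float = 120.0
    allow_consecutive_dates: bool = True
    require_site_agreement_callsign: bool = True
    cmp_site_cad: str = "flag"          # ignore | flag | require
    cad_tie_break: str = "nearest_arrival"  # nearest_arrival | exact_date

    def __post_init__(self):
        if self.time_tolerance_minutes <= 0:
            raise ConfigurationError("time_tolerance_minutes must be > 0")
        if self.cmp_site_cad not in ("ignore", "flag", "require"):
            raise ConfigurationError(f"bad cmp_site_cad {self.cmp_site_cad!r}")
        if self.cad_tie_break not in ("nearest_arrival", "exact_date"):
            raise ConfigurationError(f"bad cad_tie_break {self.cad_tie_break!r}")


class AmbRec(NamedTuple):
    amb_id: str
    cad_number: int
    incident_date: date
    call_sign: str
    ed_arrival: pd.Timestamp
    site: str


@dataclass
class AmbulanceIndex:
    by_cad_date: dict[tuple[int, date], AmbRec]
    by_callsign_date: dict[tuple[str, date], list[AmbRec]]
    quarantined: list[AmbRec] = field(default_factory=list)

    def __len__(self):
        return len(self.by_cad_date)


@dataclass(frozen=True)
class LinkResult:
    ed_row_id: str
    amb_id: Optional[str]
    method: str  # cad_date | callsign_datetime | unmatched | no_identifier
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        assert (self.method in ("cad_date", "callsign_datetime")) == \
            (self.amb_id is not None)


def build_index(ambulance: pd.DataFrame) -> AmbulanceIndex:
    """Index ambulance records by (CAD, date) and (call sign, date).

    (CAD, date) keys that occur more than once violate the uniqueness the CAD
    pathway relies on; all records under such keys are quarantined from CAD
    matching (never silently overwritten) but stay reachable by call sign.
    """
    by_cad: dict[tuple[int, date], list[AmbRec]] = defaultdict(list)
    by_cs: dict[tuple[str, date], list[AmbRec]] = defaultdict(list)
    for r in ambulance.itertuples(index=False):
        d = r.incident_date if isinstance(r.incident_date, date) and not isinstance(
            r.incident_date, pd.Timestamp) else pd.Timestamp(r.incident_date).date()
        rec = AmbRec(r.amb_id, int(r.cad_number), d, str(r.call_sign),
                     pd.Timestamp(r.ed_arrival), str(r.destination_site))
        by_cad[(rec.cad_number, rec.incident_date)].append(rec)
        by_cs[(rec.call_sign, rec.incident_date)].append(rec)

    quarantined: list[AmbRec] = []
    cad_index: dict[tuple[int, date], AmbRec] = {}
    for key, recs in by_cad.items():
        if len(recs) == 1:
            cad_index[key] = recs[0]
        else:
            quarantined.extend(recs)
    cs_index = {k: sorted(v, key=lambda rec: (rec.ed_arrival, rec.amb_id))
                for k, v in by_cs.items()}
    return AmbulanceIndex(by_cad_date=cad_index, by_callsign_date=cs_index,
                          quarantined=quarantined)


class _Row(NamedTuple):
    ed_row_id: str
    arrival: pd.Timestamp
    site: Optional[str]
    cad: Optional[int]
    call_sign: Optional[str]
    parse_status: str


def _minutes_apart(a: pd.Timestamp, b: pd.Timestamp) -> float:
    return abs((a - b).total_seconds()) / 60.0


def match_cad_date(row: _Row, index: AmbulanceIndex,
                   cfg: LinkConfig = LinkConfig()) -> Optional[LinkResult]:
    """CAD pathway: exact (CAD, date) lookup, consecutive date for crossers."""
    d = row.arrival.date()
    exact = index.by_cad_date.get((row.cad, d))
    prev = (index.by_cad_date.get((row.cad, d - timedelta(days=1)))
            if cfg.allow_consecutive_dates else None)
    flags = set()
    if exact is not None and prev is not None:
        if cfg.cad_tie_break == "exact_date":
            chosen = exact
        else:
            da, db = (_minutes_apart(exact.ed_arrival, row.arrival),
                      _minutes_apart(prev.ed_arrival, row.arrival))
            chosen = exact if da <= db else prev
            if chosen is prev:
                flags.add("consecutive_date_used")
    elif exact is not None:
        chosen = exact
    elif prev is not None:
        chosen = prev
        flags.add("consecutive_date_used")
    else:
        return None

    if row.site is not None and chosen.site != row.site:
        if cfg.cmp_site_cad == "require":
            return None
        if cfg.cmp_site_cad == "flag":
            flags.add("site_disagreement")
    return LinkResult(row.ed_row_id, chosen.amb_id, "cad_date", frozenset(flags))


def match_callsign(row: _Row, index: AmbulanceIndex,
                   cfg: LinkConfig = LinkConfig()) -> Optional[LinkResult]:
    """Call-sign pathway: nearest same-shift arrival within the tolerance."""
    d = row.arrival.date()
    candidates = list(index.by_callsign_date.get((row.call_sign, d), ()))
    if cfg.allow_consecutive_dates:
        candidates += index.by_callsign_date.get(
            (row.call_sign, d - timedelta(days=1)), ())
    if cfg.require_site_agreement_callsign and row.site is not None:
        candidates = [c for c in candidates if c.site == row.site]
    in_window = [(c, _minutes_apart(c.ed_arrival, row.arrival))
                 for c in candidates]
    in_window = [(c, dist) for c, dist in in_window
                 if dist <= cfg.time_tolerance_minutes]
    if not in_window:
        return None
    best_dist = min(dist for _, dist in in_window)
    best = [c for c, dist in in_window if dist == best_dist]
    if len(best) > 1 and len({c.amb_id for c in best}) > 1:
        return LinkResult(row.ed_row_id, None, "unmatched",
                          frozenset({"ambiguous_candidates"}))
    chosen = best[0]
    flags = set()
    if chosen.incident_date != d:
        flags.add("consecutive_date_used")
    return LinkResult(row.ed_row_id, chosen.amb_id, "callsign_datetime",
                      frozenset(flags))


def _rows_from_frame(rows: pd.DataFrame):
    for r in rows.itertuples(index=False):
        cad = getattr(r, "parsed_cad", None)
        cs = getattr(r, "parsed_call_sign", None)
        yield _Row(
            ed_row_id=r.ed_row_id,
            arrival=pd.Timestamp(r.ed_arrival_datetime),
            site=None if pd.isna(r.hospital_site) else str(r.hospital_site),
            cad=None if pd.isna(cad) else int(cad),
            call_sign=None if pd.isna(cs) else str(cs),
            parse_status=r.parse_status,
        )


def link_all(rows: pd.DataFrame, ambulance: pd.DataFrame,
             cfg: LinkConfig = LinkConfig()) -> tuple[pd.DataFrame, dict]:
    """Link every cleaned ED row, CAD pathway first, call sign on failure.

    Returns one result per input row (columns ``ed_row_id``, ``amb_id``,
    ``method``, ``flags`` — plus ``trust`` when the input carries it) and a
    tally dict with per-site method counts and the ambulance records linked
    by more than one ED row.
    """
    index = build_index(ambulance)
    results = []
    for row in _rows_from_frame(rows):
        if row.parse_status == "none":
            res = LinkResult(row.ed_row_id, None, "no_identifier")
        else:
            res = None
            if row.cad is not None:
                res = match_cad_date(row, index, cfg)
            if res is None or res.amb_id is None:
                carry = res.flags if res is not None else frozenset()
                if row.call_sign is not None:
                    cs_res = match_callsign(row, index, cfg)
                    if cs_res is not None:
                        res = LinkResult(cs_res.ed_row_id, cs_res.amb_id,
                                         cs_res.method, cs_res.flags | carry)
                if res is None:
                    res = LinkResult(row.ed_row_id, None, "unmatched", carry)
        results.append(res)

    out = pd.DataFrame({
        "ed_row_id": [r.ed_row_id for r in results],
        "amb_id": [r.amb_id for r in results],
        "method": [r.method for r in results],
        "flags": [";".join(sorted(r.flags)) for r in results],
    })
    if "trust" in rows.columns:
        out["trust"] = rows["trust"].to_numpy()

    by_site = (pd.DataFrame({"site": rows["hospital_site"].to_numpy(),
                             "method": out["method"].to_numpy()})
               .groupby(["site", "method"], dropna=False).size()
               .rename("n").reset_index())
    linked = out["amb_id"].dropna()
    multi = sorted(linked[linked.duplicated(keep=False)].unique())
    tallies = {
        "by_site": by_site,
        "multi_link_amb_ids": multi,
        "n_quarantined_cad_keys": len(index.quarantined),
        "time_tolerance_minutes": cfg.time_tolerance_minutes,
    }
    return out, tallies
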