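"""Linkage-quality reporting: per-trust match rates, unmatched-record trends
and ground-truth scoring.

The match report follows the study-report convention: per-trust counts of
records available for matching, records with no usable identifier, matched
records, and a nearest-integer match rate (matched / available), with a
totals row. Pathway counts are additionally expressed as shares of *total*
records. Trend analysis over unmatched rows flags identifier values that
recur suspiciously often (e.g. "136" recorded for Mental Health Act cases)
and summarises time-of-day and age against the matched rows. Ground-truth
scoring computes the precision / recall / false-non-link figures that a
de-identified real-world deployment cannot observe.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .errors import ConsistencyError

_MATCH_METHODS = ("cad_date", "callsign_datetime")

AGE_BIN_EDGES = (0, 5, 18, 65, 200)
AGE_BIN_LABELS = ("0-4", "5-17", "18-64", "65+")


def _half_up(x: float) -> int:
    """Round half away from zero — reproduces conventional printed rates."""
    return int(math.floor(x + 0.5))


@dataclass
class MatchReport:
    """Per-trust completeness and linkage rates with a totals row."""

    table: pd.DataFrame
    overall_match_rate_pct: Optional[int]
    pct_no_identifier: Optional[float]
    pathway: Optional[dict] = None

    def to_text(self) -> str:
        lines = [self.table.to_string(index=False)]
        if self.pathway:
            lines.append(
                f"CAD + date: {self.pathway['n_cad_date']:,} "
                f"({self.pathway['share_cad_pct']}% of records); call sign: "
                f"{self.pathway['n_callsign']:,} "
                f"({self.pathway['share_callsign_pct']}% of records)")
        return "\n".join(lines)


def _report_from_counts(counts: pd.DataFrame,
                        pathway_counts: Optional[Mapping[str, int]]) -> MatchReport:
    t = counts.copy().reset_index(drop=True)
    total = pd.DataFrame([{
        "trust": "Total",
        "n_available": t["n_available"].sum(),
        "n_no_identifier": t["n_no_identifier"].sum(),
        "n_matched": t["n_matched"].sum(),
    }])
    for extra in ("n_cad_date", "n_callsign"):
        if extra in t.columns:
            total[extra] = t[extra].sum()
    t = pd.concat([t, total], ignore_index=True)

    rates, inconsistent = [], []
    for r in t.itertuples(index=False):
        rates.append(_half_up(100.0 * r.n_matched / r.n_available)
                     if r.n_available > 0 else pd.NA)
        inconsistent.append(r.n_no_identifier + r.n_matched > r.n_available)
    t["match_rate_pct"] = pd.array(rates, dtype="Int64")
    t["inconsistent"] = inconsistent

    n_avail_total = int(total.loc[0, "n_available"])
    overall = (_half_up(100.0 * total.loc[0, "n_matched"] / n_avail_total)
               if n_avail_total else None)
    pct_noid = (round(100.0 * total.loc[0, "n_no_identifier"] / n_avail_total, 1)
                if n_avail_total else None)

    pathway = None
    if pathway_counts is None and "n_cad_date" in t.columns:
        pathway_counts = {"n_cad_date": int(total.loc[0, "n_cad_date"]),
                          "n_callsign": int(total.loc[0, "n_callsign"])}
    if pathway_counts is not None and n_avail_total:
        # Shares of *total* records, mirroring the study-report convention.
        pathway = {
            "n_cad_date": int(pathway_counts["n_cad_date"]),
            "n_callsign": int(pathway_counts["n_callsign"]),
            "share_cad_pct": round(100.0 * pathway_counts["n_cad_date"]
                                   / n_avail_total, 1),
            "share_callsign_pct": round(100.0 * pathway_counts["n_callsign"]
                                        / n_avail_total, 1),
        }
    return MatchReport(table=t, overall_match_rate_pct=overall,
                       pct_no_identifier=pct_noid, pathway=pathway)


def compute_match_report(data: pd.DataFrame,
                         pathway_counts: Optional[Mapping[str, int]] = None
                         ) -> MatchReport:
    """Build the per-trust match report.

    Accepts either per-row link results (columns ``trust`` and ``method``,
    one row per ED record) or a pre-aggregated counts table (columns
    ``trust``, ``n_available``, ``n_no_identifier``, ``n_matched``).
    """
    if "method" in data.columns:
        if "trust" not in data.columns:
            raise ValueError("per-row results need a 'trust' column")
        grouped = data.groupby("trust", sort=True)
        counts = pd.DataFrame({
            "trust": [t for t, _ in grouped],
            "n_available": grouped.size().to_numpy(),
            "n_no_identifier": grouped["method"].apply(
                lambda m: int((m == "no_identifier").sum())).to_numpy(),
            "n_matched": grouped["method"].apply(
                lambda m: int(m.isin(_MATCH_METHODS).sum())).to_numpy(),
            "n_cad_date": grouped["method"].apply(
                lambda m: int((m == "cad_date").sum())).to_numpy(),
            "n_callsign": grouped["method"].apply(
                lambda m: int((m == "callsign_datetime").sum())).to_numpy(),
        })
    else:
        required = {"trust", "n_available", "n_no_identifier", "n_matched"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"counts table missing columns: {sorted(missing)}")
        counts = data
    return _report_from_counts(counts, pathway_counts)


@dataclass
class TrendReport:
    flagged_values: list[tuple[str, int, int]]  # (value, count, threshold)
    hour_histogram_unmatched: list[int]
    hour_histogram_matched: Optional[list[int]]
    age_summary: pd.DataFrame  # bins x {unmatched, matched}

    def to_dict(self) -> dict:
        return {
            "flagged_values": [list(f) for f in self.flagged_values],
            "hour_histogram_unmatched": self.hour_histogram_unmatched,
            "hour_histogram_matched": self.hour_histogram_matched,
            "age_summary": self.age_summary.to_dict(),
        }


def _hour_hist(frame: pd.DataFrame) -> list[int]:
    hours = pd.to_datetime(frame["ed_arrival_datetime"]).dt.hour.dropna()
    return [int((hours == h).sum()) for h in range(24)]


def _age_counts(frame: pd.DataFrame) -> pd.Series:
    ages = pd.to_numeric(frame.get("age"), errors="coerce").dropna()
    cats = pd.cut(ages, bins=AGE_BIN_EDGES, labels=AGE_BIN_LABELS, right=False)
    return cats.value_counts().reindex(AGE_BIN_LABELS, fill_value=0)


def analyse_unmatched(unmatched: pd.DataFrame, flag_threshold: int = 20,
                      matched: Optional[pd.DataFrame] = None) -> TrendReport:
    """Look for trends among rows the matcher could not link.

    Any exact identifier value (parsed CAD or call sign) occurring at least
    ``flag_threshold`` times among the unmatched rows is flagged with its
    count — the signature of a field being repurposed (a genuine identifier
    should not recur across unrelated attendances). Hour-of-day and coarse
    age distributions are reported for unmatched (and, when provided,
    matched) rows.
    """
    counter: Counter[str] = Counter()
    if not unmatched.empty:
        if "parsed_cad" in unmatched.columns:
            counter.update(str(int(v)) for v in unmatched["parsed_cad"].dropna())
        if "parsed_call_sign" in unmatched.columns:
            counter.update(str(v) for v in unmatched["parsed_call_sign"].dropna())
    flagged = sorted(((v, n, flag_threshold) for v, n in counter.items()
                      if n >= flag_threshold), key=lambda f: (-f[1], f[0]))

    if unmatched.empty:
        age = pd.DataFrame({"unmatched": pd.Series(0, index=AGE_BIN_LABELS)})
        return TrendReport([], [0] * 24, None if matched is None
                           else _hour_hist(matched), age)

    age = pd.DataFrame({"unmatched": _age_counts(unmatched)})
    hist_m = None
    if matched is not None:
        age["matched"] = _age_counts(matched)
        hist_m = _hour_hist(matched)
    return TrendReport(flagged, _hour_hist(unmatched), hist_m, age)


@dataclass(frozen=True)
class TruthEvaluation:
    """Confusion counts of the linkage against synthetic ground truth."""

    true_links: int
    false_links: int
    false_non_links: int
    true_non_links: int
    precision: Optional[float]
    recall: Optional[float]

    @property
    def n_rows(self) -> int:
        return (self.true_links + self.false_links + self.false_non_links
                + self.true_non_links)

    def to_dict(self) -> dict:
        return {
            "true_links": self.true_links, "false_links": self.false_links,
            "false_non_links": self.false_non_links,
            "true_non_links": self.true_non_links,
            "precision": self.precision, "recall": self.recall,
        }


def evaluate_against_truth(results: pd.DataFrame,
                           truth: Mapping[str, str]) -> TruthEvaluation:
    """Score link results against the generator's ground truth.

    Each result row is exactly one of: true link (linked to its truth
    partner), false link (linked to anything else, or linked despite having
    no truth pair), false non-link (unlinked despite a truth pair), true
    non-link (unlinked, no truth pair). Truth pairs must refer to rows
    present in the results.
    """
    ids = set(results["ed_row_id"])
    missing = [k for k in truth if k not in ids]
    if missing:
        raise ConsistencyError(
            f"{len(missing)} ground-truth row(s) absent from results "
            f"(first: {missing[0]!r}); results and truth must refer to the "
            "same extract")
    tl = fl = fnl = tnl = 0
    for r in results.itertuples(index=False):
        expected = truth.get(r.ed_row_id)
        linked = not pd.isna(r.amb_id)
        if linked:
            if expected is not None and r.amb_id == expected:
                tl += 1
            else:
                fl += 1
        else:
            if expected is not None:
                fnl += 1
            else:
                tnl += 1
    precision = tl / (tl + fl) if (tl + fl) else None
    recall = tl / (tl + fnl) if (tl + fnl) else None
    return TruthEvaluation(tl, fl, fnl, tnl, precision, recall)
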