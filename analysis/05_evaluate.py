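#!/usr/bin/env python
"""Step 5 — report match rates, unmatched trends and ground-truth accuracy.

Produces under ``results/report/``:

    match_report.csv / .txt   per-trust available / no-identifier / matched
                              counts with rounded match rates and pathway shares
    trend_report.json         over-represented identifier values and 24-hour /
                              age profiles of unmatched vs matched rows
    truth_evaluation.csv      precision and recall per trust against the
                              simulation's ground truth
"""

import json

import pandas as pd

from _study import CLEAN_DIR, DATA_DIR, LINK_DIR, REPORT_DIR, TRUSTS

from edlink.evaluation import (analyse_unmatched, compute_match_report,
                               evaluate_against_truth)
from edlink.synth import read_truth


def load(trust: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    cleaned = pd.read_csv(CLEAN_DIR / f"{trust}.csv",
                          dtype={"parsed_cad": "Int64", "age": "Int64"})
    cleaned["ed_arrival_datetime"] = pd.to_datetime(
        cleaned["ed_arrival_datetime"])
    results = pd.read_csv(LINK_DIR / f"{trust}.csv")
    return cleaned, results


def main() -> None:
    REPORT_DIR.mkdir(parents=True, exist_ok=True)

    all_results, trend_inputs, truth_rows = [], {"un": [], "m": []}, []
    for trust in TRUSTS:
        cleaned, results = load(trust)
        all_results.append(results)

        merged = cleaned.merge(results[["ed_row_id", "method"]], on="ed_row_id")
        is_match = merged["method"].isin(("cad_date", "callsign_datetime"))
        trend_inputs["un"].append(merged[~is_match])
        trend_inputs["m"].append(merged[is_match])

        ev = evaluate_against_truth(
            results, read_truth(DATA_DIR / "truth" / f"{trust}.csv"))
        truth_rows.append({
            "trust": trust, "n_rows": ev.n_rows,
            "true_links": ev.true_links, "false_links": ev.false_links,
            "false_non_links": ev.false_non_links,
            "true_non_links": ev.true_non_links,
            "precision": ev.precision, "recall": ev.recall,
        })

    report = compute_match_report(pd.concat(all_results, ignore_index=True))
    report.table.to_csv(REPORT_DIR / "match_report.csv", index=False)
    (REPORT_DIR / "match_report.txt").write_text(report.to_text() + "\n")
    print(report.to_text())

    trend = analyse_unmatched(
        pd.concat(trend_inputs["un"], ignore_index=True), flag_threshold=20,
        matched=pd.concat(trend_inputs["m"], ignore_index=True))
    payload = {
        "flagged_values": [{"value": v, "count": n, "threshold": t}
                           for v, n, t in trend.flagged_values],
        "hour_histogram_unmatched": trend.hour_histogram_unmatched,
        "hour_histogram_matched": trend.hour_histogram_matched,
        "age_summary": {col: {bin_: int(n) for bin_, n
                              in trend.age_summary[col].items()}
                        for col in trend.age_summary.columns},
    }
    (REPORT_DIR / "trend_report.json").write_text(
        json.dumps(payload, indent=2) + "\n")
    print(f"\nover-represented unmatched identifier values: "
          f"{len(trend.flagged_values)}")

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(REPORT_DIR / "truth_evaluation.csv", index=False)
    print("\nground-truth accuracy per trust:")
    print(truth[["trust", "precision", "recall"]].to_string(index=False))


if __name__ == "__main__":
    main()
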