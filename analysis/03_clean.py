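#!/usr/bin/env python
"""Step 3 — clean each extract: parse identifiers, drop duplicate rows.

Reads the transferred extracts back through the format layer, extracts the
CAD number (1–4 digit token under 7000) and the registry-verified call sign
from however each trust recorded them, and removes exact duplicate rows.
Cleaned tables go to ``results/clean/<Trust>.csv`` with the parsed columns
appended; a one-line parse summary per trust goes to
``results/clean/cleaning_summary.csv``.
"""

import pandas as pd

from _study import CLEAN_DIR, DATA_DIR, TRUSTS

from edlink.cleaning import CallSignRegistry, clean_extract
from edlink.extract_io import FormatSpec, read_extract


def main() -> None:
    CLEAN_DIR.mkdir(parents=True, exist_ok=True)
    spec = FormatSpec()
    registry = CallSignRegistry.from_csv(DATA_DIR / "callsign_registry.csv")
    summaries = []
    for trust in TRUSTS:
        rows = read_extract(DATA_DIR / "extracts" / f"{trust}.csv", spec)
        cleaned, report = clean_extract(rows, registry)
        cleaned.to_csv(CLEAN_DIR / f"{trust}.csv", index=False)
        counts = cleaned["parse_status"].value_counts()
        summaries.append({
            "trust": trust,
            "n_rows": len(rows),
            "n_duplicates_removed": report.n_duplicates_removed,
            "n_cleaned": len(cleaned),
            **{f"n_{status}": int(counts.get(status, 0))
               for status in ("both", "cad_only", "callsign_only", "none")},
        })
        print(f"  {trust:8s} {len(rows):6,} rows -> {len(cleaned):6,} after "
              f"de-duplication; no identifier on "
              f"{int(counts.get('none', 0)):,}")
    pd.DataFrame(summaries).to_csv(CLEAN_DIR / "cleaning_summary.csv",
                                   index=False)


if __name__ == "__main__":
    main()
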