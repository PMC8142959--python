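#!/usr/bin/env python
"""Step 4 — deterministic n-1 linkage of cleaned extracts to the ambulance data.

CAD number + incident date first; where that fails, call sign + date with
arrival-time corroboration (nearest crew arrival within the tolerance, same
site). A row links if either identifier succeeds. Per-trust link results go
to ``results/links/<Trust>.csv``.
"""

import pandas as pd

from _study import CLEAN_DIR, DATA_DIR, LINK_DIR, TRUSTS

from edlink.linkage import LinkConfig, link_all
from edlink.synth import read_ambulance_dataset


def read_cleaned(trust: str) -> pd.DataFrame:
    df = pd.read_csv(CLEAN_DIR / f"{trust}.csv",
                     dtype={"parsed_cad": "Int64"}, keep_default_na=True)
    df["ed_arrival_datetime"] = pd.to_datetime(df["ed_arrival_datetime"])
    df["trust"] = trust
    return df


def main() -> None:
    LINK_DIR.mkdir(parents=True, exist_ok=True)
    ambulance = read_ambulance_dataset(DATA_DIR / "ambulance.csv")
    cfg = LinkConfig()
    for trust in TRUSTS:
        cleaned = read_cleaned(trust)
        results, tallies = link_all(cleaned, ambulance, cfg)
        results.to_csv(LINK_DIR / f"{trust}.csv", index=False)
        n_matched = int(results["method"].isin(
            ("cad_date", "callsign_datetime")).sum())
        print(f"  {trust:8s} {n_matched:6,} / {len(results):6,} linked "
              f"({tallies['n_quarantined_cad_keys']} reissued CAD keys "
              f"quarantined)")


if __name__ == "__main__":
    main()
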