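"""Naive all-pairs linkage oracle, independent of the indexed implementation.

Applies the same matching rules by brute-force scans over plain Python
tuples: no AmbulanceIndex, no dictionaries keyed on (identifier, date).
Used to cross-check ``edlink.linkage.link_all`` on small instances.
"""

from collections import Counter
from datetime import timedelta

import pandas as pd

from edlink.linkage import LinkConfig


def _minutes(a, b):
    return abs((a - b).total_seconds()) / 60.0


def naive_link(rows: pd.DataFrame, ambulance: pd.DataFrame,
               cfg: LinkConfig = LinkConfig()) -> pd.DataFrame:
    amb = [(r.amb_id, int(r.cad_number),
            pd.Timestamp(r.incident_date).date(), str(r.call_sign),
            pd.Timestamp(r.ed_arrival), str(r.destination_site))
           for r in ambulance.itertuples(index=False)]
    # (cad, date) keys occurring more than once are unusable for CAD matching
    key_counts = Counter((cad, d) for _, cad, d, _, _, _ in amb)

    out = []
    for row in rows.itertuples(index=False):
        rid = row.ed_row_id
        if row.parse_status == "none":
            out.append((rid, None, "no_identifier"))
            continue
        arrival = pd.Timestamp(row.ed_arrival_datetime)
        d = arrival.date()
        site = None if pd.isna(row.hospital_site) else str(row.hospital_site)
        dates = [d] + ([d - timedelta(days=1)] if cfg.allow_consecutive_dates
                       else [])

        linked = None
        if not pd.isna(row.parsed_cad):
            cad = int(row.parsed_cad)
            cands = [a for a in amb
                     if a[1] == cad and a[2] in dates
                     and key_counts[(a[1], a[2])] == 1]
            if cands:
                if len(cands) == 1:
                    chosen = cands[0]
                elif cfg.cad_tie_break == "exact_date":
                    chosen = next(a for a in cands if a[2] == d)
                else:
                    exact = next(a for a in cands if a[2] == d)
                    prev = next(a for a in cands if a[2] != d)
                    chosen = (exact if _minutes(exact[4], arrival)
                              <= _minutes(prev[4], arrival) else prev)
                if (site is not None and chosen[5] != site
                        and cfg.cmp_site_cad == "require"):
                    chosen = None
                if chosen is not None:
                    linked = (rid, chosen[0], "cad_date")

        if linked is None and not pd.isna(row.parsed_call_sign):
            cs = str(row.parsed_call_sign)
            cands = [a for a in amb if a[3] == cs and a[2] in dates]
            if cfg.require_site_agreement_callsign and site is not None:
                cands = [a for a in cands if a[5] == site]
            scored = [(a, _minutes(a[4], arrival)) for a in cands]
            scored = [(a, dist) for a, dist in scored
                      if dist <= cfg.time_tolerance_minutes]
            if scored:
                best = min(dist for _, dist in scored)
                winners = {a[0] for a, dist in scored if dist == best}
                if len(winners) == 1:
                    linked = (rid, winners.pop(), "callsign_datetime")

        out.append(linked if linked else (rid, None, "unmatched"))
    return pd.DataFrame(out, columns=["ed_row_id", "amb_id", "method"])
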