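"""Deterministic matcher: pathway rules, precedence, index quarantine,
brute-force oracle equivalence, and tolerance monotonicity."""

import dataclasses
from datetime import date

import numpy as np
import pandas as pd
import pytest

from edlink.linkage import (LinkConfig, _Row, build_index, link_all,
                            match_cad_date, match_callsign)
from edlink.pipeline import run_trust
from edlink.synth import (SimulationConfig, generate_ambulance_dataset,
                          generate_ed_extract)
from conftest import clean_profile
from oracle_linkage import naive_link


def amb_frame(rows):
    """rows: (amb_id, cad, incident_date, call_sign, ed_arrival, site)"""
    df = pd.DataFrame(rows, columns=["amb_id", "cad_number", "incident_date",
                                     "call_sign", "ed_arrival",
                                     "destination_site"])
    df["incident_date"] = pd.to_datetime(df["incident_date"]).dt.date
    df["ed_arrival"] = pd.to_datetime(df["ed_arrival"])
    return df


def ed_row(rid="e1", arrival="2014-05-02 10:30", site="S1", cad=None,
           call_sign=None):
    status = {(True, True): "both", (True, False): "cad_only",
              (False, True): "callsign_only", (False, False): "none"}[
                  (cad is not None, call_sign is not None)]
    return _Row(rid, pd.Timestamp(arrival), site, cad, call_sign, status)


AMB = amb_frame([
    ("a1", 123, "2014-05-02", "Q001", "2014-05-02 10:25", "S1"),
    ("a2", 123, "2014-05-03", "Q002", "2014-05-03 11:00", "S1"),
    ("a3", 7, "2014-05-02", "Q003", "2014-05-02 16:40", "S1"),
    ("a4", 8, "2014-05-02", "Q003", "2014-05-02 10:25", "S1"),
])


class TestBuildIndex:
    def test_distinct_keys_all_indexed(self):
        idx = build_index(AMB)
        assert len(idx.by_cad_date) == 4 and not idx.quarantined

    def test_duplicate_cad_date_quarantined_not_overwritten(self):
        dup = amb_frame([
            ("a1", 5, "2014-05-02", "Q001", "2014-05-02 10:00", "S1"),
            ("a2", 5, "2014-05-02", "Q002", "2014-05-02 11:00", "S1"),
            ("a3", 6, "2014-05-02", "Q003", "2014-05-02 12:00", "S1"),
        ])
        idx = build_index(dup)
        assert len(idx.quarantined) == 2
        assert (5, date(2014, 5, 2)) not in idx.by_cad_date
        assert len(idx.by_callsign_date) == 3  # still callsign-reachable

    def test_empty_input(self):
        idx = build_index(AMB.iloc[:0])
        assert len(idx.by_cad_date) == 0 and len(idx.by_callsign_date) == 0


class TestMatchCadDate:
    def test_direct_date_match(self):
        res = match_cad_date(ed_row(cad=123), build_index(AMB))
        assert res.amb_id == "a1" and res.method == "cad_date"
        assert res.flags == frozenset()

    def test_consecutive_date_for_midnight_crossing(self):
        amb = amb_frame([("a1", 200, "2014-05-02", "Q001",
                          "2014-05-03 00:15", "S1")])
        res = match_cad_date(ed_row(arrival="2014-05-03 00:20", cad=200),
                             build_index(amb))
        assert res.amb_id == "a1" and "consecutive_date_used" in res.flags

    def test_wrong_date_no_result(self):
        assert match_cad_date(ed_row(arrival="2014-05-05 10:00", cad=123),
                              build_index(AMB)) is None

    def test_dual_date_candidates_resolved_by_nearest_arrival(self):
        # a CAD reissued the next day: the crosser's row must reach its own
        # record, not the reissue
        amb = amb_frame([
            ("cross", 300, "2014-05-02", "Q001", "2014-05-03 00:20", "S1"),
            ("reissue", 300, "2014-05-03", "Q002", "2014-05-03 14:00", "S1"),
        ])
        res = match_cad_date(ed_row(arrival="2014-05-03 00:22", cad=300),
                             build_index(amb))
        assert res.amb_id == "cross" and "consecutive_date_used" in res.flags
        literal = match_cad_date(
            ed_row(arrival="2014-05-03 00:22", cad=300), build_index(amb),
            LinkConfig(cad_tie_break="exact_date"))
        assert literal.amb_id == "reissue"

    def test_site_disagreement_flagged_or_rejected(self):
        row = ed_row(cad=123, site="S9")
        res = match_cad_date(row, build_index(AMB))
        assert res.amb_id == "a1" and "site_disagreement" in res.flags
        assert match_cad_date(row, build_index(AMB),
                              LinkConfig(cmp_site_cad="require")) is None


class TestMatchCallsign:
    def test_single_candidate_within_window(self):
        res = match_callsign(ed_row(cad=None, call_sign="Q001"),
                             build_index(AMB))
        assert res.amb_id == "a1" and res.method == "callsign_datetime"

    def test_nearest_of_two_shift_arrivals(self):
        # same crew at 10:25 and 16:40; ED arrival 16:45 -> the 16:40 record
        res = match_callsign(ed_row(arrival="2014-05-02 16:45", cad=None,
                                    call_sign="Q003"), build_index(AMB))
        assert res.amb_id == "a3"

    def test_window_exceeded_no_result(self):
        res = match_callsign(ed_row(arrival="2014-05-02 12:35", cad=None,
                                    call_sign="Q001"), build_index(AMB))
        assert res is None  # 130 min away, tolerance 120

    def test_equidistant_candidates_are_ambiguous(self):
        amb = amb_frame([
            ("a1", 1, "2014-05-02", "Q009", "2014-05-02 10:00", "S1"),
            ("a2", 2, "2014-05-02", "Q009", "2014-05-02 11:00", "S1"),
        ])
        res = match_callsign(ed_row(arrival="2014-05-02 10:30", cad=None,
                                    call_sign="Q009"), build_index(amb))
        assert res.amb_id is None and "ambiguous_candidates" in res.flags

    def test_site_agreement_required_by_default(self):
        row = ed_row(cad=None, call_sign="Q001", site="S9")
        assert match_callsign(row, build_index(AMB)) is None
        res = match_callsign(row, build_index(AMB),
                             LinkConfig(require_site_agreement_callsign=False))
        assert res.amb_id == "a1"


def cleaned_frame(rows):
    """rows: (rid, arrival, site, cad, call_sign)"""
    df = pd.DataFrame(rows, columns=["ed_row_id", "ed_arrival_datetime",
                                     "hospital_site", "parsed_cad",
                                     "parsed_call_sign"])
    df["ed_arrival_datetime"] = pd.to_datetime(df["ed_arrival_datetime"])
    df["parsed_cad"] = df["parsed_cad"].astype("Int64")
    df["parse_status"] = [
        "none" if pd.isna(c) and pd.isna(s) else
        "both" if not pd.isna(c) and not pd.isna(s) else
        "cad_only" if not pd.isna(c) else "callsign_only"
        for c, s in zip(df["parsed_cad"], df["parsed_call_sign"])]
    return df


class TestLinkAll:
    def test_cad_pathway_runs_first(self):
        rows = cleaned_frame([("e1", "2014-05-02 10:30", "S1", 123, "Q001")])
        res, _ = link_all(rows, AMB)
        assert res.loc[0, "method"] == "cad_date"

    def test_callsign_used_when_cad_unresolvable(self):
        rows = cleaned_frame([("e1", "2014-05-02 10:30", "S1", 999, "Q001")])
        res, _ = link_all(rows, AMB)
        assert res.loc[0, "method"] == "callsign_datetime"
        assert res.loc[0, "amb_id"] == "a1"

    def test_sentinel_only_rows_flagged_no_identifier(self):
        rows = cleaned_frame([("e1", "2014-05-02 10:30", "S1", None, None)])
        res, _ = link_all(rows, AMB)
        assert res.loc[0, "method"] == "no_identifier"
        assert pd.isna(res.loc[0, "amb_id"])

    def test_exhaustive_partition(self, ambulance, base_config, registry):
        profile = clean_profile(base_config, null_identifier_rate=0.2,
                                trust_name="Part")
        run = run_trust(ambulance, profile, base_config, registry)
        assert len(run.results) == len(run.cleaned)
        counts = run.results["method"].value_counts()
        assert counts.sum() == len(run.results)
        assert set(counts.index) <= {"cad_date", "callsign_datetime",
                                     "unmatched", "no_identifier"}

    def test_many_to_one_links_tallied(self):
        rows = cleaned_frame([
            ("e1", "2014-05-02 10:30", "S1", 123, None),
            ("e2", "2014-05-02 10:31", "S1", 123, None),
        ])
        res, tallies = link_all(rows, AMB)
        assert (res["amb_id"] == "a1").all()
        assert tallies["multi_link_amb_ids"] == ["a1"]


class TestOracleEquivalence:
    """Indexed link_all equals a naive all-pairs scan on small instances."""

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_naive_all_pairs(self, trial):
        rng = np.random.default_rng(1000 + trial)
        cfg = SimulationConfig(
            n_incidents=int(rng.integers(80, 400)),
            date_range=(date(2014, 6, 1),
                        date(2014, 6, int(rng.integers(2, 8)))),
            n_sites=int(rng.integers(1, 4)),
            midnight_crossing_fraction=float(rng.uniform(0, 0.2)),
            multi_patient_shift_rate=float(rng.uniform(0, 0.3)),
            timestamp_jitter_minutes=float(rng.uniform(0, 30)),
            seed=int(rng.integers(2**31)))
        mode = ["separate_fields", "combined_freetext",
                "cad_only"][trial % 3]
        profile = clean_profile(
            cfg, mode=mode,
            null_identifier_rate=float(rng.uniform(0, 0.4)),
            duplicate_rate=float(rng.uniform(0, 0.1)),
            misuse_sentinel="136" if trial % 2 else None,
            misuse_rate=0.05 if trial % 2 else 0.0)
        link_cfg = LinkConfig(
            time_tolerance_minutes=float(rng.uniform(10, 240)),
            allow_consecutive_dates=bool(rng.integers(2)),
            require_site_agreement_callsign=bool(rng.integers(2)),
            cmp_site_cad=["ignore", "flag", "require"][trial % 3],
            cad_tie_break=["nearest_arrival", "exact_date"][trial % 2])
        run = run_trust(generate_ambulance_dataset(cfg), profile, cfg,
                        link_cfg=link_cfg)
        naive = naive_link(run.cleaned, generate_ambulance_dataset(cfg),
                           link_cfg)
        got = run.results[["ed_row_id", "amb_id", "method"]].fillna("-")
        want = naive.fillna("-")
        pd.testing.assert_frame_equal(got.reset_index(drop=True),
                                      want.reset_index(drop=True))


class TestMonotonicity:
    def test_callsign_matches_nondecreasing_in_tolerance(self, ambulance,
                                                         base_config,
                                                         registry):
        profile = clean_profile(base_config, trust_name="Mono")
        run = run_trust(ambulance, profile, base_config, registry)
        # strip CADs so every link must come from the call-sign pathway
        rows = run.cleaned.copy()
        rows["parsed_cad"] = pd.NA
        rows["parse_status"] = "callsign_only"
        previous = -1
        for tol in (5, 15, 30, 60, 120, 240, 480):
            res, _ = link_all(rows, ambulance,
                              LinkConfig(time_tolerance_minutes=tol))
            n = int((res["method"] == "callsign_datetime").sum())
            assert n >= previous
            previous = n
        assert previous > 0


class TestPrecedenceSafety:
    def test_callsign_only_never_more_false_links_than_cad(self, ambulance,
                                                           base_config,
                                                           registry):
        """The CAD pathway is the riskier one (a repurposed CAD value can
        collide with a genuine incident number); removing CADs must not
        increase ground-truth contradictions on the same rows."""
        profile = clean_profile(base_config, mode="separate_fields",
                                misuse_sentinel="42", misuse_rate=0.05,
                                trust_name="Risky")
        run = run_trust(ambulance, profile, base_config, registry)
        fl_full = run.truth_eval.false_links
        rows = run.cleaned.copy()
        rows.loc[:, "parsed_cad"] = pd.NA
        rows["parse_status"] = np.where(rows["parsed_call_sign"].isna(),
                                        "none", "callsign_only")
        res_cs, _ = link_all(rows, ambulance)
        from edlink.evaluation import evaluate_against_truth
        fl_cs = evaluate_against_truth(res_cs, run.bundle.truth).false_links
        assert fl_cs <= fl_full
        assert fl_full > 0  # the misused CAD value really does collide
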