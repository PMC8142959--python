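"""End-to-end orchestration helpers: simulate -> clean -> link -> evaluate.

These are the study drivers the analysis scripts and the acceptance checks
share; each step simply calls the corresponding module.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Optional

import pandas as pd

from .cleaning import CallSignRegistry, CleaningReport, clean_extract
from .errors import ConfigurationError
from .evaluation import TruthEvaluation, evaluate_against_truth
from .linkage import LinkConfig, link_all
from .synth import (ExtractBundle, SimulationConfig, TrustProfile,
                    generate_ambulance_dataset, generate_callsign_registry,
                    generate_ed_extract, inject_sentinel_misuse)


@dataclass
class TrustRun:
    """Everything one trust's pass through the pipeline produced."""

    profile: TrustProfile
    bundle: ExtractBundle
    cleaned: pd.DataFrame
    cleaning_report: CleaningReport
    results: pd.DataFrame
    tallies: dict
    truth_eval: TruthEvaluation


def default_registry(config: SimulationConfig) -> CallSignRegistry:
    return CallSignRegistry.from_iterable(
        generate_callsign_registry(config.registry_size))


def run_trust(ambulance: pd.DataFrame, profile: TrustProfile,
              config: SimulationConfig,
              registry: Optional[CallSignRegistry] = None,
              link_cfg: LinkConfig = LinkConfig(),
              bundle: Optional[ExtractBundle] = None) -> TrustRun:
    """Generate (or take) one trust's extract and push it through the pipeline."""
    registry = registry or default_registry(config)
    if bundle is None:
        bundle = generate_ed_extract(ambulance, profile, config)
    cleaned, creport = clean_extract(bundle.rows, registry)
    cleaned = cleaned.copy()
    cleaned["trust"] = profile.trust_name
    results, tallies = link_all(cleaned, ambulance, link_cfg)
    ev = evaluate_against_truth(results, bundle.truth)
    return TrustRun(profile=profile, bundle=bundle, cleaned=cleaned,
                    cleaning_report=creport, results=results, tallies=tallies,
                    truth_eval=ev)


def misuse_study(n_misuse: int = 60, seed: int = 0,
                 sentinel: str = "136") -> TrustRun:
    """A CAD-only trust whose CAD field was repurposed for ``n_misuse`` rows.

    Daily incident volume is kept well below the sentinel's numeric value so
    no genuine CAD equals it and the affected rows cannot link — the
    over-representation then surfaces in the unmatched-trend analysis.
    """
    config = SimulationConfig(
        n_incidents=2000, date_range=(date(2015, 3, 1), date(2015, 3, 28)),
        n_sites=2, timestamp_jitter_minutes=5.0, seed=seed)
    profile = TrustProfile(
        trust_name="Foxtrot", site_ids=config.site_labels,
        available_variables=frozenset(
            {"hospital_site", "ed_arrival_datetime", "age", "gender",
             "diagnosis", "outcome", "departure_datetime", "cad_number"}),
        identifier_mode="cad_only", null_identifier_rate=0.2)
    ambulance = generate_ambulance_dataset(config)
    if int(ambulance["cad_number"].max()) >= int(sentinel):
        raise ConfigurationError(
            "daily volume reached the sentinel value; misuse rows could link")
    bundle = generate_ed_extract(ambulance, profile, config)
    bundle = inject_sentinel_misuse(bundle, n=n_misuse, sentinel=sentinel,
                                    seed=seed + 1)
    return run_trust(ambulance, profile, config, bundle=bundle)


def unmatched_and_matched(run: TrustRun) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a run's cleaned rows by link outcome, for trend analysis."""
    merged = run.cleaned.merge(run.results[["ed_row_id", "method"]],
                               on="ed_row_id")
    is_match = merged["method"].isin(("cad_date", "callsign_datetime"))
    return merged[~is_match], merged[is_match]
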