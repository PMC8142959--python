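from datetime import date

import pytest

from edlink.cleaning import CallSignRegistry
from edlink.extract_io import ED_VARIABLES
from edlink.synth import (SimulationConfig, TrustProfile,
                          generate_ambulance_dataset,
                          generate_callsign_registry)


@pytest.fixture(scope="session")
def base_config() -> SimulationConfig:
    """A small, fully-featured service period shared by read-only tests."""
    return SimulationConfig(
        n_incidents=1500, date_range=(date(2014, 5, 1), date(2014, 5, 14)),
        n_sites=4, midnight_crossing_fraction=0.02,
        multi_patient_shift_rate=0.08, timestamp_jitter_minutes=5.0, seed=11)


@pytest.fixture(scope="session")
def ambulance(base_config):
    return generate_ambulance_dataset(base_config)


@pytest.fixture(scope="session")
def registry(base_config) -> CallSignRegistry:
    return CallSignRegistry.from_iterable(
        generate_callsign_registry(base_config.registry_size))


def clean_profile(config, mode="separate_fields", **overrides):
    """A corruption-free trust covering every site of ``config``."""
    kwargs = dict(
        trust_name=overrides.pop("trust_name", "Testshire"),
        site_ids=config.site_labels,
        available_variables=frozenset(ED_VARIABLES),
        identifier_mode=mode,
        null_identifier_rate=0.0,
    )
    if mode == "combined_freetext" and "format_mix" not in overrides:
        kwargs["format_mix"] = {"label_comma": 0.4, "comma_label": 0.3,
                                "slash": 0.3}
    kwargs.update(overrides)
    return TrustProfile(**kwargs)
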