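#!/usr/bin/env python
"""Step 1 — simulate the ground-truthed study data.

Generates one ambulance service's conveyance records for the study window,
the crew call-sign registry, and one ED extract per acute trust under that
trust's preset recording behaviour. Everything lands under ``results/data/``:

    ambulance.csv            the service-side dataset (one row per incident)
    callsign_registry.csv    valid call signs, for registry-verified parsing
    extracts/<Trust>.csv     the extract each trust would transfer
    truth/<Trust>.csv        ed_row_id -> amb_id ground truth for scoring
"""

from _study import CONFIG, DATA_DIR, TRUSTS

from edlink.extract_io import FormatSpec, write_extract
from edlink.synth import (generate_ambulance_dataset, generate_callsign_registry,
                          generate_ed_extract, trust_presets,
                          write_ambulance_dataset, write_registry, write_truth)


def main() -> None:
    (DATA_DIR / "extracts").mkdir(parents=True, exist_ok=True)
    (DATA_DIR / "truth").mkdir(exist_ok=True)

    ambulance = generate_ambulance_dataset(CONFIG)
    write_ambulance_dataset(ambulance, DATA_DIR / "ambulance.csv")
    registry = generate_callsign_registry(CONFIG.registry_size)
    write_registry(registry, DATA_DIR / "callsign_registry.csv")
    print(f"ambulance dataset: {len(ambulance):,} conveyed incidents, "
          f"{CONFIG.n_sites} sites, {len(registry)} registered call signs")

    spec = FormatSpec()
    presets = trust_presets(CONFIG.site_labels)
    for trust in TRUSTS:
        profile = presets[trust]
        bundle = generate_ed_extract(ambulance, profile, CONFIG)
        write_extract(bundle.rows, spec, DATA_DIR / "extracts" / f"{trust}.csv")
        write_truth(bundle.truth, DATA_DIR / "truth" / f"{trust}.csv")
        print(f"  {trust:8s} {len(bundle.rows):6,} rows "
              f"({profile.identifier_mode}, "
              f"null rate {profile.null_identifier_rate:.3f})")


if __name__ == "__main__":
    main()
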