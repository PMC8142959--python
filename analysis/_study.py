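"""Shared study conditions for the numbered analysis drivers.

One metropolitan ambulance service, 13 EDs across six acute trusts, four
months of conveyances at a scale that keeps every driver comfortably
desk-runnable. The per-trust recording behaviours come from the preset
profiles (Alpha/Charlie separate identifier fields, Bravo/Delta/Echo one
unformatted free-text field, Foxtrot CAD only).
"""

from datetime import date
from pathlib import Path

from edlink.synth import SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "results" / "data"
VALIDATION_DIR = ROOT / "results" / "validation"
CLEAN_DIR = ROOT / "results" / "clean"
LINK_DIR = ROOT / "results" / "links"
REPORT_DIR = ROOT / "results" / "report"

CONFIG = SimulationConfig(
    n_incidents=30_000,
    date_range=(date(2014, 3, 1), date(2014, 6, 28)),
    n_sites=13,
    midnight_crossing_fraction=0.01,
    multi_patient_shift_rate=0.05,
    timestamp_jitter_minutes=5.0,
    seed=2014,
)

TRUSTS = ("Alpha", "Bravo", "Charlie", "Delta", "Echo", "Foxtrot")
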