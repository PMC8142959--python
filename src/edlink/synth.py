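"""Ground-truthed synthetic ambulance conveyances and per-trust ED extracts.

The generator emulates the recording environment of a UK metropolitan
ambulance service feeding multiple acute-trust EDs:

* CAD incident numbers are small integers assigned sequentially from 1 within
  each service day (the dispatch system resets at midnight) and capped below
  7000, so (CAD, incident date) is unique per day.
* Call signs identify a crew's vehicle shift — a letters-then-digits token
  (e.g. ``Q987``) drawn from a registry; one crew can convey several patients
  to the same ED in a shift, and a journey started before midnight can arrive
  after it.
* Each trust's extract reflects its own recording behaviour (:class:`TrustProfile`):
  which of the 18 requested variables it supplies, whether CAD and call sign
  arrive in separate fields, a single unformatted free-text field, or CAD
  only, plus missing identifiers, sentinel misuse ("136" for Mental Health
  Act cases), duplicate rows and clock jitter between the two systems.

Every ED row that originates from a conveyance is paired with its source
ambulance record in a :class:`GroundTruth` mapping, which is what lets the
evaluation module measure the precision/recall/false-non-link behaviour a
real de-identified study cannot.
"""

from __future__ import annotations

import string
import warnings
import zlib
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigurationError
from .extract_io import ED_VARIABLES

#: Largest CAD number the dispatch system will issue in one day.
MAX_CAD = 6999

AMB_COLUMNS = ("amb_id", "cad_number", "incident_date", "call_sign",
               "ed_arrival", "destination_site", "age", "gender")

#: The three free-text layouts commonly seen when CAD and call sign share one
#: unformatted field.
FREETEXT_LAYOUTS: dict[str, str] = {
    "label_comma": "CAD{cad}, {cs}",          # 'CAD123, Q987'
    "comma_label": "{cad}, Call sign {cs}",   # '123, Call sign Q987'
    "slash": "{cs}/{cad}",                    # 'Q987/123'
}

_ETHNICITIES = ("White", "Black", "Asian", "Mixed", "Other")
_DIAGNOSES = ("INJURY", "CARDIAC", "RESP", "GI", "NEURO", "OTHER")
_MH_DIAGNOSIS = "MENTAL_HEALTH"
_OUTCOMES = ("Admitted", "Discharged", "Transferred")
_LOCATIONS = ("Resus", "Majors", "Minors")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated service period."""

    n_incidents: int
    date_range: tuple[date, date]
    n_sites: int = 13
    conveyed_fraction: float = 0.70
    midnight_crossing_fraction: float = 0.01
    multi_patient_shift_rate: float = 0.05
    timestamp_jitter_minutes: float = 5.0
    site_swap_rate: float = 0.0
    registry_size: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.n_incidents <= 0:
            raise ConfigurationError("n_incidents must be positive")
        if self.n_sites <= 0:
            raise ConfigurationError("n_sites must be positive")
        start, end = self.date_range
        if start > end:
            raise ConfigurationError("date_range start must be <= end")
        for name in ("conveyed_fraction", "midnight_crossing_fraction",
                     "multi_patient_shift_rate", "site_swap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not 0.0 < self.conveyed_fraction:
            raise ConfigurationError("conveyed_fraction must be in (0, 1]")
        if self.timestamp_jitter_minutes < 0:
            raise ConfigurationError("timestamp_jitter_minutes must be >= 0")
        if self.registry_size <= 0:
            raise ConfigurationError("registry_size must be positive")

    @property
    def site_labels(self) -> tuple[str, ...]:
        return tuple(f"SITE{i:02d}" for i in range(1, self.n_sites + 1))

    @property
    def days(self) -> list[date]:
        start, end = self.date_range
        return [start + timedelta(days=i) for i in range((end - start).days + 1)]


@dataclass(frozen=True)
class TrustProfile:
    """Generative description of one acute trust's extract behaviour."""

    trust_name: str
    site_ids: tuple[str, ...]
    available_variables: frozenset[str]
    identifier_mode: str  # separate_fields | combined_freetext | cad_only
    null_identifier_rate: float = 0.0
    cad_null_rate: float = 0.0  # CAD lost in recording, call sign survives
    format_mix: Optional[Mapping[str, float]] = None
    misuse_sentinel: Optional[str] = None
    misuse_rate: float = 0.0
    duplicate_rate: float = 0.0
    extract_error_rate: float = 0.0

    def __post_init__(self):
        if self.identifier_mode not in ("separate_fields", "combined_freetext",
                                        "cad_only"):
            raise ConfigurationError(
                f"unknown identifier_mode {self.identifier_mode!r}")
        required = {"hospital_site", "ed_arrival_datetime"}
        if not required <= set(self.available_variables):
            raise ConfigurationError(
                "available_variables must include hospital site and ED "
                "arrival date/time")
        unknown = set(self.available_variables) - set(ED_VARIABLES)
        if unknown:
            raise ConfigurationError(f"unknown ED variables: {sorted(unknown)}")
        for name in ("null_identifier_rate", "cad_null_rate", "misuse_rate",
                     "duplicate_rate", "extract_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.identifier_mode == "combined_freetext":
            if not self.format_mix:
                raise ConfigurationError(
                    "combined_freetext mode requires a format_mix")
            unknown = set(self.format_mix) - set(FREETEXT_LAYOUTS)
            if unknown:
                raise ConfigurationError(f"unknown layouts: {sorted(unknown)}")
            if abs(sum(self.format_mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError("format_mix probabilities must sum to 1")
        if self.identifier_mode == "cad_only" and self.cad_null_rate > 0:
            raise ConfigurationError(
                "cad_null_rate needs a call sign to survive; cad_only "
                "extracts never carry one")


@dataclass(frozen=True)
class ExtractProvenance:
    """What the generator injected — the oracle for corruption-aware tests."""

    nulled_ids: tuple[str, ...] = ()
    cad_nulled_ids: tuple[str, ...] = ()  # CAD lost, call sign retained
    misuse_ids: tuple[str, ...] = ()
    duplicate_ids: tuple[str, ...] = ()
    layout_by_row: Mapping[str, str] = field(default_factory=dict)

    @property
    def n_duplicates_injected(self) -> int:
        return len(self.duplicate_ids)


@dataclass(frozen=True)
class ExtractBundle:
    """One trust's extract plus its ground truth and injection provenance."""

    rows: pd.DataFrame
    truth: dict[str, str]      # ed_row_id -> amb_id, original rows only
    provenance: ExtractProvenance


def generate_callsign_registry(size: int, start_letter: str = "Q") -> list[str]:
    """Deterministic vehicle-shift call-sign registry.

    Signs are a letter block plus zero-padded digits (``Q001``..``Q999``,
    continuing into the following letters when ``size`` exceeds 999).
    """
    letters = string.ascii_uppercase
    first = letters.index(start_letter)
    signs = []
    for i in range(size):
        block, num = divmod(i, 999)
        signs.append(f"{letters[(first + block) % 26]}{num + 1:03d}")
    return signs


def generate_ambulance_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Simulate one conveyed patient record per incident.

    CADs are assigned sequentially from 1 within each service day in call-time
    order; a fraction of journeys starts late enough that the patient reaches
    the ED after midnight (incident date + 1). Deterministic under the config
    seed: the same config always yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    days = config.days
    counts = rng.multinomial(config.n_incidents, [1 / len(days)] * len(days))
    if counts.max() > MAX_CAD:
        raise CapacityError(
            f"{counts.max()} incidents on one day exceeds the daily CAD "
            f"capacity of {MAX_CAD}")

    sites = config.site_labels
    records = []
    amb_counter = 0
    for day, k in zip(days, counts):
        if k == 0:
            continue
        n_cross = int(round(config.midnight_crossing_fraction * k))
        crossing = np.zeros(k, dtype=bool)
        crossing[rng.choice(k, size=n_cross, replace=False)] = True

        call_secs = np.empty(k)
        delays = np.empty(k)
        # Non-crossers: call any time up to 22:30, arrive 15-90 min later,
        # clamped inside the day. Crossers: call 22:45-23:50, arrive 10-50
        # min after midnight.
        call_secs[~crossing] = rng.uniform(0, 22.5 * 3600, size=(~crossing).sum())
        delays[~crossing] = rng.uniform(15 * 60, 90 * 60, size=(~crossing).sum())
        call_secs[crossing] = rng.uniform(22.75 * 3600, 23 * 3600 + 50 * 60,
                                          size=crossing.sum())
        delays[crossing] = (24 * 3600 - call_secs[crossing]
                            + rng.uniform(10 * 60, 50 * 60, size=crossing.sum()))

        order = np.argsort(call_secs, kind="stable")
        day_start = datetime.combine(day, time())
        fresh_signs = iter(generate_callsign_registry(config.registry_size))
        assigned: list[tuple[str, str]] = []  # (call_sign, site) this day
        for cad, idx in enumerate(order, start=1):
            call_dt = day_start + timedelta(seconds=float(call_secs[idx]))
            arrival = call_dt + timedelta(seconds=float(delays[idx]))
            if not crossing[idx] and arrival.date() != day:
                arrival = datetime.combine(day, time(23, 59, 59))
            arrival = arrival.replace(microsecond=0)
            if assigned and rng.random() < config.multi_patient_shift_rate:
                sign, site = assigned[int(rng.integers(len(assigned)))]
            else:
                try:
                    sign = next(fresh_signs)
                except StopIteration:
                    raise CapacityError(
                        "call-sign registry exhausted for one day; increase "
                        "registry_size") from None
                site = sites[int(rng.integers(len(sites)))]
            assigned.append((sign, site))
            amb_counter += 1
            records.append((
                f"AMB{amb_counter:07d}", cad, day, sign, arrival, site,
                int(rng.integers(0, 101)),
                ("female", "male", "other")[int(rng.choice(3, p=(0.49, 0.49, 0.02)))],
            ))

    df = pd.DataFrame(records, columns=AMB_COLUMNS)
    df["ed_arrival"] = pd.to_datetime(df["ed_arrival"])
    return df


def _trust_rng(config: SimulationConfig, profile: TrustProfile) -> np.random.Generator:
    # Stable per-trust stream so extracts are independent of generation order.
    return np.random.default_rng(
        [config.seed, zlib.crc32(profile.trust_name.encode())])


def generate_ed_extract(ambulance: pd.DataFrame, profile: TrustProfile,
                        config: SimulationConfig) -> ExtractBundle:
    """Render the trust's ED attendance extract for its sites.

    One row per conveyance to a profile site, plus injected duplicates.
    Identifier fields follow the profile's recording mode; with probability
    ``null_identifier_rate`` both identifiers are blanked (the row keeps its
    truth pair and becomes a false-non-link candidate); otherwise with
    ``cad_null_rate`` only the CAD is lost and the call sign survives, so the
    row can still link through the call-sign pathway; with ``misuse_rate``
    the CAD field is overwritten with the misuse sentinel and the diagnosis
    becomes a mental-health code. Variables the trust does not supply are
    missing for every row. ED arrival is the ambulance-recorded arrival plus
    symmetric uniform jitter.
    """
    if ambulance.empty:
        raise ConfigurationError("ambulance dataset is empty")
    rng = _trust_rng(config, profile)
    sub = ambulance[ambulance["destination_site"].isin(profile.site_ids)]
    if sub.empty:
        warnings.warn(f"no conveyances to any site of {profile.trust_name}; "
                      "empty extract", stacklevel=2)
        return ExtractBundle(
            rows=pd.DataFrame(columns=("ed_row_id",) + ED_VARIABLES),
            truth={}, provenance=ExtractProvenance())

    jitter = config.timestamp_jitter_minutes
    layouts = list(FREETEXT_LAYOUTS) if profile.format_mix is None else list(profile.format_mix)
    probs = None if profile.format_mix is None else [profile.format_mix[k] for k in layouts]
    avail = set(profile.available_variables)

    rows = []
    truth: dict[str, str] = {}
    nulled, cad_nulled, misused = [], [], []
    layout_by_row: dict[str, str] = {}
    for i, amb in enumerate(sub.itertuples(index=False), start=1):
        rid = f"{profile.trust_name.upper()}-{i:07d}"
        arrival = amb.ed_arrival
        if jitter > 0:
            arrival = arrival + timedelta(
                seconds=float(np.floor(rng.uniform(-jitter, jitter) * 60)))
        site = amb.destination_site
        if config.site_swap_rate and rng.random() < config.site_swap_rate:
            others = [s for s in config.site_labels if s != site]
            if others:
                site = others[int(rng.integers(len(others)))]
        diagnosis = _DIAGNOSES[int(rng.integers(len(_DIAGNOSES)))]

        cad_field: object = str(amb.cad_number)
        cs_field: object = amb.call_sign
        if profile.identifier_mode == "combined_freetext":
            key = layouts[int(rng.choice(len(layouts), p=probs))]
            layout_by_row[rid] = key
            cad_field = FREETEXT_LAYOUTS[key].format(cad=amb.cad_number,
                                                     cs=amb.call_sign)
            cs_field = pd.NA
        elif profile.identifier_mode == "cad_only":
            cs_field = pd.NA

        if rng.random() < profile.null_identifier_rate:
            cad_field, cs_field = pd.NA, pd.NA
            nulled.append(rid)
        elif profile.cad_null_rate and rng.random() < profile.cad_null_rate:
            if profile.identifier_mode == "combined_freetext":
                cad_field, cs_field = amb.call_sign, pd.NA
            else:
                cad_field, cs_field = pd.NA, amb.call_sign
            cad_nulled.append(rid)
        elif profile.misuse_sentinel and rng.random() < profile.misuse_rate:
            cad_field = profile.misuse_sentinel
            cs_field = pd.NA
            diagnosis = _MH_DIAGNOSIS
            misused.append(rid)

        row = {
            "ed_row_id": rid,
            "hospital_site": site,
            "ed_arrival_datetime": arrival,
            "ethnicity": _ETHNICITIES[int(rng.integers(len(_ETHNICITIES)))],
            "age": amb.age,
            "gender": amb.gender,
            "gp_practice_id": f"GP{int(rng.integers(1, 500)):04d}",
            "first_ed_location": _LOCATIONS[int(rng.integers(len(_LOCATIONS)))],
            "blue_light_journey": "Y" if rng.random() < 0.3 else "N",
            "pathology": "FBC;U+E" if rng.random() < 0.5 else "NONE",
            "imaging": "XRAY" if rng.random() < 0.4 else "NONE",
            "treatment": "ANALGESIA" if rng.random() < 0.6 else "NONE",
            "diagnosis": diagnosis,
            "specialty_referral": "MEDICINE" if rng.random() < 0.25 else "NONE",
            "outcome": _OUTCOMES[int(rng.integers(len(_OUTCOMES)))],
            "outcome_destination": "WARD" if rng.random() < 0.35 else "HOME",
            "departure_datetime": arrival + timedelta(
                minutes=int(rng.integers(30, 360))),
            "cad_number": cad_field,
            "call_sign": cs_field,
        }
        for var in ED_VARIABLES:
            if var not in avail:
                row[var] = pd.NA
        rows.append(row)
        truth[rid] = amb.amb_id

    df = pd.DataFrame(rows, columns=("ed_row_id",) + ED_VARIABLES)

    duplicate_ids: list[str] = []
    if profile.duplicate_rate > 0:
        dup_mask = rng.random(len(df)) < profile.duplicate_rate
        dups = df[dup_mask].copy()
        dups["ed_row_id"] = [f"{profile.trust_name.upper()}-D{j:06d}"
                             for j in range(1, len(dups) + 1)]
        duplicate_ids = list(dups["ed_row_id"])
        df = pd.concat([df, dups], ignore_index=True)

    df["age"] = df["age"].astype("Int64")
    for col in ("ed_arrival_datetime", "departure_datetime"):
        df[col] = pd.to_datetime(df[col])
    return ExtractBundle(
        rows=df, truth=truth,
        provenance=ExtractProvenance(
            nulled_ids=tuple(nulled), cad_nulled_ids=tuple(cad_nulled),
            misuse_ids=tuple(misused),
            duplicate_ids=tuple(duplicate_ids), layout_by_row=layout_by_row))


def inject_sentinel_misuse(bundle: ExtractBundle, n: int, sentinel: str = "136",
                           seed: int = 0) -> ExtractBundle:
    """Overwrite the CAD field of ``n`` original rows with a misuse sentinel.

    Models administrative misuse of the incident-number field (e.g. recording
    "136" for Mental Health Act section 136 cases) at an exact count rather
    than a rate; the affected rows also receive a mental-health diagnosis and
    lose their call sign. Rows keep their truth pairs.
    """
    rng = np.random.default_rng(seed)
    df = bundle.rows.copy()
    originals = df.index[df["ed_row_id"].isin(bundle.truth)]
    if len(originals) < n:
        raise ConfigurationError(
            f"extract has only {len(originals)} original rows; cannot "
            f"inject {n}")
    chosen = rng.choice(originals, size=n, replace=False)
    df.loc[chosen, "cad_number"] = sentinel
    df.loc[chosen, "call_sign"] = pd.NA
    df.loc[chosen, "diagnosis"] = _MH_DIAGNOSIS
    ids = tuple(df.loc[chosen, "ed_row_id"])
    prov = replace(bundle.provenance,
                   misuse_ids=bundle.provenance.misuse_ids + ids)
    return ExtractBundle(rows=df, truth=dict(bundle.truth), provenance=prov)


# ---------------------------------------------------------------------------
# Transfer-error injection (exercises the extract validator)

@dataclass(frozen=True)
class TransferInjection:
    kind: str    # null_sentinel | bad_datetime | header_typo | column_swap
    locus: str
    #: the validator rule expected to catch this injection
    rule: str


_KIND_TO_RULE = {
    "null_sentinel": "missing_sentinel",
    "bad_datetime": "datetime_format",
    "header_typo": "column_title",
    "column_swap": "column_order",
}


def inject_transfer_errors(path, kinds: Sequence[str], seed: int = 0,
                           n_cells: int = 3) -> list[TransferInjection]:
    """Corrupt a written extract file in place with specification violations.

    Emulates the common provider errors seen during transfer: "NULL" in place
    of the missing sentinel, timestamps in the wrong dialect, a typo in a
    column title, and re-ordered columns. Returns one record per injection so
    tests can check each is caught by exactly its matching validator rule.
    """
    import csv as _csv

    rng = np.random.default_rng(seed)
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(_csv.reader(fh))
    header, body = rows[0], rows[1:]
    injections: list[TransferInjection] = []

    for kind in kinds:
        if kind == "null_sentinel":
            cells = [(r, c) for r, row in enumerate(body)
                     for c, cell in enumerate(row) if cell == "XXXX"]
            if not cells:
                raise ConfigurationError("no sentinel cells to corrupt")
            for j in rng.choice(len(cells), size=min(n_cells, len(cells)),
                                replace=False):
                r, c = cells[int(j)]
                body[r][c] = "NULL"
                injections.append(TransferInjection(
                    kind, f"row {r + 2}, col {header[c]}", _KIND_TO_RULE[kind]))
        elif kind == "bad_datetime":
            c = header.index("ed_arrival_datetime")
            candidates = [r for r, row in enumerate(body) if row[c] != "XXXX"]
            r = int(rng.choice(candidates))
            dt = datetime.strptime(body[r][c], "%Y-%m-%d %H:%M:%S")
            body[r][c] = dt.strftime("%d-%m-%Y %H.%M")
            injections.append(TransferInjection(
                kind, f"row {r + 2}, col {header[c]}", _KIND_TO_RULE[kind]))
        elif kind == "header_typo":
            c = header.index("gender")
            header[c] = "Gender "
            injections.append(TransferInjection(kind, f"col {header[c]}",
                                                _KIND_TO_RULE[kind]))
        elif kind == "column_swap":
            a, b = header.index("ethnicity"), header.index("gender")
            header[a], header[b] = header[b], header[a]
            for row in body:
                row[a], row[b] = row[b], row[a]
            injections.append(TransferInjection(kind, "header",
                                                _KIND_TO_RULE[kind]))
        else:
            raise ConfigurationError(f"unknown transfer-error kind {kind!r}")

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = _csv.writer(fh)
        w.writerow(header)
        w.writerows(body)
    return injections


# ---------------------------------------------------------------------------
# Preset trust profiles

_AVAILABILITY: dict[str, set[str]] = {
    # Which of the 18 requested variables each trust supplies.
    "Alpha": set(ED_VARIABLES) - {"treatment"},
    "Bravo": set(ED_VARIABLES) - {"pathology", "imaging", "treatment"},
    "Charlie": set(ED_VARIABLES) - {"pathology"},
    "Delta": set(ED_VARIABLES) - {"pathology", "specialty_referral"},
    "Echo": set(ED_VARIABLES) - {"first_ed_location", "specialty_referral"},
    "Foxtrot": set(ED_VARIABLES) - {"first_ed_location", "specialty_referral",
                                    "outcome_destination", "call_sign"},
}

_DEFAULT_MIX = {"label_comma": 0.4, "comma_label": 0.3, "slash": 0.3}


def trust_presets(site_labels: Sequence[str] = None) -> dict[str, TrustProfile]:
    """Six preset trusts, Alpha–Foxtrot, partitioning the service's EDs.

    Variable availability and identifier-recording mode follow the observed
    per-trust behaviours (separate fields for Alpha/Charlie, one unformatted
    free-text field for Bravo/Delta/Echo, CAD only for Foxtrot); the
    corruption rates are plausible approximations, not calibrated estimates.
    """
    if site_labels is None:
        site_labels = tuple(f"SITE{i:02d}" for i in range(1, 14))
    site_labels = list(site_labels)
    shares = {"Alpha": 1, "Bravo": 2, "Charlie": 2, "Delta": 2, "Echo": 4,
              "Foxtrot": 2}
    # Deal sites round-robin across trusts (respecting each trust's ED share)
    # so every trust gets at least one site whenever there are >= 6 sites.
    sites: dict[str, list[str]] = {t: [] for t in shares}
    pool: list[str] = []
    remaining = dict(shares)
    while any(remaining.values()):
        for t, k in remaining.items():
            if k > 0:
                pool.append(t)
                remaining[t] -= 1
    for i, s in enumerate(site_labels):
        sites[pool[i % len(pool)]].append(s)

    def prof(name, mode, null_rate, **kw):
        return TrustProfile(
            trust_name=name, site_ids=tuple(sites[name]),
            available_variables=frozenset(_AVAILABILITY[name]),
            identifier_mode=mode, null_identifier_rate=null_rate, **kw)

    return {
        "Alpha": prof("Alpha", "separate_fields", 0.10, cad_null_rate=0.18),
        "Bravo": prof("Bravo", "combined_freetext", 0.08,
                      format_mix=_DEFAULT_MIX, cad_null_rate=0.18),
        "Charlie": prof("Charlie", "separate_fields", 0.001,
                        duplicate_rate=0.01, cad_null_rate=0.18),
        "Delta": prof("Delta", "combined_freetext", 0.19,
                      format_mix=_DEFAULT_MIX, cad_null_rate=0.18),
        "Echo": prof("Echo", "combined_freetext", 0.08,
                     format_mix=_DEFAULT_MIX, cad_null_rate=0.18),
        "Foxtrot": prof("Foxtrot", "cad_only", 0.50,
                        misuse_sentinel="136", misuse_rate=0.002),
    }


# ---------------------------------------------------------------------------
# CSV artifacts

def write_ambulance_dataset(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    out["incident_date"] = pd.to_datetime(out["incident_date"]).dt.strftime("%Y-%m-%d")
    out["ed_arrival"] = pd.to_datetime(out["ed_arrival"]).dt.strftime("%Y-%m-%d %H:%M:%S")
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_ambulance_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"call_sign": str, "destination_site": str})
    df["incident_date"] = pd.to_datetime(df["incident_date"]).dt.date
    df["ed_arrival"] = pd.to_datetime(df["ed_arrival"])
    return df


def write_registry(signs: Sequence[str], path) -> Path:
    path = Path(path)
    pd.DataFrame({"call_sign": list(signs)}).to_csv(path, index=False)
    return path


def write_truth(truth: Mapping[str, str], path) -> Path:
    path = Path(path)
    pd.DataFrame(sorted(truth.items()), columns=["ed_row_id", "amb_id"]).to_csv(
        path, index=False)
    return path


def read_truth(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["ed_row_id"], df["amb_id"]))
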