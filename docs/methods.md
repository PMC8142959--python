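# Methods

This note records the generative model, the matching rules and the numerical
conventions the package implements, with the reasoning behind each choice.

## Setting

One ambulance service conveys patients to the EDs of several acute trusts.
No shared patient identifier exists across the two settings, so linkage rests
on two operational identifiers:

- **CAD number** — the dispatch system's incident number. It is a small
  integer (1–4 digits), assigned sequentially through the day, and **resets
  at midnight**: a CAD number is only meaningful together with the incident
  date, and the same (CAD, date) key can identify different incidents in
  different years only if data span that long (they do not here).
- **Call sign** — a letters-then-digits code (e.g. `Q987`) identifying a
  vehicle crew for a shift. One crew conveys several patients per shift, so
  a call sign + date is *not* unique per patient; it needs corroboration.

Matching is **deterministic**: a candidate pair either satisfies an exact
rule or it does not. There are no weights or thresholds to train, which
keeps every decision auditable — the price is that a record with neither
identifier can never link.

## Generative model (`edlink.synth`)

`generate_ambulance_dataset` simulates the service side:

- Incidents are allocated to days by a uniform multinomial draw over the
  study window. Within a day, conveyed incidents get CAD numbers 1, 2, 3, …
  in call-time order. Daily volume is capped at 6999 (`CapacityError`
  beyond it) so that the cleaning rule "a CAD is an integer under 7000" is
  lossless by construction.
- Call signs are drawn from a finite registry (`generate_callsign_registry`;
  default 400 entries). With probability `multi_patient_shift_rate` an
  incident reuses a (call sign, destination site) pair already active that
  day — the multi-patient shift that makes time corroboration necessary.
- With probability `midnight_crossing_fraction` an incident is called in
  late evening and arrives at the ED **after midnight**: its ED arrival date
  is one day after its incident date. These rows are why date-exact matching
  alone is insufficient.
- ED arrival times carry symmetric uniform jitter
  (± `timestamp_jitter_minutes`) relative to the service-recorded arrival,
  modelling clock disagreement between the two systems.

`generate_ed_extract` renders one trust's extract from the conveyances to
its sites, under a `TrustProfile`:

- `identifier_mode`: `separate_fields` (CAD and call sign in their own
  columns), `combined_freetext` (both jumbled into the CAD column under one
  of three layouts — `CAD{cad}, {cs}`, `{cad}, Call sign {cs}`,
  `{cs}/{cad}` — drawn per row from `format_mix`), or `cad_only`.
- `null_identifier_rate`: both identifiers blanked (the record keeps its
  ground-truth pair and becomes an unavoidable false non-link).
- `cad_null_rate`: only the CAD is lost; the call sign survives (in
  free-text modes the combined field then carries just the call sign). This
  is what exercises the call-sign pathway at realistic volume.
- `misuse_sentinel`/`misuse_rate`: the CAD field is overwritten with a fixed
  non-CAD value and the diagnosis becomes a mental-health code — modelling
  administrative repurposing of the field for a case category.
- `duplicate_rate`: exact duplicate rows under fresh row ids.
- Variables the trust does not supply are filled with the missing sentinel
  for every row, keeping a single extract layout across trusts.

Ground truth maps each original (non-duplicate) ED row to exactly one
ambulance record; injected duplicates are recorded in provenance instead.
All randomness flows from `numpy.random.default_rng` seeded per
(seed, trust), so every artifact is bit-reproducible.

### Preset trusts

`trust_presets` defines six trusts, Alpha–Foxtrot, partitioning 13 EDs
(shares 1/2/2/2/4/2). Variable availability per trust (17/15/17/16/16/14 of
the 18 agreed variables) and recording mode (Alpha, Charlie separate fields;
Bravo, Delta, Echo combined free text; Foxtrot CAD-only) are fixed; the
corruption rates (nulling 0.001–0.50, `cad_null_rate` 0.18 where a call
sign is recorded, Charlie's duplicates, Foxtrot's misuse) are plausible
approximations chosen to span easy-to-hard, **not** calibrated estimates.

## Extract format and validation (`edlink.extract_io`)

One fixed CSV layout: `ed_row_id` plus 18 agreed variables, comma-delimited,
missing values as the sentinel `XXXX`, datetimes in a single convention
(ISO `YYYY-MM-DD HH:MM:SS` by default). `validate_extract` reports
violations with a rule name and a cell/row/column locus, covering:
delimiter, column titles, column order, per-row field count, forbidden
missing-value spellings (`NULL`, `N/A`, `NA`, empty), and datetime format.
Validation reads the raw file with the stdlib `csv` module because
cell-level loci need access pandas does not give; reading/writing proper
uses pandas. `read_extract` attaches the validation report and either warns
(default) or raises (`strict=True`).

## Cleaning (`edlink.cleaning`)

`parse_identifiers` is total — any input yields a result, at worst
`parse_status="none"`:

- **CAD rule**: tokenise the field; the first all-digit token of 1–4 digits
  whose value is in [1, 6999] is the CAD. 7000 and above is rejected (the
  dispatch system never issues them), as is 0.
- **Call-sign rule**: the first letters-then-digits token that appears in
  the supplied registry (case-normalised) is the call sign. Registry
  verification is what stops free-text noise (`CAD123` itself is
  letters-then-digits) from being mistaken for a call sign.

Both rules are applied to both raw fields, so separate-field,
combined-free-text and CAD-only extracts all flow through one parser.
Exact duplicate rows (all non-id columns equal) are dropped, keeping the
first.

## Linkage (`edlink.linkage`)

Per cleaned row, in order:

1. **No identifier** → `no_identifier`, never matched.
2. **CAD + date pathway**: look up (CAD, ED arrival date) and, if
   `allow_consecutive_dates`, (CAD, date − 1) — the previous day's key
   catches journeys that crossed midnight. If both days hold a candidate,
   the one whose service-recorded ED arrival is nearest wins
   (`cad_tie_break="nearest_arrival"`, the default; ties fall to the exact
   date). Time is used only to break this date tie, never as a matching
   item on its own. Rationale: with CAD numbers reset daily, the previous
   day's crosser and today's reissue of the same number are both legitimate
   candidates, and date preference alone picks the wrong one for every
   crosser; nearest arrival resolves it without admitting time as evidence
   anywhere else.
3. **Call sign + date + time pathway** (only if the CAD pathway produced no
   match): candidates are the crew's conveyances on the arrival date and the
   previous day, filtered to the same site
   (`require_site_agreement_callsign`), and the nearest by arrival time
   within `time_tolerance_minutes` (default 120) wins. Two distinct
   ambulance records exactly equidistant → unmatched with an
   `ambiguous_candidates` flag; guessing would trade silent false links for
   an auditable miss.

Ambulance-side (CAD, date) keys that occur more than once — possible only
under data corruption, never in clean generated data — are **quarantined**
from the CAD index (still reachable via call sign) rather than matched
arbitrarily. Flags (`consecutive_date_used`, `site_disagreement` under the
`flag` policy, `ambiguous_candidates`) travel with each result row.

## Evaluation (`edlink.evaluation`)

- Match-rate tables accept either per-row link results or pre-aggregated
  per-trust counts, add a Total row, and round rates **half-up**
  (`floor(x + 0.5)`) to whole percent — the convention that reproduces a
  published table's printed rates exactly; the no-identifier share is
  reported to one decimal. Rows where matched + no-identifier exceeds
  available are *flagged* `inconsistent`, not rejected: published tables
  contain such rows and the report must be able to represent them.
- Pathway counts are reported as shares of **total records** (not of
  matches), again following published convention.
- `analyse_unmatched` flags any exact identifier value occurring ≥
  `flag_threshold` times (default 20) among unmatched rows — a genuine CAD
  or call sign should not recur across unrelated attendances, so
  over-representation is the signature of field misuse — and reports
  24-hour arrival histograms and coarse age bins (0–4, 5–17, 18–64, 65+)
  for unmatched vs matched rows.
- `evaluate_against_truth` scores results against the generator's ground
  truth: true/false links, false/true non-links, precision, recall
  (`None` when the denominator is empty). A truth row absent from the
  results is a `ConsistencyError`, not a silent skip.

## Problem sizes and verification

- The analysis drivers run 30,000 conveyed incidents over 17 weeks across
  13 sites and six trusts (~30,000 extract rows total) in seconds.
- The acceptance script uses 2,000 incidents over 4 weeks with 60 injected
  misuse rows; daily volume stays below the sentinel's numeric value so no
  genuine CAD collides with it, making the flagged count exactly the
  injected count for any seed.
- The matcher is verified against an independently written brute-force
  oracle (all-pairs scan, no indexes) on randomised
  configurations — 25 in the acceptance suite, more in the module tests —
  plus: perfect precision/recall on uncorrupted data across seeds (jitter
  off), recall tracking `1 − null rate` within binomial tolerance at
  n = 20,000 with precision exactly 1, monotonicity of call-sign matches in
  the time tolerance, and extract round-trip/fault-injection coverage.

## Limitations

- The generator is a caricature sufficient to exercise every code path, not
  a calibrated model of any real service: arrival jitter is uniform, case
  mix is random, duplicates are exact copies, and free-text noise is limited
  to the three layouts. Typos inside identifiers (transposed digits,
  mis-keyed call signs) are not modelled, so parsing failures beyond
  nulling/misuse are unexercised.
- Deterministic matching has no notion of near-miss: a single corrupted
  digit loses the pair (or, for CAD, silently points at a different
  incident on a day the generator never reuses numbers — the oracle tests
  cover the implemented behaviour, not all conceivable corruption).
- Site disagreement defaults to `flag` for the CAD pathway; under
  `site_swap_rate > 0` a swapped site therefore flags rather than blocks a
  CAD match. That is a policy choice (`cmp_site_cad="require"` reverses it),
  not a claim about which is operationally correct.
- Precision below 1.0 is possible through call-sign ambiguity when jitter
  moves an arrival closer to a sibling conveyance of the same shift; the
  ground-truth evaluation quantifies this rather than preventing it.
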