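#!/usr/bin/env python
"""Step 2 — validate every transferred extract against the agreed format.

Checks delimiter, column titles and order, row structure, the ``XXXX``
missing-value sentinel and the datetime convention. Per-extract violation
reports go to ``results/validation/<Trust>.csv``; a non-zero exit means at
least one extract failed and should be sent back to the trust.
"""

import sys

from _study import DATA_DIR, TRUSTS, VALIDATION_DIR

from edlink.extract_io import FormatSpec, validate_extract


def main() -> int:
    VALIDATION_DIR.mkdir(parents=True, exist_ok=True)
    spec = FormatSpec()
    any_bad = False
    for trust in TRUSTS:
        report = validate_extract(DATA_DIR / "extracts" / f"{trust}.csv", spec)
        report.to_frame().to_csv(VALIDATION_DIR / f"{trust}.csv", index=False)
        status = "ok" if report.file_ok else "FAIL"
        print(f"  {trust:8s} {status}  "
              + (", ".join(f"{rule}={n}" for rule, n in
                           sorted(report.counts.items())) or "no violations"))
        any_bad = any_bad or not report.file_ok
    return 1 if any_bad else 0


if __name__ == "__main__":
    sys.exit(main())
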