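#!/usr/bin/env python
"""Populate the reference-structure cache used by the acceptance tests.

Downloads the five crystal structures whose published geometry the test
suite checks (1KX5, 1AOI, 1ZBB, 5AY8, 4QLC) from the RCSB PDB into
``tests/data/reference/``.  Requires network access; run once, then the
full test suite (including the published-value checks) can run offline.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ENTRIES = ["1kx5", "1aoi", "1zbb", "5ay8", "4qlc"]
URL = "https://files.rcsb.org/download/{}.cif"
DEST = Path(__file__).resolve().parent.parent / "tests" / "data" / "reference"


def main() -> int:
    DEST.mkdir(parents=True, exist_ok=True)
    failures = []
    for entry in ENTRIES:
        target = DEST / f"{entry}.cif"
        if target.exists():
            print(f"{entry}: already cached")
            continue
        try:
            print(f"{entry}: downloading ...")
            with urllib.request.urlopen(URL.format(entry.upper()),
                                        timeout=60) as resp:
                target.write_bytes(resp.read())
        except OSError as exc:
            failures.append((entry, str(exc)))
            print(f"{entry}: FAILED ({exc})")
    if failures:
        print(f"{len(failures)} downloads failed; the published-value "
              "acceptance tests will not be able to run")
        return 1
    print(f"cache complete at {DEST}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
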