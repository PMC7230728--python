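#!/usr/bin/env python
"""Fetch the seven deposited HF1-group genomes from NCBI into data/accessions/.

Needs network access; the library itself never fetches. Usage:

    python scripts/fetch_accessions.py [--out data/accessions]
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSIONS = {
    "AY190604": "HF1",
    "AF222060": "HF2",
    "MN901520": "Hardycor2",
    "MN901521": "Serpecor1",
    "KC292022": "HRTV-5",
    "KC292020": "HRTV-8",
    "KC292021": "HRTV-7",
}

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accession: str) -> str:
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "gbwithparts", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=120) as response:
        return response.read().decode()


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="data/accessions", type=Path)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for accession, name in ACCESSIONS.items():
        target = args.out / f"{accession}.gb"
        if target.exists():
            print(f"{accession} ({name}): already present", file=sys.stderr)
            continue
        print(f"{accession} ({name}): fetching...", file=sys.stderr)
        text = fetch(accession)
        if "ORIGIN" not in text:
            print(f"{accession}: response has no sequence, not saved", file=sys.stderr)
            return 1
        target.write_text(text)
        time.sleep(0.4)  # NCBI rate limit
    print(f"done; records in {args.out}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
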