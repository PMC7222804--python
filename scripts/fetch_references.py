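#!/usr/bin/env python
"""Download the twelve reference mitochondrial genomes from NCBI.

Fetches FASTA and GenBank flat files for the accessions of the comparative
study into data/references/.  Requires network access; the library itself
never downloads anything.

Usage:  python scripts/fetch_references.py [--outdir data/references]
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSIONS = {
    "NC_001328.1": ("Caenorhabditis elegans", "invertebrate"),
    "NC_024511.2": ("Drosophila melanogaster", "invertebrate"),
    "NC_026914.1": ("Daphnia magna", "invertebrate"),
    "NC_001804.1": ("Latimeria chalumnae", "vertebrate"),
    "NC_002333.2": ("Danio rerio", "vertebrate"),
    "NC_005797.1": ("Ambystoma mexicanum", "vertebrate"),
    "NC_040970.1": ("Gallus gallus", "vertebrate"),
    "NC_005089.1": ("Mus musculus", "vertebrate"),
    "NC_002008.4": ("Canis lupus familiaris", "vertebrate"),
    "NC_008143.1": ("Crocodylus porosus", "vertebrate"),
    "KM679417.1": ("Pan troglodytes ellioti", "vertebrate"),
    "NC_012920.1": ("Homo sapiens", "vertebrate"),
}

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(acc: str, rettype: str) -> bytes:
    query = urllib.parse.urlencode({
        "db": "nuccore", "id": acc, "rettype": rettype, "retmode": "text"})
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as resp:
        return resp.read()


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="data/references")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for acc, (species, group) in ACCESSIONS.items():
        for rettype, ext in (("fasta", "fasta"), ("gbwithparts", "gb")):
            dest = outdir / f"{acc}.{ext}"
            if dest.exists():
                print(f"{dest} exists, skipping", file=sys.stderr)
                continue
            print(f"fetching {acc} ({species}, {group}) [{rettype}]",
                  file=sys.stderr)
            dest.write_bytes(fetch(acc, rettype))
            time.sleep(0.4)  # NCBI rate limit
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
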