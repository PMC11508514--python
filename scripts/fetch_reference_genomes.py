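#!/usr/bin/env python
"""Download the study's deposited mitogenome records from NCBI.

Fetches the 15 Scoliidae accessions (plus the two outgroups) as GenBank
flat files into ``data/reference_genomes/``, where the accession-dependent
acceptance test expects them.  Requires network access to NCBI eutils;
nothing else in the package needs the network.

Usage:  python scripts/fetch_reference_genomes.py [--out-dir data/reference_genomes]
"""

from __future__ import annotations

import argparse
import time
import urllib.request
from pathlib import Path

ACCESSIONS = [
    # Scoliidae (Table of study records)
    "PP874258", "PP874259", "PP874260", "PP874261", "PP874262", "PP874263",
    "PP874264", "PP874265", "PP874266", "PP874267",
    "OM103697", "OP946654", "OP946655", "MH748671", "OP661167",
    # outgroups
    "FJ154897", "MG923499",
]

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=gb&retmode=text")


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path,
                    default=Path(__file__).resolve().parent.parent / "data" / "reference_genomes")
    args = ap.parse_args(argv)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = args.out_dir / f"{acc}.gb"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=60) as resp:
            dest.write_bytes(resp.read())
        print(f"{acc}: fetched {dest.stat().st_size} bytes")
        time.sleep(0.4)  # NCBI rate limit


if __name__ == "__main__":
    main()
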