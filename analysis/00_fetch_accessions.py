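#!/usr/bin/env python
"""Fetch the six deposited Brassica mitotype records (needs network).

Downloads GenBank flat files for the mitotypes into data/accessions/ so
the real-data regression in tests/test_acceptance.py can run:

    cam JF920285   ole JF920286   car JF920287
    jun JF920288   nap AP006444.1 pol FR715249 (EMBL, via ENA)

Roughly 1.5 MB in total.  Run on a networked machine:
    python analysis/00_fetch_accessions.py
"""

import sys
import urllib.request
from pathlib import Path

NCBI = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&rettype=gbwithparts&retmode=text&id={acc}"
)
ENA = "https://www.ebi.ac.uk/ena/browser/api/embl/{acc}"

ACCESSIONS = {
    "JF920285": NCBI,  # cam (B. rapa)
    "JF920286": NCBI,  # ole (B. oleracea)
    "JF920287": NCBI,  # car (B. carinata)
    "JF920288": NCBI,  # jun (B. juncea)
    "AP006444": NCBI,  # nap (B. napus)
    "FR715249": ENA,  # pol (B. napus)
}


def main():
    outdir = Path(__file__).resolve().parent.parent / "data" / "accessions"
    outdir.mkdir(parents=True, exist_ok=True)
    for acc, url in ACCESSIONS.items():
        dest = outdir / f"{acc}.gb"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        print(f"fetching {acc} ...")
        try:
            with urllib.request.urlopen(url.format(acc=acc), timeout=60) as r:
                dest.write_bytes(r.read())
        except Exception as exc:
            print(f"  failed: {exc}", file=sys.stderr)
            return 1
    print(f"records in {outdir}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
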