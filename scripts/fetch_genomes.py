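#!/usr/bin/env python
"""Fetch the published host and phage genomes from NCBI into data/accessions/.

Requires network access to eutils.ncbi.nlm.nih.gov. The host is
*Pseudoalteromonas* sp. strain 13-15 (two replicons, CP019162.1 and
CP019163.1); the phages are Pseudoalteromonas phages PSA-HP1 and PSA-HS2,
located by Entrez search since their flat-file accessions are not part of
the strain assembly.

Usage: python scripts/fetch_genomes.py [--out data/accessions]
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path
from xml.etree import ElementTree

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"


def efetch_gb(query_id: str, dest: Path) -> None:
    url = (
        f"{EUTILS}/efetch.fcgi?db=nuccore&id={urllib.parse.quote(query_id)}"
        "&rettype=gbwithparts&retmode=text"
    )
    with urllib.request.urlopen(url, timeout=120) as resp:
        dest.write_bytes(resp.read())
    print(f"wrote {dest}")
    time.sleep(0.5)  # NCBI rate limit


def esearch_one(term: str) -> str:
    url = f"{EUTILS}/esearch.fcgi?db=nuccore&term={urllib.parse.quote(term)}"
    with urllib.request.urlopen(url, timeout=60) as resp:
        tree = ElementTree.fromstring(resp.read())
    ids = [e.text for e in tree.iter("Id")]
    if not ids:
        raise SystemExit(f"no nuccore record found for {term!r}")
    return ids[0]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("data/accessions"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for acc in ("CP019162.1", "CP019163.1"):
        efetch_gb(acc, args.out / f"{acc.split('.')[0]}.gb")
    for name in ("PSA-HP1", "PSA-HS2"):
        uid = esearch_one(f"Pseudoalteromonas phage {name}[Title] AND complete genome")
        efetch_gb(uid, args.out / f"{name}.gb")


if __name__ == "__main__":
    main()
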