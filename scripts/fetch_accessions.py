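#!/usr/bin/env python
"""Download the GenBank accessions used by the sequence-level checks.

The library itself never touches the network; this helper fetches the
public records once, on a networked machine, and stores them under
``data/`` where the test suite and analysis scripts look for them.

Usage:
    python scripts/fetch_accessions.py [--outdir data]
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

EUTILS = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=fasta&retmode=text"
)

# virus/provirus genomes and the host contigs carrying their att sites
ACCESSIONS = [
    "MT152698",  # Hardycor1
    "MW344764",  # Humcor2
    "MW344765",  # Humcor1
    "MW344766",  # Halfgib1
    "MW344767",  # Harhisp1
    "AOJL01000020",  # Hrr. coriense draft contig 20 (Humcor2 att region)
]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("data"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = args.outdir / f"{acc}.fasta"
        if dest.exists():
            print(f"{dest} already present, skipping")
            continue
        url = EUTILS.format(acc=acc)
        print(f"fetching {acc} ...")
        with urllib.request.urlopen(url, timeout=60) as resp:
            dest.write_bytes(resp.read())
        print(f"  -> {dest}")


if __name__ == "__main__":
    main()
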