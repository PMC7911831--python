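#!/usr/bin/env python
"""Simulate a sequenced halovirus stock containing an induced provirus.

Builds a 15 kb host chromosome with a 5 kb provirus integrated at a
synthetic tRNA gene (13 bp att core), then draws 250 nt reads from a
mixture of the chromosome and the excised circular element at 5 circles
per chromosome and 50x chromosomal coverage — the composition the
induction screen is designed to detect.  Writes FASTA/GFF3/FASTQ plus the
truth ledger under results/stock/.
"""

import sys
from pathlib import Path

from haloprov.seqio import write_fasta, write_gff3
from haloprov.synthetic import build_lysogen, simulate_stock, write_fastq

OUT = Path(__file__).resolve().parent.parent / "results" / "stock"

SEED = 1
COPY_RATIO = 5.0
COVERAGE = 50.0
READ_LEN = 250


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lysogen, element, truth = build_lysogen(
        host_length=15000, element_length=5000, att_len=13, seed=SEED
    )
    reads, abundances = simulate_stock(
        lysogen, element, COPY_RATIO, COVERAGE, READ_LEN, seed=SEED + 1
    )
    truth.template_abundances = abundances
    write_fasta(lysogen, OUT / "lysogen.fasta")
    write_fasta(element, OUT / "element.fasta")
    write_gff3(lysogen, OUT / "lysogen.gff3")
    write_gff3(element, OUT / "element.gff3")
    write_fastq(reads, OUT / "reads.fastq")
    truth.to_json(OUT / "truth.json")
    t = truth.provirus
    print(f"lysogen: {len(lysogen.seq)} bp; element: {len(element.seq)} bp circle")
    print(f"att core: {t['att_core']} ({len(t['att_core'])} bp), "
          f"attL at {t['attL_start']}, attR at {t['attR_start']}")
    print(f"reads: {len(reads)} x {READ_LEN} nt at circle:chromosome ratio {COPY_RATIO}")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    sys.exit(main())
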