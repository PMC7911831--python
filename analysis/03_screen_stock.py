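#!/usr/bin/env python
"""Screen the simulated stock's reads for induced proviruses.

Consumes the output of 01_simulate_stock.py, recomputes the induction
evidence (attP/attB junction-spanning reads, inside/outside coverage) for
the candidate provirus, and prints the call next to the generator truth.
Writes results/induction_evidence.json.
"""

import json
import sys
from pathlib import Path

from haloprov.induction import detect_circular_contig
from haloprov.report import run_stock_screen
from haloprov.seqio import read_fasta
from haloprov.synthetic import read_fastq

ROOT = Path(__file__).resolve().parent.parent
STOCK = ROOT / "results" / "stock"


def main() -> int:
    if not (STOCK / "reads.fastq").exists():
        print("run analysis/01_simulate_stock.py first", file=sys.stderr)
        return 1
    truth = json.loads((STOCK / "truth.json").read_text())
    t = truth["provirus"]
    core_len = len(t["att_core"])
    lysogen = read_fasta(STOCK / "lysogen.fasta")
    element = read_fasta(STOCK / "element.fasta", topology="circular")
    reads = read_fastq(STOCK / "reads.fastq")

    circ, unit = detect_circular_contig(element.seq + element.seq[:30], 20)
    print(f"assembled element contig: circular={circ}, unit={len(unit)} bp "
          f"(truth {t['element_length']} bp)")

    row = {
        "provirus_id": "syn_provirus",
        "host_id": lysogen.id,
        "start": t["attL_start"],
        "end": t["attR_start"] + core_len - 1,
        "core_len": core_len,
    }
    (ev,) = run_stock_screen(reads, {lysogen.id: lysogen}, [row])
    out = ROOT / "results" / "induction_evidence.json"
    out.write_text(json.dumps(ev.__dict__, indent=1) + "\n")
    print(f"attP junction reads: {ev.attP_junction_reads}; "
          f"attB junction reads: {ev.attB_junction_reads}")
    print(f"coverage inside/outside: {ev.coverage_inside:.1f}/{ev.coverage_outside:.1f} "
          f"(ratio {ev.ratio:.2f})")
    print(f"call: {ev.call}")
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
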