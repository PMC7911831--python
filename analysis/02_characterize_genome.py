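#!/usr/bin/env python
"""Characterize a halovirus-like genome: composition, avoidance, architecture.

Runs the full per-genome report on the Hardycor1 genome if its FASTA has
been fetched (data/MT152698.fasta, see scripts/fetch_accessions.py);
otherwise on a synthetic stand-in with the same length and G+C content and
the three headline palindromic tetramers (AGCT, CTAG, TGCA) depleted to
zero.  CDS-level statistics always use the published MT152698 coordinate
table bundled under data/.  Writes results/genome_report.json and a motif
TSV.
"""

import json
import sys
from pathlib import Path

from haloprov.report import run_genome_report
from haloprov.seqio import GenomeRecord, read_fasta, read_features_tsv
from haloprov.synthetic import deplete_motifs, make_genome

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"

SEED = 1


def load_genome() -> tuple[GenomeRecord, bool]:
    fasta = ROOT / "data" / "MT152698.fasta"
    feats = read_features_tsv(ROOT / "data" / "MT152698_features.tsv")
    if fasta.exists():
        rec = read_fasta(fasta, topology="circular")
        rec.features = feats
        rec.__post_init__()
        return rec, True
    seq = deplete_motifs(
        make_genome(45142, 0.678, SEED), ["AGCT", "CTAG", "TGCA"], SEED + 1
    )
    rec = GenomeRecord(id="synthetic_hardycor1_like", seq=seq, topology="circular",
                       features=feats)
    return rec, False


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rec, real = load_genome()
    rep = run_genome_report(rec)
    (OUT / "genome_report.json").write_text(json.dumps(rep, indent=1, default=str) + "\n")
    src = "accession sequence" if real else "synthetic stand-in sequence"
    print(f"genome: {rec.id} ({src}), {rep['length']} bp, G+C {rep['gc_percent']}%")
    print(f"absent tetramers: {', '.join(rep['kmer_avoidance']['absent_tetramers'])}")
    print(f"absent palindromic 6-mers: {len(rep['kmer_avoidance']['absent_palindromic_6mers'])} "
          f"(+{len(rep['kmer_avoidance']['excluded_6mers'])} excluded by avoided cores)")
    print(f"cumulative AT-skew maximum at nt {rep['at_skew']['cumulative_max_coordinate']}")
    sp = rep["spacing"]
    print(f"genes: {sp['n_genes']}; overlapping: {sp['n_overlapping_genes']}; "
          f"close (<=10 bp): {sp['n_close_genes']}")
    print(f"wrote {OUT / 'genome_report.json'}")


if __name__ == "__main__":
    sys.exit(main())
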