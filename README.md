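# haloprov

Genome characterization of haloarchaeal viruses and detection of **induced
proviruses** — prophage-like elements that have excised from their host
chromosome, circularised, and begun replicating — from shotgun-read
evidence.

## Who this is for

Virologists and microbial genomicists working with small archaeal virus
genomes (tens of kb, often circular assemblies from circularly permuted,
terminally redundant virions) and with sequenced virus stocks that may be
contaminated by induced proviruses of the production host. The package
provides the desk-scale analyses such a study needs, each as a plain
library function, plus a CLI and numbered analysis drivers.

## What it computes

**Motif avoidance.** Virus genomes under host restriction–modification
pressure deplete the recognition motifs of host enzymes. For each tetramer
*w = w₁w₂w₃w₄* on a circular genome the maximal-order Markov odds ratio is

ρ(w) = N(w₁w₂w₃w₄)·N(w₂w₃) / (N(w₁w₂w₃)·N(w₂w₃w₄)),

with ρ ≪ 1 indicating avoidance. The avoidance report lists absent
tetramers (count 0), under-represented tetramers (0 < ρ ≤ 0.15), and the
absent palindromic 6-mers after excluding any 6-mer containing an avoided
tetramer core.

**Skew profiling.** Per-window AT skew (A−T)/(A+T) in non-overlapping
45 nt tiles and its exact cumulative sum; the global extremum of the
cumulative series marks the transcription-direction flip point of a
typical siphovirus genome map.

**Gene architecture.** Per-gene overlap/close-spacing census over
coordinate-adjacent CDS (circular adjacency included), CxxC zinc-finger
motif scanning, identical N-terminus lengths, maximal exact direct-repeat
finding, programmed −1 frameshift slippery heptamers (X XXY YYZ) in the
3′ tail of a CDS, and siphovirus tail-length prediction from the tape
measure protein size (L = 0.15·aa − 20.7 nm, reported as ⌊L⌋).

**Provirus geometry.** tRNA-integrated elements duplicate a short *att*
core (the tRNA 3′ end) as attL/attR. `find_att_core` matches tRNA
suffixes into a circular element; `integrate`/`excise` are exact inverse
coordinate operations; `find_bridging_cds` locates the ORF that spans
attP between the integrase and a downstream CxxC-protein gene — complete
on the circle, split between the provirus ends after integration.

**Induction evidence.** Circular-contig recognition by terminal overlap,
attP/attB junction-spanning read counts by exact anchored matching, and
inside/outside read-depth ratio via unique 31-mer placement, combined into
a call: `induced`, `excision-only`, or `silent`.

**Synthetic data.** `haloprov.synthetic` generates GC-controlled genomes
with selected motifs depleted to zero, lysogens with planted att/tRNA/
integrase/bridging-ORF structure, and read sets from mixtures of
chromosome, excised circle, and headfully packaged virions — each with a
machine-readable truth ledger, so every detector above is testable
without downloads.

## Worked example

```sh
python analysis/01_simulate_stock.py
python analysis/03_screen_stock.py
```

prints (seed 1):

```
lysogen: 20000 bp; element: 5000 bp circle
att core: GCGCATTTCCGCC (13 bp), attL at 6059, attR at 11059
reads: 9000 x 250 nt at circle:chromosome ratio 5.0
...
assembled element contig: circular=True, unit=5000 bp (truth 5000 bp)
attP junction reads: 214; attB junction reads: 0
coverage inside/outside: 293.7/52.1 (ratio 5.64)
call: induced
```

Reading: the stock carries 5 excised circles per chromosome, so the
provirus region is covered ≈ 6× deeper than the chromosomal background
(1 chromosomal copy + 5 circles; the estimate 5.64 is within the sampling
error of that expectation), 214 reads span the attP junction — a sequence
that does not exist in the intact chromosome — and the element is
therefore called induced. `analysis/02_characterize_genome.py` runs the
genome-characterization layer and reports, among other things, the
spacing census of the published Hardycor1 CDS table: 53 genes, 27
overlapping a neighbour, 13 more within 10 bp.

The same operations are available as subcommands of the `haloprov` CLI
(`simulate`, `kmer-report`, `skew`, `features`, `provirus-scan`,
`induction`, `report`, `screen`).

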