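# Methods

This note records the models, conventions and deliberate choices behind
each analysis layer, what the synthetic-data generator does and does not
emulate, and the numerical details a maintainer would otherwise have to
reverse-engineer from the code.

## Coordinates and topology

All coordinates are 1-based inclusive, the convention of GenBank feature
tables. On circular records a feature may wrap the origin, encoded as
`start > stop`; `span_length` and `subseq` honour the wrap. N bases are
tolerated in host sequences (draft contigs) but rejected inside att cores,
and any k-mer window containing an N is skipped rather than counted.
GC% excludes N from the denominator and rounds half-up to one decimal,
matching how such values are printed in genome reports.

## k-mer census and avoidance

Counts are taken on the forward strand of the deposited sequence; a
circular genome contributes exactly L windows (the census sums to L, a
useful conservation invariant), a linear one L−k+1. The under-
representation statistic is the maximal-order (second-order) Markov odds
ratio ρ(w₁w₂w₃w₄) = N(w₁w₂w₃w₄)·N(w₂w₃) / (N(w₁w₂w₃)·N(w₂w₃w₄)). On an
i.i.d. genome this estimator is unbiased around 1 (property-tested at
1 Mb), and it is undefined — flagged, not silently zero — when a
denominator sub-k-mer is unobserved.

Choices: the under-representation threshold defaults to ρ ≤ 0.15, just
above the largest odds value conventionally still reported as avoided
(0.11); strand pooling is available (`pool_strands`) but off by default —
the headline absences in this problem domain are palindromes, which are
strand-invariant anyway. The 6-mer stage enumerates the 64 palindromic
6-mers, excludes those containing an avoided tetramer as a substring
(recording which core triggered each exclusion), and reports the
zero-count remainder. Collapsing concrete pairs into R/Y degenerate
families (e.g. CTATAG + CTGCAG → CTRYAG) is presentation-only; machine
output always lists concrete motifs.

## Skew profiles

Windows are non-overlapping tiles (default 45 nt) — one value per window
keeps the cumulative series an exact prefix sum, reproducible to the bit
across runs; the final partial window is discarded. A window with no A or
T contributes skew 0 rather than NaN so the cumulative series remains
totally ordered. The reported "inflection" is the window-start coordinate
of the global maximum of the cumulative series (ties to the smallest
coordinate); it is descriptive — no origin-of-replication calling is
attempted.

## Gene architecture

The spacing census counts per gene, not per pair: a CDS is *overlapping*
if it shares ≥1 bp with any coordinate-adjacent CDS (circular adjacency
included, strand ignored), and *close* if it does not overlap but lies
within 10 bp of a neighbour. This rule was fixed by hand-enumerating the
published 53-gene Hardycor1 table before implementation; it reproduces
the published 27 overlapping / 13 close tally exactly, with a gene that
both overlaps one neighbour and sits close to another counted once, in
the overlap tally.

The repeat finder reports maximal exact direct repeats (seed-and-extend
over a min_len-mer index, de-duplicated per offset), sorted by unit
length; `tandem` marks immediately adjacent copies. It is exact-match
only and is property-tested against a quadratic left-maximal-pair oracle
on inputs up to 2 kb.

The slippery-site scanner searches the 3′-terminal 30 codons (default) of
a CDS for heptamers X XXY YYZ with X ≠ Y and Z unconstrained — both
canonical archaeal examples (G GGA AAT, G GGA AAG) satisfy this, and
stricter eukaryotic-style constraints are deliberately not imposed. Hits
are reported 5′→3′ with plus-strand genome coordinates; the 3′-most hit
is the biologically expected one.

Tail-length prediction uses the linear regression L = 0.15·aa − 20.7 nm
for tape measure proteins, reported as ⌊L⌋; the coefficients live in
`TAIL_LENGTH_COEFFS` so an alternative calibration can be swapped in
without touching code. Protein length from a CDS span is (span)/3 − 1
(one stop codon).

## Provirus geometry

The att core is defined as the longest suffix of the tRNA gene occurring
exactly in the element (circular search, so a core straddling the element
origin is found); a floor of 8 bp bounds chance matches — this floor is a
tunable, since real cores in this domain run ~13 bp and no principled
minimum exists. Equally long placements at several positions are returned
flagged ambiguous rather than resolved arbitrarily.

`integrate` linearizes the element immediately after its single att-core
copy and inserts it so the core is duplicated: attL ends the tRNA, attR
closes the element. `excise` is its exact inverse: the circular element
is the host span [attL_start, attR_start−1] (one core copy, placed at
position 1 so attP = 1), and the restored host keeps a single core
(attB). Both are pure coordinate/string operations and are round-trip
tested over 100 random lysogens.

The bridging-CDS scanner works on the integrase strand (elements are
reverse-complemented first if needed): ORFs with archaeal-compatible
starts (ATG/GTG/TTG), ≥150 nt, beginning within 100 bp downstream of the
integrase stop, spanning attP, and ending within 100 bp of (or
overlapping) the next annotated same-strand CDS. The downstream CDS is
verified to encode ≥2 CxxC motifs; failure of that check is a warning
flag, not a rejection. Longest qualifying ORF wins ties. Integrase and
CxxC genes are located by annotation (product strings or locus tags) —
profile/homology searches are out of scope. Coordinates are reported both
on the circle and as the split the ORF would have in the integrated form;
on synthetic lysogens the 5′ fragment is verified never to reach a stop
codon within the provirus.

## Induction evidence

All read evidence uses exact matching; no aligner is involved. This is a
deliberate scope choice: the evidence sought is qualitative
presence/absence of junction sequences and a coarse depth ratio, the
synthetic reads are error-free, and real data at these depths would be
pre-filtered anyway.

- Circular contigs: a terminal overlap of ≥20 bp (exact; configurable)
  identifies a circular assembly, and the unit sequence trims one copy.
- Junction reads: a read counts if it (or its reverse complement)
  contains the exact 40-mer centred on the junction point (20 bp anchors
  each side). The attP junction — the joined termini of the excised
  circle — does not exist in the intact chromosome, so host-only read
  sets yield exactly zero.
- Coverage: reads are placed by their first 31-mer that is unique in the
  host, contributing depth over their footprint; bases inside the att
  cores are excluded from both means because the duplicated core is
  ambiguous by construction. The ratio is inside/outside mean depth.
- Call: `induced` needs ≥2 attP-junction reads and ratio ≥5;
  `excision-only` has the junction evidence without the coverage
  elevation (an element that excises but barely replicates);
  `silent` otherwise. The thresholds are conventions, not reproductions
  of any published cutoff: observed induced proviruses show
  provirus-region coverages tens to hundreds of times the chromosomal
  background, so 5 is conservative, and 2 junction reads excludes
  single-read artifacts.

## The synthetic-data generator

The generator defines the study conditions under which the detectors are
validated:

- Genomes are i.i.d. with P(G)=P(C)=gc/2 — they emulate composition and
  planted structure, not codon usage, oligonucleotide autocorrelation, or
  repeat families of real haloarchaeal genomes.
- Motif depletion substitutes the central base of each occurrence (both
  strands, circular) and re-scans to a fixed point, changing nothing
  else; it emulates the end state of selection, not its dynamics.
- Lysogens: a 72 bp synthetic tRNA whose 3′-terminal 13 bp (default) form
  the att core; the element carries integrase, bridging ORF (wrapping the
  element origin, hence spanning attP) and CxxC CDS on one strand with
  the spacing geometry described above. The lysogen is produced by
  `integrate` itself, so generator truth and detector conventions cannot
  drift apart.
- Reads: error-free 250 nt (a substitution-rate knob exists, default 0),
  uniform start positions, uniform strand, Q40 placeholder qualities.
  Headful virions carry 5% terminal redundancy (within the accepted
  2–10% range for headful packaging). There is no amplification-bias or
  quality model; passing tests therefore demonstrate correctness of the
  detectors' logic and calibration of their statistics, not robustness
  to sequencing error.
- Stock composition: `copy_ratio` is the number of excised circles per
  host chromosome; the chromosome itself carries the provirus too, so the
  expected inside/outside depth ratio is 1 + copy_ratio, and the
  copy-number estimate recovered from a screen is (ratio − 1). Coverage
  is parameterised by the chromosomal (outside) mean depth.

## Problem sizes used in the test battery

The statistical acceptance battery runs at sizes chosen to make each
check decisive on a single CPU: k-mer oracles on 2 kb sequences over 200
seeds; repeat-finder oracles at 0.8–2 kb; integrate/excise round trips on
100 lysogens (6 kb hosts); the induction screen on 50 induced and 50
silent stocks (15 kb hosts, 5 kb elements, 50× chromosomal coverage,
copy ratio 5); copy-ratio recovery at ratios 1, 5 and 20. At 50×
coverage the depth-ratio standard error is well under 2%, so the ±30%
recovery band and the ratio-≥5 call threshold (expected ratio 6 at copy
ratio 5) are tested with wide margins rather than at knife's edge.

## Known limitations

- The bridging-CDS scanner requires a plus-strand integrase annotation;
  minus-strand elements must be reverse-complemented first.
- The repeat finder's relaxed (mismatch-tolerant) mode mentioned for
  20–83 bp intergenic repeat families is not implemented; only exact
  repeats are reported.
- Junction counting is exact-match and will undercount on error-rich
  reads; min_anchor trades sensitivity against chance matches.
- `detect_circular_contig` assumes a clean assembly; chimeric overlaps
  shorter than min_overlap are not considered.
- Sequence-level reproduction of the Hardycor1 characterization requires
  the MT152698 FASTA, which is fetched by `scripts/fetch_accessions.py`
  and not redistributed.
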