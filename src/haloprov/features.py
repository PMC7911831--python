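"""Gene-architecture statistics and small motif analytics.

Covers the descriptive genome-characterization layer: CDS spacing/overlap
census, CxxC zinc-finger-like motif scanning, identical N-terminus lengths,
maximal exact direct-repeat finding, programmed -1 frameshift slippery-site
detection, and tape-measure-protein tail-length prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seqio import GenomeRecord

__all__ = [
    "SpacingStats",
    "RepeatHit",
    "SlipperyHit",
    "spacing_stats",
    "cxxc_scan",
    "longest_common_prefix",
    "find_direct_repeats",
    "find_slippery",
    "tmp_tail_length",
    "protein_len_from_cds",
    "TAIL_LENGTH_COEFFS",
]

# Tail-length regression for siphovirus tape measure proteins:
# tail_nm = slope * n_residues + intercept.  Values are configuration, not
# hard-coded in the function, so an alternative calibration can be swapped in.
TAIL_LENGTH_COEFFS = {"slope_nm_per_aa": 0.15, "intercept_nm": -20.7}


@dataclass
class SpacingStats:
    n_genes: int
    n_overlapping_genes: int  # genes sharing >=1 bp with an adjacent CDS
    n_close_genes: int  # gap to nearest neighbour 1..10 bp, not overlapping
    gaps: list[int]  # per adjacent pair; negative = overlap size


def spacing_stats(record: GenomeRecord, close_max: int = 10) -> SpacingStats:
    """Per-gene overlap and close-spacing census over coordinate-adjacent CDS.

    Adjacency is genome order irrespective of strand; on circular records
    the last and first CDS are also adjacent.  A gene counts once as
    *overlapping* if it intersects any neighbour, and once as *close* if it
    does not overlap but lies within ``close_max`` bp of a neighbour.
    """
    cds = record.cds_features()
    if not cds:
        raise ValueError("record has no CDS features")
    n = len(cds)
    L = len(record.seq)
    overlapping = [False] * n
    close = [False] * n
    gaps: list[int] = []
    pairs = list(zip(range(n - 1), range(1, n)))
    if record.topology == "circular" and n > 1:
        pairs.append((n - 1, 0))
    for i, j in pairs:
        left, right = cds[i], cds[j]
        if j == 0:  # wrap pair on circular record
            gap = (L - left.stop) + (right.start - 1)
        else:
            gap = right.start - left.stop - 1
        gaps.append(gap)
        if gap < 0:
            overlapping[i] = overlapping[j] = True
        elif 1 <= gap <= close_max:
            close[i] = close[j] = True
    n_over = sum(overlapping)
    n_close = sum(c and not o for c, o in zip(close, overlapping))
    return SpacingStats(
        n_genes=n, n_overlapping_genes=n_over, n_close_genes=n_close, gaps=gaps
    )


def cxxc_scan(protein: str) -> list[int]:
    """1-based start positions of CxxC motifs; overlaps allowed."""
    protein = protein.upper()
    return [
        i + 1
        for i in range(len(protein) - 3)
        if protein[i] == "C" and protein[i + 3] == "C"
    ]


def longest_common_prefix(prot_a: str, prot_b: str) -> int:
    """Number of identical N-terminal residues shared by two proteins."""
    if not prot_a or not prot_b:
        raise ValueError("empty protein sequence")
    n = 0
    for a, b in zip(prot_a, prot_b):
        if a != b:
            break
        n += 1
    return n


@dataclass(frozen=True)
class RepeatHit:
    unit_length: int
    copy1_start: int  # 1-based
    copy2_start: int
    tandem: bool  # copy2 immediately follows copy1

    @property
    def span(self) -> tuple[int, int]:
        return self.copy1_start, self.copy2_start + self.unit_length - 1


def find_direct_repeats(seq: str, min_len: int = 20) -> list[RepeatHit]:
    """All maximal exact direct repeats with unit length >= ``min_len``.

    Seed-and-extend over an index of ``min_len``-mers: every repeated pair
    of seed positions is extended maximally left and right, then de-duplicated
    on the maximal pair.  Hits are sorted by unit length descending, then by
    position.  ``tandem`` marks immediately adjacent copies.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    L = len(seq)
    seeds: dict[str, list[int]] = {}
    for i in range(L - min_len + 1):
        seeds.setdefault(seq[i : i + min_len], []).append(i)
    found: set[tuple[int, int, int]] = set()
    for positions in seeds.values():
        if len(positions) < 2:
            continue
        for a_idx in range(len(positions) - 1):
            for b_idx in range(a_idx + 1, len(positions)):
                i, j = positions[a_idx], positions[b_idx]
                while i > 0 and j > 0 and seq[i - 1] == seq[j - 1]:
                    i -= 1
                    j -= 1
                length = min_len + (positions[a_idx] - i)
                while j + length < L and seq[i + length] == seq[j + length]:
                    length += 1
                found.add((length, i, j))
    # drop non-maximal pairs contained in a larger one with the same offset
    maximal = []
    by_offset: dict[int, list[tuple[int, int, int]]] = {}
    for length, i, j in found:
        by_offset.setdefault(j - i, []).append((length, i, j))
    for offset, group in by_offset.items():
        group.sort(key=lambda t: (-t[0], t[1]))
        kept: list[tuple[int, int, int]] = []
        for length, i, j in group:
            if any(ki <= i and i + length <= ki + kl for kl, ki, _ in kept):
                continue
            kept.append((length, i, j))
        maximal.extend(kept)
    hits = [
        RepeatHit(
            unit_length=length,
            copy1_start=i + 1,
            copy2_start=j + 1,
            tandem=(j - i == length),
        )
        for length, i, j in maximal
        if length >= min_len
    ]
    hits.sort(key=lambda h: (-h.unit_length, h.copy1_start, h.copy2_start))
    return hits


@dataclass(frozen=True)
class SlipperyHit:
    start: int  # 1-based genome coordinate (+ strand representation)
    heptamer: str  # XXXYYYZ
    containing_cds: str


def is_slippery(heptamer: str) -> bool:
    """XXXYYYZ predicate: X repeated 3x, Y repeated 3x, X != Y; Z free."""
    if len(heptamer) != 7:
        return False
    x, y = heptamer[0], heptamer[3]
    return (
        heptamer[1] == x
        and heptamer[2] == x
        and heptamer[4] == y
        and heptamer[5] == y
        and x != y
    )


def find_slippery(
    record: GenomeRecord, cds: str, tail_codons: int = 30
) -> list[SlipperyHit]:
    """Scan the 3'-terminal ``tail_codons`` codons of a CDS for -1 slippery
    heptamers of the form X XXY YYZ.

    Hits are reported 5'->3' along the coding strand, with genome
    coordinates given for the + strand representation of the heptamer.
    """
    if tail_codons < 1:
        raise ValueError("tail_codons must be >= 1")
    feat = record.feature_by_tag(cds)  # KeyError if unknown
    coding = record.feature_seq(feat)
    tail_nt = min(tail_codons * 3, len(coding))
    offset0 = len(coding) - tail_nt  # 0-based offset of scan start in CDS
    tail = coding[offset0:]
    L = len(record.seq)
    hits = []
    for i in range(len(tail) - 6):
        hep = tail[i : i + 7]
        if not is_slippery(hep):
            continue
        cds_off = offset0 + i  # 0-based along coding strand
        if feat.strand == "+":
            start = (feat.start - 1 + cds_off) % L + 1
        else:
            # + strand coordinate of the last base of the heptamer's revcomp
            end_off = cds_off + 6
            start = (feat.stop - 1 - end_off) % L + 1
        hits.append(SlipperyHit(start=start, heptamer=hep, containing_cds=cds))
    return hits


def tmp_tail_length(tmp_aa: int) -> int:
    """Predicted siphovirus tail length (nm) from tape-measure-protein size.

    Uses the linear regression in :data:`TAIL_LENGTH_COEFFS`
    (default 0.15 nm/aa - 20.7 nm) and reports floor(nm).
    """
    if tmp_aa < 1:
        raise ValueError("residue count must be positive")
    nm = TAIL_LENGTH_COEFFS["slope_nm_per_aa"] * tmp_aa + TAIL_LENGTH_COEFFS["intercept_nm"]
    return math.floor(nm)


def protein_len_from_cds(start: int, stop: int) -> int:
    """Residue count encoded by a CDS span (1-based inclusive, one stop codon)."""
    span = stop - start + 1
    if span % 3:
        raise ValueError(f"CDS span {span} is not a multiple of 3")
    return span // 3 - 1
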