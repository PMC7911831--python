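"""Read-level evidence for provirus induction.

An induced provirus excises from the chromosome, circularises, and
replicates.  Three signals betray it in a sequenced stock: the excised
genome assembles as a circular contig; reads span the joined termini of
the circle (the attP junction, a sequence absent from the intact
chromosome); and read depth over the provirus region rises above the
chromosomal background.  This module quantifies each signal by exact
matching — no aligner is involved, which is appropriate for the
presence/absence character of the evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import GenomeRecord, reverse_complement

__all__ = [
    "InductionEvidence",
    "detect_circular_contig",
    "junction_sequences",
    "count_spanning_reads",
    "coverage_ratio",
    "classify",
]

JUNCTION_MIN_DEFAULT = 2
RATIO_MIN_DEFAULT = 5.0


@dataclass
class InductionEvidence:
    provirus_id: str
    circular_contig: bool
    unit_length: int
    attP_junction_reads: int
    attB_junction_reads: int
    coverage_inside: float
    coverage_outside: float
    ratio: float
    call: str  # induced | excision-only | silent


def detect_circular_contig(contig: str, min_overlap: int = 20) -> tuple[bool, str]:
    """Recognise a circular assembly by its terminal overlap.

    A contig assembled from a circular template carries its first
    ``min_overlap`` (or more) bases duplicated at its end.  Returns
    ``(is_circular, unit)`` where the unit has one overlap copy trimmed;
    non-circular contigs are returned unchanged.
    """
    if len(contig) <= 2 * min_overlap:
        raise ValueError("contig too short relative to min_overlap")
    best = 0
    for k in range(len(contig) // 2, min_overlap - 1, -1):
        if contig[:k] == contig[-k:]:
            best = k
            break
    if best == 0:
        return False, contig
    return True, contig[:-best]


def junction_sequences(
    host: GenomeRecord,
    provirus_start: int,
    provirus_end: int,
    core_len: int,
    flank: int = 50,
) -> tuple[str, str]:
    """attP and attB junction sequences for a provirus on its host.

    ``provirus_start``/``provirus_end`` delimit the provirus *including*
    attL and attR (``provirus_start`` is the first base of attL,
    ``provirus_end`` the last base of attR).  The attP junction is the
    joined termini of the excised circle (last ``flank`` bases + first
    ``flank`` bases); the attB junction is the restored host around the
    single remaining core.  Both are ``2 * flank`` long with the junction
    point at the centre.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    span = provirus_end - provirus_start + 1
    if flank > span // 2:
        raise ValueError("flank exceeds half the provirus length")
    attL_start = provirus_start
    attR_start = provirus_end - core_len + 1
    # excised circle: [attL_start, attR_start - 1], core-first rotation
    circle = host.seq[attL_start - 1 : attR_start - 1]
    attP = circle[-flank:] + circle[:flank]
    left = host.seq[attL_start - 1 + core_len - flank : attL_start - 1 + core_len]
    right = host.seq[provirus_end : provirus_end + flank]
    if len(left) < flank or len(right) < flank:
        raise ValueError("provirus too close to the host ends for this flank")
    attB = left + right
    return attP, attB


def count_spanning_reads(
    reads: list[str], junction: str, min_anchor: int = 20
) -> int:
    """Count reads containing the junction-centred ``2*min_anchor``-mer.

    A read counts once if it, or its reverse complement, contains the exact
    probe anchored ``min_anchor`` bases each side of the junction point
    (taken to be the centre of ``junction``).
    """
    if len(junction) < 2 * min_anchor:
        raise ValueError("junction shorter than 2 * min_anchor")
    mid = len(junction) // 2
    probe = junction[mid - min_anchor : mid + min_anchor]
    probe_rc = reverse_complement(probe)
    n = 0
    for r in reads:
        if probe in r or probe_rc in r:
            n += 1
    return n


def coverage_ratio(
    reads: list[str],
    host: GenomeRecord,
    provirus_start: int,
    provirus_end: int,
    k: int = 31,
    core_len: int = 0,
) -> tuple[float, float, float]:
    """Mean read depth inside vs outside a provirus region.

    Reads are placed on the host by their first ``k``-mer that is unique in
    the host (either strand); each placed read contributes depth over its
    footprint.  Bases within the att cores are excluded from both means
    (the duplicated core is ambiguous by construction).  Returns
    ``(inside_mean, outside_mean, ratio)`` with ratio ``inf`` when the
    outside mean is 0 and ``0`` when the inside mean is 0.
    """
    H = len(host.seq)
    if provirus_end - provirus_start + 1 >= H:
        raise ValueError("provirus span must be smaller than the host")
    index: dict[str, int] = {}
    dupes: set[str] = set()
    for i in range(H - k + 1):
        kmer = host.seq[i : i + k]
        if kmer in dupes:
            continue
        if kmer in index:
            del index[kmer]
            dupes.add(kmer)
        else:
            index[kmer] = i
    depth = np.zeros(H, dtype=np.int64)
    placed = 0
    for r in reads:
        pos = None
        for orient in (r, reverse_complement(r)):
            for j in range(0, len(orient) - k + 1):
                hit = index.get(orient[j : j + k])
                if hit is not None:
                    pos = hit - j
                    break
            if pos is not None:
                break
        if pos is None:
            continue
        placed += 1
        lo = max(pos, 0)
        hi = min(pos + len(r), H)
        if hi > lo:
            depth[lo:hi] += 1
    if placed == 0:
        raise ValueError("no reads could be placed on the host")
    mask_inside = np.zeros(H, dtype=bool)
    mask_inside[provirus_start - 1 : provirus_end] = True
    excluded = np.zeros(H, dtype=bool)
    if core_len:
        attR_start = provirus_end - core_len + 1
        excluded[provirus_start - 1 : provirus_start - 1 + core_len] = True
        excluded[attR_start - 1 : provirus_end] = True
    inside = float(depth[mask_inside & ~excluded].mean())
    outside = float(depth[~mask_inside & ~excluded].mean())
    if outside == 0:
        ratio = float("inf") if inside > 0 else 0.0
    else:
        ratio = inside / outside
    return inside, outside, ratio


def classify(
    attP_junction_reads: int,
    ratio: float,
    junction_min: int = JUNCTION_MIN_DEFAULT,
    ratio_min: float = RATIO_MIN_DEFAULT,
) -> str:
    """Call a provirus from its junction and coverage evidence.

    ``induced``: excision detected (attP junction reads >= ``junction_min``)
    and the element replicates (depth ratio >= ``ratio_min``).
    ``excision-only``: junction evidence without coverage elevation — the
    pattern of an element that excises but is present in low copy.
    ``silent`` otherwise.
    """
    if attP_junction_reads >= junction_min:
        return "induced" if ratio >= ratio_min else "excision-only"
    return "silent"
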