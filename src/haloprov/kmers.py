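"""k-mer census and motif-avoidance statistics for (circular) viral genomes.

Virus genomes evolving under host restriction-modification pressure deplete
the short motifs their hosts' restriction enzymes recognise, most visibly
palindromes.  This module provides the census (:func:`count_kmers`), the
maximal-order Markov odds ratio that quantifies under-representation
(:func:`markov_odds`), and the combined avoidance report covering absent
tetramers and absent palindromic 6-mers with core-exclusion bookkeeping
(:func:`avoidance_report`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .seqio import GenomeRecord, reverse_complement

__all__ = [
    "count_kmers",
    "markov_odds",
    "palindromic_kmers",
    "avoidance_report",
    "KmerAvoidanceReport",
    "collapse_iupac_families",
]

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_BASES = "ACGT"


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def count_kmers(seq: str, k: int, topology: str = "linear") -> dict[str, int]:
    """Count forward-strand k-mers.

    Circular sequences contribute L windows (wrapping the origin); linear
    sequences L-k+1.  Windows containing N are skipped.
    """
    if not 1 <= k <= 8:
        raise ValueError("k must be in 1..8")
    L = len(seq)
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    s = seq + seq[: k - 1] if topology == "circular" else seq
    codes = _BASE_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    valid = np.ones(n, dtype=bool)
    kmer_codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        col = codes[j : j + n]
        valid &= col >= 0
        kmer_codes = (kmer_codes << 2) | np.where(col >= 0, col, 0)
    uniq, cnt = np.unique(kmer_codes[valid], return_counts=True)
    return {_decode(int(c), k): int(m) for c, m in zip(uniq, cnt)}


def markov_odds(
    counts4: dict[str, int],
    counts3: dict[str, int],
    counts2: dict[str, int],
    motif: str,
) -> float:
    """Maximal-order Markov odds ratio for a tetramer.

    rho(w1w2w3w4) = N(w1w2w3w4) * N(w2w3) / (N(w1w2w3) * N(w2w3w4)).
    Values well below 1 indicate avoidance.  Raises if a denominator
    sub-k-mer is unobserved (the ratio is undefined there).
    """
    if len(motif) != 4:
        raise ValueError("motif must be a tetramer")
    left, right, core = motif[:3], motif[1:], motif[1:3]
    n_left = counts3.get(left, 0)
    n_right = counts3.get(right, 0)
    n_core = counts2.get(core, 0)
    if n_left == 0 or n_right == 0 or n_core == 0:
        raise ZeroDivisionError(
            f"Markov odds undefined for {motif}: zero sub-k-mer count"
        )
    return counts4.get(motif, 0) * n_core / (n_left * n_right)


def palindromic_kmers(k: int) -> list[str]:
    """All self-reverse-complementary k-mers of even length k, sorted."""
    if k % 2:
        raise ValueError("palindromic nucleotide motifs have even length")
    if k > 8:
        raise ValueError("k must be <= 8")
    half = k // 2
    return sorted(
        "".join(p) + reverse_complement("".join(p))
        for p in product(_BASES, repeat=half)
    )


@dataclass
class KmerAvoidanceReport:
    """Absent/under-represented tetramers and absent palindromic 6-mers."""

    k4_counts: dict[str, int]
    odds: dict[str, float]  # absent motifs carry no odds entry
    absent_tetramers: list[str]
    under_represented_tetramers: list[str]
    absent_palindromic_6mers: list[str]
    excluded_6mers: dict[str, str] = field(default_factory=dict)  # motif -> offending core
    odds_threshold: float = 0.15
    undefined_odds: list[str] = field(default_factory=list)

    @property
    def avoided_tetramers(self) -> list[str]:
        return self.absent_tetramers + self.under_represented_tetramers


def avoidance_report(
    record: GenomeRecord,
    odds_threshold: float = 0.15,
    pool_strands: bool = False,
) -> KmerAvoidanceReport:
    """Full motif-avoidance report for a genome.

    Stage 1: tetramers with count 0 are *absent*; tetramers with
    0 < rho <= ``odds_threshold`` are *under-represented*.  Stage 2
    enumerates palindromic 6-mers, excludes any containing an avoided
    tetramer as a substring (the exclusion is recorded with its offending
    core), and reports the zero-count remainder.

    With ``pool_strands`` the census adds reverse-complement counts; the
    default uses the forward strand of the deposited sequence only.
    """
    if len(record.seq) < 4096:
        warnings.warn(
            "genome shorter than ~4 kb: chance absences dominate the 6-mer stage",
            stacklevel=2,
        )

    def census(k: int) -> dict[str, int]:
        c = count_kmers(record.seq, k, record.topology)
        if pool_strands:
            rc = count_kmers(reverse_complement(record.seq), k, record.topology)
            c = {m: c.get(m, 0) + rc.get(m, 0) for m in set(c) | set(rc)}
        return c

    c4, c3, c2 = census(4), census(3), census(2)
    all4 = ["".join(p) for p in product(_BASES, repeat=4)]
    absent = [m for m in all4 if c4.get(m, 0) == 0]
    odds: dict[str, float] = {}
    undefined: list[str] = []
    for m in all4:
        if c4.get(m, 0) == 0:
            continue
        try:
            odds[m] = markov_odds(c4, c3, c2, m)
        except ZeroDivisionError:
            undefined.append(m)
    under = sorted(m for m, r in odds.items() if 0 < r <= odds_threshold)

    avoided = set(absent) | set(under)
    c6 = census(6)
    absent6: list[str] = []
    excluded: dict[str, str] = {}
    for m in palindromic_kmers(6):
        core = next((t for t in avoided if t in m), None)
        if core is not None:
            excluded[m] = core
        elif c6.get(m, 0) == 0:
            absent6.append(m)

    return KmerAvoidanceReport(
        k4_counts={m: c4.get(m, 0) for m in all4},
        odds=odds,
        absent_tetramers=sorted(absent),
        under_represented_tetramers=under,
        absent_palindromic_6mers=absent6,
        excluded_6mers=excluded,
        odds_threshold=odds_threshold,
        undefined_odds=undefined,
    )


_IUPAC_PAIRS = {("A", "G"): "R", ("C", "T"): "Y"}
_PARTNER = {"R": "Y", "Y": "R"}


def collapse_iupac_families(motifs: list[str]) -> list[str]:
    """Presentation-only collapse of palindrome pairs into R/Y families.

    Two palindromic motifs differing only at one position i (purine pair
    A/G) and its complementary position (pyrimidine pair C/T) merge into a
    single degenerate motif, e.g. CTATAG + CTGCAG -> no; CTACAG is not
    palindromic -- the canonical examples are CTRYAG and GRGCYC.  Machine
    output elsewhere always lists concrete motifs.
    """
    motifs = sorted(motifs)
    merged: list[str] = []
    used = [False] * len(motifs)
    for i, a in enumerate(motifs):
        if used[i]:
            continue
        family = a
        for j in range(i + 1, len(motifs)):
            b = motifs[j]
            if used[j] or len(b) != len(a):
                continue
            diff = [p for p in range(len(a)) if a[p] != b[p]]
            if len(diff) != 2:
                continue
            p, q = diff
            if p + q != len(a) - 1:  # must be complementary positions
                continue
            pair_p = tuple(sorted((a[p], b[p])))
            pair_q = tuple(sorted((a[q], b[q])))
            if pair_p in _IUPAC_PAIRS and _IUPAC_PAIRS[pair_p] == _PARTNER.get(
                _IUPAC_PAIRS.get(pair_q, ""), None
            ):
                code_p = _IUPAC_PAIRS[pair_p]
                family = a[:p] + code_p + a[p + 1 : q] + _IUPAC_PAIRS[pair_q] + a[q + 1 :]
                used[j] = True
                break
        used[i] = True
        merged.append(family)
    return merged
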