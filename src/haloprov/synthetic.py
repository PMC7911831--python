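"""Synthetic genomes, lysogens and read sets with a truth ledger.

The generator emulates the composition of sequenced halovirus stocks: a
host chromosome carrying a tRNA-integrated provirus with a duplicated att
core (attL/attR), the excised circular form of that provirus, and virion
templates packaged headfully (circularly permuted, terminally redundant).
Every construction records its ground truth so downstream detectors can be
scored without external data.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds reproduce byte-identical sequences and FASTQ output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .provirus import START_CODONS, STOP_CODONS, integrate
from .seqio import Feature, GenomeRecord, reverse_complement

__all__ = [
    "SyntheticTruth",
    "SimulatedRead",
    "make_genome",
    "deplete_motifs",
    "build_lysogen",
    "simulate_reads",
    "write_fastq",
    "simulate_stock",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# terminal redundancy fraction for headful packaging (fraction of genome
# length duplicated at the ends; 2-10% is the accepted range)
TERMINAL_REDUNDANCY = 0.05


@dataclass
class SyntheticTruth:
    """Ground-truth ledger emitted alongside every synthetic construction."""

    seed: int
    planted_absent_motifs: list[str] = field(default_factory=list)
    provirus: dict = field(default_factory=dict)
    template_abundances: dict[str, float] = field(default_factory=dict)
    slippery_sites: list[tuple[int, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")


def make_genome(length: int, gc: float, seed: int) -> str:
    """i.i.d. random genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def deplete_motifs(seq: str, motifs: list[str], seed: int, max_sweeps: int = 100) -> str:
    """Remove every occurrence of the given motifs (both strands, circular).

    Each occurrence is broken by a single substitution at its central base;
    the sequence is re-scanned until a fixed point.  Length is unchanged.
    """
    if not motifs:
        raise ValueError("motifs must be non-empty")
    if any(len(m) > 8 or len(m) < 2 for m in motifs):
        raise ValueError("motif lengths must be in 2..8")
    rng = np.random.default_rng(seed)
    forbidden = sorted({m.upper() for m in motifs} | {reverse_complement(m.upper()) for m in motifs})
    L = len(seq)
    s = list(seq.upper())
    maxk = max(len(m) for m in forbidden)
    for _ in range(max_sweeps):
        doubled = "".join(s) + "".join(s[: maxk - 1])
        edits: list[int] = []
        for m in forbidden:
            i = doubled.find(m)
            while i != -1:
                edits.append((i + len(m) // 2) % L)
                i = doubled.find(m, i + 1)
        if not edits:
            return "".join(s)
        for pos in sorted(set(edits)):
            old = s[pos]
            choices = [b for b in "ACGT" if b != old]
            s[pos] = choices[int(rng.integers(len(choices)))]
    raise RuntimeError(f"motif depletion did not converge in {max_sweeps} sweeps")


# ---------------------------------------------------------------------------
# lysogen construction

_STOPFREE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c not in START_CODONS
]


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_STOPFREE_CODONS), size=n)
    return "".join(_STOPFREE_CODONS[i] for i in idx)


def _orf(rng: np.random.Generator, nt_len: int) -> str:
    """A clean ORF: ATG + stop-free codons + TAA, total nt_len (multiple of 3)."""
    if nt_len % 3 or nt_len < 9:
        raise ValueError("ORF length must be a multiple of 3, >= 9")
    return "ATG" + _random_codons(rng, nt_len // 3 - 2) + "TAA"


def _cxxc_orf(rng: np.random.Generator, nt_len: int, n_motifs: int = 2) -> str:
    """An ORF whose translation carries ``n_motifs`` CxxC motifs."""
    if nt_len % 3 or nt_len // 3 - 2 < 4 * n_motifs:
        raise ValueError("ORF too short for the requested CxxC motifs")
    n_codons = nt_len // 3 - 2
    motif = ["TGC", "GCA", "GAC", "TGT"]  # C x x C
    body: list[str] = []
    remaining = n_codons - 4 * n_motifs
    spacer = remaining // (n_motifs + 1)
    for _ in range(n_motifs):
        body += [_STOPFREE_CODONS[int(rng.integers(len(_STOPFREE_CODONS)))] for _ in range(spacer)]
        body += motif
    while len(body) < n_codons:
        body.append(_STOPFREE_CODONS[int(rng.integers(len(_STOPFREE_CODONS)))])
    return "ATG" + "".join(body[:n_codons]) + "TAA"


def _has_internal_stop(orf_nt: str) -> bool:
    inner = [orf_nt[i : i + 3] for i in range(3, len(orf_nt) - 3, 3)]
    return any(c in STOP_CODONS for c in inner)


def build_lysogen(
    host_length: int = 15000,
    element_length: int = 5000,
    att_len: int = 13,
    seed: int = 0,
    gc: float = 0.6,
) -> tuple[GenomeRecord, GenomeRecord, SyntheticTruth]:
    """Build a host chromosome with an integrated provirus plus its circle.

    ``host_length`` is the chromosome length *before* integration; the
    returned lysogen is ``host_length + element_length`` bp.  The host
    carries a synthetic tRNA gene whose 3'-terminal ``att_len`` bases are
    duplicated as attL/attR around the element.  The circular element has
    its att core at positions ``1..att_len`` (attP = 1) and carries three
    same-strand planted CDS: an integrase, a bridging ORF that wraps the
    origin (spanning attP), and a CxxC-motif CDS just downstream of the
    bridging stop.

    Returns ``(lysogen, circular element, truth)``; excising the planted
    provirus recovers the element byte-identically.
    """
    if att_len < 8:
        raise ValueError("att_len must be >= 8")
    if element_length < 3 * att_len:
        raise ValueError("element_length must be >= 3 * att_len")
    if element_length < 1200:
        raise ValueError("element_length must be >= 1200 to fit the planted CDS layout")
    rng = np.random.default_rng(seed)
    m, c = element_length, att_len

    # --- element layout (1-based), core at [1..c]:
    #   [core][bridge 3' part ...TAA][gap1][cxxc CDS][filler][integrase][gap2][bridge head ATG...]
    rem = (-c) % 3  # bases completing the codon straddling the core boundary
    post_len = rem + 3 * 38 + 3  # straddle completion + stop-free codons + TAA
    gap1 = 8
    cxxc_len = 210
    integrase_len = 300
    gap2 = 15
    head_len = 90  # bridge head before the origin (ATG + codons, multiple of 3)
    filler_len = m - (c + post_len + gap1 + cxxc_len + integrase_len + gap2 + head_len)
    if filler_len < 50:
        raise ValueError("element_length too small for the planted layout")

    for _attempt in range(500):
        core = make_genome(c, gc, int(rng.integers(2**31)))
        head = "ATG" + _random_codons(rng, head_len // 3 - 1)
        comp = make_genome(rem, gc, int(rng.integers(2**31))) if rem else ""
        post = comp + _random_codons(rng, 38) + "TAA"
        bridge_nt = head + core + post
        if len(bridge_nt) % 3 == 0 and not _has_internal_stop(bridge_nt):
            break
    else:
        raise RuntimeError("could not plant a stop-free bridging ORF")

    cxxc_nt = _cxxc_orf(rng, cxxc_len)
    integrase_nt = _orf(rng, integrase_len)
    filler = make_genome(filler_len, gc, int(rng.integers(2**31)))
    # keep the scanner window between integrase stop and the bridge start
    # free of spurious start codons
    while True:
        gap2_seq = make_genome(gap2, gc, int(rng.integers(2**31)))
        probe = gap2_seq + "AT"  # next two bases are the bridge's A,T
        if not any(probe[i : i + 3] in START_CODONS for i in range(len(probe) - 2)):
            break
    element_seq = core + post + make_genome(gap1, gc, int(rng.integers(2**31))) + cxxc_nt
    element_seq += filler + integrase_nt
    element_seq += gap2_seq + head
    assert len(element_seq) == m

    cxxc_start = c + post_len + gap1 + 1
    integrase_start = cxxc_start + cxxc_len + filler_len
    bridge_start = integrase_start + integrase_len + gap2  # head begins here
    bridge_stop = c + post_len  # wraps the origin
    feats = [
        Feature("CDS", cxxc_start, cxxc_start + cxxc_len - 1, "+", "syn_cxxc", "CxxC motif protein"),
        Feature("CDS", integrase_start, integrase_start + integrase_len - 1, "+", "syn_int", "integrase"),
        Feature("CDS", bridge_start, bridge_stop, "+", "syn_bridge", "hypothetical protein"),
    ]
    element = GenomeRecord(id=f"syn_element_{seed}", seq=element_seq, topology="circular", features=feats)
    # the core must occur exactly once on the circle (both strands)
    doubled = element_seq + element_seq[: c - 1]
    if doubled.count(core) != 1 or reverse_complement(core) in doubled:
        return build_lysogen(host_length, element_length, att_len, seed + 100003, gc)

    # --- host with tRNA gene whose 3' end is the core
    host_seq = make_genome(host_length, gc, int(rng.integers(2**31)))
    trna_len = 72
    t_start = int(0.4 * host_length)  # 1-based
    trna_seq = make_genome(trna_len - c, gc, int(rng.integers(2**31))) + core
    host_seq = host_seq[: t_start - 1] + trna_seq + host_seq[t_start - 1 + trna_len :]
    if host_seq.count(core) != 1 or reverse_complement(core) in host_seq:
        return build_lysogen(host_length, element_length, att_len, seed + 200003, gc)
    site = t_start + trna_len - 1  # host position of the core's last base
    host = GenomeRecord(
        id=f"syn_host_{seed}",
        seq=host_seq,
        topology="linear",
        features=[Feature("tRNA", t_start, site, "+", "syn_trna_pro", "tRNA-Pro")],
    )
    lysogen = integrate(host, site, element, core)
    lysogen.id = f"syn_lysogen_{seed}"

    attL_start = site - c + 1
    attR_start = site + m - c + 1
    truth = SyntheticTruth(
        seed=seed,
        provirus={
            "host_insertion_pos": site,
            "element_length": m,
            "att_core": core,
            "trna_locus": "syn_trna_pro",
            "trna_start": t_start,
            "trna_stop": site,
            "attL_start": attL_start,
            "attR_start": attR_start,
            "integrase_cds": "syn_int",
            "cxxc_cds": "syn_cxxc",
            "bridging_cds": "syn_bridge",
            "bridge_circular_start": bridge_start,
            "bridge_circular_stop": bridge_stop,
            "attP_pos": 1,
        },
    )
    return lysogen, element, truth


# ---------------------------------------------------------------------------
# read simulation

@dataclass(frozen=True)
class SimulatedRead:
    id: str
    seq: str
    template_id: str
    start: int  # 1-based on template (or virion for headful mode)
    strand: str


def simulate_reads(
    templates: list[tuple[GenomeRecord, str, float]],
    n_reads: int,
    read_len: int,
    seed: int,
    error_rate: float = 0.0,
) -> list[SimulatedRead]:
    """Draw error-free reads from a weighted mixture of templates.

    ``templates`` holds ``(record, mode, weight)`` with mode one of
    ``circular`` (start uniform on [1, L], wraps the origin),
    ``headful-linear`` (a virion is cut at a uniform rotation with 5%
    terminal redundancy, then the read is drawn uniformly from it) and
    ``linear`` (uniform, no wrap).  Strand is uniform; an optional uniform
    substitution error rate is applied (default 0).
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    for rec, mode, _w in templates:
        if mode not in ("circular", "headful-linear", "linear"):
            raise ValueError(f"unknown mode {mode!r}")
        if read_len >= len(rec.seq):
            raise ValueError("read_len must be shorter than every template")
    weights = np.array([max(w, 0.0) for _r, _m, w in templates], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("at least one template weight must be positive")
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        t = int(rng.choice(len(templates), p=weights))
        rec, mode, _w = templates[t]
        L = len(rec.seq)
        if mode == "circular":
            start = int(rng.integers(1, L + 1))
            seq = (rec.seq + rec.seq)[start - 1 : start - 1 + read_len]
        elif mode == "headful-linear":
            rot = int(rng.integers(1, L + 1))
            virion_len = int(round(L * (1 + TERMINAL_REDUNDANCY)))
            virion = (rec.seq * 3)[rot - 1 : rot - 1 + virion_len]
            vstart = int(rng.integers(1, virion_len - read_len + 2))
            start = (rot - 1 + vstart - 1) % L + 1
            seq = virion[vstart - 1 : vstart - 1 + read_len]
        else:
            start = int(rng.integers(1, L - read_len + 2))
            seq = rec.seq[start - 1 : start - 1 + read_len]
        strand = "+" if rng.integers(2) == 0 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        if error_rate > 0:
            s = list(seq)
            hits = np.nonzero(rng.random(read_len) < error_rate)[0]
            for p in hits:
                s[p] = "ACGT"[(("ACGT".index(s[p])) + int(rng.integers(1, 4))) % 4]
            seq = "".join(s)
        reads.append(
            SimulatedRead(
                id=f"r{i:06d}|{rec.id}|{start}|{strand}",
                seq=seq,
                template_id=rec.id,
                start=start,
                strand=strand,
            )
        )
    return reads


def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    """Write reads as FASTQ with Q40 placeholder qualities."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences (only) from an uncompressed FASTQ file."""
    seqs: list[str] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ record near {header!r}")
            seqs.append(seq)
    return seqs


def simulate_stock(
    lysogen: GenomeRecord,
    element: GenomeRecord,
    copy_ratio: float,
    mean_coverage: float,
    read_len: int,
    seed: int,
) -> tuple[list[SimulatedRead], dict[str, float]]:
    """Simulate a sequenced virus stock from a lysogen and its excised circle.

    ``copy_ratio`` is the number of excised circles per host chromosome; the
    chromosome itself contributes one further copy of the provirus region,
    so the expected inside/outside depth ratio is ``1 + copy_ratio``.
    ``mean_coverage`` sets the expected chromosomal (outside) depth.
    Returns the reads and the template-abundance mapping used.
    """
    H, m = len(lysogen.seq), len(element.seq)
    w_host = float(H)
    w_elem = float(copy_ratio * m)
    n_host = mean_coverage * H / read_len
    n_elem = mean_coverage * copy_ratio * m / read_len
    n_reads = int(round(n_host + n_elem))
    templates = [(lysogen, "linear", w_host), (element, "circular", w_elem)]
    if w_elem == 0:
        templates = [(lysogen, "linear", w_host)]
    reads = simulate_reads(templates, n_reads, read_len, seed)
    return reads, {lysogen.id: w_host, element.id: w_elem}
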