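"""tRNA-anchored provirus geometry: att cores, integration and excision.

Integrative haloarchaeal viruses insert at a host tRNA gene via site-specific
recombination across a short *att* core identical to the tRNA 3' end.  In
the integrated state the core is duplicated as attL (closing the tRNA) and
attR (closing the element); the circular (excised) form carries a single
copy, attP.  Several pleolipovirus-like elements additionally carry a
"bridging" CDS that spans attP — complete only on the circle, split between
the provirus ends after integration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from Bio.Seq import Seq

from .features import cxxc_scan
from .seqio import Feature, GenomeRecord

__all__ = [
    "ProvirusModel",
    "BridgingCDS",
    "AttHit",
    "find_att_core",
    "integrate",
    "excise",
    "find_bridging_cds",
]

START_CODONS = ("ATG", "GTG", "TTG")  # archaeal-compatible starts
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class AttHit:
    core: str
    length: int
    element_pos: int  # 1-based start of the core in the element
    ambiguous: bool = False
    all_positions: tuple[int, ...] = ()


@dataclass
class BridgingCDS:
    start: int  # circular-form coordinates (may wrap: start > stop)
    stop: int
    strand: str
    # provirus-form split: 5' fragment and 3' fragment host coordinates
    split_5p: tuple[int, int] | None = None
    split_3p: tuple[int, int] | None = None
    cxxc_warning: bool = False  # downstream CDS lacked the expected CxxC pair


@dataclass
class ProvirusModel:
    host_id: str
    trna_locus: str
    att_core: str
    attL_start: int
    attR_start: int
    element_length: int
    integrase_cds: str = ""
    cxxc_cds: str = ""
    bridging_cds: Optional[BridgingCDS] = None

    @property
    def core_len(self) -> int:
        return len(self.att_core)

    @property
    def provirus_span(self) -> tuple[int, int]:
        """Host span including attL and attR."""
        return self.attL_start, self.attR_start + self.core_len - 1


def _circular_find_all(element: GenomeRecord, probe: str) -> list[int]:
    """1-based start positions of ``probe`` in a circular element."""
    if element.topology == "circular":
        hay = element.seq + element.seq[: len(probe) - 1]
    else:
        hay = element.seq
    out = []
    i = hay.find(probe)
    while i != -1:
        out.append(i + 1)
        i = hay.find(probe, i + 1)
    return out


def find_att_core(
    trna_seq: str, element: GenomeRecord, min_len: int = 8
) -> Optional[AttHit]:
    """Longest suffix of a tRNA gene occurring exactly in an element.

    The search is circular (the core may straddle the element origin).
    Returns ``None`` when no suffix of at least ``min_len`` bp matches; when
    the longest matching suffix occurs at several positions the hit is
    flagged ambiguous and all positions are reported.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8 to bound chance matches")
    trna_seq = trna_seq.upper()
    if len(trna_seq) < min_len:
        raise ValueError("tRNA sequence shorter than min_len")
    if "N" in trna_seq:
        raise ValueError("N bases are not allowed in att cores")
    best: Optional[AttHit] = None
    for length in range(len(trna_seq), min_len - 1, -1):
        suffix = trna_seq[-length:]
        positions = _circular_find_all(element, suffix)
        if positions:
            best = AttHit(
                core=suffix,
                length=length,
                element_pos=positions[0],
                ambiguous=len(positions) > 1,
                all_positions=tuple(positions),
            )
            break
    return best


def integrate(
    host: GenomeRecord, site: int, element: GenomeRecord, att_core: str
) -> GenomeRecord:
    """Insert a circular element at a host att site, duplicating the core.

    ``site`` is the host position of the last base of the att core at the
    tRNA 3' end.  The element is linearized immediately after its single
    att-core copy, so the integrated provirus begins just after the tRNA and
    ends with the duplicated core (attR).  Features of both molecules are
    lifted to the new coordinates.
    """
    att_core = att_core.upper()
    c = len(att_core)
    if element.topology != "circular":
        raise ValueError("element must be circular")
    positions = _circular_find_all(element, att_core)
    if len(positions) != 1:
        raise ValueError(
            f"att core must occur exactly once in the element (found {len(positions)})"
        )
    if host.subseq(site - c + 1, site) != att_core:
        raise ValueError("host sequence at the integration site does not end with the att core")
    p = positions[0]  # core start in element
    m = len(element.seq)
    # rotate the element so the core occupies its final c bases:
    # the first base after the core becomes position 1
    rot = element.rotated((p + c - 1) % m + 1)
    insert = rot.seq
    new_seq = host.seq[:site] + insert + host.seq[site:]
    feats = []
    for f in host.features:
        if f.start <= site and f.stop <= site:
            feats.append(f)
        else:
            feats.append(
                replace(
                    f,
                    start=f.start + (m if f.start > site else 0),
                    stop=f.stop + (m if f.stop > site else 0),
                )
            )
    for f in rot.features:
        if f.start <= f.stop:
            feats.append(replace(f, start=f.start + site, stop=f.stop + site))
        else:
            # an origin-wrapping element feature is split by integration:
            # its 5' half ends the provirus, its 3' half starts it
            feats.append(
                replace(f, kind="misc", locus_tag=f"{f.locus_tag}_5p",
                        start=f.start + site, stop=site + m)
            )
            feats.append(
                replace(f, kind="misc", locus_tag=f"{f.locus_tag}_3p",
                        start=site + 1, stop=f.stop + site)
            )
    return GenomeRecord(id=host.id, seq=new_seq, topology=host.topology, features=feats)


def excise(
    host: GenomeRecord, attL_start: int, attR_start: int, core_len: int
) -> tuple[GenomeRecord, GenomeRecord]:
    """Excise a provirus delimited by identical attL/attR cores.

    Returns ``(circular element, restored host)``.  The element is the host
    span ``[attL_start, attR_start + core_len - 1]`` minus one core copy,
    returned as a circle whose first ``core_len`` bases are the att core
    (attP at position 1); the restored host keeps a single core (attB).
    """
    if attR_start <= attL_start:
        raise ValueError("attR must lie right of attL")
    attL = host.subseq(attL_start, attL_start + core_len - 1)
    attR = host.subseq(attR_start, attR_start + core_len - 1)
    if attL != attR:
        raise ValueError("att repeats differ; not a provirus boundary pair")
    m = attR_start - attL_start  # element length
    if m <= core_len:
        raise ValueError("degenerate provirus: att copies abut or overlap")
    element_seq = host.seq[attL_start - 1 : attR_start - 1]
    element = GenomeRecord(
        id=f"{host.id}|excised_{attL_start}_{attR_start}",
        seq=element_seq,
        topology="circular",
        features=[
            replace(f, start=f.start - attL_start + 1, stop=f.stop - attL_start + 1)
            for f in host.features
            if attL_start <= f.start <= f.stop < attR_start
        ],
    )
    restored_seq = host.seq[: attL_start + core_len - 1] + host.seq[attR_start + core_len - 1 :]
    feats = []
    for f in host.features:
        if f.stop < attL_start + core_len:
            feats.append(f)
        elif f.start > attR_start + core_len - 1:
            feats.append(replace(f, start=f.start - m, stop=f.stop - m))
    restored = GenomeRecord(
        id=host.id, seq=restored_seq, topology=host.topology, features=feats
    )
    return element, restored


def _orf_at(seq_2x: str, start0: int, max_len: int) -> Optional[int]:
    """0-based exclusive stop offset of the ORF starting at ``start0``."""
    if seq_2x[start0 : start0 + 3] not in START_CODONS:
        return None
    i = start0
    while i + 3 <= len(seq_2x) and i - start0 < max_len:
        codon = seq_2x[i : i + 3]
        if codon in STOP_CODONS:
            return i + 3
        i += 3
    return None


def find_bridging_cds(
    element: GenomeRecord,
    attP_pos: int,
    integrase: str,
    max_gap: int = 100,
    min_orf_nt: int = 150,
    core_len: int | None = None,
) -> Optional[BridgingCDS]:
    """Locate the CDS that spans attP between integrase and CxxC genes.

    Scans the integrase strand for ORFs (ATG/GTG/TTG start, >=``min_orf_nt``)
    that begin within ``max_gap`` bp downstream of the integrase stop, span
    ``attP_pos``, and end within ``max_gap`` bp of (or overlapping) the next
    annotated downstream CDS.  The downstream CDS is verified to encode >=2
    CxxC motifs; if it does not, the hit is returned with a warning flag.
    Longest qualifying ORF wins ties.  Coordinates are reported both on the
    circle and split as they would appear in the integrated (provirus) form.
    """
    if element.topology != "circular":
        raise ValueError("bridging-CDS scan requires a circular element")
    try:
        int_feat = element.feature_by_tag(integrase)
    except KeyError as exc:
        raise ValueError(f"integrase CDS {integrase!r} not annotated") from exc
    m = len(element.seq)
    strand = int_feat.strand
    if strand == "-":
        raise NotImplementedError(
            "bridging-CDS scan is implemented for + strand integrases; "
            "reverse-complement the element first"
        )
    # linearize on a doubled sequence so ORFs can wrap the origin
    seq2 = element.seq + element.seq
    int_stop0 = int_feat.stop  # 0-based position just after integrase stop
    candidates = []
    for s0 in range(int_stop0, int_stop0 + max_gap + 1):
        end0 = _orf_at(seq2, s0, max_len=m)
        if end0 is None or end0 - s0 < min_orf_nt:
            continue
        # must span attP (positions are on the circle)
        attP0 = (attP_pos - 1) % m
        rel = (attP0 - s0) % m
        if not rel < (end0 - s0):
            continue
        candidates.append((s0, end0))
    if not candidates:
        return None
    # next downstream annotated CDS after the integrase (other than itself)
    others = [
        f
        for f in element.cds_features()
        if f.locus_tag != integrase and f.strand == strand
    ]

    def dist_downstream(f: Feature) -> int:
        return (f.start - 1 - int_stop0) % m

    others.sort(key=dist_downstream)
    best: Optional[tuple[int, int, Feature]] = None
    for s0, end0 in sorted(candidates, key=lambda c: -(c[1] - c[0])):
        for f in others:
            f_start0 = (f.start - 1) % m
            rel_start = (f_start0 - s0) % m
            if rel_start == 0:
                continue  # the candidate ORF's own annotation
            gap = (f_start0 - end0) % m
            overlaps = rel_start < (end0 - s0)
            if overlaps or gap <= max_gap:
                best = (s0, end0, f)
                break
        if best:
            break
    if best is None:
        return None
    s0, end0, downstream = best
    n_cxxc = len(cxxc_scan(str(Seq(element.feature_seq(downstream)).translate())))
    start = s0 % m + 1
    stop = (end0 - 1) % m + 1
    bridging = BridgingCDS(
        start=start,
        stop=stop,
        strand=strand,
        cxxc_warning=n_cxxc < 2,
    )
    # provirus-form split: integration cuts the circle at the end of the att
    # core, so express the ORF in coordinates of the linearized insert that
    # begins immediately after the core.  An ORF spanning attP wraps that
    # origin and splits into a 5' fragment ending the provirus and a 3'
    # fragment starting it.
    if core_len is not None:
        o0 = (attP_pos - 1 + core_len) % m  # 0-based insert origin on the circle
        ins_start = (s0 - o0) % m + 1
        ins_stop = (end0 - 1 - o0) % m + 1
        if ins_start > ins_stop:
            bridging.split_5p = (ins_start, m)
            bridging.split_3p = (1, ins_stop)
        else:
            bridging.split_5p = (ins_start, ins_stop)
            bridging.split_3p = None
    return bridging
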