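"""Combined per-genome characterization report and stock screening.

``run_genome_report`` aggregates the descriptive analyses (length, GC%,
motif avoidance, skew extremum, gene spacing, CxxC census, repeats,
slippery sites) into one JSON-serialisable dict; ``run_stock_screen``
applies the induction evidence pipeline to each candidate provirus of a
sequenced stock.  Both embed their full configuration for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from typing import Any

from Bio.Seq import Seq

from . import __version__
from .features import cxxc_scan, find_direct_repeats, find_slippery, spacing_stats
from .induction import (
    InductionEvidence,
    classify,
    count_spanning_reads,
    coverage_ratio,
    junction_sequences,
)
from .kmers import avoidance_report
from .seqio import GenomeRecord, gc_percent
from .skew import at_skew_profile, inflection

log = logging.getLogger("haloprov")

__all__ = ["run_genome_report", "run_stock_screen"]


def _translate(record: GenomeRecord, feat) -> str:
    nt = record.feature_seq(feat)
    nt = nt[: len(nt) - len(nt) % 3]
    return str(Seq(nt).translate()).rstrip("*")


def run_genome_report(
    record: GenomeRecord,
    window: int = 45,
    odds_threshold: float = 0.15,
    repeat_min_len: int = 100,
    slippery_tail_codons: int = 30,
) -> dict[str, Any]:
    """Characterize one genome; sections needing annotation are marked
    absent when the record carries no CDS features."""
    config = {
        "version": __version__,
        "window": window,
        "odds_threshold": odds_threshold,
        "repeat_min_len": repeat_min_len,
        "slippery_tail_codons": slippery_tail_codons,
    }
    rep: dict[str, Any] = {
        "id": record.id,
        "topology": record.topology,
        "length": len(record.seq),
        "gc_percent": gc_percent(record.seq),
        "config": config,
    }
    av = avoidance_report(record, odds_threshold=odds_threshold)
    rep["kmer_avoidance"] = {
        "absent_tetramers": av.absent_tetramers,
        "under_represented_tetramers": av.under_represented_tetramers,
        "odds": {m: round(r, 4) for m, r in sorted(av.odds.items())},
        "absent_palindromic_6mers": av.absent_palindromic_6mers,
        "excluded_6mers": av.excluded_6mers,
    }
    prof = at_skew_profile(record, window=window)
    rep["at_skew"] = {
        "window": window,
        "cumulative_max_coordinate": inflection(prof),
        "cumulative_max_value": max(prof.cumulative),
    }
    rep["repeats"] = [
        asdict(h) for h in find_direct_repeats(record.seq, min_len=repeat_min_len)[:20]
    ]
    cds = record.cds_features()
    if cds:
        sp = spacing_stats(record)
        rep["spacing"] = {
            "n_genes": sp.n_genes,
            "n_overlapping_genes": sp.n_overlapping_genes,
            "n_close_genes": sp.n_close_genes,
        }
        census = {}
        slippery = []
        for f in cds:
            try:
                hits = cxxc_scan(_translate(record, f))
            except Exception as exc:  # translation failure should name the stage
                log.warning("cxxc stage: skipping %s (%s)", f.locus_tag, exc)
                continue
            if hits:
                census[f.locus_tag or f"{f.start}-{f.stop}"] = len(hits)
            for hit in find_slippery(record, f.locus_tag, slippery_tail_codons) if f.locus_tag else []:
                slippery.append(asdict(hit))
        rep["cxxc_census"] = census
        rep["slippery_hits"] = slippery
    else:
        rep["spacing"] = None
        rep["cxxc_census"] = None
        rep["slippery_hits"] = None
    return rep


def run_stock_screen(
    reads: list[str],
    hosts: dict[str, GenomeRecord],
    provirus_table: list[dict[str, Any]],
    junction_min: int = 2,
    ratio_min: float = 5.0,
    min_anchor: int = 20,
    flank: int = 50,
) -> list[InductionEvidence]:
    """Screen a read set against candidate proviruses.

    Each ``provirus_table`` row needs ``provirus_id``, ``host_id``,
    ``start``, ``end`` (host coordinates including attL/attR) and
    ``core_len``.  Rows with missing coordinates are skipped with a
    warning.  Returns one evidence row per candidate; all-silent results
    are a normal outcome, not an error.
    """
    if not reads:
        raise ValueError("empty read set: nothing to screen")
    out: list[InductionEvidence] = []
    for row in provirus_table:
        try:
            host = hosts[row["host_id"]]
            start, end, core_len = int(row["start"]), int(row["end"]), int(row["core_len"])
        except (KeyError, TypeError, ValueError) as exc:
            log.warning("screen: skipping row %r (%s)", row, exc)
            continue
        attP, attB = junction_sequences(host, start, end, core_len, flank=flank)
        n_attP = count_spanning_reads(reads, attP, min_anchor=min_anchor)
        n_attB = count_spanning_reads(reads, attB, min_anchor=min_anchor)
        inside, outside, ratio = coverage_ratio(
            reads, host, start, end, core_len=core_len
        )
        call = classify(n_attP, ratio, junction_min=junction_min, ratio_min=ratio_min)
        out.append(
            InductionEvidence(
                provirus_id=str(row["provirus_id"]),
                circular_contig=False,
                unit_length=end - start + 1 - core_len,
                attP_junction_reads=n_attP,
                attB_junction_reads=n_attB,
                coverage_inside=inside,
                coverage_outside=outside,
                ratio=ratio,
                call=call,
            )
        )
    return out
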