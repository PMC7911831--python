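"""Genome records, coordinate arithmetic, and standard-format I/O.

All coordinates are 1-based inclusive (GenBank convention).  On circular
records a feature may wrap the origin, encoded as ``start > stop``.  Every
other module builds on the :class:`GenomeRecord` container and the two
arithmetic helpers :func:`span_length` and :func:`gc_percent`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Feature",
    "GenomeRecord",
    "span_length",
    "gc_percent",
    "reverse_complement",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
]

_COMPLEMENT = str.maketrans("ACGTNRYacgtnry", "TGCANYRtgcanyr")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC R/Y aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a genome.

    ``start``/``stop`` are 1-based inclusive; ``start > stop`` encodes a
    feature wrapping the origin of a circular record.
    """

    kind: str  # CDS, tRNA, repeat_region, misc
    start: int
    stop: int
    strand: str = "+"
    locus_tag: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("CDS", "tRNA", "repeat_region", "misc"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class GenomeRecord:
    """A nucleotide sequence with topology and an ordered feature table."""

    id: str
    seq: str
    topology: str = "linear"  # or "circular"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular or linear, got {self.topology!r}")
        self.seq = self.seq.upper()
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        L = len(self.seq)
        for f in self.features:
            if not (1 <= f.start <= L and 1 <= f.stop <= L):
                raise ValueError(
                    f"feature {f.locus_tag or f.kind} coordinates {f.start}..{f.stop} "
                    f"outside [1, {L}]"
                )
            if f.start > f.stop and self.topology != "circular":
                raise ValueError(
                    f"wrap-around feature {f.locus_tag or f.kind} on a linear record"
                )
            if f.kind == "CDS" and self.topology == "linear":
                if self.feature_span(f) % 3:
                    warnings.warn(
                        f"CDS {f.locus_tag} span {self.feature_span(f)} not a "
                        "multiple of 3 on linear record",
                        stacklevel=2,
                    )
        self.features.sort(key=lambda f: (f.start, f.stop))

    def __len__(self) -> int:
        return len(self.seq)

    def feature_span(self, feat: Feature) -> int:
        return span_length(feat.start, feat.stop, len(self.seq), self.topology)

    def subseq(self, start: int, stop: int) -> str:
        """Extract [start, stop] (1-based inclusive), wrapping if circular."""
        L = len(self.seq)
        if not (1 <= start <= L and 1 <= stop <= L):
            raise ValueError(f"coordinates {start}..{stop} outside [1, {L}]")
        if start <= stop:
            return self.seq[start - 1 : stop]
        if self.topology != "circular":
            raise ValueError("wrap-around extraction on a linear record")
        return self.seq[start - 1 :] + self.seq[:stop]

    def feature_seq(self, feat: Feature) -> str:
        """Coding-strand sequence of a feature."""
        s = self.subseq(feat.start, feat.stop)
        return reverse_complement(s) if feat.strand == "-" else s

    def cds_features(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "CDS"]

    def feature_by_tag(self, locus_tag: str) -> Feature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(f"no feature with locus_tag {locus_tag!r}")

    def rotated(self, new_origin: int) -> "GenomeRecord":
        """Rotate a circular record so position ``new_origin`` becomes 1.

        Features are re-based; the feature table is re-sorted.
        """
        if self.topology != "circular":
            raise ValueError("only circular records can be rotated")
        L = len(self.seq)
        shift = new_origin - 1

        def move(p: int) -> int:
            return (p - 1 - shift) % L + 1

        feats = [replace(f, start=move(f.start), stop=move(f.stop)) for f in self.features]
        return GenomeRecord(
            id=self.id,
            seq=self.seq[shift:] + self.seq[:shift],
            topology="circular",
            features=feats,
        )


def span_length(start: int, stop: int, record_length: int, topology: str = "linear") -> int:
    """Length in bp of the 1-based inclusive span [start, stop].

    On circular records ``stop < start`` wraps the origin.
    """
    if not (1 <= start <= record_length and 1 <= stop <= record_length):
        raise ValueError(
            f"coordinates {start}..{stop} outside [1, {record_length}]"
        )
    if stop >= start:
        return stop - start + 1
    if topology != "circular":
        raise ValueError("stop < start on a linear record")
    return record_length - start + 1 + stop


def gc_percent(seq: str) -> float:
    """G+C content as a percentage, rounded half-up to 1 decimal.

    N bases are excluded from the denominator; an all-N sequence is an error.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    pct = Decimal(100 * gc) / Decimal(acgt)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# GenBank

_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "repeat_region": "repeat_region"}


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read a GenBank flat file into a :class:`GenomeRecord`.

    Topology is taken from the LOCUS line; features are kept in coordinate
    order.  A CDS with a non-multiple-of-3 span on a linear record raises a
    warning but is kept.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    topology = rec.annotations.get("topology", "linear")
    feats = []
    for f in rec.features:
        kind = _KIND_MAP.get(f.type)
        if kind is None:
            if f.type == "source":
                continue
            kind = "misc"
        start = int(f.location.start) + 1
        stop = int(f.location.end)
        # compound wrap-around location on circular records
        if len(getattr(f.location, "parts", [])) > 1 and topology == "circular":
            parts = sorted(f.location.parts, key=lambda p: int(p.start))
            if int(parts[0].start) == 0 and int(parts[-1].end) == len(rec.seq):
                start = int(parts[-1].start) + 1
                stop = int(parts[0].end)
        strand = "-" if f.location.strand == -1 else "+"
        feats.append(
            Feature(
                kind=kind,
                start=start,
                stop=stop,
                strand=strand,
                locus_tag=str(f.qualifiers.get("locus_tag", [""])[0]),
                product=str(f.qualifiers.get("product", [""])[0]),
            )
        )
    return GenomeRecord(id=rec.id, seq=str(rec.seq), topology=topology, features=feats)


def write_genbank(record: GenomeRecord, path: str | Path) -> None:
    """Write a :class:`GenomeRecord` as a GenBank flat file (round-trips)."""
    L = len(record.seq)
    feats = []
    for f in record.features:
        if f.start <= f.stop:
            loc = FeatureLocation(f.start - 1, f.stop, strand=1 if f.strand == "+" else -1)
        else:  # origin-wrapping feature on a circular record
            strand = 1 if f.strand == "+" else -1
            loc = FeatureLocation(f.start - 1, L, strand=strand) + FeatureLocation(
                0, f.stop, strand=strand
            )
        quals: dict[str, list[str]] = {}
        if f.locus_tag:
            quals["locus_tag"] = [f.locus_tag]
        if f.product:
            quals["product"] = [f.product]
        ftype = f.kind if f.kind != "misc" else "misc_feature"
        feats.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    rec = SeqRecord(
        Seq(record.seq),
        id=record.id,
        name=record.id[:16],
        description="",
        features=feats,
        annotations={"molecule_type": "DNA", "topology": record.topology},
    )
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, topology: str = "linear") -> GenomeRecord:
    rec = SeqIO.read(str(path), "fasta")
    return GenomeRecord(id=rec.id, seq=str(rec.seq), topology=topology)


def write_fasta(record: GenomeRecord, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.id} topology={record.topology}\n")
        for i in range(0, len(record.seq), width):
            fh.write(record.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (minimal: 9-column core, locus_tag/product/ID attributes)

_GFF_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "repeat_region": "repeat_region"}


def read_gff3(path: str | Path) -> list[Feature]:
    """Read features from a GFF3 file (product taken from the product attribute)."""
    feats = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns")
        _, _, ftype, start, stop, _, strand, _, attrs = cols
        kind = _GFF_KINDS.get(ftype, "misc")
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
        )
        feats.append(
            Feature(
                kind=kind,
                start=int(start),
                stop=int(stop),
                strand=strand if strand in "+-" else "+",
                locus_tag=attr.get("locus_tag", attr.get("ID", "")),
                product=attr.get("product", ""),
            )
        )
    feats.sort(key=lambda f: (f.start, f.stop))
    return feats


def write_gff3(record: GenomeRecord, path: str | Path) -> None:
    lines = ["##gff-version 3", f"##sequence-region {record.id} 1 {len(record.seq)}"]
    for f in record.features:
        ftype = f.kind if f.kind != "misc" else "misc_feature"
        attrs = []
        if f.locus_tag:
            attrs.append(f"ID={f.locus_tag};locus_tag={f.locus_tag}")
        if f.product:
            attrs.append(f"product={f.product}")
        lines.append(
            "\t".join(
                [
                    record.id,
                    "haloprov",
                    ftype,
                    str(f.start),
                    str(f.stop),
                    ".",
                    f.strand,
                    ".",
                    ";".join(attrs) or ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_features_tsv(path: str | Path) -> list[Feature]:
    """Read a simple CDS coordinate table (start, stop, locus_tag, length, direction).

    Accepts the tab-separated layout used for published annotation tables.
    """
    feats: list[Feature] = []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = [c.strip() for c in line.split("\t")]
        if header is None:
            header = [c.lower() for c in cols]
            continue
        row = dict(zip(header, cols))
        feats.append(
            Feature(
                kind=row.get("kind", "CDS"),
                start=int(row["start"].replace(",", "")),
                stop=int(row["stop"].replace(",", "")),
                strand=row.get("direction", row.get("strand", "+")).replace("–", "-") or "+",
                locus_tag=row.get("locus_tag", row.get("locus tag", "")),
                product=row.get("product", ""),
            )
        )
    feats.sort(key=lambda f: (f.start, f.stop))
    return feats
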