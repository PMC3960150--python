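"""Coordinate/sequence/annotation data model and text-format I/O.

Internal convention: every coordinate is 0-based half-open on the forward
strand of its contig.  Conversion to 1-based inclusive (GTF) or 0-based
half-open (BED/bedGraph) happens only at file boundaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open, stranded."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.contig}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def expanded(self, pad: int, contig_length: Optional[int] = None) -> "Interval":
        start = max(0, self.start - pad)
        end = self.end + pad
        if contig_length is not None:
            end = min(end, contig_length)
        return replace(self, start=start, end=end)


@dataclass
class Genome:
    """Named uppercase nucleotide sequences."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for contig {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"illegal character {sorted(bad)[0]!r} in contig {name!r}"
                )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self.sequences == other.sequences

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])

    def fetch(self, iv: Interval) -> str:
        """Sequence of the interval; reverse-complemented for '-' strand."""
        seq = self.sequences[iv.contig][iv.start : iv.end]
        return revcomp(seq) if iv.strand == "-" else seq


@dataclass(frozen=True)
class CdsSegment:
    """One exon's coding portion with its GTF frame.

    ``phase`` follows the GTF frame column: the number of bases to skip at the
    segment start to reach the first base of a complete codon.
    """

    interval: Interval
    phase: int

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"bad phase {self.phase}")


@dataclass
class GeneModel:
    """Stranded multi-exon gene with optional CDS and named protein domains.

    ``exons`` are kept in transcription order (reversed genomic order on the
    minus strand); ``cds`` parallels a subset of exons; ``domains`` maps a
    domain name (e.g. "kinase") to its genomic interval within the CDS.
    """

    gene_id: str
    span: Interval
    exons: list[Interval]
    cds: Optional[list[CdsSegment]] = None
    domains: dict[str, Interval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in itertools.pairwise(genomic):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        expect = genomic if self.span.strand == "+" else genomic[::-1]
        if list(self.exons) != expect:
            raise ValueError(f"exons of {self.gene_id} not in transcription order")

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def contig(self) -> str:
        return self.span.contig

    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def introns(self) -> list[Interval]:
        """Introns in transcription order."""
        out = []
        for a, b in itertools.pairwise(self.exons):
            lo, hi = (a.end, b.start) if self.strand == "+" else (b.end, a.start)
            out.append(Interval(self.contig, lo, hi, self.strand))
        return out

    def spliced_sequence(self, genome: Genome) -> str:
        return "".join(genome.fetch(replace(e, strand=self.strand)) for e in self.exons)

    def unspliced_sequence(self, genome: Genome) -> str:
        return genome.fetch(self.span)

    def cds_sequence(self, genome: Genome) -> str:
        if self.cds is None:
            raise ValueError(f"gene {self.gene_id} has no CDS")
        return "".join(
            genome.fetch(replace(seg.interval, strand=self.strand)) for seg in self.cds
        )


@dataclass
class ReadPair:
    """A paired-end fragment's two mates; origin tags the assay type."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    origin: str = "rnaseq"

    def __post_init__(self) -> None:
        for seq in (self.seq1, self.seq2):
            if set(seq) - VALID_BASES:
                raise ValueError(f"illegal base in read {self.read_id}")


@dataclass
class Alignment:
    """Placement of one mate; split alignments carry >1 segment.

    ``segments`` is a list of ``((qstart, qend), Interval)`` pairs, disjoint in
    query coordinates and ordered along the reference.
    """

    read_id: str
    mate: int
    interval: Interval
    aligned_length: int
    segments: list[tuple[tuple[int, int], Interval]] = field(default_factory=list)
    unique: bool = True

    def __post_init__(self) -> None:
        if not self.segments:
            self.segments = [((0, self.aligned_length), self.interval)]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate contig {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(f"illegal character {sorted(bad)[0]!r} in contig {rec.id!r}")
        if not seq:
            raise FormatError(f"empty sequence for contig {rec.id!r}")
        sequences[rec.id] = seq
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
    return path


# ---------------------------------------------------------------------------
# FASTQ (paired files)
# ---------------------------------------------------------------------------

def read_fastq(path1: str | Path, path2: str | Path, origin: str = "rnaseq") -> Iterator[ReadPair]:
    """Iterate index-aligned mate files as ReadPairs."""
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for rec1, rec2 in itertools.zip_longest(it1, it2):
        if rec1 is None or rec2 is None:
            raise FormatError("mate files have different record counts")
        id1 = rec1.id.removesuffix("/1")
        id2 = rec2.id.removesuffix("/2")
        if id1 != id2:
            raise FormatError(f"read_id mismatch: {rec1.id!r} vs {rec2.id!r}")
        q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
        yield ReadPair(id1, str(rec1.seq).upper(), q1, str(rec2.seq).upper(), q2, origin)


def write_fastq(pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _gtf_attributes(gene_id: str, extra: Optional[dict[str, str]] = None) -> str:
    parts = [f'gene_id "{gene_id}"', f'transcript_id "{gene_id}.t1"']
    for key, val in (extra or {}).items():
        parts.append(f'{key} "{val}"')
    return "; ".join(parts) + ";"


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def write_gtf(models: Sequence[GeneModel], path: str | Path, source: str = "fusionsurvey") -> Path:
    """Emit gene/exon/CDS/domain feature rows, 1-based inclusive coordinates."""
    path = Path(path)
    with open(path, "w") as fh:
        for m in models:
            rows: list[tuple[Interval, str, str, str]] = [
                (m.span, "gene", ".", _gtf_attributes(m.gene_id))
            ]
            for e in m.exons:
                rows.append((e, "exon", ".", _gtf_attributes(m.gene_id)))
            for seg in m.cds or []:
                rows.append((seg.interval, "CDS", str(seg.phase), _gtf_attributes(m.gene_id)))
            for name, iv in m.domains.items():
                rows.append(
                    (iv, "domain", ".", _gtf_attributes(m.gene_id, {"domain_id": name}))
                )
            for iv, feature, frame, attrs in rows:
                fh.write(
                    "\t".join(
                        [
                            iv.contig,
                            source,
                            feature,
                            str(iv.start + 1),  # GTF is 1-based inclusive
                            str(iv.end),
                            ".",
                            m.strand,
                            frame,
                            attrs,
                        ]
                    )
                    + "\n"
                )
    return path


def read_gtf(path: str | Path) -> list[GeneModel]:
    spans: dict[str, Interval] = {}
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[CdsSegment]] = {}
    domains: dict[str, dict[str, Interval]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 columns")
            contig, _src, feature, start, end, _score, strand, frame, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinate") from exc
            if end_i < start_i:
                raise FormatError(f"line {lineno}: end < start")
            if strand not in "+-":
                raise FormatError(f"line {lineno}: unknown strand {strand!r}")
            iv = Interval(contig, start_i - 1, end_i, strand)
            gene_id = _parse_attributes(attrs).get("gene_id")
            if gene_id is None:
                raise FormatError(f"line {lineno}: missing gene_id")
            if gene_id not in spans and gene_id not in exons:
                order.append(gene_id)
            if feature == "gene":
                spans[gene_id] = iv
            elif feature == "exon":
                exons.setdefault(gene_id, []).append(iv)
            elif feature == "CDS":
                if frame not in ("0", "1", "2"):
                    raise FormatError(f"line {lineno}: CDS needs a frame")
                cds.setdefault(gene_id, []).append(CdsSegment(iv, int(frame)))
            elif feature == "domain":
                name = _parse_attributes(attrs).get("domain_id", "domain")
                domains.setdefault(gene_id, {})[name] = iv

    models = []
    for gene_id in order:
        if gene_id not in exons:
            raise FormatError(f"gene {gene_id} has no exon rows")
        exs = sorted(exons[gene_id], key=lambda e: e.start)
        span = spans.get(gene_id)
        strand = span.strand if span else exs[0].strand
        if strand == "-":
            exs = exs[::-1]
        if span is None:
            lo = min(e.start for e in exs)
            hi = max(e.end for e in exs)
            span = Interval(exs[0].contig, lo, hi, strand)
        segs = cds.get(gene_id)
        if segs is not None:
            segs = sorted(segs, key=lambda s: s.interval.start)
            if strand == "-":
                segs = segs[::-1]
        models.append(GeneModel(gene_id, span, exs, segs, domains.get(gene_id, {})))
    return models


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected >=3 BED columns")
            out.append(Interval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path, names: Optional[Sequence[str]] = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\n")
    return path


def write_bedgraph(depths: Sequence[int] | np.ndarray, contig: str, path: str | Path) -> Path:
    """Run-length encode a per-base depth vector; zero-depth runs omitted."""
    depths = np.asarray(depths)
    if depths.size and depths.min() < 0:
        raise ValueError("negative depth")
    path = Path(path)
    with open(path, "w") as fh:
        start = 0
        for value, run in _runs(depths):
            if value > 0:
                fh.write(f"{contig}\t{start}\t{start + run}\t{value}\n")
            start += run
    return path


def _runs(values: np.ndarray) -> Iterator[tuple[int, int]]:
    if values.size == 0:
        return
    change = np.flatnonzero(np.diff(values)) + 1
    bounds = np.concatenate([[0], change, [values.size]])
    for lo, hi in itertools.pairwise(bounds):
        yield int(values[lo]), int(hi - lo)


def read_bedgraph(path: str | Path, contig: str, length: int) -> np.ndarray:
    """Expand a bedGraph file back into a per-base depth vector."""
    depths = np.zeros(length, dtype=int)
    with open(path) as fh:
        for line in fh:
            fields = line.split("\t")
            if fields[0] != contig:
                continue
            depths[int(fields[1]) : int(fields[2])] = int(float(fields[3]))
    return depths


# ---------------------------------------------------------------------------
# Optional SAM debug dump (minimal dialect)
# ---------------------------------------------------------------------------

def write_sam(alignments: Iterable[tuple[Alignment, str]], genome: Genome, path: str | Path) -> Path:
    """Debug dump of (alignment, read sequence) pairs in a minimal SAM dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for aln, seq in alignments:
            flag = 16 if aln.interval.strand == "-" else 0
            cigar = f"{aln.aligned_length}M"
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.interval.contig}\t{aln.interval.start + 1}"
                f"\t255\t{cigar}\t*\t0\t0\t{seq}\t*\n"
            )
    return path
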