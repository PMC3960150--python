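"""Breakpoint evidence stack: coverage discontinuity, chimeric splice-junction
reads, DNA-level fusion-point mapping and micro-homology resolution.

The DNA fusion point is recovered from 76-nt reads that straddle it: each
read is decomposed into its longest exact prefix within the 5' gene and its
longest exact suffix within the 3' gene; the overlap of the two maximal
extensions IS the micro-homology, and the break coordinate is ambiguous
exactly within that interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_model import Alignment, Genome, GeneModel, Interval, ReadPair, revcomp
from .mapper import KmerIndex, SplicedAligner, TrimStats, build_index, map_pair_exact, trim_reads


class BreakpointError(RuntimeError):
    pass


@dataclass
class CoverageTrack:
    region: Interval
    depth: np.ndarray

    def __post_init__(self) -> None:
        if len(self.depth) != len(self.region):
            raise ValueError("depth length must equal region length")
        if self.depth.size and self.depth.min() < 0:
            raise ValueError("negative depth")


@dataclass
class JunctionEvidence:
    end5: tuple[str, int]  # (contig, coordinate) of the 5' exon end
    start3: tuple[str, int]
    count: int
    min_overhang: Optional[int] = None


@dataclass
class BreakpointCall:
    contig: str
    interval5: tuple[int, int]  # width == homology; degenerate when h == 0
    interval3: tuple[int, int]
    homology: int
    support: dict[str, int] = field(default_factory=dict)
    somatic: bool = False


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def compute_coverage(alignments: Iterable[Alignment], region: Interval) -> CoverageTrack:
    """Per-base depth of aligned segments within the region."""
    diffs = np.zeros(len(region) + 1, dtype=int)
    for aln in alignments:
        for _q, iv in aln.segments:
            if iv.contig != region.contig:
                continue
            lo = max(iv.start, region.start) - region.start
            hi = min(iv.end, region.end) - region.start
            if lo < hi:
                diffs[lo] += 1
                diffs[hi] -= 1
    return CoverageTrack(region, np.cumsum(diffs[:-1]))


def locate_discontinuity(
    track: CoverageTrack,
    exons: Sequence[Interval],
    ratio: float = 10.0,
    min_depth: float = 5.0,
) -> Optional[int]:
    """First inter-exon boundary with an abrupt drop in mean exon depth.

    Exons are given in transcription order; the returned index names the
    intron (boundary) after that exon, or None when coverage is flat.
    """
    means = []
    for e in exons:
        lo = e.start - track.region.start
        hi = e.end - track.region.start
        lo, hi = max(lo, 0), min(hi, len(track.depth))
        means.append(track.depth[lo:hi].mean() if hi > lo else 0.0)
    for i in range(len(means) - 1):
        a, b = means[i], means[i + 1]
        hi_side, lo_side = max(a, b), min(a, b)
        if hi_side >= min_depth and lo_side < hi_side / ratio:
            return i
    return None


# ---------------------------------------------------------------------------
# gene-pair reference
# ---------------------------------------------------------------------------

@dataclass
class GenePairReference:
    """Two wild-type genes (+/- flank) lifted onto their own contigs."""

    reference: Genome
    models: list[GeneModel]  # in reference coordinates, one per contig
    offsets: dict[str, tuple[str, int]]  # gene_id -> (contig, genome offset)

    def to_ref(self, iv: Interval) -> Optional[Interval]:
        """Translate a genome interval into reference coordinates."""
        for gene_id, (contig, offset) in self.offsets.items():
            length = len(self.reference.sequences[contig])
            start, end = iv.start - offset, iv.end - offset
            if end <= 0 or start >= length:
                continue
            return Interval(contig, max(start, 0), min(end, length), iv.strand)
        return None


def build_gene_pair_reference(
    genome: Genome, gene5: GeneModel, gene3: GeneModel, flank: int = 1000
) -> GenePairReference:
    sequences: dict[str, str] = {}
    models: list[GeneModel] = []
    offsets: dict[str, tuple[str, int]] = {}
    for m in (gene5, gene3):
        span = m.span.expanded(flank, genome.length(m.contig))
        contig = f"ref_{m.gene_id}"
        sequences[contig] = genome.sequences[m.contig][span.start : span.end]
        offsets[m.gene_id] = (contig, span.start)

        def lift(iv: Interval) -> Interval:
            return Interval(contig, iv.start - span.start, iv.end - span.start, iv.strand)

        models.append(
            GeneModel(
                m.gene_id,
                lift(m.span),
                [lift(e) for e in m.exons],
                None,
                {},
            )
        )
    return GenePairReference(Genome(sequences), models, offsets)


# ---------------------------------------------------------------------------
# chimeric splice-junction reads
# ---------------------------------------------------------------------------

def find_junction_reads(
    reads: Iterable[ReadPair],
    pair_ref: GenePairReference,
    junction_exon5: int,
    junction_exon3: int,
    min_overhang: int = 8,
) -> JunctionEvidence:
    """Count mates whose split alignment crosses the chimeric exon-exon
    junction with at least ``min_overhang`` exact bases on each side.

    ``junction_exon5`` / ``junction_exon3`` index, in transcription order,
    the last retained exon of the 5' gene and the first retained exon of the
    3' gene.
    """
    ref5, ref3 = pair_ref.models
    end5 = (ref5.contig, ref5.exons[junction_exon5].end)
    start3 = (ref3.contig, ref3.exons[junction_exon3].start)
    aligner = SplicedAligner(
        pair_ref.reference, pair_ref.models, min_segment=min_overhang
    )

    count = 0
    overhangs: list[int] = []
    for pair in reads:
        for seq in (pair.seq1, pair.seq2):
            aln = aligner.map(seq, pair.read_id)
            if aln is None or len(aln.segments) != 2:
                continue
            (q0a, q1a), iv_a = aln.segments[0]
            (q0b, q1b), iv_b = aln.segments[1]
            if (iv_a.contig, iv_a.end) == end5 and (iv_b.contig, iv_b.start) == start3:
                over = min(q1a - q0a, q1b - q0b)
                if over >= min_overhang:
                    count += 1
                    overhangs.append(over)
    return JunctionEvidence(end5, start3, count, min(overhangs) if overhangs else None)


# ---------------------------------------------------------------------------
# DNA fusion-point candidate reads (dual-17 filtering)
# ---------------------------------------------------------------------------

def map_fusion_point_reads(
    pairs: Sequence[ReadPair],
    pair_ref: GenePairReference,
    suspected_introns: dict[str, Interval],
    repeat_mask: Sequence[Interval] = (),
    k: int = 17,
) -> list[tuple[ReadPair, int]]:
    """Original 76-nt reads whose dual-17 ends flag a DNA-level fusion point.

    Each read's two 17-nt ends are mapped as an exact pair onto the two-gene
    reference; the read is retained iff (1) the ends map uniquely to the two
    different genes, (2) either end falls inside a suspected break intron,
    and (3) neither end overlaps a repeat-masked interval.  Coordinates of
    ``suspected_introns`` and ``repeat_mask`` are in reference coordinates.
    """
    index = build_index(pair_ref.reference, k)
    synthetic = trim_reads(pairs, "dual_17", TrimStats())
    by_id = {p.read_id: p for p in pairs}

    mask = [iv for iv in repeat_mask]
    retained: list[tuple[ReadPair, int]] = []
    for syn in synthetic:
        placements = map_pair_exact(index, syn)
        if len(placements) != 1:
            continue
        a1, a2 = placements[0]
        if not (a1.unique and a2.unique):
            continue
        iv1, iv2 = a1.interval, a2.interval
        if iv1.contig == iv2.contig:
            continue  # both ends in the same gene
        in_suspect = any(
            iv.overlaps(susp)
            for iv in (iv1, iv2)
            for susp in suspected_introns.values()
        )
        if not in_suspect:
            continue
        if any(iv.overlaps(m) for iv in (iv1, iv2) for m in mask):
            continue
        read_id, mate = syn.read_id.rsplit("|", 1)
        retained.append((by_id[read_id], int(mate)))
    return retained


# ---------------------------------------------------------------------------
# micro-homology resolution
# ---------------------------------------------------------------------------

def _max_extension_prefix(region: str, read: str, seed: int = 12) -> Optional[tuple[int, int]]:
    """(region_pos, match_len) of the longest exact prefix placement."""
    best = None
    probe = read[:seed]
    pos = region.find(probe)
    while pos != -1:
        m = seed
        while m < len(read) and pos + m < len(region) and region[pos + m] == read[m]:
            m += 1
        if best is None or m > best[1]:
            best = (pos, m)
        pos = region.find(probe, pos + 1)
    return best


def _max_extension_suffix(region: str, read: str, seed: int = 12) -> Optional[tuple[int, int]]:
    """(region_end, match_len) of the longest exact suffix placement."""
    best = None
    probe = read[-seed:]
    pos = region.find(probe)
    while pos != -1:
        end = pos + seed
        m = seed
        while m < len(read) and pos > 0 and region[pos - 1] == read[len(read) - m - 1]:
            pos -= 1
            m += 1
        if best is None or m > best[1]:
            best = (end, m)
        pos = region.find(probe, end - seed + 1)
    return best


def resolve_breakpoint(
    reads_by_source: dict[str, Sequence[str]],
    genome: Genome,
    gene5: GeneModel,
    gene3: GeneModel,
    flank: int = 1000,
    min_support: int = 2,
    seed: int = 12,
) -> BreakpointCall:
    """Aggregate candidate fusion-point reads into a breakpoint call.

    ``reads_by_source`` maps an origin label (tumor_rna / tumor_exome /
    normal_exome) to 76-nt read sequences.  Each read is split-aligned
    against the wild-type genome (longest exact prefix in the 5' gene,
    longest exact suffix in the 3' gene); the overlap of the two maximal
    extensions defines the micro-homology length and the two break intervals.
    Calls are aggregated by majority vote (ties -> widest homology).
    """
    span5 = gene5.span.expanded(flank, genome.length(gene5.contig))
    span3 = gene3.span.expanded(flank, genome.length(gene3.contig))
    region5 = genome.sequences[gene5.contig][span5.start : span5.end]
    region3 = genome.sequences[gene3.contig][span3.start : span3.end]

    votes: dict[tuple[int, int, int], dict[str, int]] = {}
    for source, seqs in reads_by_source.items():
        for raw in seqs:
            for oriented in (raw, revcomp(raw)):
                pre = _max_extension_prefix(region5, oriented, seed)
                suf = _max_extension_suffix(region3, oriented, seed)
                if pre is None or suf is None:
                    continue
                ppos, m1 = pre
                send, m2 = suf
                q1, q2 = m1, len(oriented) - m2
                if q1 < q2:
                    continue  # gap: the read does not span the junction
                h = q1 - q2
                b5 = span5.start + ppos + q1
                b3 = span3.start + send - m2 + (q1 - q2)
                key = (b5, b3, h)
                votes.setdefault(key, {})[source] = (
                    votes.get(key, {}).get(source, 0) + 1
                )
                break
    if not votes:
        raise BreakpointError("no confident fusion point")

    def weight(item):
        key, tally = item
        return (sum(tally.values()), key[2])  # majority, ties -> widest h

    (b5, b3, h), tally = max(votes.items(), key=weight)
    if sum(tally.values()) < min_support:
        raise BreakpointError("no confident fusion point")
    tumor_support = tally.get("tumor_rna", 0) + tally.get("tumor_exome", 0)
    somatic = tally.get("normal_exome", 0) == 0 and tumor_support > 0
    return BreakpointCall(
        contig=gene5.contig,
        interval5=(b5 - h, b5),
        interval3=(b3 - h, b3),
        homology=h,
        support=dict(tally),
        somatic=somatic,
    )
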