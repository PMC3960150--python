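"""Exact paired-end mapping and desk-scale splice-aware split mapping.

Mapping is strictly exact: no mismatches, indels or within-segment splicing.
A base 'N' never matches anything.  Multi-mapping placements are retained but
flagged non-unique; downstream discordant-pair analysis keeps unique-unique
pairs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io_model import Alignment, Genome, GeneModel, Interval, ReadPair, revcomp

log = logging.getLogger(__name__)


class MapperError(ValueError):
    pass


# ---------------------------------------------------------------------------
# read trimming
# ---------------------------------------------------------------------------

@dataclass
class TrimStats:
    kept: int = 0
    skipped: int = 0


def trim_reads(
    pairs: Iterable[ReadPair], mode: str, stats: Optional[TrimStats] = None
) -> list[ReadPair]:
    """Trim reads for mapping.

    ``five_prime_30``: both mates cut to their first 30 bases (spreads the
    mates apart on the fragment, raising the chance the fusion point falls
    between them).

    ``dual_17``: each 76-nt mate becomes its own synthetic pair — the first
    17 bases and the reverse complement of the last 17 (mimicking opposite
    strand mate convention) — so a single read whose two ends flank a DNA
    fusion point turns into a mappable discordant pair.  Synthetic read ids
    are ``<read_id>|1`` / ``<read_id>|2`` so the original read is recoverable.
    """
    stats = stats if stats is not None else TrimStats()
    out: list[ReadPair] = []
    if mode == "five_prime_30":
        for p in pairs:
            if len(p.seq1) < 30 or len(p.seq2) < 30:
                stats.skipped += 1
                continue
            out.append(
                ReadPair(p.read_id, p.seq1[:30], p.qual1[:30], p.seq2[:30], p.qual2[:30], p.origin)
            )
            stats.kept += 1
    elif mode == "dual_17":
        for p in pairs:
            for mate, (seq, qual) in enumerate(
                ((p.seq1, p.qual1), (p.seq2, p.qual2)), start=1
            ):
                if len(seq) < 34:
                    stats.skipped += 1
                    continue
                out.append(
                    ReadPair(
                        f"{p.read_id}|{mate}",
                        seq[:17],
                        qual[:17],
                        revcomp(seq[-17:]),
                        qual[-17:][::-1],
                        p.origin,
                    )
                )
                stats.kept += 1
    else:
        raise MapperError(f"unknown trim mode {mode!r}")
    if stats.skipped:
        log.info("trim_reads(%s): %d reads skipped as too short", mode, stats.skipped)
    return out


# ---------------------------------------------------------------------------
# k-mer index + exact placement
# ---------------------------------------------------------------------------

class KmerIndex:
    """Complete k-mer -> sorted [(contig, position)] index of a reference."""

    def __init__(self, sequences: dict[str, str], k: int = 17):
        if k < 1:
            raise MapperError("k must be positive")
        if min(len(s) for s in sequences.values()) < k:
            raise MapperError("k exceeds shortest reference sequence")
        self.k = k
        self.sequences = sequences
        self.lengths = {name: len(s) for name, s in sequences.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in sequences.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((name, pos))
        self.index = index

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def build_index(sequences: dict[str, str] | Genome, k: int = 17) -> KmerIndex:
    if isinstance(sequences, Genome):
        sequences = sequences.sequences
    return KmerIndex(sequences, k)


def find_exact(index: KmerIndex, query: str) -> list[Interval]:
    """All exact placements of the query on both reference strands."""
    placements: list[Interval] = []
    if len(query) < index.k or "N" in query:
        return placements
    for strand, seq in (("+", query), ("-", revcomp(query))):
        for contig, pos in index.lookup(seq[: index.k]):
            ref = index.sequences[contig]
            end = pos + len(seq)
            if end <= len(ref) and ref[pos:end] == seq:
                placements.append(Interval(contig, pos, end, strand))
    return placements


def map_pair_exact(
    index: KmerIndex, pair: ReadPair
) -> list[tuple[Alignment, Alignment]]:
    """All opposite-strand exact placements of the two mates.

    No insert-size or orientation-distance constraint is applied (the
    abnormal-insert-size filter stays disabled so genuinely distant fusion
    pairs survive).  ``unique`` is set per mate iff that mate has exactly one
    placement on the reference.
    """
    p1 = find_exact(index, pair.seq1)
    p2 = find_exact(index, pair.seq2)
    u1, u2 = len(p1) == 1, len(p2) == 1
    out = []
    for iv1 in p1:
        for iv2 in p2:
            if iv1.strand == iv2.strand:
                continue  # mate2 is expected on the opposite strand
            a1 = Alignment(pair.read_id, 1, iv1, len(pair.seq1), unique=u1)
            a2 = Alignment(pair.read_id, 2, iv2, len(pair.seq2), unique=u2)
            out.append((a1, a2))
    return out


# ---------------------------------------------------------------------------
# splice-aware single-end split mapping
# ---------------------------------------------------------------------------

def _maximal_prefix_hits(
    seqs: dict[str, str], sub: KmerIndex, read: str
) -> list[tuple[str, int, int]]:
    """(contig, pos, match_len) for maximal extensions of the read prefix."""
    hits = []
    for contig, pos in sub.lookup(read[: sub.k]):
        ref = seqs[contig]
        m = sub.k
        while m < len(read) and pos + m < len(ref) and ref[pos + m] == read[m]:
            m += 1
        hits.append((contig, pos, m))
    return hits


def _maximal_suffix_hits(
    seqs: dict[str, str], sub: KmerIndex, read: str
) -> list[tuple[str, int, int]]:
    """(contig, end, match_len) for maximal extensions of the read suffix."""
    hits = []
    tail = read[-sub.k :]
    for contig, pos in sub.lookup(tail):
        ref = seqs[contig]
        end = pos + sub.k
        m = sub.k
        while m < len(read) and pos - 1 >= 0 and ref[pos - 1] == read[len(read) - m - 1]:
            pos -= 1
            m += 1
        hits.append((contig, end, m))
    return hits


def _exon_boundaries(models: Sequence[GeneModel]) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
    ends = set()
    starts = set()
    for m in models:
        for e in m.exons:
            ends.add((e.contig, e.end))
            starts.add((e.contig, e.start))
    return ends, starts


class SplicedAligner:
    """Splice-aware single-end aligner over a small (two-gene) reference.

    Decomposes a read into <=2 exact segments separated by an intron-like
    reference gap.  Annotated exon-boundary splits are preferred; unannotated
    same-contig gaps must be >= ``min_intron``; cross-contig (chimeric) splits
    are allowed only at annotated exon boundaries.  Ties go to the smallest
    gap.  Both read orientations are tried (unstranded library).
    """

    def __init__(
        self,
        reference: Genome,
        models: Sequence[GeneModel],
        min_segment: int = 8,
        min_intron: int = 20,
        split_k: int = 8,
        seed_k: int = 17,
    ):
        self.seqs = reference.sequences
        self.min_segment = min_segment
        self.min_intron = min_intron
        self.sub = KmerIndex(self.seqs, split_k)
        self.full = KmerIndex(self.seqs, seed_k)
        self.ends, self.starts = _exon_boundaries(models)

    def map(self, seq: str, read_id: str = "read") -> Optional[Alignment]:
        contiguous = find_exact(self.full, seq)
        if contiguous:
            iv = contiguous[0]
            return Alignment(read_id, 1, iv, len(seq), unique=len(contiguous) == 1)

        best: Optional[tuple[tuple[int, int], list]] = None  # (rank, segments)
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            if "N" in oriented:
                continue
            L = len(oriented)
            prefixes = _maximal_prefix_hits(self.seqs, self.sub, oriented)
            suffixes = _maximal_suffix_hits(self.seqs, self.sub, oriented)
            for pc, pp, m1 in prefixes:
                for sc, se, m2 in suffixes:
                    if m1 + m2 < L:
                        continue
                    lo = max(L - m2, self.min_segment)
                    hi = min(m1, L - self.min_segment)
                    if lo > hi:
                        continue
                    annotated_cuts = [
                        i
                        for i in range(lo, hi + 1)
                        if (pc, pp + i) in self.ends
                        and (sc, se - (L - i)) in self.starts
                    ]
                    if pc == sc:
                        # the reference gap is independent of the cut position
                        gap = (se - L) - pp
                        if gap < 1:
                            continue
                        if gap < self.min_intron and not annotated_cuts:
                            continue
                        cut = annotated_cuts[0] if annotated_cuts else hi
                        rank = (0 if annotated_cuts else 1, gap)
                    elif annotated_cuts:
                        cut = annotated_cuts[0]
                        rank = (0, 0)
                    else:
                        continue
                    seg1 = ((0, cut), Interval(pc, pp, pp + cut, strand))
                    seg2 = ((cut, L), Interval(sc, se - (L - cut), se, strand))
                    if best is None or rank < best[0]:
                        best = (rank, [seg1, seg2])
        if best is None:
            return None
        segments = best[1]
        return Alignment(
            read_id,
            1,
            segments[0][1],
            sum(q1 - q0 for (q0, q1), _ in segments),
            segments=segments,
        )


def map_single_spliced(
    reference: Genome,
    models: Sequence[GeneModel],
    read: ReadPair | str,
    read_id: str = "read",
    min_segment: int = 8,
    min_intron: int = 20,
) -> Optional[Alignment]:
    """One-shot convenience wrapper around :class:`SplicedAligner`."""
    seq = read if isinstance(read, str) else read.seq1
    aligner = SplicedAligner(reference, models, min_segment, min_intron)
    return aligner.map(seq, read_id)
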