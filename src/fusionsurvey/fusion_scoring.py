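"""Discordant read-pair enumeration and expression-normalized fusion scoring.

A discordant pair has both mates uniquely and exactly placed in two different
genes; its count per gene pair, normalized against how strongly the two genes
are expressed, is the primary fusion-candidate statistic:

* SPER    — discordant (inter) pairs per million mapped pairs;
* DASPER  — SPER minus the expression-based expectation of inter pairs,
            d_hat(A,B) = D_tot * p_A p_B / sum over candidates of p_X p_Y,
            with p_G the gene's share of mapped pairs (floored at 1/M);
* RESPER  — SPER relative to the sample's mean candidate SPER.

High DASPER flags more support than expression alone explains; high RESPER
flags support standing out among the sample's own candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io_model import Alignment, GeneModel, Interval, ReadPair


class ScoringError(ValueError):
    pass


@dataclass
class DiscordantPair:
    read_id: str
    gene5: str
    gene3: str
    placement5: Alignment
    placement3: Alignment


@dataclass
class FusionCandidate:
    gene5: str
    gene3: str
    fusion_type: str = "intra"
    inter_reads: int = 0
    intra_reads5: int = 0
    intra_reads3: int = 0
    sper: float = 0.0
    dasper: float = 0.0
    resper: float = 0.0
    sample: str = "sample"

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass
class PairAccounting:
    """Mate bookkeeping for the conservation invariant."""

    mapped_pairs: int = 0
    concordant_pairs: int = 0
    discordant_pairs: int = 0
    dropped_multimap_pairs: int = 0
    unassigned_mates: int = 0
    lone_gene_mates: int = 0  # in-gene mate whose partner fell outside any gene


def _assign_gene(iv: Interval, models: Sequence[GeneModel]) -> Optional[str]:
    for m in models:
        if m.span.overlaps(iv):
            return m.gene_id
    return None


def collect_discordant_pairs(
    mapped: Iterable[tuple[ReadPair, list[tuple[Alignment, Alignment]]]],
    models: Sequence[GeneModel],
) -> tuple[list[DiscordantPair], dict[str, int], PairAccounting]:
    """Split mapped pairs into discordant pairs and per-gene intra counts.

    A pair is discordant iff both mates map uniquely and their enclosing genes
    differ.  Concordant same-gene pairs increment that gene's intra count;
    mates outside any gene are ignored; any multi-mapping mate drops the pair.
    """
    discordant: list[DiscordantPair] = []
    intra: dict[str, int] = {m.gene_id: 0 for m in models}
    acct = PairAccounting()

    for pair, alignments in mapped:
        if not alignments:
            continue
        acct.mapped_pairs += 1
        a1, a2 = alignments[0]
        if not (a1.unique and a2.unique):
            acct.dropped_multimap_pairs += 1
            continue
        g1 = _assign_gene(a1.interval, models)
        g2 = _assign_gene(a2.interval, models)
        if g1 is None or g2 is None:
            acct.unassigned_mates += (g1 is None) + (g2 is None)
            acct.lone_gene_mates += (g1 is not None) + (g2 is not None)
            continue
        if g1 == g2:
            intra[g1] += 1
            acct.concordant_pairs += 1
        else:
            discordant.append(DiscordantPair(pair.read_id, g1, g2, a1, a2))
            acct.discordant_pairs += 1
    return discordant, intra, acct


def classify_fusion_type(
    gene_a: str, gene_b: str, models: Sequence[GeneModel]
) -> str:
    """inter / read-through / cis / intra, from annotation adjacency.

    Adjacent means no annotated gene lies between the two on their contig;
    adjacent same-strand pairs are read-through, adjacent opposite-strand
    pairs are cis.
    """
    by_id = {m.gene_id: m for m in models}
    try:
        ma, mb = by_id[gene_a], by_id[gene_b]
    except KeyError as exc:
        raise ScoringError(f"unknown gene {exc}") from exc
    if ma.contig != mb.contig:
        return "inter"
    lo, hi = sorted((ma, mb), key=lambda m: m.span.start)
    between = [
        m
        for m in models
        if m.contig == ma.contig
        and m.gene_id not in (gene_a, gene_b)
        and m.span.start >= lo.span.end
        and m.span.end <= hi.span.start
    ]
    if between:
        return "intra"
    return "read-through" if ma.strand == mb.strand else "cis"


def build_candidates(
    discordant: Sequence[DiscordantPair],
    intra: dict[str, int],
    models: Sequence[GeneModel],
    sample: str = "sample",
) -> list[FusionCandidate]:
    """Aggregate discordant pairs into ordered-gene-pair candidates.

    The 5' partner of each pair is decided by majority vote: per fragment the
    5' gene is the one whose mate aligned on that gene's sense strand (the
    upstream mate of an unstranded fragment reads the transcript sense
    strand).  Ties break lexicographically.
    """
    strand_of = {m.gene_id: m.strand for m in models}
    votes: dict[frozenset, dict[str, int]] = {}
    support: dict[frozenset, list[DiscordantPair]] = {}
    for dp in discordant:
        key = frozenset((dp.gene5, dp.gene3))
        support.setdefault(key, []).append(dp)
        tally = votes.setdefault(key, {})
        for gene, aln in ((dp.gene5, dp.placement5), (dp.gene3, dp.placement3)):
            if aln.interval.strand == strand_of[gene]:
                tally[gene] = tally.get(gene, 0) + 1

    out = []
    for key, pairs in support.items():
        genes = sorted(key)
        tally = votes[key]
        ranked = sorted(genes, key=lambda g: (-tally.get(g, 0), g))
        g5, g3 = ranked[0], (ranked[1] if len(ranked) > 1 else ranked[0])
        out.append(
            FusionCandidate(
                gene5=g5,
                gene3=g3,
                fusion_type=classify_fusion_type(g5, g3, models),
                inter_reads=len(pairs),
                intra_reads5=intra.get(g5, 0),
                intra_reads3=intra.get(g3, 0),
                sample=sample,
            )
        )
    out.sort(key=lambda c: c.key)
    return out


def score_candidates(
    candidates: Sequence[FusionCandidate], total_mapped_pairs: int
) -> list[FusionCandidate]:
    """Attach SPER / DASPER / RESPER to every candidate."""
    if not candidates:
        return []
    if total_mapped_pairs <= 0:
        raise ScoringError("total mapped pairs must be positive")
    m = float(total_mapped_pairs)
    d_tot = sum(c.inter_reads for c in candidates)

    def p(intra_count: int) -> float:
        return max(intra_count, 1) / m  # floor keeps silent genes scoreable

    pp = [p(c.intra_reads5) * p(c.intra_reads3) for c in candidates]
    pp_sum = sum(pp)
    for c, ppi in zip(candidates, pp):
        c.sper = c.inter_reads / m * 1e6
        d_hat = d_tot * ppi / pp_sum
        c.dasper = c.sper - d_hat / m * 1e6
    mean_sper = sum(c.sper for c in candidates) / len(candidates)
    for c in candidates:
        c.resper = c.sper / mean_sper if mean_sper > 0 else 0.0
    return list(candidates)


def threshold_filter(
    candidates: Sequence[FusionCandidate],
    dasper_min: float = 1.0,
    resper_min: float = 1.0,
) -> list[FusionCandidate]:
    """Keep candidates with DASPER and RESPER strictly above the cutoffs,
    sorted by RESPER descending (ties: inter reads, then gene-pair name)."""
    kept = [c for c in candidates if c.dasper > dasper_min and c.resper > resper_min]
    kept.sort(key=lambda c: (-c.resper, -c.inter_reads, c.gene5, c.gene3))
    return kept


def candidates_to_frame(candidates: Sequence[FusionCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                fusion_type=c.fusion_type,
                gene1=c.gene5,
                gene2=c.gene3,
                sample=c.sample,
                inter_reads=c.inter_reads,
                intra_reads_1=c.intra_reads5,
                intra_reads_2=c.intra_reads3,
                SPER=c.sper,
                DASPER=c.dasper,
                RESPER=c.resper,
            )
            for c in candidates
        ],
        columns=[
            "fusion_type",
            "gene1",
            "gene2",
            "sample",
            "inter_reads",
            "intra_reads_1",
            "intra_reads_2",
            "SPER",
            "DASPER",
            "RESPER",
        ],
    )
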