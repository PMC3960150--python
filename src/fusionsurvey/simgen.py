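"""Synthetic-data generator: genomes, fusions, reads, cohort expression.

Every generator is a pure function of its configuration and seed.  The
generated coding sequences are built so that reading-frame arithmetic and
direct conceptual translation agree exactly:

* the in-frame codon stream never contains a stop codon;
* a 9-nt cassette (GTAAGTAAG) is embedded at a codon boundary in every exon,
  which places a stop codon in both shifted reading frames;
* the first coding base of every exon is forced to 'C', so a chimeric codon
  formed at any exon-exon fusion junction can never be a stop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    CdsSegment,
    Genome,
    GeneModel,
    Interval,
    ReadPair,
    revcomp,
)

log = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
# no stop codon in either shifted frame reads through this cassette
_FRAMESHIFT_CASSETTE = "GTAAGTAAG"

_BASES = np.array(list("ACGT"))
_SAFE_CODONS = np.array(
    sorted(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    )
)


class ConfigError(ValueError):
    """Infeasible or invalid simulation configuration."""


class SimulationError(RuntimeError):
    """A requested synthetic structure cannot be constructed."""


@dataclass(frozen=True)
class FusionSpec:
    """A single somatic (or germline) DNA-level fusion to plant.

    The 5' partner's leading exons are joined to the 3' partner's trailing
    exons by breaking inside the designated introns; ``homology`` bases of
    identical sequence immediately upstream of both break positions make the
    exact break coordinate ambiguous within an interval of that width.
    """

    gene5: str
    gene3: str
    break_intron5: int = 1
    break_intron3: int = 1
    homology: int = 2
    somatic: bool = True

    def __post_init__(self) -> None:
        if self.homology < 0:
            raise ConfigError("homology must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome and read sets."""

    seed: int = 0
    n_genes: int = 8
    exons_per_gene: int = 4
    exon_length: tuple[int, int] = (150, 250)
    intron_length: tuple[int, int] = (300, 600)
    intergenic_length: tuple[int, int] = (400, 900)
    read_length: int = 76
    insert_mean: float = 250.0
    insert_sd: float = 30.0
    n_pairs: int = 2000
    premrna_fraction: float = 0.01
    exome_flank: int = 150
    expression_weights: Optional[dict[str, float]] = None
    capture_weights: Optional[dict[str, float]] = None  # exome; 1.0 = diploid
    base_error_rate: float = 0.0
    kinase_genes: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        positive = (
            self.n_genes,
            self.exons_per_gene,
            self.read_length,
            self.insert_mean,
            self.n_pairs,
        )
        if any(v <= 0 for v in positive):
            raise ConfigError("counts and lengths must be positive")
        if self.insert_sd < 0 or self.exome_flank < 0 or self.base_error_rate < 0:
            raise ConfigError("sd, flank and error rate must be non-negative")
        if not 0.0 <= self.premrna_fraction <= 1.0:
            raise ConfigError("premrna_fraction must be a probability")
        for lo, hi in (self.exon_length, self.intron_length, self.intergenic_length):
            if not 0 < lo <= hi:
                raise ConfigError("length ranges must satisfy 0 < lo <= hi")
        if self.exon_length[0] < 30:
            raise ConfigError("exons must be >= 30 nt to carry coding structure")

    def gene_ids(self) -> list[str]:
        return [f"G{i:03d}" for i in range(self.n_genes)]

    def weight(self, gene_id: str) -> float:
        if self.expression_weights is None:
            return 1.0
        return float(self.expression_weights.get(gene_id, 0.0))

    def capture_weight(self, gene_id: str) -> float:
        if self.capture_weights is None:
            return 1.0
        return float(self.capture_weights.get(gene_id, 0.0))


@dataclass
class TruthRecord:
    """Exact ground truth for one planted fusion (acceptance oracle)."""

    spec: FusionSpec
    break5: int  # wild-type coordinate, junction is [..break5) + [break3..)
    break3: int
    tumor_break: int  # same junction position on the rearranged contig
    homology_interval5: Interval | None
    homology_interval3: Interval | None
    fused_transcript: str
    junction_offset: int  # exon-exon junction position in the spliced transcript
    contig: str  # wild-type contig carrying both partners
    tumor_contig: str = ""  # rearranged allele contig
    abundance: Optional[dict[str, float]] = None


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _random_coding_stream(rng: np.random.Generator, exon_lengths: Sequence[int]) -> list[str]:
    """Per-exon coding chunks forming one stop-free codon stream."""
    total = sum(exon_lengths)
    n_codons = total // 3 + 1
    stream = list("".join(rng.choice(_SAFE_CODONS, size=n_codons)))[:total]

    offset = 0
    for length in exon_lengths:
        # cassette at the first codon boundary at least 3 nt into the exon
        b = offset + 3
        b += (-b) % 3
        if b + len(_FRAMESHIFT_CASSETTE) <= offset + length:
            stream[b : b + len(_FRAMESHIFT_CASSETTE)] = _FRAMESHIFT_CASSETTE
        # junction-codon guard: exon never begins a stop codon completion
        stream[offset] = "C"
        offset += length

    chunks = []
    offset = 0
    for length in exon_lengths:
        chunks.append("".join(stream[offset : offset + length]))
        offset += length
    return chunks


def make_reference(config: SimConfig) -> tuple[Genome, list[GeneModel]]:
    """Deterministic genome + gene models for the configured study."""
    rng = np.random.default_rng(config.seed)
    kinase = (
        set(config.kinase_genes)
        if config.kinase_genes is not None
        else {config.n_genes - 1}
    )

    pieces: list[str] = []
    models: list[GeneModel] = []
    cursor = 0
    contig = "chr1"

    def random_seq(length: int) -> str:
        return "".join(rng.choice(_BASES, size=length))

    for idx, gene_id in enumerate(config.gene_ids()):
        gap = int(rng.integers(config.intergenic_length[0], config.intergenic_length[1] + 1))
        pieces.append(random_seq(gap))
        cursor += gap

        strand = "-" if idx % 3 == 2 else "+"
        exon_lengths = [
            int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            for _ in range(config.exons_per_gene)
        ]
        intron_lengths = [
            int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
            for _ in range(config.exons_per_gene - 1)
        ]
        chunks = _random_coding_stream(rng, exon_lengths)

        exon_ivs: list[Interval] = []
        gene_start = cursor
        # genomic order; for '-' genes transcription order is reversed, so the
        # coding chunks are laid down right-to-left
        tx_order = range(config.exons_per_gene)
        genomic_chunks = (
            list(chunks) if strand == "+" else [revcomp(c) for c in reversed(chunks)]
        )
        genomic_lengths = (
            exon_lengths if strand == "+" else list(reversed(exon_lengths))
        )
        for j in tx_order:
            exon_seq = genomic_chunks[j]
            exon_ivs.append(Interval(contig, cursor, cursor + genomic_lengths[j], strand))
            pieces.append(exon_seq)
            cursor += genomic_lengths[j]
            if j < config.exons_per_gene - 1:
                pieces.append(random_seq(intron_lengths[j]))
                cursor += intron_lengths[j]

        span = Interval(contig, gene_start, cursor, strand)
        exons_tx = exon_ivs if strand == "+" else exon_ivs[::-1]
        tx_lengths = [len(e) for e in exons_tx]
        cds = []
        cum = 0
        for e in exons_tx:
            frame = (3 - cum % 3) % 3
            cds.append(CdsSegment(replace(e, strand=strand), frame))
            cum += len(e)
        assert tx_lengths == ([len(s.interval) for s in cds])

        domains: dict[str, Interval] = {}
        if idx in kinase and config.exons_per_gene >= 2:
            domains["transmembrane"] = replace(exons_tx[-2], strand=strand)
            domains["kinase"] = replace(exons_tx[-1], strand=strand)
        models.append(GeneModel(gene_id, span, exons_tx, cds, domains))

    pieces.append(random_seq(200))
    genome = Genome({contig: "".join(pieces)})
    return genome, models


def make_repeats(models: Sequence[GeneModel], width: int = 50) -> list[Interval]:
    """Decoy repeat-masked intervals, centred in each gene's first intron."""
    out = []
    for m in models:
        introns = m.introns()
        if not introns:
            continue
        intron = introns[0]
        if len(intron) < width + 40:
            continue
        mid = (intron.start + intron.end) // 2
        out.append(Interval(intron.contig, mid - width // 2, mid - width // 2 + width))
    return out


# ---------------------------------------------------------------------------
# fusion planting
# ---------------------------------------------------------------------------

def apply_fusion(
    genome: Genome,
    models: Sequence[GeneModel],
    spec: FusionSpec,
    break_offset_range: tuple[int, int] = (40, 120),
) -> tuple[Genome, GeneModel, TruthRecord]:
    """Plant a DNA-level fusion on a rearranged allele.

    The tumor genome keeps the intact wild-type contig (the second allele)
    and gains a derived contig ``<contig>_t`` equal to ``wt[:b5] + wt[b3:]``
    — an interstitial deletion joining the partners.  Break positions are
    searched inside the designated introns so that exactly ``spec.homology``
    bases of identical context sit immediately upstream of both breaks (and
    the homology is not extendable on either side); they are biased toward
    the start of the break intron so exome flank capture reaches the
    junction.
    """
    by_id = {m.gene_id: m for m in models}
    try:
        g5, g3 = by_id[spec.gene5], by_id[spec.gene3]
    except KeyError as exc:
        raise SimulationError(f"unknown gene {exc}") from exc
    if g5.strand != "+" or g3.strand != "+":
        raise SimulationError("fusion partners must both be on the + strand")
    if g5.contig != g3.contig or g5.span.end >= g3.span.start:
        raise SimulationError("5' partner must precede 3' partner on one contig")
    introns5, introns3 = g5.introns(), g3.introns()
    if spec.break_intron5 >= len(introns5) or spec.break_intron3 >= len(introns3):
        raise SimulationError("break intron index out of range")
    intron5, intron3 = introns5[spec.break_intron5], introns3[spec.break_intron3]
    h = spec.homology
    if h > min(len(intron5), len(intron3)):
        raise SimulationError("homology exceeds flanking intron length")

    seq = genome.sequences[g5.contig]
    lo5 = intron5.start + max(h + 1, break_offset_range[0])
    hi5 = min(intron5.start + break_offset_range[1], intron5.end - 1)
    lo3, hi3 = intron3.start + h + 1, intron3.end - 1

    found = None
    for b5 in range(lo5, max(hi5, lo5) + 1):
        ctx = seq[b5 - h : b5]
        for b3 in range(lo3, hi3 + 1):
            if seq[b3 - h : b3] != ctx:
                continue
            if seq[b3 - h - 1] == seq[b5 - h - 1]:
                continue  # homology would extend left
            if seq[b3] == seq[b5]:
                continue  # homology would extend right
            found = (b5, b3)
            break
        if found:
            break
    if found is None:
        raise SimulationError(
            f"no break positions with exactly {h} nt of shared context"
        )
    b5, b3 = found
    shift = b3 - b5

    tumor_contig = f"{g5.contig}_t"
    tumor_sequences = dict(genome.sequences)
    tumor_sequences[tumor_contig] = seq[:b5] + seq[b3:]
    tumor = Genome(tumor_sequences)

    def shifted(iv: Interval) -> Interval:
        return Interval(tumor_contig, iv.start - shift, iv.end - shift, iv.strand)

    def lifted(iv: Interval) -> Interval:
        return replace(iv, contig=tumor_contig)

    n5 = spec.break_intron5 + 1  # exons retained from the 5' partner
    fused_exons = [lifted(e) for e in g5.exons[:n5]] + [
        shifted(e) for e in g3.exons[spec.break_intron3 + 1 :]
    ]
    fused_cds = None
    if g5.cds and g3.cds:
        fused_cds = [CdsSegment(lifted(s.interval), s.phase) for s in g5.cds[:n5]] + [
            CdsSegment(shifted(s.interval), s.phase)
            for s in g3.cds[spec.break_intron3 + 1 :]
        ]
    fused_domains = {
        name: shifted(iv) for name, iv in g3.domains.items() if iv.start >= b3
    }
    fused_domains.update(
        {name: lifted(iv) for name, iv in g5.domains.items() if iv.end <= b5}
    )
    fused = GeneModel(
        f"{spec.gene5}-{spec.gene3}",
        Interval(tumor_contig, g5.span.start, g3.span.end - shift, "+"),
        fused_exons,
        fused_cds,
        fused_domains,
    )

    junction_offset = sum(len(e) for e in g5.exons[:n5])
    # h=0 break is unambiguous: intervals degenerate to the exact coordinate
    truth = TruthRecord(
        spec=spec,
        break5=b5,
        break3=b3,
        tumor_break=b5,
        homology_interval5=Interval(g5.contig, b5 - h, b5) if h else None,
        homology_interval3=Interval(g3.contig, b3 - h, b3) if h else None,
        fused_transcript=fused.spliced_sequence(tumor),
        junction_offset=junction_offset,
        contig=g5.contig,
        tumor_contig=tumor_contig,
    )
    return tumor, fused, truth


def in_frame_intron_pairs(gene5: GeneModel, gene3: GeneModel) -> list[tuple[int, int]]:
    """Break-intron index pairs that keep the 3' partner's frame intact."""
    if not (gene5.cds and gene3.cds):
        raise SimulationError("both partners need a CDS for frame bookkeeping")
    out = []
    for i5 in range(len(gene5.exons) - 1):
        len5 = sum(len(s.interval) for s in gene5.cds[: i5 + 1])
        for i3 in range(len(gene3.exons) - 1):
            if (len5 + gene3.cds[i3 + 1].phase) % 3 == 0:
                out.append((i5, i3))
    return out


def models_on_tumor(
    models: Sequence[GeneModel], truth: TruthRecord, fused: GeneModel
) -> list[GeneModel]:
    """Gene models valid on the tumor genome.

    The intact allele keeps every wild-type model; the rearranged allele
    contributes the fused gene on its own contig.
    """
    return list(models) + [fused]


def fusion_study_weights(
    models: Sequence[GeneModel],
    fused_id: str,
    spec: FusionSpec,
    fusion_weight: float = 15.0,
) -> dict[str, float]:
    """Expression weights emulating a promoter-swap fusion tumor.

    The wild-type 3' partner (the kinase gene) is silent — its expression in
    the cohort is an outlier driven purely by the fusion — while the fusion
    transcript is strongly expressed relative to every other gene.  This is
    what produces the abrupt per-exon coverage discontinuity in both
    partners.
    """
    weights = {m.gene_id: 1.0 for m in models}
    weights[spec.gene3] = 0.0
    weights[fused_id] = fusion_weight
    return weights


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _fragment_reads(
    rng: np.random.Generator,
    template: str,
    start: int,
    frag_len: int,
    flipped: bool,
    read_length: int,
    error_rate: float,
) -> tuple[str, str]:
    frag = template[start : start + frag_len]
    if flipped:
        frag = revcomp(frag)
    seq1 = frag[:read_length]
    seq2 = revcomp(frag[-read_length:])
    if error_rate > 0:
        seq1 = _mutate(rng, seq1, error_rate)
        seq2 = _mutate(rng, seq2, error_rate)
    return seq1, seq2


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_rnaseq(
    genome: Genome,
    models: Sequence[GeneModel],
    config: SimConfig,
    junction_offsets: Optional[dict[str, int]] = None,
    junction_min_overhang: int = 8,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Paired-end RNA-seq from spliced mRNA with a small pre-mRNA fraction.

    Fragments are drawn from a transcript chosen proportionally to its gene
    weight; with probability ``premrna_fraction`` the unspliced pre-mRNA is
    the template.  The library is unstranded: each fragment is flipped with
    probability 1/2.  The truth table records, per fragment, how many mates
    span the chimeric exon-exon junction of genes listed in
    ``junction_offsets`` (spliced templates only) with at least
    ``junction_min_overhang`` bases on each side — shorter overhangs are not
    junction-specific.
    """
    rng = np.random.default_rng(config.seed)
    junction_offsets = junction_offsets or {}
    rl = config.read_length

    usable = []
    for m in models:
        spliced = m.spliced_sequence(genome)
        if len(spliced) < rl:
            log.warning("gene %s transcript shorter than read length; skipped", m.gene_id)
            continue
        w = config.weight(m.gene_id)
        if w > 0:
            usable.append((m, spliced, m.unspliced_sequence(genome), w))
    if not usable:
        raise ConfigError("expression weights leave no usable transcript")
    weights = np.array([u[3] for u in usable], dtype=float)
    weights /= weights.sum()

    gene_idx = rng.choice(len(usable), size=config.n_pairs, p=weights)
    use_pre = rng.random(config.n_pairs) < config.premrna_fraction
    inserts = rng.normal(config.insert_mean, config.insert_sd, config.n_pairs)
    flips = rng.random(config.n_pairs) < 0.5
    starts_u = rng.random(config.n_pairs)

    pairs: list[ReadPair] = []
    rows = []
    for i in range(config.n_pairs):
        m, spliced, unspliced, _ = usable[gene_idx[i]]
        pre = bool(use_pre[i])
        # unspliced_sequence is already sense-strand (span carries the strand)
        template = unspliced if pre else spliced
        frag = int(np.clip(round(inserts[i]), rl, len(template)))
        start = int(starts_u[i] * (len(template) - frag + 1))
        seq1, seq2 = _fragment_reads(
            rng, template, start, frag, bool(flips[i]), rl, config.base_error_rate
        )
        rid = f"r{i:06d}"
        pairs.append(ReadPair(rid, seq1, "I" * rl, seq2, "I" * rl, "rnaseq"))

        n_span = 0
        joff = junction_offsets.get(m.gene_id)
        if joff is not None and not pre:
            for a, b in ((start, start + rl), (start + frag - rl, start + frag)):
                if a + junction_min_overhang <= joff <= b - junction_min_overhang:
                    n_span += 1
        rows.append(
            dict(
                read_id=rid,
                gene_id=m.gene_id,
                template="premrna" if pre else "spliced",
                frag_start=start,
                frag_end=start + frag,
                flipped=bool(flips[i]),
                junction_mates=n_span,
            )
        )
    return pairs, pd.DataFrame(rows)


def capture_windows(
    genome: Genome, models: Sequence[GeneModel], flank: int
) -> list[tuple[Interval, str]]:
    """Merged exon +/- flank windows per gene (exome capture design)."""
    out = []
    for m in models:
        clen = genome.length(m.contig)
        ivs = sorted(
            (e.expanded(flank, clen) for e in m.exons), key=lambda iv: iv.start
        )
        merged = [ivs[0]]
        for iv in ivs[1:]:
            if iv.start <= merged[-1].end:
                merged[-1] = replace(merged[-1], end=max(merged[-1].end, iv.end))
            else:
                merged.append(iv)
        out.extend((replace(iv, strand="+"), m.gene_id) for iv in merged)
    return out


def simulate_exome(
    genome: Genome,
    models: Sequence[GeneModel],
    config: SimConfig,
    tissue: str = "tumor",
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Paired-end exome reads drawn uniformly from exon +/- flank windows.

    Fragments lie fully inside a capture window; with a nonzero flank the
    windows reach into the adjacent introns, which is how intronic sequence
    near an exon (including a DNA fusion point) gets fortuitously captured.
    Capture weights (not expression weights) set per-gene pulldown intensity,
    which lets a caller emulate copy-number amplification.
    """
    if tissue not in ("tumor", "normal"):
        raise ConfigError("tissue must be 'tumor' or 'normal'")
    rng = np.random.default_rng(config.seed + (1 if tissue == "tumor" else 2))
    rl = config.read_length

    windows = [
        (iv, gid)
        for iv, gid in capture_windows(genome, models, config.exome_flank)
        if config.capture_weight(gid) > 0
    ]
    if not windows:
        raise ConfigError("no capture windows")
    wprob = np.array(
        [len(iv) * config.capture_weight(gid) for iv, gid in windows], float
    )
    wprob /= wprob.sum()

    widx = rng.choice(len(windows), size=config.n_pairs, p=wprob)
    inserts = rng.normal(config.insert_mean, config.insert_sd, config.n_pairs)
    flips = rng.random(config.n_pairs) < 0.5
    starts_u = rng.random(config.n_pairs)

    pairs: list[ReadPair] = []
    rows = []
    for i in range(config.n_pairs):
        iv, gid = windows[widx[i]]
        contig_seq = genome.sequences[iv.contig]
        # fragment fully inside the capture window (pulldown spans the insert)
        frag = min(int(max(round(inserts[i]), rl)), len(iv))
        if frag < rl:
            continue
        start = iv.start + int(starts_u[i] * (len(iv) - frag + 1))
        end = start + frag
        seq1, seq2 = _fragment_reads(
            rng,
            contig_seq,
            start,
            end - start,
            bool(flips[i]),
            rl,
            config.base_error_rate,
        )
        rid = f"{tissue[0]}e{i:06d}"
        pairs.append(ReadPair(rid, seq1, "I" * rl, seq2, "I" * rl, "exome"))
        rows.append(
            dict(
                read_id=rid,
                gene_id=gid,
                contig=iv.contig,
                frag_start=start,
                frag_end=end,
                window_start=iv.start,
                window_end=iv.end,
                flipped=bool(flips[i]),
            )
        )
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort expression
# ---------------------------------------------------------------------------

def simulate_cohort_expression(
    n_samples: int,
    n_genes: int,
    signature: Sequence[tuple[str, int]],
    activated_samples: Sequence[int],
    fold: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    baseline_mean: float = 6.0,
    outlier_samples: Sequence[int] = (),
    outlier_gene: Optional[str] = None,
    outlier_shift: float = 6.0,
):
    """Log2-scale cohort matrix with planted pathway activation and outliers.

    Baseline is N(baseline_mean, noise_sd) per gene/sample; activated samples
    are shifted by +/- log2(fold) on signature genes according to each gene's
    direction; designated outlier samples get ``outlier_shift`` added on the
    target gene.  Gene ids are ``EG0000``..; sample ids ``S000``..
    """
    from .expression_pathway import ExpressionMatrix

    if n_samples <= 0 or n_genes <= 0 or fold <= 0 or noise_sd < 0:
        raise ConfigError("cohort parameters must be positive")
    rng = np.random.default_rng(seed)
    gene_ids = [f"EG{i:04d}" for i in range(n_genes)]
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    gi = {g: i for i, g in enumerate(gene_ids)}

    values = rng.normal(baseline_mean, noise_sd, size=(n_genes, n_samples))
    shift = np.log2(fold)
    for gene, direction in signature:
        if gene not in gi:
            raise ConfigError(f"signature gene {gene} outside cohort gene space")
        for s in activated_samples:
            values[gi[gene], s] += direction * shift
    if outlier_gene is not None:
        for s in outlier_samples:
            values[gi[outlier_gene], s] += outlier_shift

    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(frame, scale="log2_array")


def write_scenario(
    config: SimConfig,
    outdir,
    fusion: Optional[FusionSpec] = None,
) -> dict:
    """Emit a complete synthetic study to ``outdir``.

    Writes genome.fa + genes.gtf (wild type), repeats.bed, tumor RNA and
    tumor/normal exome FASTQ pairs, and truth.tsv.  When a fusion is given,
    tumor reads are simulated from the rearranged genome; normal exome reads
    always come from the wild type.
    """
    from pathlib import Path

    from .io_model import write_bed, write_fasta, write_fastq, write_gtf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, models = make_reference(config)
    write_fasta(genome, outdir / "genome.fa")
    write_gtf(models, outdir / "genes.gtf")
    write_bed(make_repeats(models), outdir / "repeats.bed")

    truth_rows = []
    rna_config = config
    if fusion is not None:
        tumor, fused, truth = apply_fusion(genome, models, fusion)
        tumor_models = models_on_tumor(models, truth, fused)
        joffs = {fused.gene_id: truth.junction_offset}
        if config.expression_weights is None:
            rna_config = replace(
                config,
                expression_weights=fusion_study_weights(models, fused.gene_id, fusion),
            )
        truth_rows.append(
            dict(
                gene5=fusion.gene5,
                gene3=fusion.gene3,
                fused_gene=fused.gene_id,
                break5=truth.break5,
                break3=truth.break3,
                homology=fusion.homology,
                somatic=fusion.somatic,
                junction_offset=truth.junction_offset,
                junction_window=truth.fused_transcript[
                    max(truth.junction_offset - config.read_length, 0) : truth.junction_offset
                    + config.read_length
                ],
            )
        )
    else:
        tumor, tumor_models, joffs = genome, models, {}

    rna, rna_truth = simulate_rnaseq(tumor, tumor_models, rna_config, joffs)
    write_fastq(rna, outdir / "tumor_rna_1.fq", outdir / "tumor_rna_2.fq")
    rna_truth.to_csv(outdir / "rna_truth.tsv", sep="\t", index=False)

    exome_t, _ = simulate_exome(tumor, tumor_models, config, "tumor")
    write_fastq(exome_t, outdir / "tumor_exome_1.fq", outdir / "tumor_exome_2.fq")
    normal_genome = genome if (fusion is None or fusion.somatic) else tumor
    normal_models = models if (fusion is None or fusion.somatic) else tumor_models
    exome_n, _ = simulate_exome(normal_genome, normal_models, config, "normal")
    write_fastq(exome_n, outdir / "normal_exome_1.fq", outdir / "normal_exome_2.fq")

    pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return {
        "genome": genome,
        "models": models,
        "tumor": tumor,
        "tumor_models": tumor_models,
        "truth": truth_rows,
    }


def default_cohort_signature(n_genes_signature: int = 50, offset: int = 100) -> list[tuple[str, int]]:
    """A directional signature over cohort gene ids, half up / half down."""
    out = []
    for i in range(n_genes_signature):
        direction = 1 if i < (n_genes_signature + 1) // 2 else -1
        out.append((f"EG{offset + i:04d}", direction))
    return out
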