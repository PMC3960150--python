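"""Exclusion ledger: turn scored candidates into a decision table.

Candidates are screened, in a fixed order, for the classic false-positive and
passenger modes of discordant-pair fusion calls: already-known fusions are set
aside, amplicon-associated candidates (likely by-products of chromosomal
amplification) and annotation artifacts are excluded, then frame-breaking
junctions and candidates without any junction-spanning read are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fusion_scoring import FusionCandidate
from .io_model import Alignment, Genome, GeneModel, Interval

EXCLUSION_REASONS = (
    "amplicon",
    "misannotation",
    "off-frame",
    "no junction reads",
)


class LedgerError(ValueError):
    pass


@dataclass
class CopyNumberTrack:
    """Windowed read-depth folds relative to the genome-wide median window."""

    window_size: int
    folds: dict[str, np.ndarray]

    def max_fold(self, iv: Interval) -> float:
        track = self.folds.get(iv.contig)
        if track is None:
            return 0.0
        lo = iv.start // self.window_size
        hi = (iv.end - 1) // self.window_size + 1
        return float(track[lo : min(hi, len(track))].max(initial=0.0))


@dataclass
class FrameReport:
    in_frame: bool
    junction_phase: int
    retained_domains: list[str] = field(default_factory=list)


@dataclass
class LedgerRow:
    candidate: FusionCandidate
    status: str  # retained | excluded | set_aside_known
    reason: str = ""


def estimate_copy_number(
    alignments: Iterable[Alignment], genome: Genome, window: int = 10_000
) -> CopyNumberTrack:
    """Per-window depth folds: window mean depth / genome-wide median window
    depth.  Suited to uniform (whole-genome-style) coverage; capture-style
    data with large uncovered gaps will inflate folds and should use a window
    comparable to the capture target size."""
    depth = {name: np.zeros(len(seq) + 1) for name, seq in genome.sequences.items()}
    n = 0
    for aln in alignments:
        iv = aln.interval
        if iv.contig in depth:
            depth[iv.contig][iv.start] += 1
            depth[iv.contig][iv.end] -= 1
            n += 1
    if n == 0:
        raise LedgerError("insufficient coverage: no aligned reads")
    window_means: dict[str, np.ndarray] = {}
    all_means = []
    for name, diffs in depth.items():
        per_base = np.cumsum(diffs[:-1])
        n_win = (per_base.size + window - 1) // window
        means = np.array(
            [per_base[i * window : (i + 1) * window].mean() for i in range(n_win)]
        )
        window_means[name] = means
        all_means.append(means)
    median = float(np.median(np.concatenate(all_means)))
    if median <= 0:
        raise LedgerError("insufficient coverage: zero median window depth")
    return CopyNumberTrack(window, {k: v / median for k, v in window_means.items()})


def flag_amplicon(
    candidate: FusionCandidate,
    track: CopyNumberTrack,
    models: Sequence[GeneModel],
    radius: int = 1_000_000,
    fold_threshold: float = 3.0,
) -> bool:
    """True iff either gene sits within ``radius`` of a high-fold window."""
    by_id = {m.gene_id: m for m in models}
    for gene in (candidate.gene5, candidate.gene3):
        model = by_id.get(gene)
        if model is None:
            raise LedgerError(f"no annotation for gene {gene}")
        if track.max_fold(model.span.expanded(radius)) >= fold_threshold:
            return True
    return False


def flag_misannotation(
    gene_a: str,
    gene_b: str,
    models: Sequence[GeneModel],
    joining_transcripts: Iterable[tuple[str, str]],
) -> bool:
    """True iff the pair is adjacent, same-strand, and a known transcript
    model (e.g. EST-supported) joins the two gene ids — i.e. the "fusion" is
    one mis-split gene."""
    from .fusion_scoring import classify_fusion_type

    joined = {frozenset(p) for p in joining_transcripts}
    if frozenset((gene_a, gene_b)) not in joined:
        return False
    return classify_fusion_type(gene_a, gene_b, models) == "read-through"


def check_frame(fused: GeneModel, n_exons5: int) -> FrameReport:
    """Reading-frame check at the chimeric junction.

    The fusion is in frame iff the 5' partner's coding length up to the
    junction, plus the GTF frame of the 3' junction exon, is a whole number
    of codons.  Named 3'-gene domains wholly downstream of the junction are
    reported as retained only when the frame is preserved.
    """
    if not fused.cds:
        raise LedgerError(f"no coding model for {fused.gene_id}")
    if not 0 < n_exons5 < len(fused.exons):
        raise LedgerError("junction must split the exon list")
    len5 = sum(len(seg.interval) for seg in fused.cds[:n_exons5])
    phase = fused.cds[n_exons5].phase
    in_frame = (len5 + phase) % 3 == 0
    retained: list[str] = []
    if in_frame:
        junction_start = fused.exons[n_exons5].start
        retained = sorted(
            name
            for name, iv in fused.domains.items()
            if iv.start >= junction_start
        )
    return FrameReport(in_frame=in_frame, junction_phase=phase, retained_domains=retained)


# ---------------------------------------------------------------------------
# the ledger itself
# ---------------------------------------------------------------------------

@dataclass
class EvidenceBundle:
    """Per-candidate evidence feeding the staged exclusions.

    Dictionaries are keyed by ``(gene5, gene3, sample)`` with a
    ``(gene5, gene3)`` fallback.
    """

    known_fusions: set[frozenset] = field(default_factory=set)
    amplicon: Mapping = field(default_factory=dict)
    misannotation: Mapping = field(default_factory=dict)
    junction_reads: Mapping = field(default_factory=dict)
    frame: Mapping = field(default_factory=dict)

    def get(self, table: Mapping, c: FusionCandidate, what: str):
        for key in ((c.gene5, c.gene3, c.sample), (c.gene5, c.gene3)):
            if key in table:
                return table[key]
        raise LedgerError(f"missing {what} evidence for {c.gene5}-{c.gene3} ({c.sample})")


def apply_ledger(
    candidates: Sequence[FusionCandidate], evidence: EvidenceBundle
) -> list[LedgerRow]:
    """One row per candidate; rules applied in the stated order."""
    rows = []
    for c in candidates:
        if frozenset((c.gene5, c.gene3)) in evidence.known_fusions:
            rows.append(LedgerRow(c, "set_aside_known", "known fusion"))
            continue
        if evidence.get(evidence.amplicon, c, "amplicon"):
            rows.append(LedgerRow(c, "excluded", "amplicon"))
            continue
        if evidence.get(evidence.misannotation, c, "misannotation"):
            rows.append(LedgerRow(c, "excluded", "misannotation"))
            continue
        frame: Optional[FrameReport] = evidence.get(evidence.frame, c, "frame")
        if frame is not None and not frame.in_frame:
            rows.append(LedgerRow(c, "excluded", "off-frame"))
            continue
        if evidence.get(evidence.junction_reads, c, "junction reads") == 0:
            rows.append(LedgerRow(c, "excluded", "no junction reads"))
            continue
        rows.append(LedgerRow(c, "retained"))
    return rows


def ledger_to_frame(rows: Sequence[LedgerRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                fusion_type=r.candidate.fusion_type,
                gene1=r.candidate.gene5,
                gene2=r.candidate.gene3,
                sample=r.candidate.sample,
                score=r.candidate.resper,
                status=r.status,
                reason=r.reason,
            )
            for r in rows
        ],
        columns=["fusion_type", "gene1", "gene2", "sample", "score", "status", "reason"],
    )


# ---------------------------------------------------------------------------
# bundled worked example (published GBM survey top-20 decision table)
# ---------------------------------------------------------------------------

def load_worked_example() -> tuple[list[FusionCandidate], EvidenceBundle]:
    """The bundled top-20 candidate table from a GBM fusion survey, with its
    evidence labels encoded per row (amplicon / joining-transcript /
    frame / junction-read / known-fusion status)."""
    path = resources.files("fusionsurvey.data").joinpath("gbm_top20_candidates.tsv")
    with resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t", dtype={"sample": str})

    candidates = []
    amplicon, misannotation, junction, frame = {}, {}, {}, {}
    known: set[frozenset] = set()
    for _, row in table.iterrows():
        c = FusionCandidate(
            gene5=row["gene1"],
            gene3=row["gene2"],
            fusion_type=row["fusion_type"],
            inter_reads=int(row["inter_reads"]),
            resper=float(row["resper"]),
            sample=row["sample"],
        )
        candidates.append(c)
        key = (c.gene5, c.gene3, c.sample)
        amplicon[key] = bool(row["amplicon"])
        misannotation[key] = bool(row["misannotation"])
        junction[key] = int(row["junction_reads"])
        frame[key] = FrameReport(bool(row["in_frame"]), 0)
        if bool(row["known"]):
            known.add(frozenset((c.gene5, c.gene3)))
    bundle = EvidenceBundle(
        known_fusions=known,
        amplicon=amplicon,
        misannotation=misannotation,
        junction_reads=junction,
        frame=frame,
    )
    return candidates, bundle
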