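"""Pipeline orchestration: survey -> ledger -> validation, with manifests.

Stage groups mirror the analysis workflow: (1) a genome-wide survey scoring
discordant-pair fusion candidates, (2) the exclusion ledger, (3) the
per-candidate deep dive (coverage discontinuity, chimeric junction reads,
DNA fusion-point mapping, frame check, somatic status).  Run manifests list
inputs, their SHA-1 hashes and all parameters — and contain no timestamps,
so identical config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import breakpoint as bp
from . import candidate_ledger as ledger_mod
from . import fusion_scoring as scoring
from .io_model import (
    Alignment,
    CdsSegment,
    Genome,
    GeneModel,
    Interval,
    ReadPair,
    read_bed,
    read_fasta,
    read_fastq,
    read_gtf,
)
from .mapper import TrimStats, build_index, map_pair_exact, trim_reads

log = logging.getLogger("fusionsurvey")


class PipelineError(RuntimeError):
    pass


@dataclass
class Thresholds:
    dasper: float = 1.0
    resper: float = 1.0
    fold_threshold: float = 3.0
    amplicon_radius: int = 1_000_000
    min_overhang: int = 8
    discontinuity_ratio: float = 10.0
    min_exon_depth: float = 5.0
    fold_cutoff: float = 2.0
    outlier_k: float = 5.0
    background: float = 1.0
    gene_flank: int = 1000
    min_breakpoint_support: int = 2
    copy_window: int = 2000

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise PipelineError(f"threshold {name} must be positive")


@dataclass
class PipelineConfig:
    outdir: Path
    genome: Path
    gtf: Path
    rna_1: Optional[Path] = None
    rna_2: Optional[Path] = None
    exome_tumor_1: Optional[Path] = None
    exome_tumor_2: Optional[Path] = None
    exome_normal_1: Optional[Path] = None
    exome_normal_2: Optional[Path] = None
    repeats: Optional[Path] = None
    joining_transcripts: Optional[Path] = None
    known_fusions: Optional[Path] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    sample: str = "sample"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        paths = {
            key: Path(value) if value is not None else None
            for key, value in raw.items()
            if key not in ("seed", "sample")
        }
        return cls(
            thresholds=thresholds,
            seed=int(raw.get("seed", 0)),
            sample=str(raw.get("sample", "sample")),
            **paths,
        )

    def require(self, *names: str) -> None:
        for name in names:
            path = getattr(self, name)
            if path is None:
                raise PipelineError(f"config is missing required input '{name}'")
            if not Path(path).exists():
                raise PipelineError(f"input file not found: {path} ('{name}')")


def _sha1(path: Path) -> str:
    digest = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(config: PipelineConfig, stage: str, counts: dict) -> Path:
    inputs = {}
    for name in (
        "genome",
        "gtf",
        "rna_1",
        "rna_2",
        "exome_tumor_1",
        "exome_tumor_2",
        "exome_normal_1",
        "exome_normal_2",
        "repeats",
        "joining_transcripts",
        "known_fusions",
    ):
        path = getattr(config, name)
        if path is not None and Path(path).exists():
            inputs[name] = {"path": str(path), "sha1": _sha1(Path(path))}
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "sample": config.sample,
        "thresholds": asdict(config.thresholds),
        "inputs": inputs,
        "counts": counts,
    }
    config.outdir.mkdir(parents=True, exist_ok=True)
    out = config.outdir / f"manifest_{stage}.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


# ---------------------------------------------------------------------------
# survey
# ---------------------------------------------------------------------------

def _map_reads(
    genome: Genome, pairs: Sequence[ReadPair], k: int = 17
) -> list[tuple[ReadPair, list[tuple[Alignment, Alignment]]]]:
    index = build_index(genome, k)
    return [(p, map_pair_exact(index, p)) for p in pairs]


def run_survey(config: PipelineConfig) -> pd.DataFrame:
    """Trim -> exact paired mapping -> discordant pairs -> scores.

    The output table holds every scored candidate sorted by RESPER
    descending; ``pass_filter`` marks the strict DASPER/RESPER cutoffs.
    """
    config.require("genome", "gtf", "rna_1", "rna_2")
    genome = read_fasta(config.genome)
    models = read_gtf(config.gtf)
    pairs = list(read_fastq(config.rna_1, config.rna_2, origin="rnaseq"))

    stats = TrimStats()
    trimmed = trim_reads(pairs, "five_prime_30", stats)
    log.info("survey: %d pairs in, %d trimmed, %d skipped", len(pairs), stats.kept, stats.skipped)

    mapped = _map_reads(genome, trimmed)
    n_mapped = sum(1 for _p, alns in mapped if alns)
    discordant, intra, acct = scoring.collect_discordant_pairs(mapped, models)
    candidates = scoring.build_candidates(discordant, intra, models, config.sample)
    scoring.score_candidates(candidates, max(acct.mapped_pairs, 1))
    passing = {c.key for c in scoring.threshold_filter(
        candidates, config.thresholds.dasper, config.thresholds.resper
    )}
    log.info(
        "survey: %d mapped pairs, %d discordant, %d candidates, %d pass filter",
        n_mapped, acct.discordant_pairs, len(candidates), len(passing),
    )

    frame = scoring.candidates_to_frame(candidates)
    frame["pass_filter"] = [c.key in passing for c in candidates]
    frame = frame.sort_values(
        ["RESPER", "inter_reads", "gene1", "gene2"],
        ascending=[False, False, True, True],
    ).reset_index(drop=True)
    config.outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(config.outdir / "candidates.tsv", sep="\t", index=False, float_format="%.6g")
    write_manifest(
        config,
        "survey",
        {
            "input_pairs": len(pairs),
            "trimmed": stats.kept,
            "skipped": stats.skipped,
            "mapped_pairs": n_mapped,
            "discordant_pairs": acct.discordant_pairs,
            "candidates": len(candidates),
            "pass_filter": len(passing),
        },
    )
    return frame


# ---------------------------------------------------------------------------
# ledger
# ---------------------------------------------------------------------------

def _virtual_fusion_model(
    g5: GeneModel, g3: GeneModel, n5: int, i3: int
) -> Optional[GeneModel]:
    """Chimeric model joining g5's first ``n5`` exons to g3's exons after
    intron ``i3``; None when no coherent + strand model can be built."""
    if g5.strand != "+" or g3.strand != "+" or g5.contig != g3.contig:
        return None
    if not (g5.cds and g3.cds):
        return None
    exons = list(g5.exons[:n5]) + list(g3.exons[i3 + 1 :])
    cds = list(g5.cds[:n5]) + list(g3.cds[i3 + 1 :])
    if any(a.end > b.start for a, b in zip(exons, exons[1:])):
        return None
    domains = dict(g3.domains)
    domains.update(g5.domains)
    try:
        return GeneModel(
            f"{g5.gene_id}-{g3.gene_id}",
            Interval(g5.contig, exons[0].start, exons[-1].end, "+"),
            exons,
            cds,
            domains,
        )
    except ValueError:
        return None


def gather_evidence(
    config: PipelineConfig,
    candidates: Sequence[scoring.FusionCandidate],
    genome: Genome,
    models: Sequence[GeneModel],
    rna_pairs: Optional[Sequence[ReadPair]] = None,
) -> ledger_mod.EvidenceBundle:
    """Assemble the evidence bundle from the configured inputs.

    Copy-number folds come from tumor exome reads when provided; the
    joining-transcript table and known-fusion list are plain files;
    junction-read counts and frame reports are computed per candidate from
    the RNA reads and coverage-derived junctions.
    """
    by_id = {m.gene_id: m for m in models}
    th = config.thresholds

    known: set[frozenset] = set()
    if config.known_fusions and Path(config.known_fusions).exists():
        for line in Path(config.known_fusions).read_text().splitlines():
            parts = line.split()
            if len(parts) >= 2:
                known.add(frozenset(parts[:2]))

    joining: list[tuple[str, str]] = []
    if config.joining_transcripts and Path(config.joining_transcripts).exists():
        for line in Path(config.joining_transcripts).read_text().splitlines():
            parts = line.split()
            if len(parts) >= 2:
                joining.append((parts[0], parts[1]))

    track = None
    if config.exome_tumor_1 and Path(config.exome_tumor_1).exists():
        exome = list(
            read_fastq(config.exome_tumor_1, config.exome_tumor_2, origin="exome")
        )
        mapped = _map_reads(genome, exome)
        alignments = [
            a
            for _p, alns in mapped
            for pair_aln in alns[:1]
            for a in pair_aln
            if a.unique
        ]
        track = ledger_mod.estimate_copy_number(alignments, genome, th.copy_window)

    if rna_pairs is None and config.rna_1 and Path(config.rna_1).exists():
        rna_pairs = list(read_fastq(config.rna_1, config.rna_2, origin="rnaseq"))

    rna_alignments: Optional[list[Alignment]] = None
    if rna_pairs is not None:
        mapped = _map_reads(genome, rna_pairs)
        rna_alignments = [
            a
            for _p, alns in mapped
            for pair_aln in alns[:1]
            for a in pair_aln
            if a.unique
        ]

    amplicon, misannot, junction, frame = {}, {}, {}, {}
    for c in candidates:
        key = (c.gene5, c.gene3, c.sample)
        amplicon[key] = (
            ledger_mod.flag_amplicon(c, track, models, th.amplicon_radius, th.fold_threshold)
            if track is not None
            else False
        )
        misannot[key] = ledger_mod.flag_misannotation(c.gene5, c.gene3, models, joining)

        junction[key] = 0
        frame[key] = None
        g5, g3 = by_id.get(c.gene5), by_id.get(c.gene3)
        if g5 is None or g3 is None or rna_pairs is None or rna_alignments is None:
            continue
        i5 = _suspected_intron(rna_alignments, g5, th)
        i3 = _suspected_intron(rna_alignments, g3, th)
        if i5 is None or i3 is None:
            continue
        pair_ref = bp.build_gene_pair_reference(genome, g5, g3, th.gene_flank)
        evidence = bp.find_junction_reads(
            rna_pairs, pair_ref, i5, i3 + 1, th.min_overhang
        )
        junction[key] = evidence.count
        virtual = _virtual_fusion_model(g5, g3, i5 + 1, i3)
        if virtual is not None:
            frame[key] = ledger_mod.check_frame(virtual, i5 + 1)
    return ledger_mod.EvidenceBundle(
        known_fusions=known,
        amplicon=amplicon,
        misannotation=misannot,
        junction_reads=junction,
        frame=frame,
    )


def _suspected_intron(
    alignments: Sequence[Alignment], gene: GeneModel, th: Thresholds
) -> Optional[int]:
    track = bp.compute_coverage(alignments, gene.span)
    return bp.locate_discontinuity(
        track, gene.exons, th.discontinuity_ratio, th.min_exon_depth
    )


def run_ledger(
    config: PipelineConfig,
    candidates: Sequence[scoring.FusionCandidate],
    evidence: Optional[ledger_mod.EvidenceBundle] = None,
) -> pd.DataFrame:
    """Apply the staged exclusions; retained candidates are listed first."""
    config.require("genome", "gtf")
    genome = read_fasta(config.genome)
    models = read_gtf(config.gtf)
    if evidence is None:
        evidence = gather_evidence(config, candidates, genome, models)
    rows = ledger_mod.apply_ledger(candidates, evidence)
    frame = ledger_mod.ledger_to_frame(rows)
    order = {"retained": 0, "set_aside_known": 1, "excluded": 2}
    frame = frame.sort_values(
        ["status", "score"], key=lambda col: col.map(order) if col.name == "status" else -col
    ).reset_index(drop=True)
    config.outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(config.outdir / "ledger.tsv", sep="\t", index=False, float_format="%.6g")
    write_manifest(
        config,
        "ledger",
        {
            "candidates": len(rows),
            "retained": sum(r.status == "retained" for r in rows),
            "excluded": sum(r.status == "excluded" for r in rows),
            "set_aside": sum(r.status == "set_aside_known" for r in rows),
        },
    )
    return frame


# ---------------------------------------------------------------------------
# validation deep dive
# ---------------------------------------------------------------------------

def run_validation(config: PipelineConfig, gene5: str, gene3: str) -> dict:
    """Per-candidate evidence report: junction reads, DNA fusion point with
    micro-homology, frame check and somatic status."""
    config.require("genome", "gtf", "rna_1", "rna_2")
    genome = read_fasta(config.genome)
    models = read_gtf(config.gtf)
    by_id = {m.gene_id: m for m in models}
    th = config.thresholds
    if gene5 not in by_id or gene3 not in by_id:
        raise PipelineError(f"unknown gene in pair {gene5}-{gene3}")
    g5, g3 = by_id[gene5], by_id[gene3]

    rna_pairs = list(read_fastq(config.rna_1, config.rna_2, origin="rnaseq"))
    mapped = _map_reads(genome, rna_pairs)
    rna_alignments = [
        a
        for _p, alns in mapped
        for pair_aln in alns[:1]
        for a in pair_aln
        if a.unique
    ]

    i5 = _suspected_intron(rna_alignments, g5, th)
    i3 = _suspected_intron(rna_alignments, g3, th)
    report: dict = {
        "gene5": gene5,
        "gene3": gene3,
        "suspected_intron5": i5,
        "suspected_intron3": i3,
    }
    if i5 is None or i3 is None:
        report.update(level="no coverage discontinuity", junction_reads=0)
        _finish_validation(config, report)
        return report

    pair_ref = bp.build_gene_pair_reference(genome, g5, g3, th.gene_flank)
    evidence = bp.find_junction_reads(rna_pairs, pair_ref, i5, i3 + 1, th.min_overhang)
    report["junction_reads"] = evidence.count

    virtual = _virtual_fusion_model(g5, g3, i5 + 1, i3)
    if virtual is not None:
        fr = ledger_mod.check_frame(virtual, i5 + 1)
        report["in_frame"] = fr.in_frame
        report["retained_domains"] = fr.retained_domains

    suspected = {}
    for gene, intron_idx in ((g5, i5), (g3, i3)):
        intron = gene.introns()[intron_idx]
        lifted = pair_ref.to_ref(intron)
        if lifted is not None:
            suspected[gene.gene_id] = lifted
    mask = []
    if config.repeats and Path(config.repeats).exists():
        for iv in read_bed(config.repeats):
            lifted = pair_ref.to_ref(iv)
            if lifted is not None:
                mask.append(lifted)

    reads_by_source: dict[str, list[str]] = {}
    source_inputs = [
        ("tumor_rna", config.rna_1, config.rna_2, rna_pairs),
        ("tumor_exome", config.exome_tumor_1, config.exome_tumor_2, None),
        ("normal_exome", config.exome_normal_1, config.exome_normal_2, None),
    ]
    n_candidates = {}
    for source, p1, p2, preloaded in source_inputs:
        if p1 is None or not Path(p1).exists():
            continue
        pairs = preloaded if preloaded is not None else list(
            read_fastq(p1, p2, origin="exome")
        )
        retained = bp.map_fusion_point_reads(pairs, pair_ref, suspected, mask)
        reads_by_source[source] = [
            (p.seq1 if mate == 1 else p.seq2) for p, mate in retained
        ]
        n_candidates[source] = len(retained)
    report["fusion_point_reads"] = n_candidates

    try:
        call = bp.resolve_breakpoint(
            reads_by_source,
            genome,
            g5,
            g3,
            th.gene_flank,
            th.min_breakpoint_support,
        )
        report.update(
            level="DNA",
            break5=list(call.interval5),
            break3=list(call.interval3),
            micro_homology=call.homology,
            support=call.support,
            somatic=call.somatic,
        )
    except bp.BreakpointError:
        if evidence.count > 0:
            report["level"] = "undetermined"  # RNA junction without DNA support
        else:
            report["level"] = "no confident fusion point"
    _finish_validation(config, report)
    return report


def _finish_validation(config: PipelineConfig, report: dict) -> None:
    config.outdir.mkdir(parents=True, exist_ok=True)
    out = config.outdir / f"validation_{report['gene5']}-{report['gene3']}.json"
    out.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    write_manifest(
        config,
        f"validation_{report['gene5']}-{report['gene3']}",
        {"junction_reads": report.get("junction_reads", 0)},
    )
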