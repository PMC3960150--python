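import numpy as np
import pytest
from Bio.Seq import Seq

from fusionsurvey.candidate_ledger import (
    CopyNumberTrack,
    EvidenceBundle,
    FrameReport,
    LedgerError,
    apply_ledger,
    check_frame,
    estimate_copy_number,
    flag_amplicon,
    flag_misannotation,
    ledger_to_frame,
    load_worked_example,
)
from fusionsurvey.fusion_scoring import FusionCandidate
from fusionsurvey.io_model import Alignment, CdsSegment, Genome, GeneModel, Interval
from fusionsurvey.simgen import FusionSpec, SimConfig, apply_fusion, make_reference


def _gene(gid, contig, start, end, strand="+"):
    return GeneModel(gid, Interval(contig, start, end, strand), [Interval(contig, start, end, strand)])


class TestCopyNumber:
    def test_uniform_coverage_fold_one(self):
        genome = Genome({"c": "A" * 10_000})
        alns = [
            Alignment("r%d" % i, 1, Interval("c", s, s + 100), 100)
            for i, s in enumerate(range(0, 9900, 10))
        ]
        track = estimate_copy_number(alns, genome, window=1000)
        assert np.allclose(track.folds["c"], 1.0, atol=0.15)

    def test_empty_alignments_error(self):
        with pytest.raises(LedgerError, match="insufficient coverage"):
            estimate_copy_number([], Genome({"c": "ACGT" * 100}), window=100)

    def test_amplified_region_fold_recovered(self):
        # uniform ~30x background with an 8x-amplified 2 kb region:
        # the recovered fold lands in [7, 9]
        rng = np.random.default_rng(9)
        L, rl = 20_000, 100
        genome = Genome({"c": "A" * L})
        amplified = Interval("c", 8000, 10_000)
        alignments = []
        i = 0
        for depth_fold, region in ((1, Interval("c", 0, L)), (7, amplified)):
            n = depth_fold * 30 * len(region) // rl
            for s in rng.integers(0, len(region) - rl, size=n):
                start = region.start + int(s)
                alignments.append(
                    Alignment(f"r{i}", 1, Interval("c", start, start + rl), rl)
                )
                i += 1
        track = estimate_copy_number(alignments, genome, window=500)
        fold = track.max_fold(Interval("c", 8500, 9500))
        assert 7.0 <= fold <= 9.0
        assert track.max_fold(Interval("c", 2000, 4000)) < 2.0


class TestAmplicon:
    def _track(self, folds):
        return CopyNumberTrack(1000, {"c1": np.array(folds, dtype=float)})

    def test_gene_near_high_fold_window_flagged(self):
        # gene at 2-3 kb, 8-fold window at 5-6 kb, radius 2.5 kb
        track = self._track([1, 1, 1, 1, 1, 8, 1, 1])
        cand = FusionCandidate("A", "B")
        models = [_gene("A", "c1", 2000, 3000), _gene("B", "c1", 7500, 7900)]
        assert flag_amplicon(cand, track, models, radius=2500, fold_threshold=3.0)

    def test_gene_outside_radius_not_flagged(self):
        track = self._track([1, 1, 1, 1, 1, 1, 1, 8])
        cand = FusionCandidate("A", "B")
        models = [_gene("A", "c1", 0, 500), _gene("B", "c1", 1000, 1500)]
        assert not flag_amplicon(cand, track, models, radius=2000, fold_threshold=3.0)

    def test_mild_amplification_tolerated(self):
        track = self._track([1.8] * 8)
        cand = FusionCandidate("A", "B")
        models = [_gene("A", "c1", 0, 500), _gene("B", "c1", 1000, 1500)]
        assert not flag_amplicon(cand, track, models, radius=10_000, fold_threshold=3.0)


class TestMisannotation:
    def test_joining_transcript_flags_adjacent_pair(self):
        models = [_gene("A", "c1", 0, 1000), _gene("B", "c1", 2000, 3000)]
        assert flag_misannotation("A", "B", models, [("A", "B")])

    def test_without_joining_transcript_not_flagged(self):
        models = [_gene("A", "c1", 0, 1000), _gene("B", "c1", 2000, 3000)]
        assert not flag_misannotation("A", "B", models, [])

    def test_interchromosomal_never_flagged(self):
        models = [_gene("A", "c1", 0, 1000), _gene("B", "c2", 0, 1000)]
        assert not flag_misannotation("A", "B", models, [("A", "B")])


def _fused_model(len5: int, phase3: int):
    """Two-exon chimera with a 5' CDS of len5 and 3' junction exon phase."""
    e1 = Interval("c", 0, len5)
    e2 = Interval("c", len5 + 100, len5 + 400)
    return GeneModel(
        "F",
        Interval("c", 0, len5 + 400),
        [e1, e2],
        [CdsSegment(e1, 0), CdsSegment(e2, phase3)],
        {"kinase": e2},
    )


class TestCheckFrame:
    def test_codon_multiple_is_in_frame(self):
        report = check_frame(_fused_model(300, 0), 1)
        assert report.in_frame and report.retained_domains == ["kinase"]

    def test_one_extra_base_breaks_frame(self):
        report = check_frame(_fused_model(301, 0), 1)
        assert not report.in_frame and report.retained_domains == []

    def test_phase_complement(self):
        assert check_frame(_fused_model(301, 2), 1).in_frame

    def test_missing_cds_errors(self):
        bare = GeneModel("F", Interval("c", 0, 10), [Interval("c", 0, 10)])
        with pytest.raises(LedgerError, match="no coding model"):
            check_frame(bare, 1)

    def test_frame_agrees_with_direct_translation(self):
        """Arithmetic frame check == stop-free conceptual translation, on
        200 random toy fusions."""
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 200:
            cfg = SimConfig(
                seed=int(rng.integers(0, 2**31)),
                n_genes=4,
                exons_per_gene=3,
                exon_length=(40, 80),
                intron_length=(150, 250),
                n_pairs=10,
            )
            genome, models = make_reference(cfg)
            plus = [m for m in models if m.strand == "+"]
            i5, i3 = int(rng.integers(0, 2)), int(rng.integers(0, 2))
            h = int(rng.integers(0, 3))
            try:
                tumor, fused, _ = apply_fusion(
                    genome, models,
                    FusionSpec(plus[0].gene_id, plus[1].gene_id, i5, i3, homology=h),
                )
            except Exception:
                continue
            report = check_frame(fused, i5 + 1)
            cds = fused.cds_sequence(tumor)
            protein = str(Seq(cds[: len(cds) // 3 * 3]).translate())
            premature_stop = "*" in protein[:-1]
            assert report.in_frame == (not premature_stop)
            checked += 1


class TestWorkedExample:
    def test_staged_exclusion_counts(self):
        candidates, evidence = load_worked_example()
        assert len(candidates) == 20
        rows = apply_ledger(candidates, evidence)

        set_aside = [r for r in rows if r.status == "set_aside_known"]
        primary_excluded = [r for r in rows if r.reason in ("amplicon", "misannotation")]
        remaining = len(rows) - len(set_aside) - len(primary_excluded)
        assert remaining == 7

        retained = [r for r in rows if r.status == "retained"]
        assert len(retained) == 3
        partners = {(r.candidate.gene5, r.candidate.gene3) for r in retained}
        assert ("NFASC", "NTRK1") in partners and ("BCAN", "NTRK1") in partners
        assert ("YEATS4", "XRCC6BP1") in partners

        kif5a_rows = [r for r in rows if {"KIF5A", "BC033961"} == {r.candidate.gene5, r.candidate.gene3}]
        assert len(kif5a_rows) == 4
        assert all(r.reason == "misannotation" for r in kif5a_rows)

    def test_partition_property(self):
        candidates, evidence = load_worked_example()
        rows = apply_ledger(candidates, evidence)
        assert len(rows) == len(candidates)
        statuses = {"retained", "excluded", "set_aside_known"}
        assert {r.status for r in rows} <= statuses
        assert all((r.status == "excluded") == (r.reason in
                   ("amplicon", "misannotation", "off-frame", "no junction reads"))
                   for r in rows)

    def test_rule_order_reports_first_reason(self):
        c = FusionCandidate("X", "Y", sample="s1")
        evidence = EvidenceBundle(
            amplicon={("X", "Y"): True},
            misannotation={("X", "Y"): True},
            junction_reads={("X", "Y"): 0},
            frame={("X", "Y"): FrameReport(False, 0)},
        )
        [row] = apply_ledger([c], evidence)
        assert row.status == "excluded" and row.reason == "amplicon"

    def test_missing_evidence_names_candidate(self):
        c = FusionCandidate("X", "Y", sample="s1")
        with pytest.raises(LedgerError, match="X-Y"):
            apply_ledger([c], EvidenceBundle())

    def test_empty_ledger(self):
        assert apply_ledger([], EvidenceBundle()) == []

    def test_frame_output_columns(self):
        candidates, evidence = load_worked_example()
        frame = ledger_to_frame(apply_ledger(candidates, evidence))
        assert list(frame.columns) == [
            "fusion_type", "gene1", "gene2", "sample", "score", "status", "reason",
        ]
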