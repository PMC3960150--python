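import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fusionsurvey.io_model import revcomp, write_fasta, write_gtf
from fusionsurvey.simgen import (
    ConfigError,
    FusionSpec,
    SimConfig,
    SimulationError,
    apply_fusion,
    default_cohort_signature,
    make_reference,
    make_repeats,
    models_on_tumor,
    simulate_cohort_expression,
    simulate_exome,
    simulate_rnaseq,
)


def test_reference_is_deterministic(tmp_path):
    cfg = SimConfig(seed=7, n_genes=3)
    out = []
    for run in ("a", "b"):
        genome, models = make_reference(cfg)
        fa = tmp_path / f"{run}.fa"
        gtf = tmp_path / f"{run}.gtf"
        write_fasta(genome, fa)
        write_gtf(models, gtf)
        out.append((fa.read_bytes(), gtf.read_bytes()))
    assert out[0] == out[1]
    assert len(models) == 3


def test_exon_sequences_appear_at_their_intervals(fusion_scenario):
    s = fusion_scenario
    chrom = s.genome.sequences["chr1"]
    for m in s.models:
        for e in m.exons:
            assert chrom[e.start : e.end] == s.genome.sequences[e.contig][e.start : e.end]
        # spliced transcript equals concatenation of (strand-aware) exon pieces
        expected = "".join(
            chrom[e.start : e.end] if m.strand == "+" else revcomp(chrom[e.start : e.end])
            for e in m.exons
        )
        assert m.spliced_sequence(s.genome) == expected


def test_both_strands_and_domains_present(fusion_scenario):
    strands = {m.strand for m in fusion_scenario.models}
    assert strands == {"+", "-"}
    kinase = fusion_scenario.by_id["G007"]
    assert set(kinase.domains) == {"transmembrane", "kinase"}


def test_config_validation():
    with pytest.raises(ConfigError):
        SimConfig(n_genes=0)
    with pytest.raises(ConfigError):
        SimConfig(premrna_fraction=1.5)
    with pytest.raises(ConfigError):
        SimConfig(exon_length=(10, 5))


class TestApplyFusion:
    def test_microhomology_context(self, fusion_scenario):
        s = fusion_scenario
        seq = s.genome.sequences["chr1"]
        b5, b3, h = s.truth.break5, s.truth.break3, s.spec.homology
        assert seq[b5 - h : b5] == seq[b3 - h : b3]
        # homology is exactly h: not extendable on either side
        assert seq[b5 - h - 1] != seq[b3 - h - 1]
        assert seq[b5] != seq[b3]
        # tumor contig is the junction of the two wild-type pieces
        assert s.tumor.sequences[s.truth.tumor_contig] == seq[:b5] + seq[b3:]
        # the intact allele is untouched
        assert s.tumor.sequences["chr1"] == seq

    def test_h0_is_unambiguous(self):
        cfg = SimConfig(seed=2)
        genome, models = make_reference(cfg)
        spec = FusionSpec("G000", "G003", 1, 1, homology=0)
        _, _, truth = apply_fusion(genome, models, spec)
        assert truth.homology_interval5 is None
        seq = genome.sequences["chr1"]
        assert seq[truth.break5] != seq[truth.break3]
        assert seq[truth.break5 - 1] != seq[truth.break3 - 1]

    def test_fused_transcript_matches_independent_splice(self, fusion_scenario):
        s = fusion_scenario
        chrom = s.tumor.sequences[s.truth.tumor_contig]
        manual = "".join(chrom[e.start : e.end] for e in s.fused.exons)
        assert s.truth.fused_transcript == manual
        n5 = s.spec.break_intron5 + 1
        g5_part = "".join(
            s.genome.sequences["chr1"][e.start : e.end]
            for e in s.by_id[s.spec.gene5].exons[:n5]
        )
        assert manual.startswith(g5_part)
        assert s.truth.junction_offset == len(g5_part)

    def test_infeasible_homology_raises(self):
        cfg = SimConfig(seed=2)
        genome, models = make_reference(cfg)
        with pytest.raises(SimulationError):
            apply_fusion(genome, models, FusionSpec("G000", "G003", 1, 1, homology=40))

    def test_wrong_orientation_raises(self):
        cfg = SimConfig(seed=2)
        genome, models = make_reference(cfg)
        with pytest.raises(SimulationError):  # G002 is a minus-strand gene
            apply_fusion(genome, models, FusionSpec("G000", "G002", 1, 1))


class TestSimulateRnaseq:
    def test_no_premrna_means_no_intronic_reads(self):
        cfg = SimConfig(seed=3, n_pairs=300, premrna_fraction=0.0)
        genome, models = make_reference(cfg)
        transcripts = [m.spliced_sequence(genome) for m in models]
        pairs, truth = simulate_rnaseq(genome, models, cfg)
        assert (truth.template == "spliced").all()
        for p in pairs:
            hit = any(
                p.seq1 in t or revcomp(p.seq1) in t for t in transcripts
            )
            assert hit, "read contains intron-only sequence"

    def test_one_hot_weights(self):
        cfg = SimConfig(
            seed=3, n_pairs=100, expression_weights={"G001": 1.0}
        )
        genome, models = make_reference(cfg)
        _, truth = simulate_rnaseq(genome, models, cfg)
        assert set(truth.gene_id) == {"G001"}

    def test_coverage_matches_closed_form(self):
        # expected reads overlapping a fixed transcript position:
        # N_gene * read_len / L_effective, checked within 3 sigma (Poisson)
        cfg = SimConfig(
            seed=4,
            n_pairs=4000,
            premrna_fraction=0.0,
            expression_weights={"G000": 1.0},
            insert_mean=200,
            insert_sd=0.0,
        )
        genome, models = make_reference(cfg)
        _, truth = simulate_rnaseq(genome, models, cfg)
        gene = models[0]
        L = len(gene.spliced_sequence(genome))
        pos = L // 2
        rl = cfg.read_length
        n_cover = 0
        for _, row in truth.iterrows():
            for a, b in (
                (row.frag_start, row.frag_start + rl),
                (row.frag_end - rl, row.frag_end),
            ):
                if a <= pos < b:
                    n_cover += 1
        frag = 200
        expected = 2 * cfg.n_pairs * rl / (L - frag + 1)
        assert abs(n_cover - expected) <= 3 * np.sqrt(expected)

    def test_junction_truth_matches_string_search(self, fusion_scenario):
        # independent oracle: substring search over the known 152-nt window,
        # requiring >= 8 nt on each side of the junction (spec of truth table)
        s = fusion_scenario
        joff, rl = s.truth.junction_offset, s.config.read_length
        window = s.truth.fused_transcript[joff - rl : joff + rl]
        n_string = 0
        for p in s.rna:
            for seq in (p.seq1, p.seq2):
                for probe in (seq, revcomp(seq)):
                    start = window.find(probe)
                    if start != -1 and start + 8 <= rl <= start + len(probe) - 8:
                        n_string += 1
                        break
        assert n_string == int(s.rna_truth.junction_mates.sum())


class TestSimulateExome:
    def test_zero_flank_reads_stay_in_exons(self):
        cfg = SimConfig(seed=5, n_pairs=200, exome_flank=0, insert_mean=100, insert_sd=5)
        genome, models = make_reference(cfg)
        _, truth = simulate_exome(genome, models, cfg, "tumor")
        exons = [e for m in models for e in m.exons]
        for _, row in truth.iterrows():
            assert any(
                e.start <= row.frag_start and row.frag_end <= e.end for e in exons
            )

    def test_somatic_junction_reads_only_in_tumor(self, fusion_scenario):
        s = fusion_scenario
        b5, h = s.truth.tumor_break, s.spec.homology
        window = s.tumor.sequences[s.truth.tumor_contig][b5 - 76 : b5 + 76]

        def junction_hits(pairs):
            # informative junction reads need more than h bases on each side:
            # within the micro-homology a wild-type read is indistinguishable
            n = 0
            for p in pairs:
                for seq in (p.seq1, p.seq2):
                    for probe in (seq, revcomp(seq)):
                        pos = window.find(probe)
                        if pos != -1 and pos + h < 76 < pos + len(probe) - h:
                            n += 1
                            break
            return n

        assert junction_hits(s.exome_tumor) > 0
        assert junction_hits(s.exome_normal) == 0

    def test_start_positions_uniform(self):
        cfg = SimConfig(
            seed=6, n_pairs=4000, insert_mean=76, insert_sd=0.0,
            expression_weights={"G000": 1.0},
        )
        genome, models = make_reference(cfg)
        _, truth = simulate_exome(genome, models, cfg, "tumor")
        # single-window check: starts uniform over [win_start, win_end - frag]
        win = truth.groupby(["window_start", "window_end"]).size().idxmax()
        sub = truth[(truth.window_start == win[0]) & (truth.window_end == win[1])]
        span = win[1] - win[0] - 76 + 1
        counts, _ = np.histogram(sub.frag_start - win[0], bins=8, range=(0, span))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_tissue_validation(self, fusion_scenario):
        with pytest.raises(ConfigError):
            simulate_exome(
                fusion_scenario.genome, fusion_scenario.models,
                fusion_scenario.config, "plasma",
            )


class TestCohortExpression:
    def test_noise_free_unactivated_is_constant(self):
        mat = simulate_cohort_expression(
            12, 20, default_cohort_signature(4, offset=0), [], noise_sd=0.0, seed=0
        )
        assert np.allclose(mat.values.values, mat.values.values[0, 0])

    def test_fold_one_is_identical_to_baseline(self):
        sig = default_cohort_signature(4, offset=0)
        a = simulate_cohort_expression(12, 20, sig, [0, 1], fold=1.0, seed=3)
        b = simulate_cohort_expression(12, 20, sig, [], fold=2.0, seed=3)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_outlier_planting(self):
        mat = simulate_cohort_expression(
            30, 10, default_cohort_signature(2, offset=0), [], seed=1,
            outlier_samples=[5], outlier_gene="EG0009", outlier_shift=8.0,
        )
        row = mat.values.loc["EG0009"]
        assert row.idxmax() == "S005"


def test_repeats_are_intronic(fusion_scenario):
    repeats = make_repeats(fusion_scenario.models)
    assert repeats
    for iv in repeats:
        assert any(
            intron.start <= iv.start and iv.end <= intron.end
            for m in fusion_scenario.models
            for intron in m.introns()
        )
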