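import numpy as np
import pytest

from fusionsurvey.io_model import Genome, GeneModel, Interval, ReadPair, revcomp
from fusionsurvey.mapper import (
    KmerIndex,
    MapperError,
    SplicedAligner,
    TrimStats,
    build_index,
    find_exact,
    map_pair_exact,
    map_single_spliced,
    trim_reads,
)


def _pair(seq1, seq2, rid="r0"):
    return ReadPair(rid, seq1, "I" * len(seq1), seq2, "I" * len(seq2))


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestTrim:
    def test_five_prime_30(self):
        rng = np.random.default_rng(0)
        seq1, seq2 = _random_seq(rng, 76), _random_seq(rng, 76)
        [out] = trim_reads([_pair(seq1, seq2)], "five_prime_30")
        assert (out.seq1, out.seq2) == (seq1[:30], seq2[:30])

    def test_dual_17_members(self):
        rng = np.random.default_rng(1)
        seq1, seq2 = _random_seq(rng, 76), _random_seq(rng, 76)
        out = trim_reads([_pair(seq1, seq2)], "dual_17")
        assert len(out) == 2  # one synthetic pair per mate
        assert out[0].read_id == "r0|1" and out[1].read_id == "r0|2"
        assert out[0].seq1 == seq1[0:17]
        assert out[0].seq2 == revcomp(seq1[59:76])
        assert out[1].seq1 == seq2[0:17]

    def test_short_reads_skipped_and_counted(self):
        stats = TrimStats()
        out = trim_reads([_pair("ACGT" * 5, "ACGT" * 5)], "dual_17", stats)
        assert out == [] and stats.skipped == 2

    def test_unknown_mode(self):
        with pytest.raises(MapperError):
            trim_reads([], "nonsense")


class TestIndex:
    def test_position_count(self):
        idx = KmerIndex({"c": "ACGTACGT"}, k=4)
        assert sum(len(v) for v in idx.index.values()) == 5

    def test_duplicate_kmer_lists_both(self):
        idx = KmerIndex({"c": "ACGTACGT"}, k=4)
        assert idx.lookup("ACGT") == [("c", 0), ("c", 4)]

    def test_k_bounds(self):
        with pytest.raises(MapperError):
            KmerIndex({"c": "ACGT"}, k=8)  # k exceeds shortest sequence
        with pytest.raises(MapperError):
            KmerIndex({"c": "ACGTACGT"}, k=0)


def _naive_find(sequences, query):
    """Brute-force both-strand exact search (independent oracle)."""
    hits = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        if "N" in q:
            continue
        for contig, seq in sequences.items():
            pos = seq.find(q)
            while pos != -1:
                hits.append(Interval(contig, pos, pos + len(q), strand))
                pos = seq.find(q, pos + 1)
    return sorted(hits, key=lambda iv: (iv.contig, iv.start, iv.strand))


def test_find_exact_equals_naive_scan():
    rng = np.random.default_rng(2)
    seqs = {"c1": _random_seq(rng, 3000), "c2": _random_seq(rng, 1500)}
    idx = KmerIndex(seqs, k=17)
    for _ in range(100):
        contig = "c1" if rng.random() < 0.5 else "c2"
        start = int(rng.integers(0, len(seqs[contig]) - 30))
        q = seqs[contig][start : start + 30]
        if rng.random() < 0.5:
            q = revcomp(q)
        if rng.random() < 0.2:
            q = _random_seq(rng, 30)  # mostly unmappable
        got = sorted(find_exact(idx, q), key=lambda iv: (iv.contig, iv.start, iv.strand))
        assert got == _naive_find(seqs, q)


def test_n_bases_never_match():
    idx = KmerIndex({"c": "ACGTACGTACGTACGTACGTA"}, k=17)
    assert find_exact(idx, "NCGTACGTACGTACGTA") == []


class TestMapPairExact:
    def test_planted_pair_unique(self):
        rng = np.random.default_rng(3)
        seq = _random_seq(rng, 2000)
        idx = KmerIndex({"c": seq}, k=17)
        frag = seq[100:350]
        pair = _pair(frag[:30], revcomp(frag[-30:]))
        [(a1, a2)] = map_pair_exact(idx, pair)
        assert a1.interval == Interval("c", 100, 130, "+")
        assert a2.interval == Interval("c", 320, 350, "-")
        assert a1.unique and a2.unique

    def test_absent_read_unmapped(self):
        rng = np.random.default_rng(4)
        idx = KmerIndex({"c": _random_seq(rng, 500)}, k=17)
        assert map_pair_exact(idx, _pair("A" * 30, "C" * 30)) == []

    def test_oracle_equivalence_on_planted_pairs(self):
        rng = np.random.default_rng(5)
        seqs = {"c": _random_seq(rng, 20000)}
        idx = KmerIndex(seqs, k=17)
        for _ in range(100):
            start = int(rng.integers(0, 20000 - 250))
            frag = seqs["c"][start : start + 250]
            pair = _pair(frag[:30], revcomp(frag[-30:]))
            for mate_seq in (pair.seq1, pair.seq2):
                got = sorted(
                    find_exact(idx, mate_seq), key=lambda iv: (iv.start, iv.strand)
                )
                assert got == _naive_find(seqs, mate_seq)

    def test_prefix_trim_monotonicity(self):
        # shortening a read can only add placements, never lose one
        rng = np.random.default_rng(6)
        seqs = {"c": _random_seq(rng, 5000)}
        idx = KmerIndex(seqs, k=17)
        for _ in range(30):
            start = int(rng.integers(0, 5000 - 76))
            read = seqs["c"][start : start + 76]
            full = {(iv.start, iv.strand) for iv in find_exact(idx, read)}
            short = {(iv.start, iv.strand) for iv in find_exact(idx, read[:30])}
            assert full <= short


class TestSplicedMapping:
    @pytest.fixture()
    def two_gene_ref(self):
        rng = np.random.default_rng(7)
        a = _random_seq(rng, 1200)
        b = _random_seq(rng, 1200)
        refs = Genome({"gA": a, "gB": b})
        # gA: exons [100,300) and [500,700); gB: exons [200,400) and [600,800)
        mA = GeneModel(
            "gA", Interval("gA", 100, 700), [Interval("gA", 100, 300), Interval("gA", 500, 700)]
        )
        mB = GeneModel(
            "gB", Interval("gB", 200, 800), [Interval("gB", 200, 400), Interval("gB", 600, 800)]
        )
        return refs, [mA, mB]

    def test_exonic_read_single_segment(self, two_gene_ref):
        refs, models = two_gene_ref
        read = refs.sequences["gA"][150:226]
        aln = map_single_spliced(refs, models, read)
        assert aln is not None and len(aln.segments) == 1
        assert aln.interval == Interval("gA", 150, 226, "+")

    def test_known_intron_split(self, two_gene_ref):
        refs, models = two_gene_ref
        # 30 bases ending at exon1 end + 46 bases from exon2 start
        read = refs.sequences["gA"][270:300] + refs.sequences["gA"][500:546]
        aln = map_single_spliced(refs, models, read)
        assert aln is not None and len(aln.segments) == 2
        (q0, q1), iv1 = aln.segments[0]
        (q2, q3), iv2 = aln.segments[1]
        assert (q1 - q0, q3 - q2) == (30, 46)
        assert iv1 == Interval("gA", 270, 300, "+")
        assert iv2 == Interval("gA", 500, 546, "+")
        assert iv2.start - iv1.end == 200  # gap equals the intron length

    def test_chimeric_junction_read(self, two_gene_ref):
        refs, models = two_gene_ref
        # 38/38 read across gA exon2 end -> gB exon2 start
        read = refs.sequences["gA"][662:700] + refs.sequences["gB"][600:638]
        aln = map_single_spliced(refs, models, read)
        assert aln is not None and len(aln.segments) == 2
        _, iv1 = aln.segments[0]
        _, iv2 = aln.segments[1]
        assert (iv1.contig, iv1.end) == ("gA", 700)
        assert (iv2.contig, iv2.start) == ("gB", 600)

    def test_reverse_orientation_chimeric_read(self, two_gene_ref):
        refs, models = two_gene_ref
        read = revcomp(refs.sequences["gA"][662:700] + refs.sequences["gB"][600:638])
        aln = map_single_spliced(refs, models, read)
        assert aln is not None and len(aln.segments) == 2
        assert aln.segments[0][1].strand == "-"

    def test_min_overhang_honored(self, two_gene_ref):
        refs, models = two_gene_ref
        # only 5 bases on the gB side: below the 8-nt minimum segment
        read = refs.sequences["gA"][629:700] + refs.sequences["gB"][600:605]
        aln = map_single_spliced(refs, models, read)
        assert aln is None or len(aln.segments) == 1

    def test_unmappable_read(self, two_gene_ref):
        refs, models = two_gene_ref
        rng = np.random.default_rng(8)
        assert map_single_spliced(refs, models, _random_seq(rng, 76)) is None

    def test_aligned_bases_match_reference(self, two_gene_ref):
        refs, models = two_gene_ref
        read = refs.sequences["gA"][270:300] + refs.sequences["gA"][500:546]
        aln = SplicedAligner(refs, models).map(read)
        for (q0, q1), iv in aln.segments:
            assert refs.sequences[iv.contig][iv.start : iv.end] == read[q0:q1]
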