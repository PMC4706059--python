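"""Built-in exact aligner, uniqueness rules and mate re-pairing."""

import pysam
import pytest

from hicprep.align import (MULTI, UNIQUE, UNMAPPED, AlignerDependencyError,
                           AlignmentResult, PairingError, ReadAlignment,
                           align_external, align_read_exact,
                           classify_uniqueness, pair_reads,
                           results_from_sam, write_single_end_sam)
from hicprep.digest import reverse_complement

from .conftest import random_genome


def brute_force_occurrences(genome, seq):
    """All (chrom, pos, strand) exact placements, by full enumeration."""
    hits = []
    for chrom, chrom_seq in genome.items():
        for strand, needle in (("+", seq),
                               ("-", reverse_complement(seq))):
            for i in range(len(chrom_seq) - len(needle) + 1):
                if chrom_seq[i:i + len(needle)] == needle:
                    hits.append((chrom, i + 1, strand))
    return hits


class TestBuiltinExactAligner:
    def test_planted_reads_match_brute_force(self, rng):
        genome = {"c1": random_genome(rng, 3000),
                  "c2": random_genome(rng, 2000)}
        for i in range(50):
            chrom = "c1" if rng.random() < 0.6 else "c2"
            start = int(rng.integers(0, len(genome[chrom]) - 30))
            seq = genome[chrom][start:start + 30]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            res = align_read_exact(f"r{i}", 1, seq, genome)
            hits = brute_force_occurrences(genome, seq)
            if len(hits) == 1:
                assert res.status == UNIQUE
                aln = res.alignment
                assert (aln.chrom, aln.pos, aln.strand) == hits[0]
            else:
                assert res.status == MULTI

    def test_minus_strand_five_prime_is_rightmost_base(self):
        genome = {"c": "TTTTACGTACGGGTTT"}
        seq = reverse_complement("ACGTACGG")  # maps - strand at pos 5
        res = align_read_exact("r", 1, seq, genome)
        assert res.status == UNIQUE
        assert (res.alignment.pos, res.alignment.strand) == (5, "-")
        assert res.alignment.five_prime == 12

    def test_repeated_sequence_is_multi(self):
        genome = {"a": "CCCCAAGGTTCCAAGGTTCC"}
        res = align_read_exact("r", 1, "AAGGTTCC", genome)
        assert res.status == MULTI

    def test_cross_chromosome_repeat_is_multi(self):
        genome = {"a": "TTTTGGCCAATTGGCCTTTT", "b": "GGCCAATTGGCC"}
        res = align_read_exact("r", 1, "GGCCAATTGGCC", genome)
        assert res.status == MULTI

    def test_absent_sequence_is_unmapped(self):
        genome = {"a": "AAAAAAAAAA"}
        assert align_read_exact("r", 1, "CCCCC",
                                genome).status == UNMAPPED

    def test_palindromic_read_counts_both_strands(self):
        # revcomp(GGATCC) == GGATCC: one genomic locus, two strand hits
        genome = {"a": "TTTTTGGATCCTTTTT"}
        assert align_read_exact("r", 1, "GGATCC", genome).status == MULTI


def _sam_record(mapq=42, unmapped=False, xs=None, as_=None, xm=None):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c", "LN": 1000}]})
    rec = pysam.AlignedSegment(header)
    rec.query_name = "r"
    if unmapped:
        rec.flag = 4
        rec.reference_id = -1
    else:
        rec.flag = 0
        rec.reference_id = 0
        rec.reference_start = 10
        rec.mapping_quality = mapq
        rec.cigarstring = "30M"
    if xs is not None:
        rec.set_tag("XS", xs)
    if as_ is not None:
        rec.set_tag("AS", as_)
    if xm is not None:
        rec.set_tag("XM", xm)
    return rec


class TestClassifyUniqueness:
    def test_unmapped_record(self):
        assert classify_uniqueness(_sam_record(unmapped=True)) == UNMAPPED

    def test_high_mapq_no_secondary_is_unique(self):
        assert classify_uniqueness(_sam_record(mapq=42)) == UNIQUE

    def test_low_mapq_is_multi(self):
        assert classify_uniqueness(_sam_record(mapq=3)) == MULTI

    def test_tied_secondary_score_is_multi(self):
        rec = _sam_record(mapq=42, xs=-10, as_=-10)
        assert classify_uniqueness(rec) == MULTI

    def test_strictly_better_best_score_is_unique(self):
        rec = _sam_record(mapq=42, xs=-20, as_=-10)
        assert classify_uniqueness(rec) == UNIQUE

    def test_bowtie_mode_mapped_is_unique(self):
        assert classify_uniqueness(_sam_record(mapq=255),
                                   aligner="bowtie") == UNIQUE

    def test_bowtie_mode_suppressed_multi(self):
        rec = _sam_record(unmapped=True, xm=2)
        assert classify_uniqueness(rec, aligner="bowtie") == MULTI


class TestSamRoundTrip:
    def test_builtin_results_survive_sam_round_trip(self, rng, tmp_path):
        genome = {"c1": random_genome(rng, 2000)}
        results = []
        for i in range(20):
            start = int(rng.integers(0, 1960))
            seq = genome["c1"][start:start + 40]
            results.append(align_read_exact(f"r{i}", 1, seq, genome))
        sam = tmp_path / "m1.sam"
        write_single_end_sam(results, {"c1": 2000}, sam)
        back = list(results_from_sam(sam, mate=1))
        assert [r.status for r in back] == [r.status for r in results]
        for a, b in zip(results, back):
            if a.status == UNIQUE:
                assert (a.alignment.chrom, a.alignment.pos,
                        a.alignment.strand) == \
                    (b.alignment.chrom, b.alignment.pos,
                     b.alignment.strand)


def _res(read_id, mate, status=UNIQUE, chrom="c", pos=10, strand="+"):
    aln = None
    if status == UNIQUE:
        aln = ReadAlignment(read_id, mate, chrom, pos, strand, 30)
    return AlignmentResult(read_id, mate, status, aln)


class TestPairReads:
    def test_all_unique_forms_all_pairs(self):
        s1 = [_res(f"r{i}", 1) for i in range(5)]
        s2 = [_res(f"r{i}", 2, pos=100) for i in range(5)]
        ditags, stats = pair_reads(s1, s2)
        assert len(ditags) == 5 and stats.pairs_formed == 5
        assert stats.reads_in == 10 and stats.unique_mapped == 10

    def test_multi_mate_drops_pair_but_is_counted(self):
        s1 = [_res("a", 1), _res("b", 1)]
        s2 = [_res("a", 2), _res("b", 2, status=MULTI)]
        ditags, stats = pair_reads(s1, s2)
        assert [d.read_id for d in ditags] == ["a"]
        assert stats.multi_mapped == 1

    def test_every_read_in_exactly_one_class(self):
        s1 = [_res("a", 1), _res("b", 1, status=UNMAPPED),
              _res("c", 1, status=MULTI)]
        s2 = [_res("a", 2), _res("b", 2), _res("c", 2)]
        _, stats = pair_reads(s1, s2)
        assert stats.unique_mapped + stats.multi_mapped + \
            stats.unmapped == stats.reads_in == 6

    def test_swapping_streams_preserves_pair_count(self):
        s1 = [_res("a", 1), _res("b", 1, status=MULTI)]
        s2 = [_res("a", 2), _res("b", 2)]
        d12, _ = pair_reads(s1, s2)
        d21, _ = pair_reads(s2, s1)
        assert len(d12) == len(d21) == 1
        assert d12[0].end1.mate == 1 and d21[0].end1.mate == 2

    def test_out_of_register_streams_rejected(self):
        with pytest.raises(PairingError):
            pair_reads([_res("a", 1)], [_res("b", 2)])
        with pytest.raises(PairingError):
            pair_reads([_res("a", 1)], [_res("a", 2), _res("b", 2)])


class TestExternalAlignerContract:
    def test_missing_binary_raises_actionable_error(self, tmp_path):
        fq = tmp_path / "in.fq"
        fq.write_text("@r\nACGT\n+\nIIII\n")
        with pytest.raises(AlignerDependencyError, match="PATH"):
            align_external(fq, "idx", tmp_path / "o.sam",
                           aligner="bowtie2")

    def test_unknown_aligner_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            align_external(tmp_path / "x.fq", "idx", tmp_path / "o.sam",
                           aligner="hisat9000")

    def test_prealigned_sam_bypass(self, tmp_path):
        # aligner "none": pre-aligned per-mate SAM consumed directly
        sam = tmp_path / "pre.sam"
        results = [AlignmentResult(
            "r0", 1, UNIQUE, ReadAlignment("r0", 1, "c1", 5, "+", 30))]
        write_single_end_sam(results, {"c1": 100}, sam)
        back = list(results_from_sam(sam, mate=1))
        assert back[0].status == UNIQUE and back[0].alignment.pos == 5

    def test_empty_fastq_yields_empty_stream(self, tmp_path):
        from hicprep.align import align_builtin_exact
        fq = tmp_path / "empty.fq"
        fq.write_text("")
        assert list(align_builtin_exact(fq, {"c": "ACGT"}, 1)) == []
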