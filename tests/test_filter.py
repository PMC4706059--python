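"""Di-tag classification: fragment assignment, insert size, rule table."""

import itertools

import pytest

from hicprep.align import DiTagRaw, ReadAlignment
from hicprep.digest import digest_sequences
from hicprep.filtering import (Category, SizeRange, assign_fragment,
                               classify, filter_ditags,
                               theoretical_insert_size)

from .conftest import random_genome


def aln(chrom, pos, strand, length=20, read_id="r", mate=1):
    return ReadAlignment(read_id, mate, chrom, pos, strand, length)


def ditag(a1, a2):
    return DiTagRaw(a1, a2)


def reference_classifier(d, dmap, size_range):
    """Independent straight-line transcription of the category rules,
    written directly against the definitions (no shared helpers)."""
    a1, a2 = d.end1, d.end2
    f1 = dmap.lookup(a1.chrom, a1.five_prime)
    f2 = dmap.lookup(a2.chrom, a2.five_prime)

    def dist(a, f):
        return (f.end - a.five_prime + 1 if a.strand == "+"
                else a.five_prime - f.start + 1)

    insert = dist(a1, f1) + dist(a2, f2)
    same_chrom = a1.chrom == a2.chrom
    opposite = a1.strand != a2.strand
    if same_chrom and opposite:
        plus = a1 if a1.strand == "+" else a2
        minus = a2 if a1.strand == "+" else a1
        facing = plus.five_prime <= minus.five_prime
    else:
        facing = None  # same-strand or trans: neither facing nor away
    if same_chrom and f1.index == f2.index and opposite:
        if not facing:
            return Category.SAME_CIRCULARISED
        if a1.five_prime in (f1.start, f1.end) or \
                a2.five_prime in (f2.start, f2.end):
            return Category.SAME_DANGLING
        return Category.SAME_INTERNAL
    if same_chrom and abs(f1.index - f2.index) == 1 and facing:
        return Category.RELIGATION
    if same_chrom and facing:
        plus = a1 if a1.strand == "+" else a2
        minus = a2 if a1.strand == "+" else a1
        span = minus.five_prime - plus.five_prime + 1
        if size_range.min_bp <= span <= size_range.max_bp:
            return Category.CONTIGUOUS
    if not size_range.min_bp <= insert <= size_range.max_bp:
        return Category.WRONG_SIZE
    return Category.VALID


class TestAssignFragment:
    def test_position_one_is_first_fragment(self, toy_map):
        assert assign_fragment(toy_map, aln("chrT", 1, "+")).index == 1

    def test_minus_strand_five_prime_on_fragment_end(self, toy_map):
        # 5' base = 41 + 20 - 1 = 60 = end of fragment 1
        a = aln("chrT", 41, "-", length=20)
        assert a.five_prime == 60
        assert assign_fragment(toy_map, a).index == 1

    def test_binary_search_equals_linear_scan(self, rng, hindiii):
        seq = random_genome(rng, 50_000)
        dmap = digest_sequences({"c": seq}, "g", hindiii)
        frags = dmap.fragments["c"]
        for pos in rng.integers(1, len(seq) + 1, size=10_000):
            pos = int(pos)
            expected = next(f for f in frags if f.start <= pos <= f.end)
            assert dmap.lookup("c", pos) == expected

    def test_absent_chromosome_and_out_of_range(self, toy_map):
        with pytest.raises(KeyError):
            assign_fragment(toy_map, aln("chrX", 1, "+"))
        with pytest.raises(IndexError):
            assign_fragment(toy_map, aln("chrT", 151, "+", length=20))


class TestTheoreticalInsertSize:
    def test_symmetric_reads_at_fragment_starts(self, hindiii):
        seq = ("G" * 299 + "AAGCTT" + "G" * 295)  # cut at 301
        dmap = digest_sequences({"c": seq}, "g", hindiii)
        f1, f2 = dmap.fragments["c"]
        assert (f1.length, f2.length) == (300, 300)
        d = ditag(aln("c", 1, "+"), aln("c", 600, "-", length=1))
        assert theoretical_insert_size(d, f1, f2) == 600

    def test_minimal_insert_is_two(self, toy_map):
        f1 = toy_map.fragments["chrT"][0]
        f2 = toy_map.fragments["chrT"][1]
        # + read 5' on f1.end, - read 5' on f2.start
        d = ditag(aln("chrT", 60, "+", length=1),
                  aln("chrT", 61, "-", length=1))
        assert theoretical_insert_size(d, f1, f2) == 2

    def test_simulator_inserts_recovered(self, tmp_path):
        from hicprep.align import align_read_exact, pair_reads
        from hicprep.simulate import SimConfig, simulate_run
        from hicprep.truncate import (ligation_junction, read_fastq,
                                      truncate_read)
        cfg = SimConfig(seed=11, n_ditags=60, proportions={
            "valid_cis": 0.7, "valid_trans": 0.3})
        seqs, dmap, res = simulate_run(cfg, tmp_path)
        junction = ligation_junction(dmap.enzyme1)
        streams = []
        for mate, path in ((1, res.r1_path), (2, res.r2_path)):
            stream = []
            for rid, seq, qual in read_fastq(path):
                seq, qual, _ = truncate_read(seq, qual, junction)
                stream.append(align_read_exact(rid, mate, seq, seqs))
            streams.append(stream)
        ditags, _ = pair_reads(*streams)
        truth = {r.read_id: r.insert for r in res.truth}
        for d in ditags:
            f1 = dmap.lookup(d.end1.chrom, d.end1.five_prime)
            f2 = dmap.lookup(d.end2.chrom, d.end2.five_prime)
            assert theoretical_insert_size(d, f1, f2) == \
                truth[d.read_id]


class TestClassify:
    def test_trans_within_range_is_valid(self, toy_map, hindiii):
        dmap2 = digest_sequences({"chrU": "G" * 150}, "g", hindiii)
        toy_map.fragments["chrU"] = dmap2.fragments["chrU"]
        toy_map.__post_init__()
        d = ditag(aln("chrT", 30, "+"), aln("chrU", 60, "-"))
        out = classify(d, toy_map, SizeRange(30, 120))
        assert out.category is Category.VALID and out.is_cis is False

    def test_same_fragment_facing_interior_is_internal(self, toy_map):
        d = ditag(aln("chrT", 65, "+"), aln("chrT", 76, "-", length=20))
        out = classify(d, toy_map, SizeRange(30, 120))
        assert out.category is Category.SAME_INTERNAL

    def test_exhaustive_toy_placements_match_reference(self, toy_map):
        """Every placement of two 20 bp reads on a 3-fragment
        chromosome agrees with the independent rule-table classifier."""
        size_range = SizeRange(30, 80)
        positions = range(1, 132, 2)
        cases = 0
        for p1, s1, p2, s2 in itertools.product(positions, "+-",
                                                positions, "-+"):
            d = ditag(aln("chrT", p1, s1, mate=1),
                      aln("chrT", p2, s2, mate=2))
            got = classify(d, toy_map, size_range).category
            want = reference_classifier(d, toy_map, size_range)
            assert got is want, (p1, s1, p2, s2, got, want)
            cases += 1
        assert cases == 66 * 66 * 4

    def test_category_independent_of_stream_order(self, toy_map, rng):
        size_range = SizeRange(30, 80)
        ditags = [ditag(aln("chrT", int(rng.integers(1, 131)),
                            "+-"[int(rng.integers(2))], mate=1,
                            read_id=f"r{i}"),
                  aln("chrT", int(rng.integers(1, 131)),
                      "+-"[int(rng.integers(2))], mate=2,
                      read_id=f"r{i}"))
                  for i in range(200)]
        first = {d.read_id: classify(d, toy_map, size_range).category
                 for d in ditags}
        rng.shuffle(ditags)
        second = {d.read_id: classify(d, toy_map, size_range).category
                  for d in ditags}
        assert first == second

    def test_religation_insert_equals_boundary_distances(self, toy_map):
        # + read in fragment 2, - read in fragment 3, facing across 101
        d = ditag(aln("chrT", 70, "+"), aln("chrT", 101, "-", length=20))
        out = classify(d, toy_map, SizeRange(30, 80))
        assert out.category is Category.RELIGATION
        assert out.insert_size == (100 - 70 + 1) + (120 - 101 + 1)

    def test_contiguous_requires_fragment_separation(self, toy_map):
        # span 50..130 covers both boundaries, inside the window
        d = ditag(aln("chrT", 50, "+"), aln("chrT", 111, "-", length=20))
        out = classify(d, toy_map, SizeRange(30, 120))
        assert out.category is Category.CONTIGUOUS
        assert abs(out.frag1.index - out.frag2.index) >= 2


class TestFilterStream:
    def test_conservation_over_random_stream(self, toy_map, rng):
        ditags = [ditag(aln("chrT", int(rng.integers(1, 131)),
                            "+-"[int(rng.integers(2))], mate=1,
                            read_id=f"r{i}"),
                  aln("chrT", int(rng.integers(1, 131)),
                      "+-"[int(rng.integers(2))], mate=2,
                      read_id=f"r{i}"))
                  for i in range(500)]
        valid, stats = filter_ditags(ditags, toy_map, SizeRange(30, 80))
        assert sum(stats.counts.values()) == stats.ditags_in == 500
        assert stats.valid == len(valid)
        assert stats.valid_cis + stats.valid_trans == stats.valid
        valid_ids = {d.read_id for d in valid}
        assert [d.read_id for d in valid] == \
            [d.read_id for d in ditags if d.read_id in valid_ids]

    def test_single_category_input(self, toy_map):
        # circularised: same fragment, reads pointing away
        ditags = [ditag(aln("chrT", 80, "+", read_id=f"r{i}"),
                        aln("chrT", 51, "-", length=20,
                            read_id=f"r{i}", mate=2))
                  for i in range(10)]
        valid, stats = filter_ditags(ditags, toy_map, SizeRange(30, 80))
        assert valid == []
        assert stats.counts[Category.SAME_CIRCULARISED] == 10


class TestDoubleDigestRules:
    def test_rules_on_attributed_boundaries(self, hindiii, mboi):
        seq = ("G" * 29 + "AAGCTT" + "G" * 25 + "GATC" + "G" * 26
               + "AAGCTT" + "G" * 29)
        dmap = digest_sequences({"c": seq}, "g", hindiii, mboi)
        # fragments: (1,30) re1-3', (31,60) mboi-3', (61,91) re1-3',
        # (92,121) chromosome end
        size_range = SizeRange(2, 1000)
        ok = ditag(aln("c", 31, "+", length=30),
                   aln("c", 61, "-", length=31, mate=2))
        # read1 5' at cut 31, ligation end 60 is MboI-made -> rejected
        out = classify(ok, dmap, size_range, mode="double_digest")
        assert out.category is Category.WRONG_ENZYME
        ok2 = ditag(aln("c", 1, "+"), aln("c", 91, "-", length=31,
                                          mate=2))
        # read1 begins at chromosome start, not a cut site
        out2 = classify(ok2, dmap, size_range, mode="double_digest")
        assert out2.category is Category.NOT_AT_CUT_SITE

    def test_simulated_double_digest_fully_discriminated(self):
        from hicprep.simulate import simulate_double_digest
        dmap, tags = simulate_double_digest(seed=17, n_per_class=60)
        for tag, expected in tags:
            got = classify(tag, dmap, SizeRange(150, 800),
                           mode="double_digest").category
            assert got is expected
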