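"""Di-tag artifact classification against an in-silico digest.

Each putative di-tag is positioned on the restriction-fragment map: the 5'
base of each mate is assigned to its fragment, a theoretical insert size is
computed (the sum, over both mates, of the distance from the 5' base to the
fragment boundary in the read's 3' direction), and the di-tag is assigned
exactly one category.

Categories and the fixed precedence in which the rules are tested:

1. same fragment, reads oriented away from each other  → circularised
2. same fragment, facing, a 5' base exactly on a fragment boundary
                                                       → dangling end
3. same fragment, facing, interior                     → internal fragment
4. adjacent fragments, facing across the shared boundary → re-ligation
5. same chromosome, facing, outermost genomic span within the
   size-selection window                               → contiguous
6. theoretical insert outside the size-selection window → wrong size
7. otherwise valid (cis when both mates share a chromosome, else trans)

In double-digest mode (second digestion instead of sonication) two checks
run before rule 1: every read must begin exactly at a cut site, and both
ligation-side fragment ends must have been created by the first enzyme.
Same-fragment geometry is tested first because it is independent of the
size parameters; the order above is explicit and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

from .align import DiTagRaw, ReadAlignment
from .digest import DigestFragment, DigestMap

logger = logging.getLogger(__name__)

SONICATION = "sonication"
DOUBLE_DIGEST = "double_digest"

DEFAULT_MIN_SIZE = 150
DEFAULT_MAX_SIZE = 800


class Category(str, Enum):
    """Di-tag classes; every di-tag receives exactly one."""

    VALID = "valid"
    SAME_CIRCULARISED = "circularised"
    SAME_DANGLING = "dangling_end"
    SAME_INTERNAL = "internal"
    RELIGATION = "religation"
    CONTIGUOUS = "contiguous"
    WRONG_SIZE = "wrong_size"
    # double-digest-mode rejects
    NOT_AT_CUT_SITE = "not_at_cut_site"
    WRONG_ENZYME = "wrong_enzyme"


ARTIFACT_CATEGORIES = [c for c in Category if c is not Category.VALID]


@dataclass(frozen=True)
class SizeRange:
    """Experimental size-selection window in bp (inclusive)."""

    min_bp: int = DEFAULT_MIN_SIZE
    max_bp: int = DEFAULT_MAX_SIZE

    def __post_init__(self) -> None:
        if not 0 < self.min_bp <= self.max_bp:
            raise ValueError(
                f"invalid size range {self.min_bp}..{self.max_bp}")

    def __contains__(self, size: int) -> bool:
        return self.min_bp <= size <= self.max_bp


@dataclass(frozen=True)
class DiTagClassified:
    """A di-tag with fragment assignments, insert size and category."""

    raw: DiTagRaw
    frag1: DigestFragment
    frag2: DigestFragment
    insert_size: int
    category: Category
    is_cis: Optional[bool] = None  # defined only for VALID

    @property
    def read_id(self) -> str:
        return self.raw.read_id


def assign_fragment(digest_map: DigestMap,
                    aln: ReadAlignment) -> DigestFragment:
    """Fragment containing the read's 5' base (binary search)."""
    return digest_map.lookup(aln.chrom, aln.five_prime)


def _three_prime_distance(aln: ReadAlignment, frag: DigestFragment) -> int:
    """Distance from the 5' base to the fragment boundary in the read's
    3' direction, inclusive."""
    if aln.strand == "+":
        return frag.end - aln.five_prime + 1
    return aln.five_prime - frag.start + 1


def theoretical_insert_size(ditag: DiTagRaw, frag1: DigestFragment,
                            frag2: DigestFragment) -> int:
    """Length of the sonication fragment implied by the digest map."""
    return (_three_prime_distance(ditag.end1, frag1)
            + _three_prime_distance(ditag.end2, frag2))


def _begins_at_cut_site(aln: ReadAlignment, frag: DigestFragment,
                        digest_map: DigestMap) -> bool:
    """Double-digest check: 5' base exactly at a restriction cut site.

    Chromosome termini are not cut sites.
    """
    if aln.strand == "+":
        return aln.five_prime == frag.start and frag.index > 1
    return (aln.five_prime == frag.end
            and frag.end < digest_map.chrom_length(frag.chrom))


def _ligation_end_is_re1(aln: ReadAlignment, frag: DigestFragment) -> bool:
    """Double-digest check: the fragment end in the read's 3' direction
    (the ligated end) was created by the first enzyme."""
    return frag.re1_end_3p if aln.strand == "+" else frag.re1_end_5p


def classify(ditag: DiTagRaw, digest_map: DigestMap,
             size_range: SizeRange,
             mode: str = SONICATION) -> DiTagClassified:
    """Assign fragments, compute the insert and classify one di-tag."""
    a1, a2 = ditag.end1, ditag.end2
    frag1 = assign_fragment(digest_map, a1)
    frag2 = assign_fragment(digest_map, a2)
    insert = theoretical_insert_size(ditag, frag1, frag2)

    def done(cat: Category, is_cis: Optional[bool] = None):
        return DiTagClassified(ditag, frag1, frag2, insert, cat, is_cis)

    if mode == DOUBLE_DIGEST:
        if not (_begins_at_cut_site(a1, frag1, digest_map)
                and _begins_at_cut_site(a2, frag2, digest_map)):
            return done(Category.NOT_AT_CUT_SITE)
        if not (_ligation_end_is_re1(a1, frag1)
                and _ligation_end_is_re1(a2, frag2)):
            return done(Category.WRONG_ENZYME)
    elif mode != SONICATION:
        raise ValueError(f"unknown filtering mode {mode!r}")

    # orientation: "facing" means the + strand mate lies 5'-ward of the
    # - strand mate on the chromosome; same-strand pairs are neither
    # facing nor away and fall through to the size rules.
    facing = away = False
    if a1.chrom == a2.chrom and a1.strand != a2.strand:
        plus, minus = (a1, a2) if a1.strand == "+" else (a2, a1)
        facing = plus.five_prime <= minus.five_prime
        away = not facing

    same_fragment = (frag1.chrom == frag2.chrom
                     and frag1.index == frag2.index)
    if same_fragment and away:
        return done(Category.SAME_CIRCULARISED)
    if same_fragment and facing:
        on_boundary = any(
            aln.five_prime in (frag.start, frag.end)
            for aln, frag in ((a1, frag1), (a2, frag2)))
        return done(Category.SAME_DANGLING if on_boundary
                    else Category.SAME_INTERNAL)
    if (a1.chrom == a2.chrom and abs(frag1.index - frag2.index) == 1
            and facing):
        return done(Category.RELIGATION)
    if a1.chrom == a2.chrom and facing:
        plus, minus = (a1, a2) if a1.strand == "+" else (a2, a1)
        span = minus.five_prime - plus.five_prime + 1
        if span in size_range:
            return done(Category.CONTIGUOUS)
    if insert not in size_range:
        return done(Category.WRONG_SIZE)
    return done(Category.VALID, is_cis=a1.chrom == a2.chrom)


@dataclass
class FilterStats:
    """Per-category tallies over one filtered di-tag stream."""

    ditags_in: int = 0
    counts: dict[Category, int] = field(
        default_factory=lambda: {c: 0 for c in Category})
    valid_cis: int = 0
    valid_trans: int = 0

    def count(self, classified: DiTagClassified) -> None:
        self.ditags_in += 1
        self.counts[classified.category] += 1
        if classified.category is Category.VALID:
            if classified.is_cis:
                self.valid_cis += 1
            else:
                self.valid_trans += 1

    @property
    def valid(self) -> int:
        return self.counts[Category.VALID]


def filter_ditags(ditags: Iterable[DiTagRaw], digest_map: DigestMap,
                  size_range: SizeRange, mode: str = SONICATION,
                  ) -> tuple[list[DiTagClassified], FilterStats]:
    """Classify a di-tag stream; return VALID survivors (input order) and
    the per-category tally. Every input di-tag lands in exactly one
    category, so the tally sums to the input count."""
    stats = FilterStats()
    survivors: list[DiTagClassified] = []
    for ditag in ditags:
        classified = classify(ditag, digest_map, size_range, mode)
        stats.count(classified)
        if classified.category is Category.VALID:
            survivors.append(classified)
    return survivors, stats


def classify_stream(ditags: Iterable[DiTagRaw], digest_map: DigestMap,
                    size_range: SizeRange, mode: str = SONICATION,
                    ) -> Iterator[DiTagClassified]:
    for ditag in ditags:
        yield classify(ditag, digest_map, size_range, mode)


# ---------------------------------------------------------------------------
# SAM emission: pairs on adjacent lines

def write_pairs_sam(pairs: Iterable[DiTagClassified | DiTagRaw],
                    genome_lengths: dict[str, int],
                    out_sam: str | Path,
                    tag_category: bool = False) -> None:
    """Write di-tags as SAM with the two mates on adjacent lines.

    Accepts classified or raw di-tags. FLAG carries paired/mate bits
    (0x1, 0x40/0x80, 0x10/0x20); the optional ``CT:Z`` tag records the
    category (used for reject audit files)."""
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": ln}
                     for c, ln in genome_lengths.items()]}
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        refs = {c: i for i, c in enumerate(genome_lengths)}
        for pair in pairs:
            raw = pair.raw if isinstance(pair, DiTagClassified) else pair
            for aln, mate_aln, first in (
                    (raw.end1, raw.end2, True),
                    (raw.end2, raw.end1, False)):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = aln.read_id
                flag = 0x1 | (0x40 if first else 0x80)
                if aln.strand == "-":
                    flag |= 0x10
                if mate_aln.strand == "-":
                    flag |= 0x20
                rec.flag = flag
                rec.reference_id = refs[aln.chrom]
                rec.reference_start = aln.pos - 1
                rec.mapping_quality = aln.mapq
                rec.cigarstring = f"{aln.aligned_length}M"
                rec.next_reference_id = refs[mate_aln.chrom]
                rec.next_reference_start = mate_aln.pos - 1
                if tag_category and isinstance(pair, DiTagClassified):
                    rec.set_tag("CT", pair.category.value)
                out.write(rec)


def read_pairs_sam(sam_path: str | Path) -> Iterator[DiTagRaw]:
    """Read adjacent-line mate pairs back into raw di-tags."""
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        it = iter(sam)
        for rec1 in it:
            rec2 = next(it, None)
            if rec2 is None or rec1.query_name != rec2.query_name:
                raise ValueError(
                    f"{sam_path}: mates of {rec1.query_name} are not on "
                    "adjacent lines")
            alns = []
            for rec in (rec1, rec2):
                alns.append(ReadAlignment(
                    read_id=rec.query_name,
                    mate=1 if rec.is_read1 else 2,
                    chrom=rec.reference_name,
                    pos=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    aligned_length=rec.reference_length
                    or len(rec.query_sequence or ""),
                    mapq=rec.mapping_quality))
            yield DiTagRaw(*alns)
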