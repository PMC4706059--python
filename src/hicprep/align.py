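"""Independent per-mate alignment and di-tag re-pairing.

Valid Hi-C read pairs do not span one contiguous genomic insert, so the two
mates are aligned *independently* in single-end mode and then re-paired by
read id: a putative di-tag is formed whenever both mates aligned uniquely.

Two alignment routes exist behind one contract:

* :func:`align_external` shells out to bowtie or bowtie2 (single-end), with
  the invocation logged; uniqueness is decided by
  :func:`classify_uniqueness`.
* :func:`align_builtin_exact` is an exact substring search over the genome
  (read and reverse complement). It exists so the whole pipeline is
  testable with error-free simulated reads and zero external dependencies;
  it is not a general-purpose aligner.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

from .digest import reverse_complement
from .truncate import read_fastq

logger = logging.getLogger(__name__)

DEFAULT_MAPQ_THRESHOLD = 30

UNIQUE, MULTI, UNMAPPED = "unique", "multi", "unmapped"


class AlignerDependencyError(RuntimeError):
    pass


class PairingError(ValueError):
    pass


@dataclass(frozen=True)
class ReadAlignment:
    """One mate's mapping: chromosome, 1-based leftmost position, strand."""

    read_id: str
    mate: int  # 1 or 2
    chrom: str
    pos: int  # 1-based leftmost mapped position
    strand: str  # "+" or "-"
    aligned_length: int
    mapq: int = 42
    unique: bool = True

    @property
    def five_prime(self) -> int:
        """1-based genomic coordinate of the read's 5' base."""
        if self.strand == "+":
            return self.pos
        return self.pos + self.aligned_length - 1


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome for one read: its uniqueness class and, if unique, where."""

    read_id: str
    mate: int
    status: str  # unique | multi | unmapped
    alignment: Optional[ReadAlignment] = None


@dataclass(frozen=True)
class DiTagRaw:
    """Two uniquely mapped mates of one read id."""

    end1: ReadAlignment
    end2: ReadAlignment

    def __post_init__(self) -> None:
        if self.end1.read_id != self.end2.read_id:
            raise PairingError(
                f"mate ids differ: {self.end1.read_id} vs "
                f"{self.end2.read_id}")

    @property
    def read_id(self) -> str:
        return self.end1.read_id


@dataclass
class MappingStats:
    """Per-mate and total alignment tallies.

    ``unique_mapped + multi_mapped + unmapped == reads_in`` always.
    """

    reads_in: int = 0
    unique_mapped: int = 0
    multi_mapped: int = 0
    unmapped: int = 0
    pairs_formed: int = 0
    per_mate: dict[int, dict[str, int]] = field(
        default_factory=lambda: {1: {UNIQUE: 0, MULTI: 0, UNMAPPED: 0},
                                 2: {UNIQUE: 0, MULTI: 0, UNMAPPED: 0}})

    def count(self, result: AlignmentResult) -> None:
        self.reads_in += 1
        self.per_mate[result.mate][result.status] += 1
        if result.status == UNIQUE:
            self.unique_mapped += 1
        elif result.status == MULTI:
            self.multi_mapped += 1
        else:
            self.unmapped += 1


# ---------------------------------------------------------------------------
# built-in exact aligner

def _occurrences(haystack: str, needle: str, limit: int) -> list[int]:
    """0-based start positions of ``needle`` (up to ``limit`` of them)."""
    hits = []
    start = 0
    while len(hits) < limit:
        i = haystack.find(needle, start)
        if i < 0:
            break
        hits.append(i)
        start = i + 1
    return hits


def align_read_exact(read_id: str, mate: int, seq: str,
                     genome: dict[str, str]) -> AlignmentResult:
    """Exact-match a read (and its reverse complement) over a genome.

    ``unique`` iff exactly one occurrence exists genome-wide across both
    strands; two or more → multi; none → unmapped.
    """
    seq = seq.upper()
    rc = reverse_complement(seq)
    hits: list[tuple[str, int, str]] = []
    for chrom, chrom_seq in genome.items():
        for i in _occurrences(chrom_seq, seq, 2 - len(hits)):
            hits.append((chrom, i + 1, "+"))
            if len(hits) >= 2:
                break
        if len(hits) >= 2:
            break
        for i in _occurrences(chrom_seq, rc, 2 - len(hits)):
            hits.append((chrom, i + 1, "-"))
            if len(hits) >= 2:
                break
        if len(hits) >= 2:
            break
    if not hits:
        return AlignmentResult(read_id, mate, UNMAPPED)
    if len(hits) > 1:
        chrom, pos, strand = hits[0]
        aln = ReadAlignment(read_id, mate, chrom, pos, strand, len(seq),
                            mapq=0, unique=False)
        return AlignmentResult(read_id, mate, MULTI, aln)
    chrom, pos, strand = hits[0]
    aln = ReadAlignment(read_id, mate, chrom, pos, strand, len(seq))
    return AlignmentResult(read_id, mate, UNIQUE, aln)


def align_builtin_exact(fastq_path: str | Path, genome: dict[str, str],
                        mate: int) -> Iterator[AlignmentResult]:
    """Align every read of a FASTQ by exact substring search."""
    for read_id, seq, _qual in read_fastq(fastq_path):
        yield align_read_exact(read_id, mate, seq, genome)


# ---------------------------------------------------------------------------
# external aligner contract

_ALIGNER_ARGS = {
    # single best alignment, suppress reads with >1 reportable alignment
    "bowtie": ["--best", "--strata", "-m", "1", "--sam"],
    # default end-to-end; uniqueness decided from MAPQ + XS downstream
    "bowtie2": ["--end-to-end", "--no-unal"],
}


def align_external(fastq_path: str | Path, index_prefix: str,
                   out_sam: str | Path, aligner: str = "bowtie2",
                   threads: int = 1) -> Path:
    """Run bowtie/bowtie2 in single-end mode, writing a SAM file.

    Raises :class:`AlignerDependencyError` with an actionable message when
    the aligner binary is not on PATH.
    """
    if aligner not in _ALIGNER_ARGS:
        raise ValueError(f"unknown aligner {aligner!r}")
    exe = shutil.which(aligner)
    if exe is None:
        raise AlignerDependencyError(
            f"{aligner!r} not found on PATH; install it, pass a "
            "pre-aligned SAM, or use the builtin aligner")
    cmd = [exe, *(["-p", str(threads)] if aligner == "bowtie2" else []),
           *_ALIGNER_ARGS[aligner], "-x" if aligner == "bowtie2" else "",
           index_prefix, "-U" if aligner == "bowtie2" else "",
           str(fastq_path), "-S", str(out_sam)]
    cmd = [c for c in cmd if c]
    logger.info("running aligner: %s", " ".join(cmd))
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise subprocess.CalledProcessError(
            proc.returncode, cmd, output=proc.stdout, stderr=proc.stderr)
    return Path(out_sam)


def classify_uniqueness(record: pysam.AlignedSegment,
                        aligner: str = "bowtie2",
                        mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD) -> str:
    """Uniqueness class of a single-end alignment record.

    bowtie mode assumes the aligner was invoked with single-best,
    suppress-multi settings, so any mapped record is unique. bowtie2 (and
    builtin) mode requires MAPQ at or above the threshold and, when an XS
    (second-best score) tag is present, a strictly better best score.
    """
    if record.is_unmapped:
        if aligner == "bowtie" and record.has_tag("XM") and \
                record.get_tag("XM") > 0:
            return MULTI
        return UNMAPPED
    if aligner == "bowtie":
        return UNIQUE
    if record.mapping_quality < mapq_threshold:
        return MULTI
    if record.has_tag("XS") and record.has_tag("AS") and \
            record.get_tag("XS") >= record.get_tag("AS"):
        return MULTI
    return UNIQUE


def results_from_sam(sam_path: str | Path, mate: int,
                     aligner: str = "bowtie2",
                     mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD,
                     ) -> Iterator[AlignmentResult]:
    """Turn a single-end SAM into AlignmentResults in file order."""
    with pysam.AlignmentFile(str(sam_path), "r",
                             check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            status = classify_uniqueness(rec, aligner, mapq_threshold)
            aln = None
            if not rec.is_unmapped:
                aln = ReadAlignment(
                    read_id=rec.query_name, mate=mate,
                    chrom=rec.reference_name,
                    pos=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    aligned_length=rec.reference_length or
                    len(rec.query_sequence or ""),
                    mapq=rec.mapping_quality,
                    unique=status == UNIQUE)
            yield AlignmentResult(rec.query_name, mate, status, aln)


def write_single_end_sam(results: Iterable[AlignmentResult],
                         genome_lengths: dict[str, int],
                         out_sam: str | Path) -> None:
    """Persist builtin-aligner results as a single-end SAM file.

    Unique alignments get MAPQ 42; multi-mapped reads are written at one
    representative position with MAPQ 0, so
    :func:`classify_uniqueness` (bowtie2 rule) recovers the class.
    """
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": ln}
                     for c, ln in genome_lengths.items()]}
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        refs = {c: i for i, c in enumerate(genome_lengths)}
        for res in results:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = res.read_id
            if res.alignment is None:
                rec.flag = 4
                rec.reference_id = -1
                rec.reference_start = -1
                rec.mapping_quality = 0
            else:
                aln = res.alignment
                rec.flag = 16 if aln.strand == "-" else 0
                rec.reference_id = refs[aln.chrom]
                rec.reference_start = aln.pos - 1
                rec.mapping_quality = aln.mapq
                rec.cigarstring = f"{aln.aligned_length}M"
            out.write(rec)


# ---------------------------------------------------------------------------
# re-pairing

def pair_reads(stream1: Iterable[AlignmentResult],
               stream2: Iterable[AlignmentResult],
               ) -> tuple[list[DiTagRaw], MappingStats]:
    """Re-pair name-synchronous per-mate streams into putative di-tags.

    A di-tag is emitted for every read id whose both mates aligned
    uniquely; every read is counted in exactly one uniqueness class.
    """
    stats = MappingStats()
    ditags: list[DiTagRaw] = []
    it1, it2 = iter(stream1), iter(stream2)
    for res1 in it1:
        res2 = next(it2, None)
        if res2 is None:
            raise PairingError(
                f"read {res1.read_id} present in mate-1 stream only")
        if res1.read_id != res2.read_id:
            raise PairingError(
                f"streams out of register: {res1.read_id} vs "
                f"{res2.read_id}")
        stats.count(res1)
        stats.count(res2)
        if res1.status == UNIQUE and res2.status == UNIQUE:
            ditags.append(DiTagRaw(res1.alignment, res2.alignment))
    leftover = next(it2, None)
    if leftover is not None:
        raise PairingError(
            f"read {leftover.read_id} present in mate-2 stream only")
    stats.pairs_formed = len(ditags)
    return ditags, stats
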