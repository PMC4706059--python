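"""Ligation-junction derivation and read truncation.

The Hi-C fill-in/blunt-ligation protocol creates a *ligation junction*: the
two restriction-site halves, each with its 5' overhang filled in, joined
end to end. For HindIII (``A^AGCTT``) this is ``AAGCTAGCTT`` — a sequence
absent from the unligated genome whenever the overhang is non-empty. A
sequencing read running through the junction is a hybrid of two restriction
fragments and will not map contiguously, so reads are truncated at the
junction before alignment.

The retained portion is ``seq[0 : p + k)`` where ``p`` is the 0-based
offset of the first junction occurrence and ``k = L - c`` (site length
minus cut offset): the read keeps the reconstituted fragment end, which is
genomically contiguous with the 5' fragment, maximising alignable sequence.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator

from .digest import EnzymeSpec, EnzymeSpecError

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 20  # reads shorter than this after truncation are flagged


class FastqFormatError(ValueError):
    pass


class PairingError(ValueError):
    pass


@dataclass(frozen=True)
class JunctionSpec:
    """The Hi-C ligation junction and how much of it a read keeps.

    ``keep_len_increment`` (k) is the number of junction bases retained
    with the 5' portion of a truncated read.
    """

    junction: str
    keep_len_increment: int


def ligation_junction(enzyme: EnzymeSpec) -> JunctionSpec:
    """Derive the fill-in/blunt-ligation junction of a 5'-overhang cutter.

    With site ``S`` of length ``L`` cut at offset ``c`` the junction is
    ``S[0:c] + S[c:L-c] + S[c:L-c] + S[L-c:L]``: each ligated end
    contributes its retained genomic bases plus one filled-in copy of the
    overhang. A blunt cutter (``c = L/2``) degenerates to the site itself.
    """
    enzyme.require_fill_in_compatible()
    site, c = enzyme.site, enzyme.cut_offset
    length = len(site)
    overhang = site[c:length - c]
    junction = site[:c] + overhang + overhang + site[length - c:]
    return JunctionSpec(junction=junction, keep_len_increment=length - c)


def truncate_read(seq: str, qual: str,
                  junction: JunctionSpec) -> tuple[str, str, bool]:
    """Cut a read at the first ligation-junction occurrence.

    Returns ``(seq', qual', truncated)``; the read is unchanged when the
    junction is absent. Matching is exact (no mismatches) and
    case-sensitive on upper-cased input.
    """
    if len(seq) != len(qual):
        raise FastqFormatError("sequence/quality length mismatch")
    p = seq.find(junction.junction)
    if p < 0:
        return seq, qual, False
    keep = p + junction.keep_len_increment
    return seq[:keep], qual[:keep], True


@dataclass
class TruncationStats:
    """Per-file truncation tally."""

    reads_total: int = 0
    reads_truncated: int = 0
    truncated_length_sum: int = 0
    too_short: int = 0  # shorter than min_length after truncation

    @property
    def fraction_truncated(self) -> float:
        if self.reads_total == 0:
            return 0.0
        return self.reads_truncated / self.reads_total

    @property
    def mean_truncated_length(self) -> float:
        if self.reads_truncated == 0:
            return 0.0
        return self.truncated_length_sum / self.reads_truncated


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, seq, qual)`` from a Phred+33 FASTQ (.gz ok)."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FastqFormatError(
                    f"{path}: malformed FASTQ record near {header!r}")
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"{path}: sequence/quality length mismatch for "
                    f"{header.strip()}")
            yield header[1:].split()[0], seq.upper(), qual


def write_fastq_record(fh: IO[str], read_id: str, seq: str,
                       qual: str) -> None:
    fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def truncate_fastq_file(in_path: str | Path, out_path: str | Path,
                        junction: JunctionSpec,
                        min_length: int = DEFAULT_MIN_LENGTH,
                        ) -> TruncationStats:
    """Truncate every read of one FASTQ file, preserving order and ids."""
    stats = TruncationStats()
    with _open_text(out_path, "wt") as out:
        for read_id, seq, qual in read_fastq(in_path):
            seq2, qual2, hit = truncate_read(seq, qual, junction)
            stats.reads_total += 1
            if hit:
                stats.reads_truncated += 1
                stats.truncated_length_sum += len(seq2)
                if len(seq2) < min_length:
                    stats.too_short += 1
            write_fastq_record(out, read_id, seq2, qual2)
    return stats


def truncate_fastq(r1_path: str | Path, r2_path: str | Path,
                   junction: JunctionSpec,
                   out1_path: str | Path, out2_path: str | Path,
                   min_length: int = DEFAULT_MIN_LENGTH,
                   ) -> tuple[TruncationStats, TruncationStats]:
    """Truncate a read pair's two FASTQ files; mates stay in register.

    Returns one :class:`TruncationStats` per file. Mismatched record
    counts between the two files raise :class:`PairingError`.
    """
    stats1 = truncate_fastq_file(r1_path, out1_path, junction, min_length)
    stats2 = truncate_fastq_file(r2_path, out2_path, junction, min_length)
    if stats1.reads_total != stats2.reads_total:
        raise PairingError(
            f"record count mismatch: {r1_path} has {stats1.reads_total}, "
            f"{r2_path} has {stats2.reads_total}")
    logger.info("truncated %d/%d (R1) and %d/%d (R2) reads",
                stats1.reads_truncated, stats1.reads_total,
                stats2.reads_truncated, stats2.reads_total)
    return stats1, stats2


__all__ = [
    "JunctionSpec", "TruncationStats", "ligation_junction",
    "truncate_read", "truncate_fastq", "truncate_fastq_file",
    "read_fastq", "write_fastq_record", "FastqFormatError",
    "PairingError", "DEFAULT_MIN_LENGTH", "EnzymeSpecError",
]
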