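"""Barcode-based test of duplicate origin.

Experimental design: one of four 4-nt barcode adapters is ligated randomly
to each end of every di-tag *before* PCR amplification. PCR copies of one
molecule therefore share an ordered barcode combination, while independent
ligation events that happen to produce the same di-tag coordinates carry
independently drawn combinations (matching with probability 1/16 under
equimolar barcodes). Grouping duplicate di-tags and asking what fraction
of each group carries a single combination discriminates the two origins:
near 100% → PCR; near 100/16 = 6.25% for pairs → independent events.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .dedup import DiTagKey

logger = logging.getLogger(__name__)

BarcodePair = tuple[str, str]


class BarcodeError(ValueError):
    pass


@dataclass(frozen=True)
class BarcodeSet:
    """Four distinct 4-nt barcodes and their 16 ordered combinations."""

    barcodes: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(set(self.barcodes)) != len(self.barcodes):
            raise BarcodeError(f"barcodes not distinct: {self.barcodes}")
        for bc in self.barcodes:
            if len(bc) != 4 or set(bc) - set("ACGT"):
                raise BarcodeError(f"invalid 4-nt barcode {bc!r}")

    @property
    def combinations(self) -> list[BarcodePair]:
        return [(a, b) for a in self.barcodes for b in self.barcodes]

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.barcodes


# CCTT and CGCT are the two published adapter sequences; the remaining two
# are arbitrary distinct 4-mers used by the simulator.
DEFAULT_BARCODES = BarcodeSet(("CCTT", "CGCT", "AGAT", "TTCA"))


def extract_barcode(read_seq: str,
                    barcode_set: BarcodeSet) -> tuple[str, bool]:
    """First four bases of the read, flagged valid iff in the set."""
    if len(read_seq) < 4:
        raise BarcodeError(
            f"read of length {len(read_seq)} too short for a 4-nt barcode")
    prefix = read_seq[:4].upper()
    return prefix, prefix in barcode_set


@dataclass
class BarcodeFrequencyTable:
    """Contingency counts of barcodes and ordered combinations."""

    per_barcode: dict[str, int]
    per_combination: dict[BarcodePair, int]
    pairs_total: int
    pairs_valid: int

    @property
    def pct_valid(self) -> float:
        if self.pairs_total == 0:
            return 0.0
        return 100.0 * self.pairs_valid / self.pairs_total


def barcode_frequency_table(read_pairs: Iterable[tuple[str, str]],
                            barcode_set: BarcodeSet,
                            ) -> BarcodeFrequencyTable:
    """Quantify barcodes over ``(read1_seq, read2_seq)`` pairs.

    A pair counts as valid when both prefixes belong to the set; only
    valid pairs enter the combination table, but every valid single
    barcode is counted."""
    per_barcode: Counter[str] = Counter()
    per_combination: Counter[BarcodePair] = Counter()
    total = valid = 0
    for seq1, seq2 in read_pairs:
        bc1, ok1 = extract_barcode(seq1, barcode_set)
        bc2, ok2 = extract_barcode(seq2, barcode_set)
        total += 1
        if ok1:
            per_barcode[bc1] += 1
        if ok2:
            per_barcode[bc2] += 1
        if ok1 and ok2:
            valid += 1
            per_combination[(bc1, bc2)] += 1
    return BarcodeFrequencyTable(
        per_barcode=dict(per_barcode),
        per_combination=dict(per_combination),
        pairs_total=total, pairs_valid=valid)


@dataclass(frozen=True)
class DuplicateGroupRecord:
    """One row of the duplicate-concordance table.

    ``pct_one_combination`` is the percentage of duplicate groups of this
    copy number whose members all share one barcode combination."""

    copies: int
    n_groups: int
    pct_one_combination: float


def duplicate_concordance_table(
        records: Iterable[tuple[DiTagKey, BarcodePair]],
        ordered: bool = True) -> list[DuplicateGroupRecord]:
    """Group di-tags (duplicates retained) by key and tabulate, per copy
    number >= 2, the share of groups carrying a single barcode
    combination.

    ``ordered=False`` treats (A, B) and (B, A) as one combination, which
    raises the independent-origin null above 1/16 by the swap-collision
    term."""
    groups: dict[DiTagKey, list[BarcodePair]] = defaultdict(list)
    for key, pair in records:
        groups[key].append(pair)
    by_copies: dict[int, list[bool]] = defaultdict(list)
    for pairs in groups.values():
        if len(pairs) < 2:
            continue
        if not ordered:
            pairs = [tuple(sorted(p)) for p in pairs]
        by_copies[len(pairs)].append(len(set(pairs)) == 1)
    table = []
    for copies in sorted(by_copies):
        flags = by_copies[copies]
        table.append(DuplicateGroupRecord(
            copies=copies, n_groups=len(flags),
            pct_one_combination=100.0 * sum(flags) / len(flags)))
    return table


def concordance_tsv(table: Sequence[DuplicateGroupRecord]) -> str:
    """Render the table as TSV with columns Copies, Di-tags, One(%)."""
    lines = ["copies\tditags\tone_pct"]
    for row in table:
        lines.append(f"{row.copies}\t{row.n_groups}\t"
                     f"{row.pct_one_combination:.1f}")
    return "\n".join(lines) + "\n"
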