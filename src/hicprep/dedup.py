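"""PCR de-duplication of valid di-tags.

Duplicate di-tags are overwhelmingly PCR copies of a single ligation
event, and retaining them inflates the evidence for the affected contacts,
so all but one representative copy are removed. Two di-tags are duplicates
when their sonication endpoints coincide: the duplicate key is the pair of
``(chrom, 5' position, strand)`` triples, one per mate, ordered
lexicographically so that mate order is irrelevant. Sequence content and
aligned lengths are deliberately excluded — truncation changes lengths
without changing the underlying molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .filtering import DiTagClassified

logger = logging.getLogger(__name__)

DiTagKey = tuple[tuple[str, int, str], tuple[str, int, str]]

UNDEFINED = float("nan")


def ditag_key(classified: DiTagClassified) -> DiTagKey:
    """Canonical duplicate key; invariant under mate swapping."""
    ends = []
    for aln in (classified.raw.end1, classified.raw.end2):
        ends.append((aln.chrom, aln.five_prime, aln.strand))
    ends.sort()
    return ends[0], ends[1]


@dataclass
class DedupStats:
    """De-duplication and cis/trans tallies over the unique set."""

    ditags_in: int = 0
    ditags_unique: int = 0
    cis_count: int = 0
    trans_count: int = 0

    @property
    def fraction_unique(self) -> float:
        if self.ditags_in == 0:
            return 0.0
        return self.ditags_unique / self.ditags_in


def dedup(ditags: Iterable[DiTagClassified],
          ) -> tuple[list[DiTagClassified], DedupStats]:
    """Keep the first-seen copy of each duplicate key, in input order.

    Streams with a key set; survivors are independent of how the input is
    chunked. Cis/trans are tallied on the surviving (unique) di-tags.
    """
    stats = DedupStats()
    seen: set[DiTagKey] = set()
    survivors: list[DiTagClassified] = []
    for classified in ditags:
        stats.ditags_in += 1
        key = ditag_key(classified)
        if key in seen:
            continue
        seen.add(key)
        survivors.append(classified)
        stats.ditags_unique += 1
        if classified.raw.end1.chrom == classified.raw.end2.chrom:
            stats.cis_count += 1
        else:
            stats.trans_count += 1
    return survivors, stats


def cis_trans_ratio(stats: DedupStats) -> float:
    """trans/cis ratio of the unique set; a high ratio flags a poor
    library. Undefined (NaN) when there are no cis di-tags."""
    if stats.cis_count == 0:
        return UNDEFINED
    return stats.trans_count / stats.cis_count


def trans_percentage(stats: DedupStats) -> float:
    """Trans di-tags as a percentage of unique di-tags (0 when empty)."""
    if stats.ditags_unique == 0:
        return 0.0
    return 100.0 * stats.trans_count / stats.ditags_unique
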