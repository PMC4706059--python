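"""In-silico restriction digestion of a reference genome.

A restriction enzyme is specified as ``SITE_WITH_CARET,NAME`` (for example
``A^AGCTT,HindIII``): the caret marks the top-strand cut position inside the
recognition site. Digesting a genome with one (or, for the double-digest
protocol, two) enzymes yields a :class:`DigestMap` — a per-chromosome tiling
of restriction fragments in 1-based inclusive coordinates — which is the
coordinate oracle every downstream di-tag filter consults.

Conventions
-----------
* Coordinates are 1-based inclusive throughout (SAM convention).
* A *cut coordinate* is the 1-based position of the first base lying 3' of
  the top-strand cleavage point; a cut at coordinate ``p`` ends the previous
  fragment at ``p - 1`` and starts the next at ``p``.
* Only top-strand cut positions define boundaries. Non-palindromic sites are
  accepted with a warning (their bottom-strand cuts are ignored).
* IUPAC ambiguity codes in the site expand to base sets; ``N`` in the genome
  matches nothing.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class EnzymeSpecError(ValueError):
    """Malformed or unsupported restriction-enzyme specification."""


class DigestFormatError(ValueError):
    """Malformed digest-map TSV or FASTA input."""


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition site plus top-strand cut offset.

    ``cut_offset`` is the 0-based index within ``site`` of the first base 3'
    of the top-strand cut; ``0 <= cut_offset <= len(site)``.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site
        if len(site) < 4:
            raise EnzymeSpecError(
                f"recognition site {site!r} shorter than 4 nt")
        bad = set(site) - set(IUPAC)
        if bad:
            raise EnzymeSpecError(
                f"non-IUPAC characters {sorted(bad)} in site {site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise EnzymeSpecError(
                f"cut offset {self.cut_offset} outside site of length "
                f"{len(site)}")
        if reverse_complement(site) != site:
            logger.warning(
                "site %s (%s) is not palindromic; only top-strand cuts "
                "define fragment boundaries", site, self.name)

    @property
    def overhang_length(self) -> int:
        """Length of the 5' overhang produced by a symmetric cutter."""
        return len(self.site) - 2 * self.cut_offset

    def require_fill_in_compatible(self) -> None:
        """Fill-in protocols need a 5' overhang or a blunt cut."""
        if self.cut_offset > len(self.site) - self.cut_offset:
            raise EnzymeSpecError(
                f"{self.name}: cut offset {self.cut_offset} gives a 3' "
                "overhang; fill-in Hi-C protocols require a 5' overhang "
                "or blunt cutter")

    def __str__(self) -> str:
        return (f"{self.site[:self.cut_offset]}^"
                f"{self.site[self.cut_offset:]},{self.name}")


def parse_enzyme_spec(spec: str) -> EnzymeSpec:
    """Parse ``"A^AGCTT,HindIII"`` into an :class:`EnzymeSpec`.

    The portion before the comma is the recognition site with a single caret
    at the top-strand cut position; the portion after the comma (optional)
    is the enzyme name.
    """
    spec = spec.strip()
    if "," in spec:
        site_part, name = spec.split(",", 1)
        name = name.strip() or "unnamed"
    else:
        site_part, name = spec, "unnamed"
    if site_part.count("^") != 1:
        raise EnzymeSpecError(
            f"enzyme spec {spec!r} must contain exactly one caret marking "
            "the cut position (e.g. A^AGCTT,HindIII)")
    cut_offset = site_part.index("^")
    site = site_part.replace("^", "").upper()
    return EnzymeSpec(name=name, site=site, cut_offset=cut_offset)


def _site_regex(enzyme: EnzymeSpec) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(f"[{IUPAC[ch]}]" for ch in enzyme.site)
    return re.compile(f"(?={body})")


def find_cut_sites(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """1-based top-strand cut coordinates of ``enzyme`` in ``sequence``.

    Matching is case-insensitive; ``N`` in the sequence matches nothing.
    The scan advances by one base, so overlapping site occurrences are all
    reported. Returned coordinates are strictly increasing.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    pat = _site_regex(enzyme)
    return [m.start() + 1 + enzyme.cut_offset for m in pat.finditer(seq)]


@dataclass(frozen=True)
class DigestFragment:
    """One restriction fragment, 1-based inclusive coordinates.

    ``re1_end_5p`` / ``re1_end_3p`` record whether the 5' / 3' boundary was
    created by the first enzyme (meaningful in double-digest mode;
    chromosome termini count as neither enzyme's work).
    """

    chrom: str
    start: int
    end: int
    index: int
    re1_end_5p: bool = True
    re1_end_3p: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DigestFormatError(
                f"fragment {self.chrom}:{self.start}-{self.end} has "
                "start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(eq=False)
class DigestMap:
    """Per-chromosome tiling of restriction fragments.

    Fragments of each chromosome are sorted, contiguous and tile positions
    ``1..chrom_length``; indices are consecutive from 1.
    """

    genome_id: str
    enzyme1: EnzymeSpec
    enzyme2: Optional[EnzymeSpec] = None
    fragments: dict[str, list[DigestFragment]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._starts: dict[str, list[int]] = {
            chrom: [f.start for f in frags]
            for chrom, frags in self.fragments.items()
        }

    @property
    def chroms(self) -> list[str]:
        return list(self.fragments)

    def chrom_length(self, chrom: str) -> int:
        return self.fragments[chrom][-1].end

    def lookup(self, chrom: str, pos: int) -> DigestFragment:
        """Fragment containing 1-based position ``pos`` (binary search)."""
        if chrom not in self.fragments:
            raise KeyError(
                f"chromosome {chrom!r} absent from digest of "
                f"{self.genome_id!r}")
        frags = self.fragments[chrom]
        if pos < 1 or pos > frags[-1].end:
            raise IndexError(
                f"position {chrom}:{pos} outside 1..{frags[-1].end}")
        i = bisect_right(self._starts[chrom], pos) - 1
        return frags[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DigestMap):
            return NotImplemented
        return (self.genome_id == other.genome_id
                and str(self.enzyme1) == str(other.enzyme1)
                and (self.enzyme2 is None) == (other.enzyme2 is None)
                and (self.enzyme2 is None
                     or str(self.enzyme2) == str(other.enzyme2))
                and self.fragments == other.fragments)


def _fragments_from_cuts(chrom: str, length: int,
                         cuts1: Iterable[int],
                         cuts2: Iterable[int]) -> list[DigestFragment]:
    """Tile ``1..length`` at the union of two enzymes' cut coordinates."""
    by_enzyme1: dict[int, bool] = {}
    for p in cuts2:
        if 2 <= p <= length:
            by_enzyme1[p] = False
    for p in cuts1:  # enzyme 1 wins a coinciding boundary
        if 2 <= p <= length:
            by_enzyme1[p] = True
    boundaries = sorted(by_enzyme1)
    frags = []
    start = 1
    prev_re1 = False  # chromosome start: no enzyme made it
    for i, p in enumerate(boundaries, start=1):
        frags.append(DigestFragment(chrom, start, p - 1, i,
                                    re1_end_5p=prev_re1,
                                    re1_end_3p=by_enzyme1[p]))
        start = p
        prev_re1 = by_enzyme1[p]
    frags.append(DigestFragment(chrom, start, length, len(boundaries) + 1,
                                re1_end_5p=prev_re1, re1_end_3p=False))
    return frags


def digest_sequences(sequences: dict[str, str], genome_id: str,
                     enzyme1: EnzymeSpec,
                     enzyme2: Optional[EnzymeSpec] = None) -> DigestMap:
    """Digest in-memory chromosome sequences into a :class:`DigestMap`."""
    if not sequences:
        raise DigestFormatError("no sequences to digest")
    fragments = {}
    for chrom, seq in sequences.items():
        cuts1 = find_cut_sites(seq, enzyme1)
        cuts2 = find_cut_sites(seq, enzyme2) if enzyme2 else []
        fragments[chrom] = _fragments_from_cuts(chrom, len(seq), cuts1,
                                                cuts2)
    return DigestMap(genome_id=genome_id, enzyme1=enzyme1, enzyme2=enzyme2,
                     fragments=fragments)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly multi-record, line-wrapped) FASTA into a dict."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise DigestFormatError(
                f"duplicate chromosome name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise DigestFormatError(f"no FASTA records in {path}")
    return sequences


def digest_genome(fasta_path: str | Path, enzyme1: EnzymeSpec,
                  enzyme2: Optional[EnzymeSpec] = None) -> DigestMap:
    """Digest a FASTA genome in silico into a fragment map."""
    sequences = read_fasta(fasta_path)
    genome_id = Path(fasta_path).name
    logger.info("digesting %s with %s%s", genome_id, enzyme1.name,
                f" + {enzyme2.name}" if enzyme2 else "")
    return digest_sequences(sequences, genome_id, enzyme1, enzyme2)


_DIGEST_COLUMNS = ["chrom", "start", "end", "index", "re1_end_5p",
                   "re1_end_3p"]


def write_digest(digest_map: DigestMap, path: str | Path) -> None:
    """Write a digest map as TSV (header line carries genome and enzymes)."""
    with open(path, "w") as fh:
        header = (f"#genome_id={digest_map.genome_id}\t"
                  f"re1={digest_map.enzyme1}")
        if digest_map.enzyme2 is not None:
            header += f"\tre2={digest_map.enzyme2}"
        fh.write(header + "\n")
        fh.write("\t".join(_DIGEST_COLUMNS) + "\n")
        for frags in digest_map.fragments.values():
            for f in frags:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.index}\t"
                         f"{int(f.re1_end_5p)}\t{int(f.re1_end_3p)}\n")


def read_digest(path: str | Path) -> DigestMap:
    """Read a digest-map TSV written by :func:`write_digest`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#genome_id="):
            raise DigestFormatError(
                f"{path}: missing '#genome_id=' header line")
        fields = dict(part.split("=", 1) for part in
                      header.lstrip("#").split("\t"))
        if "re1" not in fields:
            raise DigestFormatError(f"{path}: header lacks re1 enzyme spec")
        genome_id = fields["genome_id"]
        enzyme1 = parse_enzyme_spec(fields["re1"])
        enzyme2 = (parse_enzyme_spec(fields["re2"])
                   if "re2" in fields else None)
        colnames = fh.readline().rstrip("\n").split("\t")
        if colnames != _DIGEST_COLUMNS:
            raise DigestFormatError(
                f"{path}: expected columns {_DIGEST_COLUMNS}, "
                f"got {colnames}")
        fragments: dict[str, list[DigestFragment]] = {}
        for lineno, line in enumerate(fh, start=3):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise DigestFormatError(
                    f"{path}:{lineno}: expected 6 columns, "
                    f"got {len(parts)}")
            chrom, start, end, index, r5, r3 = parts
            try:
                frag = DigestFragment(chrom, int(start), int(end),
                                      int(index), bool(int(r5)),
                                      bool(int(r3)))
            except ValueError as exc:
                raise DigestFormatError(f"{path}:{lineno}: {exc}") from exc
            fragments.setdefault(chrom, []).append(frag)
    dmap = DigestMap(genome_id=genome_id, enzyme1=enzyme1, enzyme2=enzyme2,
                     fragments=fragments)
    _validate_tiling(dmap, path)
    return dmap


def _validate_tiling(dmap: DigestMap, path: str | Path) -> None:
    for chrom, frags in dmap.fragments.items():
        if frags[0].start != 1:
            raise DigestFormatError(
                f"{path}: {chrom} does not start at 1")
        for prev, nxt in zip(frags, frags[1:]):
            if nxt.start != prev.end + 1 or nxt.index != prev.index + 1:
                raise DigestFormatError(
                    f"{path}: {chrom} fragments not contiguous at "
                    f"{prev.end}/{nxt.start}")
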