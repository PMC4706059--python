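"""Synthetic Hi-C library generator with per-read ground truth.

Builds a toy multi-chromosome genome with planted restriction sites, then
constructs error-free read pairs for every di-tag class the filter knows —
valid cis/trans, circularised, dangling end, internal, re-ligation,
contiguous, wrong size — plus PCR duplication (copies made after barcode
attachment) and 4-nt barcodes. Every emitted pair carries a ground-truth
record, so pipeline output can be compared class by class with what was
planted.

Guarantees the generator maintains so that exact-count comparisons are
meaningful with error-free reads and the exact aligner:

* the genome contains restriction sites only at the planted positions, and
  contains no copy of the ligation junction (the junction arises only from
  ligation, as in the real protocol);
* a read either lies entirely in contiguous genomic sequence or carries a
  complete ligation junction (so truncation restores mappability); partial
  junction overhangs at a read's 3' end would be unmappable without a
  mismatch model, and sonication offsets that would produce them are not
  drawn;
* planted valid cis pairs keep an outer span wider than the size-selection
  window and sit at least two fragments apart, because a narrower genuine
  contact is indistinguishable from an undigested contig under the
  span-within-window rule.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .align import DiTagRaw, ReadAlignment
from .barcode import DEFAULT_BARCODES, BarcodePair, BarcodeSet
from .dedup import DiTagKey
from .digest import (DigestFragment, DigestMap, EnzymeSpec,
                     digest_sequences, parse_enzyme_spec,
                     reverse_complement)
from .filtering import Category
from .truncate import ligation_junction, write_fastq_record

logger = logging.getLogger(__name__)

CATEGORY_NAMES = ["valid_cis", "valid_trans", "circularised", "dangling",
                  "internal", "religation", "contiguous", "wrong_size"]

TRUTH_CATEGORY = {
    "valid_cis": Category.VALID,
    "valid_trans": Category.VALID,
    "circularised": Category.SAME_CIRCULARISED,
    "dangling": Category.SAME_DANGLING,
    "internal": Category.SAME_INTERNAL,
    "religation": Category.RELIGATION,
    "contiguous": Category.CONTIGUOUS,
    "wrong_size": Category.WRONG_SIZE,
}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one synthetic library."""

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 50_000
    enzyme: str = "A^AGCTT,HindIII"
    enzyme2: Optional[str] = None
    read_length: int = 50
    size_min: int = 150
    size_max: int = 800
    n_ditags: int = 1000
    proportions: dict[str, float] = field(default_factory=lambda: {
        "valid_cis": 0.40, "valid_trans": 0.10, "circularised": 0.08,
        "dangling": 0.10, "internal": 0.10, "religation": 0.08,
        "contiguous": 0.07, "wrong_size": 0.07})
    # distribution over per-molecule PCR copy numbers
    pcr_duplication: dict[int, float] = field(
        default_factory=lambda: {1: 1.0})
    barcode_set: BarcodeSet = DEFAULT_BARCODES
    barcode_valid_rate: float = 1.0
    prepend_barcodes: bool = False
    swap_mates_prob: float = 0.5
    min_anchor: int = 20  # minimum per-end sonication distance, bp

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if any(v < 0 for v in self.proportions.values()) or \
                abs(total - 1.0) > 1e-9:
            raise SimulationError(
                f"category proportions must be >= 0 and sum to 1 "
                f"(got {total})")
        unknown = set(self.proportions) - set(CATEGORY_NAMES)
        if unknown:
            raise SimulationError(f"unknown categories {sorted(unknown)}")
        if sum(self.pcr_duplication.values()) <= 0:
            raise SimulationError("empty PCR copy-number distribution")


@dataclass(frozen=True)
class GroundTruthRecord:
    """What one emitted read pair really is."""

    read_id: str
    molecule_id: str
    category: str  # planted class name (valid_cis, dangling, ...)
    chrom1: str
    pos5_1: int
    strand1: str
    chrom2: str
    pos5_2: int
    strand2: str
    insert: int
    barcode1: str
    barcode2: str
    copy_of: str  # molecule_id of the PCR source (== molecule_id itself)

    @property
    def expected_category(self) -> Category:
        return TRUTH_CATEGORY[self.category]

    @property
    def ditag_key(self) -> DiTagKey:
        ends = sorted([(self.chrom1, self.pos5_1, self.strand1),
                       (self.chrom2, self.pos5_2, self.strand2)])
        return ends[0], ends[1]


# ---------------------------------------------------------------------------
# genome construction

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())


def _plant_positions(rng: np.random.Generator, length: int,
                     min_gap: int, max_gap: int, edge: int,
                     short_gap: Optional[tuple[int, int]] = None,
                     ) -> list[int]:
    """Cut coordinates along one chromosome: quasi-uniform long gaps,
    optionally one short gap (for a sub-window fragment) after the second
    site."""
    positions = []
    pos = edge + int(rng.integers(0, min_gap))
    while pos < length - edge:
        positions.append(pos)
        if short_gap is not None and len(positions) == 2:
            pos += int(rng.integers(*short_gap))
            short_gap = None
        else:
            pos += int(rng.integers(min_gap, max_gap))
    if len(positions) < 4:
        raise SimulationError(
            f"chromosome of length {length} too short to plant sites "
            f"with gaps >= {min_gap}")
    return positions


def _forbidden_kmers(enzymes: list[EnzymeSpec]) -> list[str]:
    """Sequences the synthetic genome must not contain outside planted
    sites: the sites themselves and any non-empty ligation junction."""
    kmers = []
    for enz in enzymes:
        kmers.append(enz.site)
        if enz.overhang_length > 0 and \
                enz.cut_offset <= len(enz.site) - enz.cut_offset:
            kmers.append(ligation_junction(enz).junction)
    return kmers


def make_genome(config: SimConfig,
                min_gap: int = 1500, max_gap: int = 6500,
                short_gap: Optional[tuple[int, int]] = (250, 450),
                ) -> tuple[dict[str, str], dict[str, dict[str, list[int]]]]:
    """Random genome with enzyme sites only at planted positions.

    Returns ``(sequences, planted)`` where ``planted[chrom][enzyme_name]``
    lists the planted 1-based cut coordinates. Deterministic for a given
    config (seeded). Accidental site or junction occurrences in the random
    background are scrubbed by point mutation so the digest is exactly the
    planted one.
    """
    rng = np.random.default_rng(config.seed)
    enzymes = [parse_enzyme_spec(config.enzyme)]
    if config.enzyme2:
        enzymes.append(parse_enzyme_spec(config.enzyme2))
    for enz in enzymes:
        if set(enz.site) - set("ACGT"):
            raise SimulationError(
                f"simulator requires a concrete ACGT site, got {enz.site}")
    sequences: dict[str, str] = {}
    planted: dict[str, dict[str, list[int]]] = {}
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = _random_sequence(rng, config.chrom_length)
        cuts = _plant_positions(rng, config.chrom_length, min_gap, max_gap,
                                edge=min_gap, short_gap=short_gap)
        # interleave enzymes over the planted positions in double-digest
        per_enzyme: dict[str, list[int]] = {e.name: [] for e in enzymes}
        footprints: list[tuple[int, int]] = []
        for i, p in enumerate(cuts):
            enz = enzymes[i % len(enzymes)]
            lo = p - enz.cut_offset - 1  # 0-based site start
            seq[lo:lo + len(enz.site)] = enz.site.encode()
            per_enzyme[enz.name].append(p)
            footprints.append((lo, lo + len(enz.site)))
        _scrub(rng, seq, enzymes, footprints)
        sequences[chrom] = seq.decode()
        planted[chrom] = per_enzyme
    return sequences, planted


def _scrub(rng: np.random.Generator, seq: bytearray,
           enzymes: list[EnzymeSpec],
           footprints: list[tuple[int, int]]) -> None:
    """Mutate away accidental site/junction occurrences (not touching
    planted site footprints)."""
    protected = np.zeros(len(seq), dtype=bool)
    for lo, hi in footprints:
        protected[lo:hi] = True
    kmers = _forbidden_kmers(enzymes)
    planted_starts = {lo for lo, _ in footprints}
    for _ in range(200):
        dirty = False
        text = bytes(seq)
        for kmer in kmers:
            needle = kmer.encode()
            start = 0
            while True:
                i = text.find(needle, start)
                if i < 0:
                    break
                start = i + 1
                if i in planted_starts and len(needle) == \
                        next(hi - lo for lo, hi in footprints if lo == i):
                    continue
                free = [j for j in range(i, i + len(needle))
                        if not protected[j]]
                if not free:
                    continue  # occurrence inside a planted footprint
                j = free[len(free) // 2]
                old = seq[j]
                choices = [b for b in b"ACGT" if b != old]
                seq[j] = int(rng.choice(choices))
                dirty = True
        if not dirty:
            return
    raise SimulationError("genome scrubbing did not converge")


def write_genome_fasta(sequences: dict[str, str],
                       path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# molecule geometry

@dataclass(frozen=True)
class _Molecule:
    category: str
    read1: str  # forward-orientation sequence as sequenced
    read2: str
    chrom1: str
    pos5_1: int
    strand1: str
    chrom2: str
    pos5_2: int
    strand2: str
    insert: int


class _Sampler:
    """Draws molecules of each class from one digested genome."""

    def __init__(self, sequences: dict[str, str], digest_map: DigestMap,
                 config: SimConfig, rng: np.random.Generator):
        self.seq = sequences
        self.dmap = digest_map
        self.cfg = config
        self.rng = rng
        enz = digest_map.enzyme1
        self.L = len(enz.site)
        self.c = enz.cut_offset
        self.fill = enz.site[enz.cut_offset:self.L - enz.cut_offset]
        self.read_len = config.read_length
        self._split_cache: dict[int, list[int]] = {}
        frags = [(c, f) for c, fl in digest_map.fragments.items()
                 for f in fl]
        n_last = {c: len(fl) for c, fl in digest_map.fragments.items()}
        # fragments long enough for same-fragment classes at any insert
        self.long = [(c, f) for c, f in frags
                     if f.length >= config.size_max + 2]
        # fragments with a genuine cut at the 3' end (donor "left" side)
        self.left_donors = [(c, f) for c, f in frags
                            if f.index < n_last[c]
                            and f.length >= config.size_max + 1]
        # fragments with a genuine cut at the 5' end (acceptor side)
        self.right_donors = [(c, f) for c, f in frags
                             if f.index > 1
                             and f.length >= config.size_max + 1]
        # short fragments flanked by long ones: contig middles
        self.contig_middles = []
        for c, fl in digest_map.fragments.items():
            for f in fl[1:-1]:
                if f.length <= config.size_max - 2 and \
                        f.index - 2 >= 0 and f.index < n_last[c]:
                    left = fl[f.index - 2]
                    right = fl[f.index]
                    if left.length >= config.read_length and \
                            right.length >= config.read_length:
                        self.contig_middles.append((c, left, f, right))
        if not self.long or not self.left_donors or not self.right_donors:
            raise SimulationError(
                "genome has no fragments long enough for the configured "
                "size range")

    # -- helpers ---------------------------------------------------------

    def _draw_insert(self) -> int:
        return int(self.rng.integers(self.cfg.size_min,
                                     self.cfg.size_max + 1))

    def _safe1(self, d: int) -> bool:
        # left-of-junction read: fully genomic or full junction present
        return (d >= self.read_len - (self.L - 2 * self.c)
                or d <= self.read_len - (2 * self.L - 3 * self.c))

    def _safe2(self, d: int) -> bool:
        # right-of-junction read (reverse strand)
        return (d >= self.read_len
                or d <= self.read_len - (self.L - self.c))

    def _split(self, s: int, max_d1: int, max_d2: int) -> tuple[int, int]:
        """Split an insert into per-end distances avoiding partial-junction
        read geometries; each distance stays within its fragment."""
        if s not in self._split_cache:
            lo = self.cfg.min_anchor
            self._split_cache[s] = [
                d for d in range(lo, s - lo + 1)
                if self._safe1(d) and self._safe2(s - d)]
        cands = [d for d in self._split_cache[s]
                 if d <= max_d1 and s - d <= max_d2]
        if not cands:
            raise SimulationError(
                f"insert {s} cannot be split into mappable end distances")
        d1 = int(self.rng.choice(cands))
        return d1, s - d1

    def _ligate(self, chrom1: str, fragA: DigestFragment, d1: int,
                chrom2: str, fragB: DigestFragment, d2: int,
                ) -> tuple[str, str, int, int]:
        """Molecule spanning a ligation of fragA's 3' end to fragB's 5'
        start; returns (read1, read2, q1, q2)."""
        g1, g2 = self.seq[chrom1], self.seq[chrom2]
        q1 = fragA.end - d1 + 1
        q2 = fragB.start + d2 - 1
        molecule = (g1[q1 - 1:fragA.end] + self.fill
                    + g2[fragB.start - 1:q2])
        read1 = molecule[:self.read_len]
        read2 = reverse_complement(molecule[-self.read_len:])
        return read1, read2, q1, q2

    def _pick(self, pool, reject=None, tries: int = 2000):
        for _ in range(tries):
            item = pool[int(self.rng.integers(len(pool)))]
            if reject is None or not reject(item):
                return item
        raise SimulationError("rejection sampling exhausted")

    def _far_cis_pair(self) -> tuple[str, DigestFragment, DigestFragment]:
        """Two same-chromosome fragments at least two indices and more
        than one size window apart."""
        gap = self.cfg.size_max
        for _ in range(2000):
            chrom, fragA = self.left_donors[
                int(self.rng.integers(len(self.left_donors)))]
            cands = [f for c, f in self.right_donors
                     if c == chrom and f.index >= fragA.index + 2
                     and f.start - fragA.end > gap]
            if cands:
                fragB = cands[int(self.rng.integers(len(cands)))]
                return chrom, fragA, fragB
        raise SimulationError(
            "no fragment pair far enough apart for a valid cis di-tag")

    # -- per-class constructors -----------------------------------------

    def valid_cis(self) -> _Molecule:
        chrom, fragA, fragB = self._far_cis_pair()
        s = self._draw_insert()
        d1, d2 = self._split(s, fragA.length, fragB.length)
        r1, r2, q1, q2 = self._ligate(chrom, fragA, d1, chrom, fragB, d2)
        return _Molecule("valid_cis", r1, r2, chrom, q1, "+",
                         chrom, q2, "-", s)

    def valid_trans(self) -> _Molecule:
        chrom1, fragA = self._pick(self.left_donors)
        chrom2, fragB = self._pick(
            self.right_donors, reject=lambda it: it[0] == chrom1)
        s = self._draw_insert()
        d1, d2 = self._split(s, fragA.length, fragB.length)
        r1, r2, q1, q2 = self._ligate(chrom1, fragA, d1, chrom2, fragB, d2)
        return _Molecule("valid_trans", r1, r2, chrom1, q1, "+",
                         chrom2, q2, "-", s)

    def circularised(self) -> _Molecule:
        # self-ligated fragment: 3' end joins its own 5' start, so the
        # + strand read sits to the right of the - strand read
        chrom, frag = self._pick(
            self.long, reject=lambda it: it[1].index == 1 or
            it[1].index == len(self.dmap.fragments[it[0]]))
        s = self._draw_insert()
        s = min(s, frag.length)  # away-orientation needs s <= length
        d1, d2 = self._split(s, frag.length, frag.length)
        r1, r2, q1, q2 = self._ligate(chrom, frag, d1, chrom, frag, d2)
        return _Molecule("circularised", r1, r2, chrom, q1, "+",
                         chrom, q2, "-", s)

    def _unligated(self, category: str, on_boundary: bool) -> _Molecule:
        chrom, frag = self._pick(
            self.long, reject=lambda it: it[1].index == 1 or
            it[1].index == len(self.dmap.fragments[it[0]]))
        s = self._draw_insert()
        if on_boundary:
            if self.rng.random() < 0.5:
                x = frag.start
            else:
                x = frag.end - s + 1
        else:
            x = frag.start + 1 + int(
                self.rng.integers(frag.length - s - 1))
        y = x + s - 1
        g = self.seq[chrom]
        molecule = g[x - 1:y]
        read1 = molecule[:self.read_len]
        read2 = reverse_complement(molecule[-self.read_len:])
        return _Molecule(category, read1, read2, chrom, x, "+",
                         chrom, y, "-", s)

    def dangling(self) -> _Molecule:
        return self._unligated("dangling", on_boundary=True)

    def internal(self) -> _Molecule:
        return self._unligated("internal", on_boundary=False)

    def religation(self) -> _Molecule:
        chrom, fragA = self._pick(
            self.left_donors,
            reject=lambda it: (
                it[1].index + 1 > len(self.dmap.fragments[it[0]])
                or self.dmap.fragments[it[0]][it[1].index].length
                < self.cfg.size_max))
        fragB = self.dmap.fragments[chrom][fragA.index]  # the next one
        s = self._draw_insert()
        d1, d2 = self._split(s, fragA.length, fragB.length)
        r1, r2, q1, q2 = self._ligate(chrom, fragA, d1, chrom, fragB, d2)
        return _Molecule("religation", r1, r2, chrom, q1, "+",
                         chrom, q2, "-", s)

    def contiguous(self) -> _Molecule:
        if not self.contig_middles:
            raise SimulationError(
                "contiguous class unsatisfiable: no fragment shorter than "
                "the size window flanked by mappable fragments")
        chrom, left, mid, right = self._pick(self.contig_middles)
        s_lo = max(self.cfg.size_min, mid.length + 2)
        s = int(self.rng.integers(s_lo, self.cfg.size_max + 1))
        a_lo = max(1, s - mid.length - right.length)
        a_hi = min(s - mid.length - 1, left.length)
        if a_hi < a_lo:
            raise SimulationError(
                "contiguous class unsatisfiable: flanking fragments too "
                "short for the drawn span")
        a = int(self.rng.integers(a_lo, a_hi + 1))
        x = left.end - a + 1
        y = x + s - 1
        g = self.seq[chrom]
        molecule = g[x - 1:y]
        read1 = molecule[:self.read_len]
        read2 = reverse_complement(molecule[-self.read_len:])
        return _Molecule("contiguous", read1, read2, chrom, x, "+",
                         chrom, y, "-", s)

    def wrong_size(self) -> _Molecule:
        chrom, fragA, fragB = self._far_cis_pair()
        lo = 2 * self.cfg.min_anchor
        if self.rng.random() < 0.5 and lo < self.cfg.size_min:
            s = int(self.rng.integers(lo, self.cfg.size_min))
        else:
            s = int(self.rng.integers(self.cfg.size_max + 1,
                                      self.cfg.size_max + 301))
        d1, d2 = self._split(s, fragA.length, fragB.length)
        r1, r2, q1, q2 = self._ligate(chrom, fragA, d1, chrom, fragB, d2)
        return _Molecule("wrong_size", r1, r2, chrom, q1, "+",
                         chrom, q2, "-", s)

    def draw(self, category: str) -> _Molecule:
        try:
            return getattr(self, category)()
        except SimulationError as exc:
            raise SimulationError(
                f"category {category!r} unsatisfiable: {exc}") from exc


# ---------------------------------------------------------------------------
# library assembly

@dataclass
class SimResult:
    r1_path: Path
    r2_path: Path
    truth_path: Path
    truth: list[GroundTruthRecord]
    planted_counts: Counter  # per emitted pair, by class name
    n_molecules: int


_TRUTH_COLUMNS = ["read_id", "molecule_id", "category", "chrom1", "pos5_1",
                  "strand1", "chrom2", "pos5_2", "strand2", "insert",
                  "barcode1", "barcode2", "copy_of"]


def _draw_barcode(rng: np.random.Generator, barcode_set: BarcodeSet,
                  valid_rate: float) -> str:
    if rng.random() < valid_rate:
        return barcode_set.barcodes[
            int(rng.integers(len(barcode_set.barcodes)))]
    while True:
        bc = "".join("ACGT"[int(rng.integers(4))] for _ in range(4))
        if bc not in barcode_set:
            return bc


def simulate_library(sequences: dict[str, str], digest_map: DigestMap,
                     config: SimConfig, out_dir: str | Path,
                     prefix: str = "sim") -> SimResult:
    """Write an R1/R2 FASTQ pair plus a ground-truth TSV.

    Molecules are drawn per the configured class proportions, each gets a
    barcode pair (attached before PCR), then a PCR copy number; every
    emitted read pair has exactly one truth record. Deterministic for a
    given config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    sampler = _Sampler(sequences, digest_map, config, rng)
    names = [n for n in CATEGORY_NAMES if config.proportions.get(n, 0) > 0]
    probs = np.array([config.proportions[n] for n in names])
    probs = probs / probs.sum()
    copy_ns = sorted(config.pcr_duplication)
    copy_ps = np.array([config.pcr_duplication[k] for k in copy_ns],
                       dtype=float)
    copy_ps = copy_ps / copy_ps.sum()

    r1_path = out_dir / f"{prefix}_R1.fastq"
    r2_path = out_dir / f"{prefix}_R2.fastq"
    truth_path = out_dir / f"{prefix}_truth.tsv"
    truth: list[GroundTruthRecord] = []
    counts: Counter = Counter()
    drawn = rng.choice(len(names), size=config.n_ditags, p=probs)
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for mol_i, cat_i in enumerate(drawn):
            category = names[int(cat_i)]
            mol = sampler.draw(category)
            if rng.random() < config.swap_mates_prob:
                mol = _swap(mol)
            bc1 = _draw_barcode(rng, config.barcode_set,
                                config.barcode_valid_rate)
            bc2 = _draw_barcode(rng, config.barcode_set,
                                config.barcode_valid_rate)
            n_copies = copy_ns[int(rng.choice(len(copy_ns), p=copy_ps))]
            molecule_id = f"{prefix}{mol_i:06d}"
            for copy_j in range(n_copies):
                read_id = f"{molecule_id}:c{copy_j}"
                seq1, seq2 = mol.read1, mol.read2
                if config.prepend_barcodes:
                    seq1, seq2 = bc1 + seq1, bc2 + seq2
                write_fastq_record(f1, read_id, seq1, "I" * len(seq1))
                write_fastq_record(f2, read_id, seq2, "I" * len(seq2))
                truth.append(GroundTruthRecord(
                    read_id=read_id, molecule_id=molecule_id,
                    category=category,
                    chrom1=mol.chrom1, pos5_1=mol.pos5_1,
                    strand1=mol.strand1,
                    chrom2=mol.chrom2, pos5_2=mol.pos5_2,
                    strand2=mol.strand2,
                    insert=mol.insert, barcode1=bc1, barcode2=bc2,
                    copy_of=molecule_id))
                counts[category] += 1
    with open(truth_path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for rec in truth:
            fh.write("\t".join(str(getattr(rec, col))
                               for col in _TRUTH_COLUMNS) + "\n")
    logger.info("simulated %d molecules -> %d read pairs (%s)",
                config.n_ditags, len(truth), dict(counts))
    return SimResult(r1_path, r2_path, truth_path, truth, counts,
                     config.n_ditags)


def _swap(mol: _Molecule) -> _Molecule:
    return replace(mol, read1=mol.read2, read2=mol.read1,
                   chrom1=mol.chrom2, pos5_1=mol.pos5_2,
                   strand1=mol.strand2, chrom2=mol.chrom1,
                   pos5_2=mol.pos5_1, strand2=mol.strand1)


def simulate_run(config: SimConfig, out_dir: str | Path,
                 prefix: str = "sim",
                 ) -> tuple[dict[str, str], DigestMap, SimResult]:
    """Genome + digest + library in one call (the CLI entry point)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sequences, _planted = make_genome(config)
    enzyme1 = parse_enzyme_spec(config.enzyme)
    enzyme2 = (parse_enzyme_spec(config.enzyme2)
               if config.enzyme2 else None)
    digest_map = digest_sequences(sequences, f"{prefix}_genome", enzyme1,
                                  enzyme2)
    write_genome_fasta(sequences, out_dir / f"{prefix}_genome.fa")
    result = simulate_library(sequences, digest_map, config, out_dir,
                              prefix)
    return sequences, digest_map, result


# ---------------------------------------------------------------------------
# barcode-experiment generators (key-level, duplicates retained)

def simulate_pure_pcr_barcodes(
        seed: int, n_molecules: int,
        copy_numbers: dict[int, float],
        barcode_set: BarcodeSet = DEFAULT_BARCODES,
        ) -> list[tuple[DiTagKey, BarcodePair]]:
    """Every duplicate group is PCR copies of one molecule whose barcode
    pair was fixed before amplification: within-group concordance is 100%
    by construction."""
    rng = np.random.default_rng(seed)
    ks = sorted(copy_numbers)
    ps = np.array([copy_numbers[k] for k in ks], dtype=float)
    ps = ps / ps.sum()
    records = []
    for i in range(n_molecules):
        key = ((f"chr{1 + i % 3}", 1000 + 10 * i, "+"),
               (f"chr{1 + (i + 1) % 3}", 5000 + 10 * i, "-"))
        pair = (_pick_bc(rng, barcode_set), _pick_bc(rng, barcode_set))
        k = ks[int(rng.choice(len(ks), p=ps))]
        records.extend([(key, pair)] * k)
    return records


def simulate_independent_barcodes(
        seed: int, n_molecules: int, n_sites: int,
        barcode_set: BarcodeSet = DEFAULT_BARCODES,
        ) -> list[tuple[DiTagKey, BarcodePair]]:
    """Duplicates are coordinate collisions between independent ligation
    events, each with its own equimolar barcode pair: a duplicate pair
    shares a combination with probability 1/16."""
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_molecules):
        site = int(rng.integers(n_sites))
        key = (("chr1", 1000 + 10 * site, "+"),
               ("chr2", 5000 + 10 * site, "-"))
        pair = (_pick_bc(rng, barcode_set), _pick_bc(rng, barcode_set))
        records.append((key, pair))
    return records


def _pick_bc(rng: np.random.Generator, barcode_set: BarcodeSet) -> str:
    return barcode_set.barcodes[int(rng.integers(
        len(barcode_set.barcodes)))]


# ---------------------------------------------------------------------------
# double-digest fixture generator (alignment level)

def simulate_double_digest(
        seed: int, n_per_class: int = 100,
        enzyme1: str = "A^AGCTT,HindIII", enzyme2: str = "^GATC,MboI",
        n_chromosomes: int = 2, chrom_length: int = 60_000,
        size_min: int = 150, size_max: int = 800,
        ) -> tuple[DigestMap, list[tuple[DiTagRaw, Category]]]:
    """Di-tags for the double-digest protocol with per-tag expectations.

    Compliant tags pair whole fragments whose ligated ends were made by
    enzyme 1, with both reads starting exactly at cut sites and the
    fragment-length sum inside the size window; violations either offset a
    read from its cut site or ligate at an enzyme-2-created end.
    """
    config = SimConfig(seed=seed, n_chromosomes=n_chromosomes,
                       chrom_length=chrom_length, enzyme=enzyme1,
                       enzyme2=enzyme2, size_min=size_min,
                       size_max=size_max)
    sequences, _ = make_genome(config, min_gap=150, max_gap=420,
                               short_gap=None)
    e1 = parse_enzyme_spec(enzyme1)
    e2 = parse_enzyme_spec(enzyme2)
    dmap = digest_sequences(sequences, "ddsim_genome", e1, e2)
    rng = np.random.default_rng(seed + 2)
    frags = [(c, f) for c, fl in dmap.fragments.items() for f in fl]
    n_last = {c: len(fl) for c, fl in dmap.fragments.items()}

    def ok_left(c, f, re1):  # usable "read1" fragment
        return (f.index > 1 and f.index < n_last[c]
                and f.re1_end_3p == re1)

    def ok_right(c, f, re1):
        return (f.index > 1 and f.index < n_last[c]
                and f.re1_end_5p == re1)

    left_re1 = [(c, f) for c, f in frags if ok_left(c, f, True)]
    right_re1 = [(c, f) for c, f in frags if ok_right(c, f, True)]
    left_re2 = [(c, f) for c, f in frags if ok_left(c, f, False)]
    if not (left_re1 and right_re1 and left_re2):
        raise SimulationError("double-digest genome lacks usable fragments")

    def pick_pair(left_pool, right_pool):
        for _ in range(5000):
            c1, fa = left_pool[int(rng.integers(len(left_pool)))]
            c2, fb = right_pool[int(rng.integers(len(right_pool)))]
            if not size_min <= fa.length + fb.length <= size_max:
                continue
            if c1 == c2 and (abs(fa.index - fb.index) <= 1
                             or abs(fb.start - fa.end) <= size_max):
                continue
            return c1, fa, c2, fb
        raise SimulationError("no compliant double-digest pair found")

    def make_tag(c1, fa, c2, fb, offset1: int = 0) -> DiTagRaw:
        end1 = ReadAlignment("dd", 1, c1, fa.start + offset1, "+",
                             fa.length - offset1)
        end2 = ReadAlignment("dd", 2, c2, fb.start, "-", fb.length)
        return DiTagRaw(end1, end2)

    tags: list[tuple[DiTagRaw, Category]] = []
    for i in range(n_per_class):
        c1, fa, c2, fb = pick_pair(left_re1, right_re1)
        tags.append((_with_id(make_tag(c1, fa, c2, fb), f"ok{i}"),
                     Category.VALID))
        c1, fa, c2, fb = pick_pair(left_re1, right_re1)
        off = int(rng.integers(2, min(10, fa.length - 1)))
        tags.append((_with_id(make_tag(c1, fa, c2, fb, offset1=off),
                              f"offcut{i}"), Category.NOT_AT_CUT_SITE))
        c1, fa, c2, fb = pick_pair(left_re2, right_re1)
        tags.append((_with_id(make_tag(c1, fa, c2, fb), f"re2lig{i}"),
                     Category.WRONG_ENZYME))
    return dmap, tags


def _with_id(tag: DiTagRaw, read_id: str) -> DiTagRaw:
    return DiTagRaw(replace(tag.end1, read_id=read_id),
                    replace(tag.end2, read_id=read_id))


def expected_counts(truth: Iterable[GroundTruthRecord],
                    ) -> Counter:
    """Planted per-Category counts over emitted pairs."""
    counts: Counter = Counter()
    for rec in truth:
        counts[rec.expected_category] += 1
    return counts
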