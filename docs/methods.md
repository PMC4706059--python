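# Methods

## The processing model

Hi-C di-tags are chimeric molecules: two restriction-fragment ends,
filled in and blunt-ligated, then sonicated and size-selected. The
pipeline models this explicitly at every stage.

**Coordinates.** Everything is 1-based inclusive (SAM convention). A
*cut coordinate* is the first base 3′ of the top-strand cleavage; a cut
at coordinate *p* ends one fragment at *p − 1* and starts the next at
*p*. Only top-strand cuts define boundaries: the supported enzymes are
palindromic, where the two strands give the same tiling; non-palindromic
sites are accepted with a warning rather than an error. Whether the
original tools of this kind place boundaries at the cut position or the
recognition-site edge is not standardised; the cut-site convention is
fixed here and used consistently by the digest, the filter and the
simulator.

**Junction and truncation.** For site *S* (length *L*, cut offset *c*,
requiring a 5′ overhang or blunt cut, i.e. *c ≤ L − c*), the junction is
`S[0:c] + o + o + S[L−c:L]` with overhang `o = S[c:L−c]`. A truncated
read keeps `p + (L − c)` bases, where *p* is the 0-based offset of the
*first* junction occurrence: the retained filled-in overhang maps to
reference bases adjacent to the cut, so this choice maximises alignable
sequence while the retained prefix can never contain a complete junction
(truncation is idempotent). Matching is exact — no mismatch model is
applied, because the pipeline's own simulated reads are error-free and a
mismatch tolerance would need an error model to calibrate against.
Junction-only reads are truncated to *L − c* bases and flagged (not
dropped) when shorter than the configurable minimum (default 20 nt, a
practical lower bound for unique mapping).

**Alignment and uniqueness.** Mates are aligned independently in
single-end mode and re-paired name-synchronously (truncation preserves
order, so no external sort is needed). "Unique high-quality" is made
precise as: bowtie2 — mapped, MAPQ ≥ 30 (configurable) and no
secondary-score tag tying the best score; bowtie — mapped under
single-best/suppress-multi invocation. The built-in aligner is an exact
substring search of the read and its reverse complement over the whole
genome (unique ⇔ exactly one occurrence); it exists so the full
pipeline runs with zero external dependencies on error-free reads and
is not a general-purpose aligner.

**Classification.** Fragments are assigned by the read's 5′ base (the
sonication endpoint — required anyway for dangling-end detection), via
binary search over fragment starts. Per-end boundary distance is taken
in the read's 3′ direction, inclusive; the theoretical insert is their
sum. The rule order (same-fragment geometry, re-ligation, contiguous,
size, valid) is fixed and documented in the package docstring: the
same-fragment tests come first because they are independent of the size
parameters, and the size test last among the rejections. "Overlaps a
cut site" (dangling end) means exact coincidence of a 5′ base with a
fragment terminal coordinate. The contiguous rule compares the
outermost genomic span (5′ of the plus-strand read to 5′ of the
minus-strand read) against the same size-selection window. Same-strand
same-chromosome pairs are neither "facing" nor "away" and fall through
to the size rules. The default window is 150–800 bp — a typical Hi-C
sonication size selection — and is always logged. Double-digest mode
adds two rejection classes before all other rules (read not starting at
a cut site; ligation at a second-enzyme fragment end), kept as their own
categories so every di-tag still lands in exactly one class and counts
conserve.

**De-duplication.** The duplicate key is the pair of (chromosome, 5′
position, strand) triples, ordered lexicographically so mate order is
irrelevant. Sequence and aligned length are excluded deliberately:
sonication endpoints define the molecule, and truncation changes read
lengths without changing the molecule. The first-seen copy is the
representative — deterministic without comparing qualities. Streaming
with a key set makes survivors independent of chunking.

**Barcode concordance.** The duplicate-origin test groups di-tags
(duplicates retained) by the dedup key and asks, per copy number, what
share of groups carries a single barcode combination. Combinations are
ordered (end1, end2) by default; under the equimolar independent-origin
null two ordered pairs agree with probability 1/16, and for groups of
*c* copies the expected one-combination share is (1/16)^(c−1). The
unordered variant is available behind a flag; it raises the null by the
swap-collision term, which is why ordered is the default. Barcodes in
simulated fixtures are carried in the ground-truth table rather than
trimmed from reads; for real data a trim-then-map preprocessing flag
(`trim_barcode_nt`) exists.

## The simulator

The generator is the package's test and acceptance surface: it emits
error-free read pairs whose geometry satisfies, by construction, the
definition of exactly one category, so pipeline output can be compared
with planted truth count-for-count and read-for-read.

*Genome.* Random A/C/G/T chromosomes (default 3 × 50 kb) with
restriction sites planted at seeded positions at roughly the background
density of a 6-cutter (gaps 1.5–6.5 kb), plus one deliberately short
fragment (250–450 bp) per chromosome so the contiguous class is always
constructible. Accidental site or junction occurrences in the random
background are removed by point mutation, so the digest is exactly the
planted one and the junction arises only from ligation — the property
the truncation step exploits on real data. The planted-site design is
what makes exact-count acceptance checks meaningful: with purely
emergent sites, some seeds would lack the fragment geometry a category
needs.

*Molecules.* Per category the construction mirrors the filter's
definition: valid di-tags ligate a fragment's 3′ end to another
fragment's 5′ start with the junction at the joint; circularised
molecules cross a self-ligation joint; dangling/internal molecules are
unligated genomic spans with or without a boundary endpoint;
re-ligation joins adjacent fragments; contiguous molecules are pure
genomic spans crossing two cut sites within the size window; wrong-size
di-tags use valid geometry with an out-of-window insert. Sonication
endpoints are drawn uniformly within the allowed span — the simplest
null satisfying the geometric constraints — with two deliberate
restrictions: per-end distances that would leave a *partial* junction
at a read's 3′ end are not drawn (such reads are unmappable without a
mismatch model), and valid cis pairs keep an outer span wider than the
size window, because a genuine contact inside the window is
indistinguishable from an undigested contig under the span rule.
PCR copy numbers are drawn per molecule after barcode assignment, and
mate order is randomised (p = 0.5) to exercise order invariance.

*What it does not emulate.* No sequencing errors or quality variation,
no contact-distance decay, no capture enrichment, no chimeric reads
spanning more than one junction, no optical duplicates. Passing tests
therefore demonstrate the correctness of the pipeline's logic
(coordinate arithmetic, rule table, keys, accounting), not its
robustness to noisy real-world reads — that robustness lives in the
external-aligner path, whose invocation is logged and configurable
rather than claimed identical to any published tool's settings.

## Problem sizes and determinism

The acceptance computations use 10,000 di-tags for the classification
mix (the point where every category has hundreds of members), 400
molecules × copy numbers 1–6 for de-duplication, 2,000 and 6,000
molecules for the two barcode experiments, and 100 di-tags per class
for the double-digest check — sizes chosen so binomial tolerances are
tight while a full run stays comfortably interactive on one CPU. All
randomness flows from a single seed through `numpy`'s Generator;
identical configurations produce byte-identical FASTQ, truth tables and
reports (the HTML embeds no timestamps for that reason).

## Known limitations

* Nicking enzymes, 3′-overhang cutters and methylation sensitivity are
  out of scope; 3′-overhang enzymes are rejected explicitly.
* Multi-fragment chimeric reads are not rescued; the first junction
  occurrence truncates the read.
* The digest TSV dialect is self-defined (documented in
  `hicprep.digest`); round-trip fidelity, not byte compatibility with
  any other tool, is the contract.
* `WRONG_SIZE` is tested after the re-ligation and contiguous rules;
  the relative order of these rejections is a documented choice, and
  permuting the input stream never changes any di-tag's category.
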