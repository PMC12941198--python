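# Methods

## Coordinates, strands and formats

All internal coordinates are 0-based half-open on the forward strand of the
assembly. Conversion from the 1-based inclusive conventions of RepeatMasker
`.out` and GFF happens only in `formats_io` parse/write boundaries, so no
other module ever reasons about coordinate dialects. RepeatMasker's `C`
strand maps to `−`, its "perc div" column is divided by 100 into a
proportion, parenthesised "(left)" columns are ignored and a trailing `*`
overlap flag is tolerated. Soft-masked genome bases are uppercased on read;
`N` is allowed in sequences but is a mismatch to every base in motif and
A-run scanning. GFF3 and GTF are both accepted; gene identity for
sub-features is resolved through the `Parent`/`gene_id` chain and features
with no resolvable gene are skipped with a warning rather than failing the
parse. Introns are derived per gene as the gaps between that gene's merged
exons; intergenic regions are the complement of merged gene spans within the
chromosome bounds. These derivations live only in `formats_io`; the
intersection code never re-derives them.

## Tail extraction

The body→tail boundary is a short "cutoff" motif at the 3′ end of the
element body. Matching is hierarchical with two passes: an exact pass over
the motif list, then a Hamming-distance-1 pass (substitutions only, no
indels). The pass structure means an exact match of a lower-priority motif
beats a one-mismatch match of a higher-priority one — the tolerance exists to
absorb post-insertion point mutations, and an exact hit is always stronger
evidence. Within each pass, motifs are tried in library order (the
subfamily's own list first, then the `*` wildcard list); within one motif the
occurrence whose end lies nearest the element's 3′ end wins, because tails
are terminal and a spurious internal copy of the motif must not truncate the
body. The tail is everything downstream of the match, uncapped. Elements
with no match take the terminal `fallback_length` bases (default 30 bp,
configurable to 20/40; the whole element when shorter) as their tail.
Fallback tails are classified like any other tail; the `strict_other` switch
instead sends every fallback element straight to "Other" for users who want
classification restricted to elements with a recognised boundary. A motif
that matches flush with the 3′ end leaves no downstream sequence, so such
elements also take the fallback path.

The cutoff-motif library is a user input (plain TSV, `subfamily<TAB>motif`,
`*` as wildcard). The shipped default (`synthetic_default_library`) is a
synthetic stand-in: one deterministic adenine-free 10-mer per subfamily.
Being adenine-free, it cannot collide with the A-based tail vocabulary,
which makes planted-fixture truth exact; real analyses should supply the
curated library for their SINE families.

## Tail classification

Seventeen labels: A-rich; (AAAAT)n, (AAAT)n, (AAT)n, (AT)n, AT-composite;
the analogous AC- and AG-series labels; Other. The decision cascade:

1. **A-rich** — longest run of consecutive A is ≥ `arich_min_run` (5) and
   covers ≥ `arich_min_coverage` (0.70) of the tail. "70 % continuous
   adenine" is read as run coverage (longest run / tail length), not total A
   content: the canonical boundary example (a 19-base run in a 27-base tail,
   70.4 %) passes under this reading. `arich_total_content` switches to the
   total-content interpretation.
2. **Composite** — a series (AT/AC/AG) qualifies when ≥
   `composite_min_distinct` (2) of its motifs each show a tandem run of ≥
   `composite_min_run` (2) adjacent copies. Composites are tested *before*
   the single-motif rules: a composite is by definition the co-occurrence of
   several repeat units of one series, and testing it first is the only
   ordering under which every canonical worked example — including the
   AC-composite example, which contains both an (AAC)×3 and an (AAAC)×2
   tandem — classifies to its own label. When several series qualify, the
   one whose motif occurrences cover the most bases wins (tie → AT, AC, AG).
3. **Single motif** — among the twelve motifs whose maximal tandem run meets
   `min_consecutive` for its length (2 copies for 3–5-mers, 3 for dimers,
   exactly the canonical criteria), the hit spanning the most bases wins; ties
   prefer the longer motif, then the leftmost run.
4. **Other** — everything else, including the empty tail.

`max_tandem_run` counts adjacent non-overlapping copies in any starting
phase and is verified in tests against an exhaustive brute-force oracle.
Classification is total and deterministic; the A-rich rule is independent of
the motif thresholds (changing `min_consecutive` can never reclassify an
A-rich tail), and all sixteen non-Other canonical examples plus the three
Other examples reproduce under the default configuration — this is the
suite's headline acceptance property.

## Insertion-age estimation

Divergence D is taken from the annotation (RepeatMasker's per-element
divergence over the complete element including the tail), not recomputed.
K = −0.75 · ln(1 − 4D/3) corrects for multiple hits; elements at or beyond
the saturation point D ≥ 0.75 are flagged and excluded from dating rather
than clamped. Age = K/(2μ) with μ = 2.3 × 10⁻⁹ substitutions·site⁻¹·yr⁻¹
(pig neutral rate) is the default; the more common transposable-element
convention K/μ is available via `age_formula="k-over-mu"`. Ages bin into
half-open 5-My intervals [L, L+5) so no age lands in two bins; ages ≥ 85 My
go to an `85+` overflow bin that composition tables exclude. Spot values
used in tests were evaluated independently from the closed forms:
K(0.10) = 0.1073256…, age(K = 0.10733) ≈ 23.33 My, and K = 4.6 × 10⁻³ gives
exactly 1.0 My.

## Genomic context

A tail overlaps a feature class when they share ≥ 1 bp (the common
interval-intersection default; no stricter rule is imposed). Class
membership is non-exclusive — a tail in a coding exon counts in pcgene, exon
and CDS simultaneously — because feature totals reported from annotation
intersections typically overlap; an additional exclusive label per tail uses
the priority CDS > UTR5 > UTR3 > exon > intron > intergenic. Only the tail
interval, not the whole element, is intersected. Intersection uses an
interval tree and is property-tested against a brute-force per-base oracle.
Chromosome density is count / (length in Mb).

## Cross-assembly comparison

Whole-genome alignments arrive as PAF with mandatory `cg:Z:` cigars
(`M/I/D/=/X` ops); the aligner itself is out of scope and the fixture
generator writes exact PAF directly. Liftover walks the cigar mapping both
interval endpoints; an endpoint in a deletion, outside every alignment, or
on a different alignment record than the other endpoint makes the locus
unmapped, and strand-reversed alignments flip the interval.

Per-locus multiple alignment is replaced by exact affine-gap global
pairwise alignment of each assembly's tail against the reference tail (star
layout; match +2, mismatch −2, gap open −4, gap extend −1, all
configurable). For ≤ 10 sequences of ≤ a few hundred bp this is exact and
deterministic, which a heuristic multiple aligner is not. Verdict cascade
with one primary call per locus: unmapped or < `presence_min_frac` (0.5) of
the reference tail aligned → `presence_absence`; any net length difference →
`length_variant` (signed per-assembly delta); differing tail categories →
`composition_change`; else `identical`. The presence threshold and the call
precedence are this package's formalisation of what is otherwise a manual
alignment-inspection step; both are exposed as configuration.

## Coding-sequence impact

mRNA is spliced from genomic exon coordinates (reverse-complemented for
minus-strand transcripts) after applying insertion edits given in reference
coordinates; edits outside every exon warn and do nothing. The ORF search
scans all six reading frames — even though the transcript strand is known —
and returns the longest ATG-initiated, stop-terminated frame (ties: forward
frames, lowest frame, leftmost); spans that run off the sequence without a
stop codon do not count. Translation uses the standard genetic code with
ambiguous codons rendered as `X`, stopping at the first stop codon; an
internal stop in a variant protein is reported, not treated as an error.
Protein comparison reports global-alignment percent identity with alignment
columns (gaps included) as the denominator — the denominator convention is
documented here because identity figures are not comparable across
conventions — plus the first divergent reference residue and a frameshift
flag that is purely arithmetic: insertion length mod 3 ≠ 0. Downstream
effects such as nonsense-mediated decay or splice disruption are out of
scope.

## Synthetic fixtures

Generators are pure functions of (parameters, seed). Planted elements are
`mutate(body, d) + cutoff + tail`: the substitution-only mutation model
(each base replaced with probability d, uniform over alternatives) keeps the
true tail boundary well-defined, and the tail itself is left unmutated so
the planted category is exact ground truth; indels enter only as explicit
assembly edits with hand-checkable cigars. Background GC defaults to 0.42
(pig-like); this is cosmetic realism, not load-bearing. `make_tail` builds a
per-category canonical construction and verifies it against the classifier
before returning. Default plant parameters — ~100–200 bp bodies, 10-bp
cutoffs, 24-bp tails (within the 1–43 bp range typical of real tails), 0 or
5 % divergence, 200-copy recovery cohorts — are the study conditions the
test suite asserts: 100 % category recovery at zero divergence and ≥ 95 % at
5 % body divergence with intact cutoffs.

What the fixtures do *not* emulate: tail mutation after insertion (so
recovery rates here say nothing about classifying genuinely degraded tails),
5′ truncation of elements, nested or overlapping insertions, and
slippage-driven tail evolution over time. Passing tests demonstrate that the
machinery is correct on known truth, not that category frequencies measured
on a real genome are unbiased.

## Numerical and degenerate-input choices

Empty tails classify as Other. Leftmost wins every positional tie (A-runs,
tandem runs). The first optimal alignment reported by the affine-gap aligner
is used, which is deterministic for a fixed scoring scheme. Zero-length
derived intervals (introns, intergenic) are dropped. The tail TSV table
carries the tail interval, element id, subfamily, method, sequence, category
and age columns; its header is fixed and checked on read.
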