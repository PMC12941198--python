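"""Canonical worked examples of the tail classification scheme.

One reference tail sequence per structural category (several for Other),
with the category's filter criterion expressed as (motif, minimum tandem
copies) where applicable. These are the sequences the classifier's default
configuration is validated against; they double as documentation of what
each category looks like in real annotation output.
"""

from __future__ import annotations

#: category label -> (first worked example, motif or None, min tandem copies or None)
CATEGORY_EXAMPLES: dict[str, tuple[str, str | None, int | None]] = {
    "(AAAAC)n": ("AAAACAAAACAAAACAAAAGACCAAAAA", "AAAAC", 2),
    "(AAAAG)n": ("AAAGAAAAAAGAAAAGGAAAAGAAAAGAA", "AAAAG", 2),
    "(AAAAT)n": ("AAAATAAAATAAAATAAAAA", "AAAAT", 2),
    "(AAAC)n": ("AAAACAAACAAACAAAAAA", "AAAC", 2),
    "(AAAG)n": ("AAAAAAAAAAAAAGAAAGAAAGAAAGAAA", "AAAG", 2),
    "(AAAT)n": ("AAATAAATAAATAAATAAATAA", "AAAT", 2),
    "(AAC)n": ("ACAACAACAACAACAACAACAACAACAAAA", "AAC", 2),
    "(AAG)n": ("AAAAAAGAAGAAGA", "AAG", 2),
    "(AAT)n": ("AGGCAAATAATAATAATAATAATAATAAAA", "AAT", 2),
    "(AC)n": ("AACACATACACACACACA", "AC", 3),
    "(AG)n": ("AAAAAAAAAAGAGAGAGAGAGAAA", "AG", 3),
    "(AT)n": ("AATATACATTATATATATAAAAGGAAAAAA", "AT", 3),
    "A-rich": ("AAAAAAAAAAAAAAAAAAAAAA", None, None),
    "AC-composite": ("GTCCTACAAAGCAAAAAACAAACAACAACA", None, None),
    "AG-composite": ("AAAAGAGAAGAAG", None, None),
    "AT-composite": ("AAAAATAAATAATAAATAAAA", None, None),
}

#: A second A-rich example: a 19-base adenine run covering 70.4% of the tail,
#: just above the default 70% coverage threshold.
A_RICH_BOUNDARY_EXAMPLE = "TAAAAAGCAAAAAAAAAAAAAAAAAAA"

#: Worked examples of tails failing every category.
OTHER_EXAMPLES = (
    "CTCCGACTCAACCCCTAGCCTGGGAACTCC",
    "TTGGGTGCAGTCCTAAAAA",
    "TCTGGCTGTGGCTGTGGCTGGCAGCTGCAGTT",
)

#: A documented 16-bp tail insertion polymorphism: the inserted sequence in
#: reference-strand orientation and on the gene-coding strand (the element is
#: antisense to the gene), which are reverse complements of each other.
VWA8_INSERTION_REF_STRAND = "CTTTCTTTATTTATTT"
VWA8_INSERTION_GENE_STRAND = "AAATAAATAAAGAAAG"
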