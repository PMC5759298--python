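"""Published *Seriola dorsalis* sex-marker resources.

Primer sequences, melting temperatures, and expected gel fragment sizes of
the two diagnostic assays (SdorDel01, SdorDel02); the 61 nt W-specific
deletion allele; the conserved 15-mer promoter motif; and the per-population
heterozygous-SNP counts observed in the sex-determining region (SDR) versus
size-matched random regions.  These are inputs to the analyses, usable
without access to the sequencing accessions.
"""

from __future__ import annotations

from collections import OrderedDict

#: W-specific deletion allele (61 nt), heterozygous in females, absent in
#: males; anchored at scaffold_22:246,495 in the reference assembly.
DELETION_61MER = (
    "CGTTCATGATTACTACTTTTACACAAATTTACACAAAAGACATCTGTACCAAAGAACAAAA"
)

#: Anchor position (1-based, base immediately left of the deleted bases).
DELETION_ANCHOR_POS = 246_495

#: Distance in bases between the deletion's 3' edge and the start of the
#: putative sex-determining gene (hsd17b1, Estradiol 17-beta-dehydrogenase).
DELETION_UPSTREAM_OFFSET = 954

#: Conserved promoter 15-mer overlapping the deletion on the minus strand.
SHARED_MOTIF = "GTCTTTTGTTCTTTG"

#: Diagnostic primer pairs: name -> (forward, reverse, product size on the
#: intact Z allele, product size on the deletion-bearing W allele, and the
#: published per-primer melting temperatures in degrees C).
PRIMER_ASSAYS = OrderedDict(
    SdorDel01=dict(
        fwd="AATTCATCCAAACCCAGCAG",
        rev="GGTCTTGTCAACTGCGATCA",
        product_z=452,
        product_w=391,
        tm_fwd=59.9,
        tm_rev=59.8,
    ),
    SdorDel02=dict(
        fwd="TGACAACAAGGCAACAGGAG",
        rev="TTGGCCTTTCTTTTGACCAC",
        product_z=282,
        product_w=221,
        tm_fwd=59.9,
        tm_rev=60.1,
    ),
)

#: Observed heterozygous-SNP counts per population and region:
#: (population, region tag, female count, male count).  CI = Cedros Island,
#: SD = San Diego, LP = La Paz.  "SDR" rows are the sex-determining region;
#: "Random" rows are size-matched control regions on other scaffolds.
HET_SNP_COUNTS = [
    ("CI", "SDR", 90, 20),
    ("SD", "SDR", 106, 27),
    ("LP", "SDR", 123, 20),
    ("LP", "Random", 140, 141),
    ("LP", "Random", 129, 107),
    ("LP", "Random", 82, 91),
    ("LP", "Random", 261, 226),
    ("SD", "Random", 161, 142),
    ("SD", "Random", 123, 97),
    ("SD", "Random", 101, 82),
    ("SD", "Random", 58, 66),
    ("SD", "Random", 238, 263),
    ("CI", "Random", 146, 170),
    ("CI", "Random", 113, 131),
    ("CI", "Random", 84, 91),
    ("CI", "Random", 55, 65),
    ("CI", "Random", 262, 238),
]
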