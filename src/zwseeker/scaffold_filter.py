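"""Assembly curation: drop short, redundant, or gene-less small scaffolds.

Rules (in order): a scaffold is removed when it is shorter than ``min_len``
bases; when at least ``containment`` of it is contained in a strictly
longer scaffold; or when it neither carries an annotated gene nor exceeds
``gene_or_len`` bases.  Containment is measured as the fraction of the
query's canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement) present in the longer scaffold's canonical k-mer set -- an
alignment-free proxy for sequence-length containment that is exactly
checkable against brute-force k-mer set intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import GeneAnnotation, ReferenceGenome, revcomp

__all__ = ["containment_fraction", "filter_scaffolds", "ScaffoldRecord"]


@dataclass
class ScaffoldRecord:
    id: str
    length: int
    has_gene: bool
    max_containment: float


def canonical_kmers(seq: str, k: int) -> set:
    """Set of canonical k-mers (min of k-mer and reverse complement)."""
    rc = revcomp(seq)
    n = len(seq)
    return {
        min(seq[i: i + k], rc[n - i - k: n - i]) for i in range(n - k + 1)
    }


def containment_fraction(query: str, subject: str, k: int = 21) -> float:
    """Fraction of the query's canonical k-mers found in the subject.

    The subject must be strictly longer than the query.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if len(query) > len(subject):
        raise ValueError("query longer than subject")
    if len(query) < k:
        return 0.0
    q = canonical_kmers(query, k)
    s = canonical_kmers(subject, k)
    return len(q & s) / len(q)


def filter_scaffolds(genome: ReferenceGenome,
                     annotation: GeneAnnotation,
                     min_len: int = 800,
                     containment: float = 0.90,
                     gene_or_len: int = 10_000,
                     k: int = 21):
    """Apply the curation rules; return (retained ids, per-scaffold log).

    Boundary semantics: "fewer than ``min_len``" keeps a scaffold of exactly
    ``min_len`` bases; "larger than ``gene_or_len``" removes a gene-less
    scaffold of exactly ``gene_or_len`` bases.  The log records the first
    rule that removed each dropped scaffold.
    """
    has_gene = set(annotation.records["scaffold"]) if annotation else set()
    lengths = genome.lengths()
    kmer_sets = {
        name: canonical_kmers(seq, k) if len(seq) >= k else set()
        for name, seq in genome.scaffolds.items()
    }
    retained, log = [], []
    for name, seq in genome.scaffolds.items():
        length = lengths[name]
        reason = "retained"
        max_cont = 0.0
        if length < min_len:
            reason = "min_len"
        else:
            q = kmer_sets[name]
            for other, other_len in lengths.items():
                if other == name or other_len <= length or not q:
                    continue
                frac = len(q & kmer_sets[other]) / len(q)
                max_cont = max(max_cont, frac)
            if max_cont >= containment:
                reason = "containment"
            elif name not in has_gene and length <= gene_or_len:
                reason = "no_gene_and_small"
        if reason == "retained":
            retained.append(name)
        log.append(dict(scaffold=name, length=length,
                        has_gene=name in has_gene,
                        max_containment=round(max_cont, 6),
                        decision=reason))
    return retained, pd.DataFrame(log)
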