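"""Phylogenetic footprinting of the W-specific deletion.

Extracts upstream promoter regions, discovers ungapped motifs shared across
orthologous promoters by seeded consensus-word enumeration with mismatches
(a deliberately simple stand-in for expectation-maximisation motif
discovery), scores windows against JASPAR-style position-weight matrices on
a relative [0,1] scale, and measures overlap between a motif and the
deletion allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .io_formats import GeneAnnotation, ReferenceGenome, revcomp

__all__ = [
    "PWM",
    "MotifHit",
    "extract_upstream",
    "find_shared_motifs",
    "relative_score",
    "scan_pwm",
    "deletion_overlap",
    "read_jaspar",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass
class PWM:
    """Position count/frequency matrix over A,C,G,T (rows) x positions."""

    counts: np.ndarray
    name: str = "pwm"
    background: np.ndarray | None = None
    pseudocount: float = 0.8

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 4 x width matrix")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def log_odds(self) -> np.ndarray:
        """log2 odds with the pseudocount split by background frequency."""
        pseudo = self.pseudocount * self.background[:, None]
        freq = (self.counts + pseudo) / (
            self.counts.sum(axis=0, keepdims=True) + self.pseudocount
        )
        return np.log2(freq / self.background[:, None])

    def reverse_complement(self) -> "PWM":
        return PWM(self.counts[::-1, ::-1], name=self.name + "_rc",
                   background=self.background[::-1],
                   pseudocount=self.pseudocount)


@dataclass
class MotifHit:
    """A fixed-width ungapped motif and where it matches each sequence."""

    motif: str
    n_sequences: int
    total_matches: int
    occurrences: pd.DataFrame  # sequence, pos (1-based), strand, mismatches


def extract_upstream(genome: ReferenceGenome, annotation: GeneAnnotation,
                     gene_id: str, span: int = 3000) -> str:
    """Promoter-side sequence upstream of a gene, 5'->3', <= span bases.

    Plus-strand genes: the span bases ending immediately before the gene
    start.  Minus-strand genes: the reverse complement of the span bases
    starting immediately after the gene end.  Truncated at scaffold edges.
    """
    gene = annotation.get(gene_id)
    scaffold = gene["scaffold"]
    length = len(genome[scaffold])
    if gene["strand"] == "+":
        end = gene["start"] - 1
        start = max(1, end - span + 1)
        if end < 1:
            warnings.warn(f"gene {gene_id} has no upstream bases",
                          stacklevel=2)
            return ""
        return genome.slice(scaffold, start, end)
    start = gene["end"] + 1
    end = min(length, start + span - 1)
    if start > length:
        warnings.warn(f"gene {gene_id} has no upstream bases", stacklevel=2)
        return ""
    return revcomp(genome.slice(scaffold, start, end))


# ---------------------------------------------------------------------------
# Shared-motif discovery


def _best_matches(words: np.ndarray, seq: str, max_mismatch: int):
    """Per word: (best mismatch count, 1-based pos, strand, n windows within).

    ``words`` is an (n_words, width) int8 array.  Both strands of ``seq``
    are searched; ties prefer the plus strand and the leftmost offset.
    """
    w = words.shape[1]
    n_words = words.shape[0]
    best_mm = np.full(n_words, w + 1, dtype=np.int32)
    best_pos = np.zeros(n_words, dtype=np.int64)
    best_strand = np.full(n_words, "+", dtype="U1")
    n_match = np.zeros(n_words, dtype=np.int64)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        enc = _encode(s)
        if len(enc) < w:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, w)
        chunk = max(1, int(2e7 // max(windows.shape[0], 1)))
        for lo in range(0, n_words, chunk):
            sub = words[lo: lo + chunk]
            mm = (sub[:, None, :] != windows[None, :, :]).sum(axis=2)
            n_match[lo: lo + chunk] += (mm <= max_mismatch).sum(axis=1)
            j = mm.argmin(axis=1)
            m = mm[np.arange(len(sub)), j]
            upd = m < best_mm[lo: lo + chunk]
            if strand == "-":
                pos = len(s) - j - w + 1
            else:
                pos = j + 1
            idx = np.arange(lo, lo + len(sub))[upd]
            best_mm[idx] = m[upd]
            best_pos[idx] = pos[upd]
            best_strand[idx] = strand
    return best_mm, best_pos, best_strand, n_match


def find_shared_motifs(sequences, width: int = 15, max_mismatch: int = 2,
                       min_seqs: int | None = None) -> list:
    """Ungapped motifs shared across sequences, by consensus-word search.

    Every ``width``-mer of the first sequence is a candidate word; a
    sequence supports a word when it contains a match within
    ``max_mismatch`` on either strand.  Words supported by >= ``min_seqs``
    sequences are ranked by (sequence count, total matching windows) and
    overlapping words are merged to the best-ranked representative.
    """
    if isinstance(sequences, dict):
        names = list(sequences)
        seqs = [sequences[n] for n in names]
    else:
        seqs = list(sequences)
        names = [f"seq_{i + 1}" for i in range(len(seqs))]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if any(len(s) < width for s in seqs):
        raise ValueError("width exceeds the shortest sequence")
    if min_seqs is None:
        min_seqs = len(seqs)

    first = _encode(seqs[0])
    all_words = np.lib.stride_tricks.sliding_window_view(first, width)
    valid = ~np.any(all_words < 0, axis=1)
    offsets = np.flatnonzero(valid)
    words, uniq_idx = np.unique(all_words[valid], axis=0, return_index=True)
    word_offset = offsets[uniq_idx]  # representative offset in sequence 1

    per_seq = [
        _best_matches(words, s, max_mismatch) for s in seqs
    ]
    support = np.zeros(len(words), dtype=np.int64)
    totals = np.zeros(len(words), dtype=np.int64)
    mm_sum = np.zeros(len(words), dtype=np.int64)
    for mm, _, _, n in per_seq:
        hit = mm <= max_mismatch
        support += hit
        totals += n
        mm_sum += np.where(hit, mm, 0)

    # rank: most sequences, then most matching windows, then the most
    # conserved representative (fewest mismatches), then leftmost
    order = np.lexsort((word_offset, mm_sum, -totals, -support))
    bases = np.array(list("ACGT"))
    taken = []  # (start, end) intervals on sequence 1
    hits = []
    for k in order:
        if support[k] < min_seqs:
            continue
        start = int(word_offset[k])
        end = start + width - 1
        if any(s <= end and start <= e for s, e in taken):
            continue
        taken.append((start, end))
        rows = []
        for (mm, pos, strand, _), name in zip(per_seq, names):
            if mm[k] <= max_mismatch:
                rows.append(dict(sequence=name, pos=int(pos[k]),
                                 strand=str(strand[k]),
                                 mismatches=int(mm[k])))
        hits.append(MotifHit(
            motif="".join(bases[words[k]]),
            n_sequences=int(support[k]),
            total_matches=int(totals[k]),
            occurrences=pd.DataFrame(
                rows, columns=["sequence", "pos", "strand", "mismatches"]
            ),
        ))
    return hits


# ---------------------------------------------------------------------------
# PWM scoring


def relative_score(pwm: PWM, window: str) -> float:
    """Log-odds score rescaled to [0,1] between the matrix min and max."""
    enc = _encode(window)
    if len(enc) != pwm.width:
        raise ValueError(
            f"window length {len(enc)} != PWM width {pwm.width}"
        )
    if np.any(enc < 0):
        raise ValueError("window contains non-ACGT characters")
    lo = pwm.log_odds()
    s = float(lo[enc, np.arange(pwm.width)].sum())
    smin = float(lo.min(axis=0).sum())
    smax = float(lo.max(axis=0).sum())
    return (s - smin) / (smax - smin)


def scan_pwm(pwm: PWM, sequence: str, threshold: float = 0.8) -> list:
    """Hits of a PWM on both strands of a sequence.

    Returns (position 1-based on the given sequence, strand, relative
    score) tuples with score >= threshold, sorted by descending score.
    """
    enc = _encode(sequence)
    w = pwm.width
    if len(enc) < w:
        raise ValueError("sequence shorter than the PWM width")
    lo = pwm.log_odds()
    smin = lo.min(axis=0).sum()
    smax = lo.max(axis=0).sum()
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    ok = ~np.any(windows < 0, axis=1)
    safe = np.where(windows < 0, 0, windows)
    cols = np.arange(w)
    hits = []
    for strand, mat in (("+", lo), ("-", pwm.reverse_complement().log_odds())):
        scores = mat[safe, cols].sum(axis=1)
        rel = (scores - smin) / (smax - smin)
        for i in np.flatnonzero(ok & (rel >= threshold)):
            hits.append((int(i) + 1, strand, float(rel[i])))
    hits.sort(key=lambda h: (-h[2], h[0], h[1]))
    return hits


def deletion_overlap(motif: str, strand: str, deletion_sequence: str) -> int:
    """Longest contiguous match between the oriented motif and the deletion.

    The motif is reverse complemented when ``strand`` is "-".  Matches may
    abut either end of the deletion, so partial boundary overlap counts.
    """
    if not motif or not deletion_sequence:
        raise ValueError("motif and deletion sequence must be non-empty")
    a = motif.upper() if strand == "+" else revcomp(motif.upper())
    b = deletion_sequence.upper()
    best = 0
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for i in range(1, len(a) + 1):
        cur = np.zeros(len(b) + 1, dtype=np.int64)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, int(cur[j]))
        prev = cur
    return best


def read_jaspar(path) -> list:
    """Read JASPAR-format PFM file(s) into PWM objects (Biopython parser)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(PWM(counts, name=m.name or m.matrix_id or "pwm"))
    return out
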