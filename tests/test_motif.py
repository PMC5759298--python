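from collections import OrderedDict
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from zwseeker import motif, resources, synthetic_data as sd
from zwseeker.io_formats import GeneAnnotation, ReferenceGenome, revcomp

MOTIF = resources.SHARED_MOTIF
DEL = resources.DELETION_61MER


# ---------------------------------------------------------------------------
# Upstream extraction


def _genome_with_genes(length=10_000):
    rng = np.random.default_rng(0)
    genome = ReferenceGenome(OrderedDict(
        s1="".join(rng.choice(list("ACGT"), size=length))
    ))
    ann = GeneAnnotation(pd.DataFrame(
        [("s1", 5_001, 6_000, "+", "plus_gene"),
         ("s1", 50, 100, "-", "minus_gene"),
         ("s1", 1_001, 1_500, "+", "edge_gene")],
        columns=["scaffold", "start", "end", "strand", "gene_id"],
    ))
    return genome, ann


def test_plus_strand_upstream_window():
    genome, ann = _genome_with_genes()
    up = motif.extract_upstream(genome, ann, "plus_gene", span=3000)
    assert up == genome.slice("s1", 2_001, 5_000)


def test_minus_strand_upstream_is_reverse_complement():
    genome, ann = _genome_with_genes(length=4_000)
    up = motif.extract_upstream(genome, ann, "minus_gene", span=3000)
    assert up == revcomp(genome.slice("s1", 101, 3_100))


def test_upstream_truncated_at_scaffold_edge():
    genome, ann = _genome_with_genes()
    up = motif.extract_upstream(genome, ann, "edge_gene", span=3000)
    assert len(up) == 1_000
    assert up == genome.slice("s1", 1, 1_000)


def test_simulated_target_gene_upstream_contains_motif(default_cohort):
    """The conserved 15-mer sits on the minus strand of the promoter,
    crossing the deletion's 3' edge."""
    genome, annotation, _t, _p, truth = default_cohort
    up = motif.extract_upstream(genome, annotation, truth.target_gene)
    assert revcomp(MOTIF) in up


# ---------------------------------------------------------------------------
# Shared-motif discovery


def test_planted_motif_found_in_all_seven():
    seqs, _ = sd.make_promoter_fixture(planted_fraction=1.0)
    hits = motif.find_shared_motifs(seqs, width=15, max_mismatch=2,
                                    min_seqs=7)
    assert hits[0].motif in (MOTIF, revcomp(MOTIF))
    assert hits[0].n_sequences == 7
    assert (hits[0].occurrences["mismatches"] == 0).all()


def test_planted_motif_found_in_five_of_seven():
    seqs, planted = sd.make_promoter_fixture(planted_fraction=5 / 7)
    hits = motif.find_shared_motifs(seqs, width=15, max_mismatch=2,
                                    min_seqs=5)
    top = hits[0]
    assert top.motif in (MOTIF, revcomp(MOTIF))
    assert top.n_sequences == 5
    assert set(top.occurrences["sequence"]) == set(planted["species"])


def brute_force_shared(seqs, width, max_mismatch, min_seqs):
    """Oracle: enumerate every word/offset/strand combination directly."""

    def mismatches(a, b):
        return sum(x != y for x, y in zip(a, b))

    support = {}
    for i in range(len(seqs[0]) - width + 1):
        word = seqs[0][i: i + width]
        n = 0
        for s in seqs:
            found = False
            for strand_seq in (s, revcomp(s)):
                for j in range(len(strand_seq) - width + 1):
                    if mismatches(word, strand_seq[j: j + width]) \
                            <= max_mismatch:
                        found = True
                        break
                if found:
                    break
            n += found
        if n >= min_seqs:
            support[word] = max(support.get(word, 0), n)
    return support


def test_discovery_matches_brute_force_on_short_sequences():
    rng = np.random.default_rng(5)
    seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(3)]
    seqs = [s + "ACGTT" for s in seqs]  # guarantee one shared word
    oracle = brute_force_shared(seqs, width=4, max_mismatch=0, min_seqs=3)
    hits = motif.find_shared_motifs(seqs, width=4, max_mismatch=0,
                                    min_seqs=3)
    # every reported word is shared per the oracle ...
    for h in hits:
        assert h.motif in oracle and oracle[h.motif] == h.n_sequences == 3
    # ... and every oracle word is covered by a reported (merged) word's
    # footprint in the first sequence
    reported_spans = [
        (h.occurrences.set_index("sequence").loc["seq_1", "pos"], h.motif)
        for h in hits
    ]
    assert oracle  # the appended tail guarantees at least one shared word
    for word in oracle:
        pos = seqs[0].find(word)
        assert any(p - 4 < pos + 1 < p + 4 for p, _ in reported_spans)


def test_exact_full_support_reduces_to_common_substring():
    # GACGT is the only 5-mer of the first sequence present in all three
    seqs = ["TTTTGACGTTTT", "AAGACGTAA", "CCGACGTCC"]
    hits = motif.find_shared_motifs(seqs, width=5, max_mismatch=0,
                                    min_seqs=3)
    assert [h.motif for h in hits] == ["GACGT"]
    assert hits[0].n_sequences == 3


# ---------------------------------------------------------------------------
# PWM scoring


def _toy_pwm():
    counts = np.array([
        [12.0, 1.0],
        [3.0, 2.0],
        [4.0, 15.0],
        [1.0, 2.0],
    ])
    return motif.PWM(counts, name="toy")


def test_relative_score_extremes():
    pwm = _toy_pwm()
    lo = pwm.log_odds()
    best = "".join("ACGT"[i] for i in lo.argmax(axis=0))
    worst = "".join("ACGT"[i] for i in lo.argmin(axis=0))
    assert motif.relative_score(pwm, best) == pytest.approx(1.0)
    assert motif.relative_score(pwm, worst) == pytest.approx(0.0)


def test_relative_score_matches_exhaustive_enumeration():
    pwm = _toy_pwm()
    lo = pwm.log_odds()
    smin = lo.min(axis=0).sum()
    smax = lo.max(axis=0).sum()
    for a, b in product("ACGT", repeat=2):
        s = lo["ACGT".index(a), 0] + lo["ACGT".index(b), 1]
        expected = (s - smin) / (smax - smin)
        assert motif.relative_score(pwm, a + b) == pytest.approx(expected)


def test_relative_score_matches_biopython_pssm():
    """Independent oracle: Biopython's PSSM with the same pseudocounts."""
    from Bio import motifs as bio_motifs
    from Bio.Seq import Seq

    instances = [Seq(w) for w in ("ACGTA", "ACGTT", "ACGCA", "TCGTA")]
    m = bio_motifs.create(instances)
    counts = np.array([[m.counts[b][i] for i in range(5)] for b in "ACGT"])
    pwm = motif.PWM(counts)
    pseudo = {b: 0.8 * 0.25 for b in "ACGT"}
    pssm = m.counts.normalize(pseudocounts=pseudo).log_odds()
    window = "ACGTA"
    s = sum(pssm[window[i]][i] for i in range(5))
    smin = sum(min(pssm[b][i] for b in "ACGT") for i in range(5))
    smax = sum(max(pssm[b][i] for b in "ACGT") for i in range(5))
    assert motif.relative_score(pwm, window) == pytest.approx(
        (s - smin) / (smax - smin)
    )


def test_relative_score_reverse_complement_invariance():
    pwm = _toy_pwm()
    rc = pwm.reverse_complement()
    for a, b in product("ACGT", repeat=2):
        w = a + b
        assert motif.relative_score(pwm, w) == pytest.approx(
            motif.relative_score(rc, revcomp(w))
        )


def test_relative_score_length_mismatch_errors():
    with pytest.raises(ValueError):
        motif.relative_score(_toy_pwm(), "ACG")


def test_scan_finds_planted_consensus():
    rng = np.random.default_rng(9)
    counts = np.eye(4)[:, [0, 1, 2, 3, 0, 2]] * 10.0  # consensus ACGTAG
    pwm = motif.PWM(counts)
    background = "".join(rng.choice(list("TT"), size=40))
    seq = background[:20] + "ACGTAG" + background[20:]
    hits = motif.scan_pwm(pwm, seq, threshold=0.99)
    assert (21, "+", ) == tuple(hits[0][:2])
    assert hits[0][2] == pytest.approx(1.0)
    assert motif.scan_pwm(pwm, seq, threshold=1.01) == []


def test_scan_matches_brute_force():
    rng = np.random.default_rng(10)
    pwm = _toy_pwm()
    seq = "".join(rng.choice(list("ACGT"), size=50))
    got = motif.scan_pwm(pwm, seq, threshold=0.0)
    expected = []
    for i in range(49):
        w = seq[i: i + 2]
        expected.append((i + 1, "+", motif.relative_score(pwm, w)))
        expected.append((i + 1, "-",
                         motif.relative_score(pwm, revcomp(w))))
    expected.sort(key=lambda h: (-h[2], h[0], h[1]))
    assert len(got) == len(expected)
    for g, e in zip(got, expected):
        assert g[:2] == e[:2]
        assert g[2] == pytest.approx(e[2])


# ---------------------------------------------------------------------------
# Deletion overlap


def test_published_motif_overlaps_deletion_on_minus_strand():
    assert motif.deletion_overlap(MOTIF, "-", DEL) >= 12


def test_full_overlap_for_contained_motif():
    sub = DEL[10:25]
    assert motif.deletion_overlap(sub, "+", DEL) == len(sub)


def test_chance_overlap_is_small_but_nonnegative():
    got = motif.deletion_overlap("GGGGGGGGGG", "+", "A" * 50 + "C" * 11)
    assert 0 <= got <= 3


@given(st.text(alphabet="ACGT", min_size=4, max_size=12))
def test_overlap_strand_consistency(word):
    # scoring a word on "-" equals scoring its reverse complement on "+"
    assert motif.deletion_overlap(word, "-", DEL) == \
        motif.deletion_overlap(revcomp(word), "+", DEL)


# ---------------------------------------------------------------------------
# JASPAR I/O


def test_read_jaspar_pfm(tmp_path):
    p = tmp_path / "toy.jaspar"
    p.write_text(
        ">MA0000.1 toy\n"
        "A [ 10  2  0 ]\n"
        "C [  0  8  1 ]\n"
        "G [  2  0  9 ]\n"
        "T [  0  2  2 ]\n"
    )
    pwms = motif.read_jaspar(p)
    assert len(pwms) == 1
    assert pwms[0].width == 3
    assert pwms[0].counts[0, 0] == 10
    consensus = "ACG"
    assert motif.relative_score(pwms[0], consensus) == pytest.approx(1.0)
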