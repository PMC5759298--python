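"""W-linked deletion marker discovery and in-silico PCR validation.

``scan_indels`` finds large (>40 nt) indels inside the SDR whose read
support is heterozygous-consistent in females and absent in males --
assessed on group-pooled allelic depths, the only robust reading at ~2x
coverage.  ``primer_tm`` reproduces classic Primer3 melting temperatures
(Breslauer 1986 nearest-neighbor thermodynamics, Schildkraut-Lifson salt
correction, 50 nM oligo / 50 mM monovalent cation); SantaLucia 1998 unified
parameters are available as an alternative.  ``in_silico_pcr`` predicts
amplicons from properly oriented primer matches, and ``call_sex`` turns the
band pattern of a diploid sample into an F/M call (two bands = ZW female,
single undeleted band = ZZ male).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CohortPanel, VariantTable, revcomp

__all__ = [
    "IndelCandidate",
    "MarkerAssay",
    "Amplicon",
    "scan_indels",
    "primer_tm",
    "in_silico_pcr",
    "call_sex",
    "genotype_cohort",
    "design_primers",
    "enumerate_primer_candidates",
]


@dataclass
class IndelCandidate:
    scaffold: str
    pos: int  # 1-based anchor (base before the event)
    sequence: str  # deleted or inserted bases
    length: int
    is_deletion: bool
    female_pooled_alt_fraction: float
    male_pooled_alt_fraction: float
    female_het_call_fraction: float  # per-sample GT summary, reported only
    male_alt_call_fraction: float
    het_in_females: bool = field(default=False)
    absent_in_males: bool = field(default=False)


@dataclass
class MarkerAssay:
    name: str
    fwd: str
    rev: str
    tm_fwd: float
    tm_rev: float
    product_without_deletion: int
    product_with_deletion: int


@dataclass
class Amplicon:
    template_id: str
    start: int  # 1-based, inclusive, spans both primer footprints
    end: int
    length: int
    strand: str  # strand of the forward-primer match


# ---------------------------------------------------------------------------
# Indel scan


def scan_indels(table: VariantTable, panel: CohortPanel, sdr_interval: tuple,
                min_len: int = 41, female_band: tuple = (0.30, 0.70),
                male_max: float = 0.05, min_depth: int = 10) -> list:
    """Sex-linked indel candidates in the SDR.

    Candidates are biallelic indels inside ``sdr_interval`` with
    |len(ref) - len(alt)| >= ``min_len`` (strictly greater than 40 by
    default) whose pooled female alt-read fraction lies in ``female_band``
    (heterozygous-consistent) while the pooled male alt-read fraction is at
    most ``male_max``, each with pooled depth >= ``min_depth``.
    """
    scaffold, start, end = sdr_interval
    females = [i for i, s in enumerate(table.samples)
               if panel.table.set_index("sample")["sex"][s] == "F"]
    males = [i for i in range(table.n_samples) if i not in females]
    sites = table.sites
    mask = (
        table.is_biallelic()
        & table.is_indel().astype(bool)
        & (sites["scaffold"] == scaffold).to_numpy()
        & (sites["pos"] >= start).to_numpy()
        & (sites["pos"] <= end).to_numpy()
    )
    out = []
    for i in np.flatnonzero(mask):
        ref = sites.iloc[i]["ref"]
        alt = sites.iloc[i]["alts"][0]
        length = abs(len(ref) - len(alt))
        if length < min_len:
            continue
        is_del = len(ref) > len(alt)
        seq = ref[len(alt):] if is_del else alt[len(ref):]
        ad = np.where(table.ad[i] < 0, 0, table.ad[i])
        stats = {}
        for tag, cols in (("F", females), ("M", males)):
            r = int(ad[cols, 0].sum())
            a = int(ad[cols, 1].sum())
            d = r + a
            stats[tag] = (a / d if d > 0 else np.nan, d)
        f_frac, f_depth = stats["F"]
        m_frac, m_depth = stats["M"]
        gt = table.gt[i]
        f_gt = gt[females]
        m_gt = gt[males]
        f_called = f_gt[f_gt[:, 0] >= 0]
        m_called = m_gt[m_gt[:, 0] >= 0]
        f_het = float(np.mean(
            (f_called[:, 0] == 0) & (f_called[:, 1] == 1)
        )) if len(f_called) else np.nan
        m_alt = float(np.mean(
            (m_called == 1).any(axis=1)
        )) if len(m_called) else np.nan
        het_f = (
            f_depth >= min_depth
            and not math.isnan(f_frac)
            and female_band[0] <= f_frac <= female_band[1]
        )
        abs_m = (
            m_depth >= min_depth
            and not math.isnan(m_frac)
            and m_frac <= male_max
        )
        if het_f and abs_m:
            out.append(IndelCandidate(
                scaffold=scaffold, pos=int(sites.iloc[i]["pos"]),
                sequence=seq, length=length, is_deletion=is_del,
                female_pooled_alt_fraction=float(f_frac),
                male_pooled_alt_fraction=float(m_frac),
                female_het_call_fraction=f_het,
                male_alt_call_fraction=m_alt,
                het_in_females=True, absent_in_males=True,
            ))
    return out


# ---------------------------------------------------------------------------
# Melting temperature

# Breslauer 1986 duplex-formation parameters as used by classic Primer3
# (oligotm): enthalpy in kcal/mol, entropy in cal/(K*mol), magnitudes.
_BRESLAUER_H = {
    "AA": 9.1, "AC": 6.5, "AG": 7.8, "AT": 8.6,
    "CA": 5.8, "CC": 11.0, "CG": 11.9, "CT": 7.8,
    "GA": 5.6, "GC": 11.1, "GG": 11.0, "GT": 6.5,
    "TA": 6.0, "TC": 5.6, "TG": 5.8, "TT": 9.1,
}
_BRESLAUER_S = {
    "AA": 24.0, "AC": 17.3, "AG": 20.8, "AT": 23.9,
    "CA": 12.9, "CC": 26.6, "CG": 27.8, "CT": 20.8,
    "GA": 13.5, "GC": 26.7, "GG": 26.6, "GT": 17.3,
    "TA": 16.9, "TC": 13.5, "TG": 12.9, "TT": 24.0,
}

# SantaLucia 1998 unified parameters (signed: duplex formation).
_SL98_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    # complementary doublets
    "TT": (-7.9, -22.2), "TG": (-8.5, -22.7), "AC": (-8.4, -22.4),
    "AG": (-7.8, -21.0), "TC": (-8.2, -22.2), "CC": (-8.0, -19.9),
}
_SL98_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8),
              "A": (2.3, 4.1), "T": (2.3, 4.1)}

_R = 1.987  # cal/(K*mol)


def primer_tm(sequence: str, dna_nM: float = 50.0, mono_mM: float = 50.0,
              method: str = "breslauer") -> float:
    """Primer melting temperature in degrees C.

    ``method="breslauer"`` (default) reproduces classic Primer3 behaviour:
    Breslauer 1986 nearest-neighbor parameters with a -10.8 eu initiation
    entropy, total-strand concentration CT/4, and the Schildkraut-Lifson
    16.6*log10[Na+] salt correction.  ``method="santalucia"`` uses the
    SantaLucia 1998 unified parameters with the entropic salt correction
    0.368*(N-1)*ln[Na+].
    """
    seq = sequence.upper()
    if not (8 <= len(seq) <= 36):
        raise ValueError("primer length must be within 8-36 bases")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"primer contains non-ACGT characters: {sorted(bad)}")
    ct = dna_nM * 1e-9
    na = mono_mM / 1000.0
    doublets = [seq[i: i + 2] for i in range(len(seq) - 1)]
    if method == "breslauer":
        dh = -1000.0 * sum(_BRESLAUER_H[d] for d in doublets)
        ds = -(sum(_BRESLAUER_S[d] for d in doublets) + 10.8)
        return dh / (ds + _R * math.log(ct / 4.0)) - 273.15 \
            + 16.6 * math.log10(na)
    if method == "santalucia":
        dh = sum(_SL98_NN[d][0] for d in doublets) * 1000.0
        ds = sum(_SL98_NN[d][1] for d in doublets)
        for endbase in (seq[0], seq[-1]):
            h, s = _SL98_INIT[endbase]
            dh += h * 1000.0
            ds += s
        ds += 0.368 * (len(seq) - 1) * math.log(na)
        return dh / (ds + _R * math.log(ct / 4.0)) - 273.15
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# In-silico PCR


def _match_positions(template: str, pattern: str, max_mismatch: int,
                     protect: str) -> list:
    """0-based start positions where pattern matches the template.

    ``protect`` is "suffix" or "prefix": the primer's 3'-terminal 3 bases
    (pattern suffix for a forward-oriented pattern, prefix for a
    reverse-complemented one) must match exactly even when mismatches are
    allowed elsewhere.
    """
    if max_mismatch == 0:
        hits, i = [], template.find(pattern)
        while i != -1:
            hits.append(i)
            i = template.find(pattern, i + 1)
        return hits
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    if len(t) < len(p):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t, len(p))
    diff = windows != p
    clamp = slice(-3, None) if protect == "suffix" else slice(0, 3)
    ok = (diff.sum(axis=1) <= max_mismatch) & ~diff[:, clamp].any(axis=1)
    return np.flatnonzero(ok).tolist()


def in_silico_pcr(template: str, fwd: str, rev: str,
                  max_product: int = 3000, max_mismatch: int = 0,
                  template_id: str = "template") -> list:
    """Predict amplicons for a primer pair on one template.

    Both orientations are searched: forward primer on the plus strand with
    the reverse primer's reverse complement downstream, and the mirrored
    arrangement (forward primer on the minus strand).  Amplicon length
    includes both primer footprints and is capped at ``max_product``.
    """
    template = template.upper()
    fwd, rev = fwd.upper(), rev.upper()
    out = []
    for strand, p5, p3 in (("+", fwd, rev), ("-", rev, fwd)):
        left_hits = _match_positions(template, p5, max_mismatch, "suffix")
        right_hits = _match_positions(template, revcomp(p3), max_mismatch,
                                      "prefix")
        for i in left_hits:
            for j in right_hits:
                if j < i + len(p5):
                    continue
                length = j + len(p3) - i
                if length > max_product:
                    continue
                out.append(Amplicon(
                    template_id=template_id, start=i + 1,
                    end=j + len(p3), length=length, strand=strand,
                ))
    out.sort(key=lambda a: (a.start, a.end, a.strand))
    return out


# ---------------------------------------------------------------------------
# Gel-pattern sex genotyping


def call_sex(band_lengths, product_without_deletion: int,
             product_with_deletion: int) -> str:
    """F / M / anomalous from a diploid sample's amplicon lengths.

    Two distinct bands matching the undeleted and deleted products -> F
    (heterozygous ZW female); only the larger (undeleted) band -> M; only
    the smaller band, extra bands, or no band -> anomalous.
    """
    bands = sorted(set(int(b) for b in band_lengths))
    expect_f = sorted({product_without_deletion, product_with_deletion})
    if bands == expect_f:
        return "F"
    if bands == [product_without_deletion]:
        return "M"
    return "anomalous"


def genotype_cohort(templates: dict, fwd: str, rev: str,
                    product_without_deletion: int,
                    product_with_deletion: int,
                    max_product: int = 3000) -> dict:
    """Run the assay on each sample's two allele templates; return calls."""
    calls = {}
    for sample, pair in templates.items():
        bands = []
        for allele in pair:
            for amp in in_silico_pcr(allele, fwd, rev,
                                     max_product=max_product):
                bands.append(amp.length)
        calls[sample] = call_sex(bands, product_without_deletion,
                                 product_with_deletion)
    return calls


# ---------------------------------------------------------------------------
# Primer design (simplified exhaustive enumeration)


def _longest_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def enumerate_primer_candidates(flank: str, target_tm: float = 60.0,
                                len_range: tuple = (18, 22)) -> list:
    """All viable primer windows in a flank, scored and sorted.

    Score = |Tm - target_tm| + 1.0 when the 3' base is not G/C; windows
    containing a homopolymer run of 5+ or non-ACGT characters are excluded.
    Returns a list of dicts sorted by ascending score.
    """
    flank = flank.upper()
    cands = []
    for w in range(len_range[0], len_range[1] + 1):
        for i in range(len(flank) - w + 1):
            window = flank[i: i + w]
            if set(window) - set("ACGT"):
                continue
            if _longest_homopolymer(window) >= 5:
                continue
            tm = primer_tm(window)
            score = abs(tm - target_tm) + (0.0 if window[-1] in "GC" else 1.0)
            cands.append(dict(start=i + 1, length=w, seq=window, tm=tm,
                              score=score))
    cands.sort(key=lambda c: (c["score"], c["start"], c["length"]))
    return cands


def design_primers(flank_left: str, flank_right: str, deletion_len: int = 0,
                   target_tm: float = 60.0, len_range: tuple = (18, 22),
                   n_pairs: int = 5) -> list:
    """Primer pairs spanning the region between two flanks.

    ``flank_left``/``flank_right`` are the sequences immediately left and
    right of the target event (e.g. a deletion of ``deletion_len`` bases).
    Forward candidates are windows of the left flank; reverse candidates
    are reverse complements of right-flank windows.  The best-scoring
    combinations are returned with predicted product sizes on the intact
    and deleted alleles.
    """
    if len(flank_left) < 100 or len(flank_right) < 100:
        raise ValueError("each flank must be at least 100 bases")
    lefts = enumerate_primer_candidates(flank_left, target_tm, len_range)
    rights = enumerate_primer_candidates(flank_right, target_tm, len_range)
    if not lefts or not rights:
        warnings.warn("no primer candidates satisfy the constraints",
                      stacklevel=2)
        return []
    pairs = []
    for lf in lefts[: n_pairs * 4]:
        for rt in rights[: n_pairs * 4]:
            span_left = len(flank_left) - lf["start"] + 1
            span_right = rt["start"] + rt["length"] - 1
            product = span_left + deletion_len + span_right
            pairs.append((lf["score"] + rt["score"], lf, rt, product))
    pairs.sort(key=lambda p: p[0])
    out = []
    for rank, (score, lf, rt, product) in enumerate(pairs[:n_pairs], 1):
        rev = revcomp(rt["seq"])
        out.append(MarkerAssay(
            name=f"pair_{rank:02d}",
            fwd=lf["seq"], rev=rev,
            tm_fwd=round(lf["tm"], 2), tm_rev=round(rt["tm"], 2),
            product_without_deletion=product,
            product_with_deletion=product - deletion_len,
        ))
    return out
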