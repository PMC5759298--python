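"""Simulated ZW resequencing cohorts and promoter fixtures.

The generator emulates the data a sexed, low-coverage (~2x) resequencing
study produces after alignment and variant calling: a multi-scaffold
reference with gene annotations, and a VCF of biallelic background SNPs
segregating under Hardy-Weinberg plus a fully sex-linked segment (the SDR)
carrying W-specific variants -- heterozygous in every true female, absent
from every true male at the haplotype level.  Observed genotypes are
degraded realistically: per sample-site read depth is Poisson with the
configured mean, allele counts are binomial in the true diploid dosage, and
genotypes are re-called from the sampled reads (zero depth -> missing call).

The reference carries, at the deletion locus, the published 452 bp assay
cassette (both diagnostic primer pairs flanking the 61 nt W-specific
deletion), so the published PCR assay amplifies directly from simulated
haplotypes.  A conserved promoter 15-mer crosses the deletion's 3' edge on
the minus strand, 954 bp upstream of the annotated target gene.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import resources
from .io_formats import (
    CohortPanel,
    GeneAnnotation,
    ReferenceGenome,
    VariantTable,
    revcomp,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_cohort",
    "make_marker_fixture",
    "make_promoter_fixture",
    "marker_cassette",
]

_NT = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_NT, size=length).tobytes().decode()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the published study design: three sampling locations of
    15 females + 15 males each (90 samples), ~2x mean coverage, genome-wide
    SNP density 0.0115/base, and an 89 kb fully sex-linked SDR on
    scaffold_22 carrying the 61 nt W-specific deletion 954 bases upstream
    of the target gene.
    """

    seed: int = 0
    populations: tuple = (("CI", 15, 15), ("SD", 15, 15), ("LP", 15, 15))
    sdr_scaffold: str = "scaffold_22"
    sdr_start: int = 231_000
    sdr_end: int = 320_000
    sdr_scaffold_length: int = 400_000
    n_other_scaffolds: int = 11
    other_scaffold_length: int = 150_000
    snp_density: float = 0.0115
    maf_range: tuple = (0.05, 0.5)
    w_snp_count: int = 900
    deletion_sequence: str = resources.DELETION_61MER
    deletion_anchor: int = resources.DELETION_ANCHOR_POS
    upstream_offset: int = resources.DELETION_UPSTREAM_OFFSET
    coverage: float = 2.0
    n_multiallelic: int = 120
    plant_decoy_indels: bool = True
    #: "ZW" -> females heterogametic; "XY" -> males heterogametic.
    sex_system: str = "ZW"

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if len(self.deletion_sequence) <= 40:
            raise ValueError("deletion sequence must be longer than 40 nt")
        if not (1 <= self.sdr_start <= self.sdr_end
                <= self.sdr_scaffold_length):
            raise ValueError("SDR interval overlaps the scaffold end")
        if self.sex_system not in ("ZW", "XY"):
            raise ValueError("sex_system must be 'ZW' or 'XY'")

    @property
    def heterogametic_sex(self) -> str:
        return "F" if self.sex_system == "ZW" else "M"


@dataclass
class TruthSet:
    """Ground truth recorded by the generator for parameter-recovery tests."""

    sdr: tuple  # (scaffold, start, end)
    w_snp_positions: np.ndarray  # positions of W-linked SNPs (on sdr scaffold)
    deletion: tuple  # (scaffold, anchor_pos, deleted sequence)
    sample_chromosomes: dict  # sample -> "ZW"/"ZZ" (or "XY"/"XX")
    target_gene: str = "hsd17b1"
    n_multiallelic: int = 0
    decoy_indels: list = field(default_factory=list)

    def true_sex(self, sample: str) -> str:
        pair = self.sample_chromosomes[sample]
        return "F" if pair in ("ZW", "XX") else "M"

    def is_heterogametic(self, sample: str) -> bool:
        pair = self.sample_chromosomes[sample]
        return pair in ("ZW", "XY")


# ---------------------------------------------------------------------------
# Marker cassette


def marker_cassette(rng_seed: int = 7) -> dict:
    """Deterministic 452 bp assay cassette around the 61 nt deletion.

    Layout 5'->3' on the intact (Z) allele: SdorDel01 forward site, spacer,
    SdorDel02 forward site, spacer, the 61-mer, spacer, SdorDel02 reverse
    complement site, spacer, SdorDel01 reverse complement site.  Spacer
    lengths are fixed so the two pairs' products are 452 bp and 282 bp
    without the deletion (391/221 with it).  The spacer following the
    deletion begins with "GAC" so the conserved 15-mer's reverse complement
    spans the deletion's 3' edge, as observed at the real locus.
    """
    rng = np.random.default_rng(rng_seed)
    a1 = resources.PRIMER_ASSAYS["SdorDel01"]
    a2 = resources.PRIMER_ASSAYS["SdorDel02"]
    deletion = resources.DELETION_61MER
    gap_a = _random_seq(rng, 65)
    gap_b = _random_seq(rng, 90)
    gap_c = "GAC" + _random_seq(rng, 88)
    gap_d = _random_seq(rng, 65)
    z = (
        a1["fwd"] + gap_a + a2["fwd"] + gap_b + deletion + gap_c
        + revcomp(a2["rev"]) + gap_d + revcomp(a1["rev"])
    )
    del_offset = len(a1["fwd"]) + len(gap_a) + len(a2["fwd"]) + len(gap_b)
    w = z[:del_offset] + z[del_offset + len(deletion):]
    assert len(z) == a1["product_z"] and len(w) == a1["product_w"]
    for primer in (a1["fwd"], a1["rev"], a2["fwd"], a2["rev"]):
        for template in (z, w):
            assert template.count(primer) + template.count(revcomp(primer)) == 1
    return {"z": z, "w": w, "deletion_offset": del_offset}


def make_marker_fixture(pad: int = 60, rng_seed: int = 7) -> ReferenceGenome:
    """Two allele templates (Z intact, W deleted) with random flanks."""
    rng = np.random.default_rng(rng_seed + 1)
    cassette = marker_cassette(rng_seed)
    left = _random_seq(rng, pad)
    right = _random_seq(rng, pad)
    return ReferenceGenome(OrderedDict(
        allele_Z=left + cassette["z"] + right,
        allele_W=left + cassette["w"] + right,
    ))


# ---------------------------------------------------------------------------
# Cohort simulation


def _call_genotypes(rng, dosage, coverage):
    """Sample depths/reads and re-call genotypes from a dosage matrix.

    Returns (gt pair array int8 (n, m, 2), ad array int32 (n, m, 2)).
    """
    n, m = dosage.shape
    if math.isinf(coverage):
        depth = np.full((n, m), 20, dtype=np.int64)
        alt = (depth * dosage) // 2
    else:
        depth = rng.poisson(coverage, size=(n, m))
        alt = rng.binomial(depth, dosage / 2.0)
    ref = depth - alt
    gt = np.zeros((n, m, 2), dtype=np.int8)
    het = (alt > 0) & (ref > 0)
    hom_alt = (alt > 0) & (ref == 0)
    miss = depth == 0
    gt[het, 1] = 1
    gt[hom_alt, 0] = 1
    gt[hom_alt, 1] = 1
    gt[miss] = -1
    ad = np.stack([ref, alt], axis=2).astype(np.int32)
    return gt, ad


def simulate_cohort(config: SimulationConfig):
    """Generate (genome, annotation, variants, panel, truth) for one cohort.

    Identical config (including seed) yields byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    deletion = config.deletion_sequence.upper()
    del_len = len(deletion)

    # --- reference scaffolds
    scaffolds = OrderedDict()
    for i in range(1, config.n_other_scaffolds + 1):
        scaffolds[f"scaffold_{i}"] = _random_seq(
            rng, config.other_scaffold_length
        )
    sdr_seq = list(_random_seq(rng, config.sdr_scaffold_length))
    cassette = marker_cassette()
    del_start = config.deletion_anchor + 1          # first deleted base
    del_end = config.deletion_anchor + del_len      # last deleted base
    cas_start = del_start - cassette["deletion_offset"]  # 1-based
    cas_end = cas_start + len(cassette["z"]) - 1
    if not (config.sdr_start <= cas_start and
            cas_end + config.upstream_offset < config.sdr_end):
        raise ValueError("deletion cassette does not fit inside the SDR")
    sdr_seq[cas_start - 1: cas_end] = cassette["z"]
    scaffolds[config.sdr_scaffold] = "".join(sdr_seq)
    genome = ReferenceGenome(scaffolds)

    # --- gene annotation: target gene + background genes
    gene_start = del_end + config.upstream_offset + 1
    genes = [(config.sdr_scaffold, gene_start, gene_start + 1489, "+",
              "hsd17b1")]
    gid = 1
    for name, seq in scaffolds.items():
        for _ in range(2):
            length = int(rng.integers(500, 2000))
            start = int(rng.integers(1, len(seq) - length))
            if name == config.sdr_scaffold and not (
                start + length < cas_start - 100 or start > gene_start + 2000
            ):
                continue
            genes.append((name, start, start + length, "+-"[gid % 2],
                          f"gene_{gid:04d}"))
            gid += 1
    annotation = GeneAnnotation(pd.DataFrame(
        genes, columns=list(GeneAnnotation.COLUMNS)
    ))

    # --- cohort panel and true sex chromosomes
    rows, chrom_pairs = [], {}
    hetero = config.heterogametic_sex
    homo_pair = "ZZ" if config.sex_system == "ZW" else "XX"
    het_pair = "ZW" if config.sex_system == "ZW" else "XY"
    for pop, n_f, n_m in config.populations:
        for sex, n in (("F", n_f), ("M", n_m)):
            for k in range(n):
                sid = f"{pop}_{sex}{k + 1:02d}"
                rows.append((sid, sex, pop))
                chrom_pairs[sid] = het_pair if sex == hetero else homo_pair
    panel = CohortPanel(pd.DataFrame(
        rows, columns=["sample", "sex", "population"]
    ))
    samples = panel.samples
    n_samples = len(samples)
    carrier = np.array(
        [1.0 if chrom_pairs[s] == het_pair else 0.0 for s in samples]
    )

    # --- indel loci (fixed, kept clear of SNPs)
    decoys = []
    decoy_records = []  # (pos, ref, alt, dosage_vector)
    if config.plant_decoy_indels:
        # 40 nt W-linked deletion: exercises the strict >40 length filter
        pos40 = config.sdr_start + 5_000
        ref40 = genome.slice(config.sdr_scaffold, pos40, pos40 + 40)
        decoy_records.append((pos40, ref40, ref40[0], carrier.copy()))
        decoys.append((config.sdr_scaffold, pos40, 40, "w_linked"))
        # 50 nt deletion segregating in both sexes (MAF 0.3)
        pos50 = config.sdr_end - 15_000
        ref50 = genome.slice(config.sdr_scaffold, pos50, pos50 + 50)
        dos50 = rng.binomial(2, 0.3, size=n_samples).astype(float)
        decoy_records.append((pos50, ref50, ref50[0], dos50))
        decoys.append((config.sdr_scaffold, pos50, 50, "autosomal_like"))

    forbidden = [(cas_start - 1, cas_end + 1)]
    forbidden += [(p, p + ln + 1) for _, p, ln, _ in decoys]

    def _free(positions: np.ndarray, scaffold: str) -> np.ndarray:
        if scaffold != config.sdr_scaffold:
            return positions
        keep = np.ones(len(positions), bool)
        for lo, hi in forbidden:
            keep &= (positions < lo) | (positions > hi)
        return positions[keep]

    # --- per-scaffold site assembly
    all_sites = []   # (scaffold, pos, ref, alts, kind, dosage or allele freqs)
    w_positions = None
    for name, seq in scaffolds.items():
        length = len(seq)
        n_bg = int(round(config.snp_density * length))
        pos = np.sort(rng.choice(length - 2, size=n_bg, replace=False)) + 2
        pos = _free(pos, name)
        entries = [(int(p), "bg") for p in pos]
        if name == config.sdr_scaffold:
            in_sdr = np.arange(config.sdr_start, config.sdr_end + 1)
            in_sdr = _free(in_sdr, name)
            in_sdr = in_sdr[~np.isin(in_sdr, pos)]
            wpos = np.sort(rng.choice(in_sdr, size=config.w_snp_count,
                                      replace=False))
            w_positions = wpos
            entries += [(int(p), "w") for p in wpos]
            entries += [
                (int(p), ("indel", ref, alt, dos))
                for p, ref, alt, dos in decoy_records
            ]
            entries.append((
                int(config.deletion_anchor),
                ("indel",
                 seq[config.deletion_anchor - 1: del_end],
                 seq[config.deletion_anchor - 1],
                 carrier.copy()),
            ))
        entries.sort(key=lambda e: e[0])
        all_sites.append((name, entries))

    # multi-allelic SNPs replace a random subset of background sites
    flat = []
    for name, entries in all_sites:
        for p, kind in entries:
            flat.append((name, p, kind))
    bg_idx = [i for i, (_, _, k) in enumerate(flat) if k == "bg"]
    multi_idx = set(
        rng.choice(bg_idx, size=min(config.n_multiallelic, len(bg_idx)),
                   replace=False).tolist()
    )

    # --- genotype truth and observed calls
    sites_rows, gt_rows, ad_rows = [], [], []
    max_alleles = 3 if multi_idx else 2

    # biallelic sites are vectorised in blocks; multiallelic handled per site
    bi_meta, bi_dosage = [], []
    multi_meta = []
    for i, (name, p, kind) in enumerate(flat):
        seq = scaffolds[name]
        if kind == "bg":
            ref = seq[p - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            if i in multi_idx:
                alt2 = rng.choice([b for b in "ACGT" if b not in (ref, alt)])
                p1, p2 = rng.uniform(0.02, 0.2, size=2)
                multi_meta.append((name, p, ref,
                                   (str(alt), str(alt2)), (p1, p2)))
                continue
            maf = rng.uniform(*config.maf_range)
            dosage = rng.binomial(2, maf, size=n_samples).astype(float)
            bi_meta.append((name, p, ref, (str(alt),)))
            bi_dosage.append(dosage)
        elif kind == "w":
            ref = seq[p - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            bi_meta.append((name, p, ref, (str(alt),)))
            bi_dosage.append(carrier.copy())
        else:
            _, ref, alt, dos = kind
            bi_meta.append((name, p, ref, (alt,)))
            bi_dosage.append(dos.astype(float))

    dosage = np.array(bi_dosage)
    gt_bi, ad_bi = _call_genotypes(rng, dosage, config.coverage)

    # multiallelic observed calls
    def _multi_call(freqs, seed_rng):
        p1, p2 = freqs
        probs = [1 - p1 - p2, p1, p2]
        alleles = seed_rng.choice(3, size=(n_samples, 2), p=probs)
        gt = np.zeros((n_samples, 2), dtype=np.int8)
        ad = np.zeros((n_samples, 3), dtype=np.int32)
        if math.isinf(config.coverage):
            depths = np.full(n_samples, 20)
        else:
            depths = seed_rng.poisson(config.coverage, size=n_samples)
        for j in range(n_samples):
            d = depths[j]
            if d == 0:
                gt[j] = (-1, -1)
                continue
            reads = seed_rng.choice(alleles[j], size=d)
            for a in (0, 1, 2):
                ad[j, a] = int(np.sum(reads == a))
            seen = sorted(set(int(r) for r in reads))
            if len(seen) == 1:
                gt[j] = (seen[0], seen[0])
            else:
                gt[j] = (seen[0], seen[1])
        return gt, ad

    # merge in original (sorted) order
    records = []
    multi_lookup = {(name, p): (ref, alts, freqs)
                    for name, p, ref, alts, freqs in multi_meta}
    bi_lookup = {(m[0], m[1]): k for k, m in enumerate(bi_meta)}
    for name, p, kind in flat:
        key = (name, p)
        if key in multi_lookup:
            ref, alts, freqs = multi_lookup[key]
            gt_m, ad_m = _multi_call(freqs, rng)
            records.append(((name, p, ref, alts), gt_m, ad_m))
        else:
            k = bi_lookup[key]
            name_k, p_k, ref, alts = bi_meta[k]
            ad_pad = np.full((n_samples, max_alleles), -1, dtype=np.int32)
            ad_pad[:, :2] = ad_bi[k]
            records.append(((name, p, ref, alts), gt_bi[k], ad_pad))

    sites = pd.DataFrame(
        [r[0] for r in records], columns=["scaffold", "pos", "ref", "alts"]
    )
    gt = np.stack([r[1] for r in records])
    ad = np.stack([r[2] for r in records])
    if max_alleles == 2:
        ad = ad[:, :, :2]
    table = VariantTable(sites=sites, gt=gt, ad=ad, samples=samples)

    truth = TruthSet(
        sdr=(config.sdr_scaffold, config.sdr_start, config.sdr_end),
        w_snp_positions=w_positions,
        deletion=(config.sdr_scaffold, config.deletion_anchor, deletion),
        sample_chromosomes=chrom_pairs,
        n_multiallelic=len(multi_meta),
        decoy_indels=decoys,
    )
    return genome, annotation, table, panel, truth


def sample_haplotype_templates(genome: ReferenceGenome, truth: TruthSet,
                               flank: int = 400) -> dict:
    """Per-sample pair of true allele templates around the deletion locus.

    The intact template is the reference slice centred on the deletion; the
    deleted template excises the deletion bases.  Heterogametic samples get
    one of each; homogametic samples two intact copies.
    """
    scaffold, anchor, deletion = truth.deletion
    lo = max(1, anchor - flank)
    hi = min(len(genome[scaffold]), anchor + len(deletion) + flank)
    intact = genome.slice(scaffold, lo, hi)
    cut = anchor - lo + 1  # 0-based offset of first deleted base
    deleted = intact[:cut] + intact[cut + len(deletion):]
    out = {}
    for sample in truth.sample_chromosomes:
        if truth.is_heterogametic(sample):
            out[sample] = (intact, deleted)
        else:
            out[sample] = (intact, intact)
    return out


# ---------------------------------------------------------------------------
# Promoter fixture


def make_promoter_fixture(n_species: int = 7,
                          motif: str = resources.SHARED_MOTIF,
                          planted_fraction: float = 1.0,
                          length: int = 3000,
                          seed: int = 11):
    """Orthologous upstream sequences sharing a planted motif.

    The motif (or its reverse complement, chosen at random) is planted at
    similar offsets in the first ``round(planted_fraction * n_species)``
    sequences; background is i.i.d. uniform nucleotides.  Returns
    (OrderedDict of sequences, DataFrame of planted positions/strands).
    """
    if len(motif) >= length:
        raise ValueError("motif must be shorter than the sequences")
    rng = np.random.default_rng(seed)
    n_planted = int(round(planted_fraction * n_species))
    center = int(rng.integers(length // 3, 2 * length // 3))
    seqs, plants = OrderedDict(), []
    for i in range(n_species):
        name = f"species_{i + 1}"
        seq = list(_random_seq(rng, length))
        if i < n_planted:
            offset = int(np.clip(
                center + rng.integers(-150, 151), 0, length - len(motif)
            ))
            strand = "+" if rng.random() < 0.5 else "-"
            word = motif if strand == "+" else revcomp(motif)
            seq[offset: offset + len(motif)] = word
            plants.append((name, offset + 1, strand))
        seqs[name] = "".join(seq)
    planted = pd.DataFrame(plants, columns=["species", "pos", "strand"])
    return seqs, planted
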