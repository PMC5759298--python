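"""Standard-format I/O and the shared in-memory containers.

Single home for coordinate and strand conventions: every coordinate in this
package is 1-based and inclusive on the forward strand of the named
scaffold; half-open arithmetic is internal and never serialized.

Formats: FASTA (via Biopython), GFF3 gene features (read via gffutils),
VCF 4.2 with per-sample GT and AD fields (read via pysam; written as text
so identical inputs produce byte-identical files), and a tab-separated
phenotype file with header ``sample\tsex\tpopulation``.
"""

from __future__ import annotations

import io
import os
from collections import OrderedDict
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_NT = set("ACGTNRYSWKMBDHV")

__all__ = [
    "ParseError",
    "ReferenceGenome",
    "GeneAnnotation",
    "VariantTable",
    "CohortPanel",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "read_vcf",
    "write_vcf",
    "keep_biallelic",
    "read_phenotypes",
    "write_phenotypes",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtn", "TGCANYRSWMKVHDBtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """A file did not conform to the expected format."""


@dataclass
class ReferenceGenome:
    """Ordered scaffold-id -> uppercase nucleotide sequence."""

    scaffolds: "OrderedDict[str, str]"

    def __post_init__(self) -> None:
        clean: "OrderedDict[str, str]" = OrderedDict()
        for name, seq in self.scaffolds.items():
            if not seq:
                raise ParseError(f"scaffold {name!r}: empty sequence")
            seq = seq.upper()
            bad = set(seq) - IUPAC_NT
            if bad:
                raise ParseError(
                    f"scaffold {name!r}: non-IUPAC characters {sorted(bad)}"
                )
            if name in clean:
                raise ParseError(f"duplicate scaffold id {name!r}")
            clean[name] = seq
        self.scaffolds = clean

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __getitem__(self, name: str) -> str:
        return self.scaffolds[name]

    def __contains__(self, name: str) -> bool:
        return name in self.scaffolds

    def lengths(self) -> "OrderedDict[str, int]":
        return OrderedDict((k, len(v)) for k, v in self.scaffolds.items())

    def slice(self, scaffold: str, start: int, end: int) -> str:
        """Sequence of ``scaffold`` between 1-based inclusive coordinates."""
        if start < 1 or end > len(self.scaffolds[scaffold]) or start > end:
            raise ValueError(
                f"invalid interval {scaffold}:{start}-{end}"
            )
        return self.scaffolds[scaffold][start - 1 : end]


@dataclass
class GeneAnnotation:
    """Gene records: scaffold, start, end (1-based inclusive), strand, gene_id."""

    records: pd.DataFrame

    COLUMNS = ("scaffold", "start", "end", "strand", "gene_id")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=list(self.COLUMNS))
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ParseError(f"duplicate gene ids: {dups}")
        if ((df["start"] < 1) | (df["start"] > df["end"])).any():
            raise ParseError("gene with start < 1 or start > end")
        if not df["strand"].isin(["+", "-"]).all():
            raise ParseError("gene strand must be '+' or '-'")
        self.records = df.reset_index(drop=True)

    def get(self, gene_id: str) -> pd.Series:
        hit = self.records[self.records["gene_id"] == gene_id]
        if hit.empty:
            raise KeyError(gene_id)
        return hit.iloc[0]

    def genes_on(self, scaffold: str) -> pd.DataFrame:
        return self.records[self.records["scaffold"] == scaffold]


@dataclass
class VariantTable:
    """Per-site variant records with per-sample genotypes and allelic depths.

    ``sites``: DataFrame with columns scaffold, pos (1-based), ref,
    alts (tuple of alternate alleles).
    ``gt``: int8 array (n_sites, n_samples, 2) of allele indices, -1 missing.
    ``ad``: int32 array (n_sites, n_samples, max alleles per site); -1 marks
    unknown depth (AD absent) and padding beyond a site's allele count.
    """

    sites: pd.DataFrame
    gt: np.ndarray
    ad: np.ndarray
    samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = pd.DataFrame(
            self.sites, columns=["scaffold", "pos", "ref", "alts"]
        ).reset_index(drop=True)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.ad = np.asarray(self.ad, dtype=np.int32)
        n = len(self.sites)
        if self.gt.shape[:2] != (n, len(self.samples)):
            raise ValueError("gt shape does not match sites/samples")
        if self.ad.shape[:2] != (n, len(self.samples)):
            raise ValueError("ad shape does not match sites/samples")
        # positions sorted within scaffold
        for _, grp in self.sites.groupby("scaffold", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) < 0):
                raise ValueError("positions not sorted within scaffold")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def n_alts(self) -> np.ndarray:
        return self.sites["alts"].map(len).to_numpy()

    def is_biallelic(self) -> np.ndarray:
        return self.n_alts() == 1

    def is_indel(self) -> np.ndarray:
        ref_len = self.sites["ref"].str.len().to_numpy()
        alt_max = self.sites["alts"].map(
            lambda a: max(len(x) for x in a)
        ).to_numpy()
        return (ref_len != 1) | (alt_max != 1)

    def subset(self, index) -> "VariantTable":
        """New table restricted to the given site index/mask (order kept)."""
        idx = np.arange(self.n_sites)[index]
        return VariantTable(
            sites=self.sites.iloc[idx],
            gt=self.gt[idx],
            ad=self.ad[idx],
            samples=list(self.samples),
        )

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage (n_sites, n_samples), NaN where missing.

        Defined for biallelic sites; at multi-allelic sites the dosage of
        the first alternate allele is returned.
        """
        d = (self.gt == 1).sum(axis=2).astype(float)
        d[np.any(self.gt < 0, axis=2)] = np.nan
        return d


@dataclass
class CohortPanel:
    """Sample sex (F/M) and population labels, aligned to VCF columns."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table, columns=["sample", "sex", "population"])
        if not df["sex"].isin(["F", "M"]).all():
            raise ParseError("sex labels must be 'F' or 'M'")
        if df["sample"].duplicated().any():
            raise ParseError("duplicate sample ids in panel")
        for pop, grp in df.groupby("population"):
            if grp["sex"].nunique() < 2:
                raise ParseError(f"population {pop!r} lacks one sex")
        self.table = df.reset_index(drop=True)

    @property
    def samples(self) -> list:
        return self.table["sample"].tolist()

    @property
    def populations(self) -> list:
        return sorted(self.table["population"].unique())

    def sex_vector(self, samples=None) -> np.ndarray:
        """Phenotype coding for association: F=1, M=0."""
        order = samples if samples is not None else self.samples
        sex = self.table.set_index("sample")["sex"]
        return np.array([1.0 if sex[s] == "F" else 0.0 for s in order])

    def group(self, population: str, sex: str) -> list:
        df = self.table
        return df[(df["population"] == population) & (df["sex"] == sex)][
            "sample"
        ].tolist()

    def swap_sexes(self) -> "CohortPanel":
        df = self.table.copy()
        df["sex"] = df["sex"].map({"F": "M", "M": "F"})
        return CohortPanel(df)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> ReferenceGenome:
    records = OrderedDict()
    with open(path) as fh:
        head = fh.read(1)
        if head != ">":
            raise ParseError(f"{path}: line 1: expected FASTA header '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} is empty")
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} has non-IUPAC characters "
                f"{sorted(bad)}"
            )
        if rec.id in records:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return ReferenceGenome(records)


def write_fasta(genome: ReferenceGenome, path, width: int = 70):
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.scaffolds.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    return path


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path) -> GeneAnnotation:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append((feat.seqid, feat.start, feat.end, feat.strand, gene_id))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=list(GeneAnnotation.COLUMNS))
    )


def write_gff(annotation: GeneAnnotation, path):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in annotation.records.itertuples(index=False):
            fh.write(
                f"{rec.scaffold}\tzwseeker\tgene\t{rec.start}\t{rec.end}"
                f"\t.\t{rec.strand}\t.\tID={rec.gene_id}\n"
            )
    return path


# ---------------------------------------------------------------------------
# VCF 4.2 (GT + AD)


def read_vcf(path) -> VariantTable:
    """Read a VCF 4.x with GT (required) and AD (optional) sample fields.

    Multi-allelic records are retained (flagged by ``is_biallelic``); absent
    AD is recorded as -1 (unknown).
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if "GT" not in vf.header.formats:
        raise ParseError(f"{path}: VCF lacks the GT FORMAT field")
    rows, gts, ads = [], [], []
    max_alleles = 2
    for rec in vf:
        alts = tuple(rec.alts or ())
        if not alts:
            continue
        rows.append((rec.chrom, rec.pos, rec.ref, alts))
        max_alleles = max(max_alleles, 1 + len(alts))
        gt_row, ad_row = [], []
        for s in samples:
            call = rec.samples[s]
            gt = call.get("GT", (None, None))
            if gt is None or any(a is None for a in gt) or len(gt) != 2:
                gt_row.append((-1, -1))
            else:
                gt_row.append(tuple(sorted(gt)))
            ad = call.get("AD", None)
            if ad is None or all(a is None for a in ad):
                ad_row.append(())
            else:
                ad_row.append(tuple(-1 if a is None else a for a in ad))
        gts.append(gt_row)
        ads.append(ad_row)
    n, m = len(rows), len(samples)
    gt = np.array(gts, dtype=np.int8).reshape(n, m, 2) if n else np.zeros(
        (0, m, 2), np.int8
    )
    ad = np.full((n, m, max_alleles), -1, dtype=np.int32)
    for i, ad_row in enumerate(ads):
        for j, vals in enumerate(ad_row):
            for k, v in enumerate(vals[:max_alleles]):
                ad[i, j, k] = v
    sites = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alts"])
    return VariantTable(sites=sites, gt=gt, ad=ad, samples=samples)


def _format_call(gt_pair, ad_vals) -> str:
    if gt_pair[0] < 0:
        gt = "./."
    else:
        gt = f"{gt_pair[0]}/{gt_pair[1]}"
    if ad_vals is None:
        return f"{gt}:."
    return gt + ":" + ",".join(str(v) for v in ad_vals)


def write_vcf(table: VariantTable, panel: CohortPanel | None, path,
              contig_lengths=None):
    """Write VCF 4.2 text; deterministic byte-for-byte for equal inputs."""
    if panel is not None and panel.samples != table.samples:
        raise ValueError("panel samples do not match variant table columns")
    sites = table.sites
    if contig_lengths is None:
        contig_lengths = {
            sc: int(grp["pos"].max()) + 1000
            for sc, grp in sites.groupby("scaffold", sort=False)
        }
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=zwseeker\n")
    for name, length in contig_lengths.items():
        buf.write(f"##contig=<ID={name},length={length}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths (ref,alt)">\n'
    )
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples)
        + "\n"
    )
    n_alleles = 1 + table.n_alts()
    for i in range(table.n_sites):
        sc, pos, ref, alts = sites.iloc[i]
        na = n_alleles[i]
        fields = [
            sc, str(pos), ".", ref, ",".join(alts), ".", ".", ".", "GT:AD",
        ]
        for j in range(table.n_samples):
            ad = table.ad[i, j, :na]
            ad_vals = None if np.all(ad < 0) else [max(int(v), 0) for v in ad]
            fields.append(_format_call(table.gt[i, j], ad_vals))
        buf.write("\t".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
    return path


def keep_biallelic(table: VariantTable) -> VariantTable:
    """Retain only sites with exactly one alternate allele (order kept)."""
    return table.subset(table.is_biallelic())


# ---------------------------------------------------------------------------
# Phenotype panel TSV


def read_phenotypes(path) -> CohortPanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["sample", "sex", "population"]
    if list(df.columns) != expected:
        raise ParseError(
            f"{path}: phenotype header must be {expected}, got "
            f"{list(df.columns)}"
        )
    return CohortPanel(df)


def write_phenotypes(panel: CohortPanel, path):
    panel.table.to_csv(path, sep="\t", index=False)
    return path
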