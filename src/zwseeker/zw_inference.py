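"""Heterogamety classification from sex-stratified heterozygosity.

In a ZW system the female is heterogametic, so fully sex-linked SNPs are
heterozygous in females and absent in males; an XY system shows the mirror
pattern.  At ~2x coverage per-individual allelic ratios are nearly
meaningless (1-3 reads), so a SNP is scored heterozygous for a group
(population x sex) by pooling allelic depths across the group's individuals
and requiring the pooled alt-read fraction to fall inside a band around 0.5
(inclusive bounds) with a minimum pooled depth.  Comparing female/male
counts in the candidate SDR against size-matched random control regions
yields the ZW/XY/undetermined call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io_formats import CohortPanel, ReferenceGenome, VariantTable

__all__ = [
    "HetRatioReport",
    "group_het_sites",
    "het_ratio",
    "random_control_regions",
    "classify_system",
    "het_ratio_report",
]


@dataclass
class HetRatioReport:
    """Per (population x region) heterozygous-SNP counts and F/M ratios."""

    table: pd.DataFrame  # population, region, female, male, ratio
    call: str = "undetermined"


def group_het_sites(table: VariantTable, panel: CohortPanel, region: tuple,
                    population: str, sex: str, lo: float = 0.4,
                    hi: float = 0.6, min_depth: int = 10,
                    per_individual: bool = False) -> int:
    """Count SNPs in ``region`` heterozygous for one population x sex group.

    ``region`` is (scaffold, start, end), 1-based inclusive.  Pooled mode
    (default): allelic depths are summed across the group's individuals and
    a SNP counts when pooled depth >= ``min_depth`` and the pooled alt
    fraction lies in [lo, hi].  ``per_individual=True`` instead requires the
    allelic ratio of every covered individual to lie in the band -- the
    literal reading, exposed for comparison but fragile at low coverage.
    """
    scaffold, start, end = region
    members = panel.table[
        (panel.table["population"] == population)
        & (panel.table["sex"] == sex)
    ]["sample"].tolist()
    if not members:
        raise ValueError(f"empty group {population}/{sex}")
    cols = [table.samples.index(s) for s in members]
    snp = ~table.is_indel() & table.is_biallelic()
    in_region = (
        (table.sites["scaffold"] == scaffold)
        & (table.sites["pos"] >= start)
        & (table.sites["pos"] <= end)
    ).to_numpy()
    idx = np.flatnonzero(snp & in_region)
    if idx.size == 0:
        return 0
    ad = table.ad[np.ix_(idx, cols)]  # (sites, members, alleles)
    ad = np.where(ad < 0, 0, ad)
    if per_individual:
        depth_i = ad[:, :, 0] + ad[:, :, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_i = ad[:, :, 1] / depth_i
        covered = depth_i > 0
        ok = (frac_i >= lo) & (frac_i <= hi)
        counted = (covered.sum(axis=1) > 0) & np.all(
            ok | ~covered, axis=1
        ) & np.any(ok & covered, axis=1)
        return int(counted.sum())
    ref = ad[:, :, 0].sum(axis=1)
    alt = ad[:, :, 1].sum(axis=1)
    depth = ref + alt
    if not np.any(depth > 0):
        warnings.warn(
            f"zero pooled depth at every site in {scaffold}:{start}-{end} "
            f"for {population}/{sex}", stacklevel=2,
        )
        return 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = alt / depth
    counted = (depth >= min_depth) & (frac >= lo) & (frac <= hi)
    return int(counted.sum())


def het_ratio(female_count: int, male_count: int, decimals: int = 1):
    """female/male count ratio, rounded half away from zero.

    Returns None (undefined) when the male count is zero.
    """
    if male_count == 0:
        return None
    q = Decimal(1).scaleb(-decimals)
    ratio = (Decimal(female_count) / Decimal(male_count)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(ratio)


def random_control_regions(genome: ReferenceGenome, sdr_interval: tuple,
                           n: int = 5, seed: int = 0) -> list:
    """n SDR-sized intervals on distinct random non-SDR scaffolds."""
    rng = np.random.default_rng(seed)
    scaffold, start, end = sdr_interval
    size = end - start + 1
    eligible = [
        name for name, length in genome.lengths().items()
        if name != scaffold and length >= size
    ]
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} scaffolds can host a {size}-base control"
        )
    chosen = rng.choice(np.array(eligible, dtype=object), size=n,
                        replace=False)
    out = []
    for name in chosen:
        length = genome.lengths()[name]
        s = int(rng.integers(1, length - size + 2))
        out.append((str(name), s, s + size - 1))
    return out


def classify_system(report: pd.DataFrame, ratio_hi: float = 2.0,
                    ratio_lo: float = 0.5) -> str:
    """ZW / XY / undetermined call from an SDR-vs-control ratio table.

    ZW when every population's SDR ratio >= ``ratio_hi`` while all control
    ratios fall strictly inside (ratio_lo, ratio_hi); XY mirrors with SDR
    ratios <= ``ratio_lo``.  Any other pattern is undetermined.  Undefined
    ratios (male count 0 in a control region) are treated as undetermined.
    """
    df = pd.DataFrame(report)
    sdr = df[df["region"] == "SDR"]
    ctrl = df[df["region"] != "SDR"]
    if sdr.empty or ctrl.empty:
        raise ValueError("report needs SDR rows and at least one control row")
    if df["ratio"].isna().any():
        return "undetermined"
    controls_flat = (
        (ctrl["ratio"] > ratio_lo) & (ctrl["ratio"] < ratio_hi)
    ).all()
    if not controls_flat:
        return "undetermined"
    if (sdr["ratio"] >= ratio_hi).all():
        return "ZW"
    if (sdr["ratio"] <= ratio_lo).all():
        return "XY"
    return "undetermined"


def het_ratio_report(table: VariantTable, panel: CohortPanel,
                     genome: ReferenceGenome, sdr_interval: tuple,
                     n_controls: int = 5, seed: int = 0,
                     lo: float = 0.4, hi: float = 0.6,
                     min_depth: int = 10) -> HetRatioReport:
    """Table-2-style report: per-population SDR and control het counts."""
    controls = random_control_regions(genome, sdr_interval, n=n_controls,
                                      seed=seed)
    rows = []
    for pop in panel.populations:
        for tag, region in [("SDR", sdr_interval)] + [
            ("Random", c) for c in controls
        ]:
            f = group_het_sites(table, panel, region, pop, "F", lo=lo, hi=hi,
                                min_depth=min_depth)
            m = group_het_sites(table, panel, region, pop, "M", lo=lo, hi=hi,
                                min_depth=min_depth)
            rows.append(dict(
                population=pop, region=tag,
                scaffold=region[0], start=region[1], end=region[2],
                female=f, male=m, ratio=het_ratio(f, m),
            ))
    df = pd.DataFrame(rows)
    return HetRatioReport(table=df, call=classify_system(df))
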