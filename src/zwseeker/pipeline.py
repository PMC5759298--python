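"""End-to-end orchestration: simulate -> associate -> zw-test -> marker ->
footprint, with plain-file handoffs between stages and one seed.

Every stage persists its intermediate in a standard format (FASTA / GFF3 /
VCF / TSV) so any stage can later be re-run on real data, and the final
``report.json`` echoes the configuration and every threshold used.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import pandas as pd

from . import association, marker, motif, resources, synthetic_data, zw_inference
from .io_formats import (
    keep_biallelic,
    write_fasta,
    write_gff,
    write_phenotypes,
    write_vcf,
)

__all__ = ["AnalysisConfig", "load_config", "run_all"]


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-stage thresholds (defaults follow the published protocol)."""

    thin_interval: int = 5000
    n_perm: int = 1000
    perm_alpha: float = 0.05
    p_cut_stage1: float = 1e-3
    p_cut_bounds: float = 1e-7
    knn_k: int = 5
    het_band: tuple = (0.4, 0.6)
    het_min_depth: int = 10
    n_controls: int = 5
    indel_min_len: int = 41
    upstream_span: int = 3000
    motif_width: int = 15
    motif_max_mismatch: int = 2
    n_promoter_species: int = 7


def load_config(path) -> tuple:
    """Read a TOML config with [simulation] and [analysis] tables."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim_kw = dict(raw.get("simulation", {}))
    if "populations" in sim_kw:
        sim_kw["populations"] = tuple(
            tuple(p) for p in sim_kw["populations"]
        )
    ana_kw = dict(raw.get("analysis", {}))
    if "het_band" in ana_kw:
        ana_kw["het_band"] = tuple(ana_kw["het_band"])
    return (synthetic_data.SimulationConfig(**sim_kw),
            AnalysisConfig(**ana_kw))


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # halt with the failing stage's name
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("simulate")
def _simulate(sim_cfg, out):
    genome, annotation, table, panel, truth = synthetic_data.simulate_cohort(
        sim_cfg
    )
    write_fasta(genome, out / "genome.fasta")
    write_gff(annotation, out / "genes.gff3")
    write_vcf(table, panel, out / "cohort.vcf",
              contig_lengths=genome.lengths())
    write_phenotypes(panel, out / "phenotypes.tsv")
    return genome, annotation, table, panel, truth


@_stage("associate")
def _associate(table, panel, sim_cfg, ana, out):
    scan = association.two_stage_scan(
        table, panel,
        thin_interval=ana.thin_interval, n_perm=ana.n_perm,
        alpha=ana.perm_alpha, p_cut_stage1=ana.p_cut_stage1,
        p_cut_bounds=ana.p_cut_bounds, seed=sim_cfg.seed, knn_k=ana.knn_k,
    )
    scan["stage1"].table.to_csv(out / "assoc_thinned.tsv", sep="\t",
                                index=False)
    for scaffold, res in scan["full"].items():
        res.table.to_csv(out / f"assoc_{scaffold}.tsv", sep="\t",
                         index=False)
    return scan


@_stage("zw-test")
def _zw_test(table, panel, genome, sdr_interval, sim_cfg, ana, out):
    report = zw_inference.het_ratio_report(
        table, panel, genome, sdr_interval,
        n_controls=ana.n_controls, seed=sim_cfg.seed,
        lo=ana.het_band[0], hi=ana.het_band[1],
        min_depth=ana.het_min_depth,
    )
    report.table.to_csv(out / "het_ratios.tsv", sep="\t", index=False)
    return report


@_stage("marker")
def _marker(table, panel, genome, truth, sdr_interval, ana, out):
    candidates = marker.scan_indels(table, panel, sdr_interval,
                                    min_len=ana.indel_min_len)
    pd.DataFrame([dataclasses.asdict(c) for c in candidates]).to_csv(
        out / "indel_candidates.tsv", sep="\t", index=False
    )
    templates = synthetic_data.sample_haplotype_templates(genome, truth)
    assay = resources.PRIMER_ASSAYS["SdorDel01"]
    calls = marker.genotype_cohort(
        templates, assay["fwd"], assay["rev"],
        assay["product_z"], assay["product_w"],
    )
    rows = [
        dict(sample=s, call=c, true_sex=truth.true_sex(s))
        for s, c in calls.items()
    ]
    df = pd.DataFrame(rows)
    df.to_csv(out / "sex_calls.tsv", sep="\t", index=False)
    accuracy = float((df["call"] == df["true_sex"]).mean())
    return candidates, df, accuracy


@_stage("footprint")
def _footprint(genome, annotation, truth, candidates, ana, out, seed):
    upstream = motif.extract_upstream(genome, annotation, truth.target_gene,
                                      span=ana.upstream_span)
    others, _ = synthetic_data.make_promoter_fixture(
        n_species=ana.n_promoter_species - 1,
        motif=resources.SHARED_MOTIF, planted_fraction=1.0,
        length=ana.upstream_span, seed=seed + 101,
    )
    seqs = {"target_species": upstream, **others}
    hits = motif.find_shared_motifs(
        seqs, width=ana.motif_width,
        max_mismatch=ana.motif_max_mismatch, min_seqs=len(seqs),
    )
    rows = []
    deletion_seq = candidates[0].sequence if candidates else None
    for h in hits[:10]:
        row = dict(motif=h.motif, n_sequences=h.n_sequences,
                   total_matches=h.total_matches)
        if deletion_seq:
            occ = h.occurrences
            strand = occ.loc[occ["sequence"] == "target_species", "strand"]
            strand = strand.iloc[0] if len(strand) else "+"
            row["strand_in_target"] = strand
            row["deletion_overlap"] = motif.deletion_overlap(
                h.motif, strand, deletion_seq
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "motifs.tsv", sep="\t", index=False)
    return df


def run_all(config_path=None, out_dir="zwseeker_run", seed=None) -> dict:
    """Run the full pipeline; returns (and writes) the structured report.

    ``config_path`` is a TOML file with optional [simulation] and
    [analysis] tables; omitted keys use the published defaults.  ``seed``
    overrides the simulation seed.  Outputs land in ``out_dir``; the same
    configuration and seed reproduce every file byte for byte.
    """
    if config_path is not None:
        sim_cfg, ana = load_config(config_path)
    else:
        sim_cfg, ana = synthetic_data.SimulationConfig(), AnalysisConfig()
    if seed is not None:
        sim_cfg = dataclasses.replace(sim_cfg, seed=int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome, annotation, table, panel, truth = _simulate(sim_cfg, out)
    bi = keep_biallelic(table)
    scan = _associate(bi, panel, sim_cfg, ana, out)
    if scan["sdr_interval"] is None:
        raise StageError("associate", "no significant SDR interval found")
    sdr_interval = (scan["sdr_scaffold"], *scan["sdr_interval"])

    het_report = _zw_test(table, panel, genome, sdr_interval, sim_cfg, ana,
                          out)
    candidates, sex_calls, accuracy = _marker(
        table, panel, genome, truth, sdr_interval, ana, out
    )
    motif_df = _footprint(genome, annotation, truth, candidates, ana, out,
                          sim_cfg.seed)

    report = {
        "config": {
            "simulation": dataclasses.asdict(sim_cfg),
            "analysis": dataclasses.asdict(ana),
        },
        "thresholds": {
            "thin_interval_bp": ana.thin_interval,
            "n_permutations": ana.n_perm,
            "het_band": list(ana.het_band),
            "indel_min_len_nt": ana.indel_min_len,
            "upstream_span_bp": ana.upstream_span,
        },
        "sdr": {
            "scaffold": sdr_interval[0],
            "start": sdr_interval[1],
            "end": sdr_interval[2],
            "permutation_threshold": scan["stage1"].threshold,
            "true_sdr": list(truth.sdr),
        },
        "heterogamety": {
            "call": het_report.call,
            "table": het_report.table.to_dict(orient="records"),
        },
        "marker": {
            "n_candidates": len(candidates),
            "candidates": [dataclasses.asdict(c) for c in candidates],
            "sex_call_accuracy": accuracy,
        },
        "motifs": motif_df.to_dict(orient="records"),
        "seed": sim_cfg.seed,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
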