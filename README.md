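# zwseeker

Discovery of sex-determining regions (SDRs) and W-linked sex markers from
low-coverage resequencing of sexed fish cohorts.

Many teleosts carry genetically young, non-heteromorphic sex chromosomes, so
sex-linked loci must be found statistically. Given a reference assembly and
~2× whole-genome resequencing of phenotypically sexed animals (here, the
California Yellowtail design: three sampling locations × 15 females + 15
males), `zwseeker`:

1. **curates** the assembly (length, k-mer containment, and gene-content
   rules);
2. **localizes the SDR** by a GWAS of sex: KNN genotype imputation, one SNP
   per 5-kb window, per-site GLM (OLS F-test of sex on allele dosage, the
   TASSEL GLM model), an experiment-wise threshold from 1000 label
   permutations, and SDR bounds from sites with p ≤ 10⁻⁷;
3. **classifies heterogamety**: a SNP is heterozygous for a population ×
   sex group when the group-pooled allelic-depth ratio falls in [0.4, 0.6];
   a female/male excess of such SNPs in the SDR — absent from size-matched
   random control regions — indicates ZW, the mirror image XY;
4. **discovers the marker**: scans the SDR for indels > 40 nt whose read
   support is heterozygous-consistent in females and absent in males, and
   validates a PCR assay by in-silico PCR (primer-site matching on both
   strands) with melting temperatures from nearest-neighbor thermodynamics
   (classic Primer3 parameters);
5. **footprints the deletion**: extracts 3000 bp upstream of the candidate
   gene across orthologous promoters, finds shared ungapped motifs by
   consensus-word enumeration with mismatches, scores them against
   JASPAR-format position-weight matrices on the relative scale
   (S − S_min)/(S_max − S_min), and measures motif/deletion overlap.

A seeded synthetic-data module (`zwseeker.synthetic_data`) generates the
entire study design — reference with the published 61-nt W-specific deletion
and its diagnostic primer cassette, GFF3 gene models, a 90-sample VCF with
Poisson read depths and genotypes re-called from sampled reads — so every
stage is testable without sequence archives, with ground truth recorded for
parameter-recovery checks.

## Worked example

```bash
zwseeker run --seed 5 --out run5/
```

runs simulate → associate → zw-test → marker → footprint with one seed and
prints:

```
{"sdr": "scaffold_22", "interval": [231063, 319788], "heterogamety": "ZW",
 "marker_candidates": 1, "sex_call_accuracy": 1.0}
```

Reading the output: the association scan bounded the SDR at
scaffold_22:231,063–319,788, overlapping the simulated truth
(231,000–320,000). The heterozygosity table (`run5/het_ratios.tsv`) shows
female/male ratios of ~4 in the SDR for every population against ~1.0 in
all control regions — the ZW signature. Exactly one indel survived the
marker scan: the 61-nt deletion, heterozygous in females and unsupported by
any male read. In-silico PCR of the published assays on each sample's true
haplotypes gives the two-band female / one-band male gel pattern (452/391 bp
and 282/221 bp products) and recovers the true sex of all 90 samples. The
footprint stage reports a 15-mer shared by all seven promoter sequences that
overlaps the deletion.

The same stages are available individually (`zwseeker simulate | curate |
assoc | zwtest | marker | epcr | footprint`) and as library functions.

## Layout

- `src/zwseeker/io_formats.py` — FASTA/GFF3/VCF/phenotype I/O, shared
  containers, coordinate conventions (1-based, inclusive)
- `src/zwseeker/synthetic_data.py` — cohort simulator, marker fixture,
  promoter fixture
- `src/zwseeker/scaffold_filter.py` — assembly curation rules
- `src/zwseeker/association.py` — imputation, thinning, GLM, permutations,
  kinship, SDR bounds
- `src/zwseeker/zw_inference.py` — heterozygosity ratios and the ZW/XY call
- `src/zwseeker/marker.py` — indel scan, Tm, in-silico PCR, sex genotyping,
  primer design
- `src/zwseeker/motif.py` — upstream extraction, shared-motif discovery,
  PWM scoring, deletion overlap
- `src/zwseeker/pipeline.py`, `src/zwseeker/cli.py` — orchestration and the
  `zwseeker` command

See `docs/methods.md` for the model, parameter defaults, and limitations.
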