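# Methods

## The inference problem

In a female-heterogametic (ZW) species, a fully sex-linked region carries
variants present on the W haplotype only: heterozygous in every female,
absent from every male. At ~2× coverage per sample, individual genotypes
are unreliable (a site is covered by 0–4 reads), so every statistic in this
package is designed around cohort-level signal: regression of sex on allele
dosage across 90 samples, pooled allelic depths within sex groups, and read
support aggregated over all females or all males. The package both
implements the analysis and simulates data with exactly the structure the
analysis assumes, so each stage can be validated by parameter recovery.

## Synthetic cohorts

`SimulationConfig` defaults encode the study design the package targets:

| parameter | default | meaning |
|---|---|---|
| populations | (CI, SD, LP) × (15 F, 15 M) | three locations, 90 samples |
| coverage | 2.0× | mean per-sample read depth (Poisson) |
| snp_density | 0.0115 / base | genome-wide biallelic SNP rate (≈7.5 M over a 653 Mb genome) |
| maf_range | U(0.05, 0.5) | background alt-allele frequency |
| SDR | scaffold_22:231,000–320,000 | fully sex-linked segment (89 kb on a 400 kb scaffold) |
| w_snp_count | 900 | W-linked SNPs in the SDR (≈1% Z–W divergence; yields SDR het ratios ≈ 4, matching the 3.9–6.2 observed range) |
| deletion | 61-nt allele at anchor 246,495 | W-specific; 954 bp upstream of the target gene |
| other scaffolds | 11 × 150 kb | host the size-matched control regions |
| n_multiallelic | 120 | tri-allelic SNPs, removed by the biallelic filter |

Background SNPs segregate under Hardy–Weinberg independently of sex; each
W-linked variant has true dosage 1 in the heterogametic sex and 0 otherwise.
Observed data are produced by sampling per-sample-site depth D ~
Poisson(coverage), alt reads ~ Binomial(D, dosage/2), and re-calling the
genotype from the sampled reads: heterozygous when both alleles are seen,
homozygous for the single seen allele otherwise, missing at D = 0 (~13.5%
of calls at 2×). `coverage = inf` gives deterministic depth 20 with exact
allele splits — the noise-free limit used to verify that truth decodes from
the VCF. An `sex_system="XY"` toggle makes males the heterogametic sex (the
classifier's negative control).

The reference carries, at the deletion locus, a deterministic 452-bp
cassette containing both published primer pairs nested around the 61-mer,
with spacer lengths fixed so the assays' products are 452/391 bp and
282/221 bp without/with the deletion; the spacer after the deletion begins
with `GAC` so the conserved 15-mer's reverse complement crosses the
deletion's 3′ edge, as at the real locus. Two decoy indels are planted by
default: a 40-nt W-linked deletion (exercises the strict >40 length filter)
and a 50-nt deletion segregating in both sexes at frequency 0.3 (exercises
the sex-pattern filter).

What the generator does **not** emulate: linkage between background sites
(sites are independent; no coalescent history), population structure or
migration between the three locations, mapping/reference bias, indel
realignment artifacts, base-calling error, and a realistic site-frequency
spectrum (the MAF distribution is uniform). Passing tests therefore show
the statistics behave correctly under the stated noise model, not that they
are robust to alignment pathologies of real low-coverage data.

## Association scan

Dosage = alt-allele count per genotype. Missing dosages are imputed from
the five nearest samples (mean squared dosage difference over mutually
observed sites; the missing entry becomes the neighbors' mean dosage at
that site, rounded to {0,1,2} — integer dosages keep the exact-Fisher
cross-check applicable). The per-site test is OLS of sex (F = 1, M = 0) on
dosage with p from the F statistic on (1, n−2) df — the GLM that TASSEL
applies to a binary trait. Centered-IBS kinship (VanRaden scaling) is
computed and reported but not entered in the model, matching that tool's
GLM semantics. The genome-wide pass uses one random SNP per 5-kb window
(seeded); scaffolds with ≥3 co-linear significant sites (p ≤ 10⁻³ within
100 kb) are re-scanned at full density, and the SDR interval is the
min/max position of sites with p ≤ 10⁻⁷ (a p equal to the cutoff counts).

The experiment-wise threshold is the k-th smallest per-permutation minimum
p over n_perm sex-label permutations, k = ⌊α(n_perm+1)⌋, so a fresh null
minimum falls below it with probability k/(n_perm+1) ≈ α; calibration is
verified by simulation (measured 0.0475 at α = 0.05 over 800 null
replicates). Perfect separation drives the F statistic to infinity; the
p-value is floored at the smallest positive double rather than reported as
zero. Because dosages are integers the null p-value distribution is
slightly sub-uniform near 1 (test-statistic discreteness); the suite
asserts validity (no excess of small p-values) and a bounded KS distance
rather than exact uniformity.

## Heterogamety classification

Per-individual allelic ratios are nearly meaningless at 1–3 reads, so
heterozygosity is scored on the **pooled** allelic depths of each
population × sex group: a SNP counts as heterozygous when the pooled alt
fraction lies in [0.4, 0.6] (inclusive) with pooled depth ≥ 10. For a
15-female group at 2× the pooled depth at a site is ~Poisson(30), giving a
detection probability of 0.736 for a true W-linked site — enough that SDR
female/male count ratios land near 4 against control ratios near 1. The
per-individual reading (every covered individual's ratio in the band) is
exposed behind `per_individual=True` but is not the default. The ZW call
requires every population's SDR ratio ≥ 2.0 while all control-region ratios
stay strictly inside (0.5, 2.0); XY is the mirror condition. The 2.0/0.5
thresholds are conservative relative to the observed separation (SDR ratios
3.9–6.2 vs controls 0.8–1.3) and symmetric so that swapping sex labels
exactly exchanges ZW and XY. Ratios are reported rounded half away from
zero to one decimal.

## Marker discovery and the assay

`scan_indels` keeps biallelic indels inside the SDR with |len(ref) −
len(alt)| ≥ 41 ("greater than 40" read strictly) whose **pooled** female
alt-read fraction lies in [0.30, 0.70] (heterozygous-consistent; ±3.8σ
around 0.5 at the expected pooled depth of ~90) while the pooled male alt
fraction is ≤ 0.05. Pooling is the deliberate design choice here: at 2× a
per-individual genotype requirement such as "0/1 in ≥90% of females" is
unattainable even for a perfectly W-linked event, because a female has any
read at all with probability only 1 − e⁻² ≈ 0.865. Per-sample call
fractions are still computed and attached to each candidate for inspection.

Melting temperatures use the classic Primer3 parameter set — Breslauer 1986
nearest-neighbor ΔH/ΔS with a −10.8 eu initiation entropy, total strand
concentration C_T/4 at 50 nM, and the Schildkraut–Lifson 16.6·log₁₀[Na⁺]
correction at 50 mM — which reproduces the published assay Tm values to
0.1 °C; SantaLucia 1998 unified parameters (entropic salt correction) are
available via `method="santalucia"` and run ~6 °C lower for these primers.
In-silico PCR matches primer sites exactly by default (mismatches can be
enabled, but never within the 3′-terminal 3 bases); an amplicon is emitted
for every properly oriented pair within the product-size cap, its length
including both primer footprints. A diploid sample's band pattern maps to
sex as on a gel: both products → F, the undeleted product alone → M,
anything else → anomalous. `design_primers` is a deliberately simple
stand-in for a full design engine: exhaustive 18–22-mer enumeration scored
by |Tm − 60| plus a 3′ G/C-clamp penalty, with homopolymer runs ≥ 5
disqualifying.

## Footprinting

Upstream extraction returns ≤ span bases 5′→3′ on the gene's own strand
(reverse complemented for minus-strand genes), truncated at scaffold edges.
Shared-motif discovery replaces expectation-maximization with seeded
consensus-word enumeration: every width-mer of the first sequence is a
candidate; a sequence supports it if a match within max_mismatch exists on
either strand; candidates are ranked by (supporting sequences, total
matching windows, fewest mismatches, leftmost) and overlapping words merge
into the best-ranked representative. This recovers a planted 15-mer
exactly on fixtures but has none of MEME's sensitivity to degenerate
motifs. PWM scores use log₂ odds with the JASPAR pseudocount convention
(0.8 split by background, uniform by default), rescaled to
(S − S_min)/(S_max − S_min) ∈ [0, 1]; matrices are read from JASPAR-format
PFM text. Only toy matrices ship with the package — published relative
scores against curated transcription-factor matrices are version-dependent
and are not asserted. Motif/deletion overlap is the longest contiguous
match between the strand-oriented motif and the deletion allele, so
boundary-crossing overlap (the real case: 12 of 15 bases inside the
deletion) is measured correctly.

## Problem sizes

The simulated genome is 2.05 Mb (one 400-kb SDR scaffold + 11 × 150 kb),
~24,500 variant records × 90 samples — large enough that the SDR scan,
het-ratio table, and marker scan operate in their intended statistical
regime, small enough that a full pipeline run takes well under a minute and
the 20-replicate parameter-recovery suite a few minutes. On these
replicates the minimum-p site fell inside the true SDR and the inferred
bounds overlapped truth in 20/20, with mean SDR het ratios > 3 and all
control ratios within [0.7, 1.4] in 20/20.

## Known limitations

- The GLM is a linear-model F-test on a binary trait (as in the tool it
  mirrors), not logistic regression; at perfect separation its p-value is a
  numerical floor, not an exact tail probability.
- Containment filtering uses canonical k-mer membership (k = 21) as an
  alignment-free proxy; diverged duplicates below ~95% identity will score
  low containment even when an aligner would call them redundant.
- The motif stage's word enumeration cannot discover motifs absent from the
  first (reference) sequence and treats width as fixed.
- No attempt is made to model recombination suppression gradients,
  sex-chromosome dosage from coverage, or partial sex linkage; the SDR is
  simulated as fully sex-linked.
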