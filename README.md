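# tbisig

Gene-set enrichment analysis of genomic signatures for neurobehavioural
outcomes after pediatric traumatic brain injury (TBI).

## The problem

Recovery after moderate-to-severe pediatric TBI is highly variable, and
single-variant association studies are hopelessly underpowered at realistic
cohort sizes (~200 children). `tbisig` implements an aggregate alternative:
instead of asking whether any one SNP reaches genome-wide significance, it
asks whether a *systems-biology-ranked set of candidate genes* carries more
nominal association signal than matched sets of background genes.

The analysis has four parts:

1. **Per-variant standardized linear models.**  For each biallelic variant
   (additive 0/1/2 minor-allele coding, standardized), two OLS models are
   fitted on standardized data:

   * *interaction model* (all participants):
     `y ~ age + sex + age:sex + PC1 + group + g + g:group`,
     where `group` is a 3-level injury factor (orthopedic-injury (OI)
     reference, moderate TBI, severe TBI).  A joint 2-df F-test on the two
     `g:group` terms asks whether the variant's association with the
     outcome *differs by injury group*;
   * *TBI-only model* (moderate + severe subset):
     `y ~ age + sex + age:sex + PC1 + severity + g`, reporting the
     variant's standardized main effect β.

2. **Variant QC** reproducing the standard chip + imputation recipe:
   participant call rate ≥ 90 %, SNP call rate ≥ 95 %, MAF ≥ 10 %,
   Hardy–Weinberg exact-test p ≥ 10⁻⁴, imputation Rsq ≥ 0.95, and exclusion
   of intergenic variants > 5,000 bp from the nearest gene.

3. **Centile-epoch permutation enrichment.**  Candidate genes are ranked by
   functional similarity to a literature-derived training set; nested
   "centile epochs" (training only, training + top 5 %, + top 10 %, …,
   + 100 %) are tested for enrichment: the number of variants with nominal
   p < 0.05 in the case set is compared against the same count over
   control-gene variant sets drawn to match the case set's minor-allele-
   frequency profile *exactly* within the bands [10, 15), [15, 20),
   [20, 30), [30, 50] %.  A case set is *enriched* when its hit count
   strictly exceeds the 95th percentile of the permutation null
   (empirical p = (r + 1)/(B + 1), default B = 10,000 draws).

4. **Effect-size reporting.**  Standardized coefficient magnitudes are
   binned at the conventional landmarks (<0.2, 0.2, 0.3, 0.4, ≥0.5), the
   genes behind the top-5th-centile effect sizes are extracted per outcome
   and model, and their cross-model overlap (Venn regions) is exported for
   external pathway-enrichment tools.

A seeded synthetic-data generator (`tbisig.simdata`) produces genotypes in
Hardy–Weinberg proportions, a 61:49:86 OI/moderate/severe cohort, age/sex/
PC1 covariate structure, and correlated continuous outcomes with variant
and variant×group effects planted in designated case genes — so the whole
pipeline runs and is validated without any external data.

## Worked example

```python
from tbisig import (SimConfig, simulate_study, run_qc, ModelSpec,
                    VariantScan, EnrichmentScan, GeneSetRanking)

bundle = simulate_study(SimConfig(
    n_participants=200, n_case_genes=50, n_control_genes=250,
    variants_per_gene=4, signal_fraction=0.5, signal_rank_band=(0, 10),
    beta_main=0.2, beta_interaction=0.6, missing_rate=0.02, seed=11))

qc = run_qc(bundle.genotypes, annotation=bundle.annotation)
assignment = qc.gene_assignment["assigned_gene"].reindex(qc.genotypes.variant_ids)
res = VariantScan(bundle.phenotypes, qc.genotypes,
                  ModelSpec(outcome="cbcl", subset="tbi", include_interaction=False),
                  gene_assignment=assignment).fit()

g2v = {}
for vid, gene in assignment.dropna().items():
    g2v.setdefault(gene, []).append(vid)
ranking = GeneSetRanking(bundle.ranking.training_genes, bundle.ranking.ranked_genes,
                         bundle.ranking.control_genes, g2v)
enr = EnrichmentScan(res, ranking, qc.genotypes.variants["maf"]).fit(
    step_percent=10, n_draws=300, seed=5)
print(enr.summary())
```

prints

```
Epoch enrichment scan (alpha=0.05, B=300)
  cbcl/tbi [cumulative]: enriched epochs [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
  cbcl/tbi [incremental]: enriched epochs [10]
```

i.e. the planted signal (10 causal variants in the top-10 % ranked genes,
TBI-group slope 0.8 on the unit-noise scale) is detected at every
cumulative epoch from 10 % on — once the signal genes enter the set, the
case hit count stays above the matched-null 95th percentile — while the
within-slice (incremental) readout localizes it to the 10 % slice alone.

The same analysis runs from the command line on PLINK/VCF + TSV inputs or
a simulation block:

```bash
tbisig simulate --seed 3 --outdir fixtures/          # write a fixture set
tbisig run-all --config config.yaml --seed 5         # QC → scans → enrichment → reports
```

The output tree contains `qc_report.tsv`, per-outcome association and
enrichment tables, effect-size bin tables, the top-centile gene lists and
their overlap, and a manifest; rerunning with the same config and seed
reproduces every file byte for byte.

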