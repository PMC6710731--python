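# methylpath

Overlap-weighted pathway enrichment and FPCA hub-gene ranking for
case/control DNA methylation studies.

## The problem

Array-based methylation studies (e.g. Illumina 450K beta values, the
fraction of methylated signal per CpG in [0, 1]) are commonly summarised
at pathway level, but naive over-representation tests double-count genes
that belong to several pathways. `methylpath` implements a pathway
screen that corrects for this overlap and then ranks genes *within*
enriched pathways by how much structure their methylation profile
carries, nominating hub genes for follow-up (e.g. RT-qPCR validation).
It is aimed at epigenomics analysts who have a beta matrix with
case/control labels, a probe manifest and a GMT pathway collection.

## The method

1. **Probe QC** — remove probes with an annotated SNP within 2 bp,
   probes failing the minor-allele-frequency rule, cross-reactive
   probes, and probes on chrX/chrY.
2. **CpG screen** — two-sided Welch t-test per CpG; tier 1 keeps
   p < 0.01, tier 2 additionally requires the delta-beta
   |S| = |mean(case) − mean(control)| ≥ 0.1. Gene methylation is the
   arithmetic mean over the gene's CpGs.
3. **Overlap-weighted enrichment** — every gene in the collection gets
   weight w = 1/n, with n the number of pathways containing it. Each
   pathway is scored by a one-sided Fisher/hypergeometric test of the
   tier-1 gene list against the collection universe and by a one-sided
   Mann–Whitney U test of the weights of its differentially methylated
   members against all background genes; the combined value is

       p_combined = (p_MWU × p_Fisher) / 2

   and pathways with p_combined < 0.05 and more than one
   differentially methylated member are reported as enriched. Note the
   product rule is a published selection heuristic, not a calibrated
   p-value (see `docs/methods.md`).
4. **Hub genes** — gene profiles are ordered on a deterministic
   pseudo-time axis (controls then cases, each sorted by mean
   methylation), smoothed with cubic B-splines, centred and decomposed
   by functional PCA, X_i(t) = μ_i + Σ_l ξ_il Φ_l(t). Each gene is
   scored with the functional F-statistic

       F_i = (RSS⁰_i − RSS¹_i) / (RSS¹_i + δ)

   (null = the gene's constant mean, alternative = the truncated FPCA
   reconstruction) and the top-3 members per enriched pathway are the
   hub genes.

A seeded synthetic-study generator (manifest + betas + GMT with a
planted differentially methylated pathway) provides ground truth for
every stage.

## Worked example

```python
import methylpath as mp

model, study = mp.MethylationPathwayModel.from_simulation(mp.SimulationConfig(seed=1))
results = model.fit()
print(results.summary())
```

prints

```
Methylation pathway analysis
============================================================
samples            20 case / 20 control
probes             840 total, 726 retained (maf rule: lt)
filter removals    snp_distance=42, snp_maf=4, crossreactive=39, sex_chromosome=39
tier-1 DM CpGs     65 (p < 0.01) covering 34 genes; 61 up / 4 down
tier-2 DM CpGs     51 (|S| >= 0.1) covering 20 genes
pathways           10 tested, 1 enriched (p_combined < 0.05, count > 1)

Enriched pathways (ascending combined p):
pathway_id       name  count  total  p_fisher  p_mwu  p_combined
      PW01 pathway_01     20     29 6.164e-16 0.8685   2.677e-16

Hub genes (top 3 by functional F per enriched pathway, pseudo-time rule: group_mean):
pathway_id  rank  gene  f_value
      PW01     1 G0004     48.5
      PW01     2 G0092    45.15
      PW01     3 G0194    40.33
```

Reading the output: 726 of 840 probes survive QC; 65 CpGs over 34 genes
pass the p < 0.01 screen (the planted pathway is PW01, and its
differentially methylated members drive the tiny combined p); all three
hub genes (`G0004`, `G0092`, `G0194`) are genes the simulation actually
planted. `results.save(outdir)` writes every stage table
(`dm_cpgs.tsv`, `gene_methylation.tsv`, `enrichment.tsv`,
`fvalues.tsv`, `hub_genes.tsv`, …) plus `summary.txt` and a
machine-readable `run_manifest.json`.

The same pipeline is available from the shell, either end-to-end or as
chainable stages working on TSV/GMT files:

```bash
methylpath simulate --outdir study --seed 1
methylpath run --outdir results \
  --betas study/betas.tsv --groups study/groups.tsv \
  --manifest study/manifest.tsv --gmt study/pathways.gmt
methylpath ddct 24 20 25 20     # 2^-ddCt fold change -> 2
```

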