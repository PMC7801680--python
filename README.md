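# fgcn

Frequent gene co-expression network (FGCN) analysis for multi-cohort bulk
transcriptomes: separates expression changes driven by **cell-type
composition** from changes driven by **transcriptional regulation**.

The pipeline:

1. **preprocess** — per-cohort gene filtering (zero-fraction for counts,
   bottom-percentile variance and mean) and cross-cohort gene intersection.
2. **corr_network** — per-cohort, per-condition all-pairs correlation
   (Pearson for continuous/microarray-like data, Spearman for counts), top
   5th-percentile |r| edge selection at p < 0.05, and aggregation into a
   frequency-weighted network (edge weight = occurrences / #cohorts).
3. **lmqcm** — local-maximum Quasi-Clique Merger module mining
   (t = 1.0, λ = 1.0, γ = 0.81, β = 0.3, min size 10), run separately on the
   disease ("AD"-prefixed modules) and control ("N"-prefixed) networks.
4. **module_scores** — per-module differential expression (mean absolute
   Welch t), differential co-expression (RMS of standardized Fisher-z
   differences), concordance (CCI, standardized leading eigenvalue of the
   module correlation matrix), median aggregation across cohorts, and
   HDE/LDE × HDC/LDC quadrant classification; plus per-gene cross-cohort DE
   calls (fold change ≥ 1.2, BH-adjusted p < 0.05, ≥ 2 cohorts).
5. **deconv** — marker-based surrogate cell-type proportions (PC1 of
   z-scored marker submatrices) for neurons, microglia, astrocytes,
   oligodendrocytes, endothelia, with Wilcoxon condition tests.
6. **association** — module eigengenes, eigengene–proportion/trait
   correlation tables with Bonferroni flags, hypergeometric marker
   enrichment, Jaccard module overlap, hub-gene gain/loss between
   conditions, hub connectivity across proportion splits, and cross-region
   proportion concordance.
7. **synthetic_data** — a multi-cohort simulator (Dirichlet cell-type
   mixtures, planted proportion-driven / regulation-perturbed / housekeeping
   modules, monotone clinicopathological traits) providing ground truth for
   every stage.

## CLI

```bash
# generate synthetic cohorts + a ready-to-run config
fgcn simulate --seed 1 --out sim/

# run everything: preprocess -> networks -> mining -> scores -> deconv -> association
fgcn run-all --config sim/pipeline_config.yaml

# or stage by stage
fgcn preprocess --matrix m.tsv --phenotype p.tsv --platform counts --out filtered
fgcn network --matrix m.tsv --phenotype p.tsv --platform continuous \
             --group disease --out edges_d1.tsv
fgcn mine --edges edges_d1.tsv --edges edges_d2.tsv --prefix AD --out modules.gmt
fgcn deconvolve --matrix m.tsv --phenotype p.tsv --platform continuous \
                --markers markers.gmt --out dec
```

Exit codes: 0 success, 2 configuration error, 3 data error.

### File formats

- Expression: TSV, genes in rows; header `gene_id<TAB>sample1<TAB>...`.
- Phenotype: TSV with `sample_id`, `condition` (aliases AD/CTL/ND accepted),
  optional `region`, `cdr`, `bb_score`, `plaque_mean`.
- Gene sets / markers / modules: standard GMT.
- Edge lists & networks: TSV `gene_a  gene_b  weight` with `gene_a < gene_b`.

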