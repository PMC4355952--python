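# chd8net

Statistical machinery linking a chromatin regulator's genomic targets to
disease risk genes:

- **`annotate`** — reduce replicate ChIP peak intervals (BED) to reproducible
  per-context target sets (≥1 bp overlap between replicates, merged
  coordinates), classify peaks against gene models (promoter > exon > distal,
  promoters = 1 kb upstream of each isoform TSS), and partition targets across
  biological contexts (Venn cells, one-to-one ortholog mapping, fragment
  densities).
- **`enrichment`** — covariate-weighted permutation tests for risk-gene
  enrichment among bound promoters: gene-label permutation weighted by
  mutability `M = Σ_j (1.2754·g_j + 0.7246·(1−g_j))·s_j·c_j` (GC, size,
  coverage per exonic locus), and promoter-label permutation weighted by total
  promoter size. Sampling is cumulative-weight inversion without replacement;
  one-sided empirical p, reported as `<1/n_iter` at zero exceedances.
- **`coexpr`** — seed-anchored co-expression networks (top-20 partners per
  seed at |r| ≥ 0.7) and seed-label permutation enrichment tests.
- **`knockdown`** — RNA-seq count QC (total ≤ 20 filter, single-unit filter,
  within-treatment VMR > 100 filter), mean-library scaling, trimmed-mean
  factors, per-gene Poisson / negative-binomial log-linear models with batch +
  knockdown effects (LRT p-values), Bonferroni thresholds and strong-DE calls
  (p < 1.68e-6, |log2FC| > 0.1, log2CPM in [2, 10]).
- **`genesets`** — Wilcoxon rank-sum dysregulation tests per gene set,
  quadratic-spline residuals of set p-value vs set size, pathway screening
  (≥20 resolvable genes; significant < 0.00011, notable < 0.001) and
  risk-list tests at the two-test level 0.025.
- **`dawn`** — sparse network estimation by neighbourhood lasso with
  power-law lambda selection, a generalized Ising hidden Markov random field
  on association Z-scores with a binding covariate `d ≥ 0`, stochastic-EM
  fitting, a smoothed-bootstrap test of `d > 0`, and Bayesian-FDR risk-gene
  calls.
- **`simulate`** — synthetic generators for every input (peaks, gene models,
  risk lists, count matrices, block-correlated expression, Ising-structured
  Z-scores) with planted ground truth.

## CLI

```sh
chd8net simulate --seed 5 --out sim/
chd8net annotate --peaks hNSC:rep1=sim/peaks_hNSC_rep1.bed \
                 --peaks hNSC:rep2=sim/peaks_hNSC_rep2.bed \
                 --peaks brain:rep1=sim/peaks_brain_rep1.bed \
                 --peaks brain:rep2=sim/peaks_brain_rep2.bed \
                 --genes sim/genes.tsv --out ann/
chd8net de --counts sim/counts.tsv --meta sim/samples.tsv --out de/
chd8net enrich --mode gene --universe universe.tsv --risk sim/risk_genes.txt \
               --targets targets.txt --iters 10000 --seed 1
chd8net coexpr --expr sim/expression.tsv --seeds seeds.txt --out net/
chd8net genesets --de de/de_kdC.tsv --sets pathways.gmt --out gs/
chd8net dawn --pvals sim/assoc_pvalues.tsv --binding sim/binding.tsv \
             --expr sim/graph_expression.tsv --boot 1000 --seed 1 --out dawn/
```

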