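# pcmkit

Phylogenetic comparative methods for continuous traits on microbial
phylogenies: trait-evolution model fitting and selection, phylogenetic-signal
statistics, phylogenetic generalized least squares (PGLS), pairwise dN/dS
filtering, and synthetic-data generators with known ground truth.

## What it does

- **`tree_core`** — rooted trees with branch lengths (Newick I/O via
  dendropy), the Brownian-motion covariance matrix, and the branch-length /
  covariance transforms: Pagel's lambda (off-diagonal scaling), kappa
  (per-branch exponent), delta (element-wise exponent), a non-ultrametric
  stationary Ornstein–Uhlenbeck covariance, an early-burst covariance, and
  a time-trend diffusion covariance. Tips lacking trait values are pruned
  with exact branch-length merging.
- **`trait_models`** — ML fits of seven models (Brownian motion, white
  noise, Pagel's lambda, Ornstein–Uhlenbeck, early burst, time-trend
  diffusion, directional drift) sharing one profiled multivariate-normal
  likelihood; model comparison by AIC with likelihood-ratio tests for
  nested pairs. Boundary estimates (e.g. early-burst collapsing onto BM)
  are flagged, never hidden.
- **`signal_stats`** — Blomberg's K with a seeded permutation test
  (+1-corrected p-value), Pagel's lambda with profile-likelihood CI and
  LRTs against 0 and 1, marginal kappa/delta estimates, and per-group
  (e.g. per-phylum) signal tables with small-sample flags.
- **`pgls_regression`** — non-phylogenetic GLS (= OLS) and PGLS with
  transforms estimated by ML (composition order: kappa on branches → BM
  matrix → delta element-wise → lambda off-diagonal), profile-likelihood
  CIs, both Nagelkerke and whitened multiple R², and nested-model ANOVA
  (F test with LRT cross-check).
- **`dnds_pipeline`** — the divergence-filtering protocol (drop pairs with
  dS > 1.5, dS < 0.1, omega > 10; strict inequalities so boundary values
  survive), the ≥25-estimates-per-genome support rule, per-genus median
  omega aggregation, a Nei–Gojobori (1986) counting estimator with
  Jukes–Cantor correction for self-contained testing, and the genome
  quality/downsampling/genus-size selection filter.
- **`synthetic_data`** — Yule trees (optionally branch-jittered to
  non-ultrametric), traits drawn from any of the model covariances,
  regression data with phylogenetically correlated residuals of known
  lambda, pairwise dN/dS tables with known survival fractions, and codon
  pairs with exact synonymous/nonsynonymous change counts.
- **`cli_pipeline`** — a config-driven runner producing TSV reports
  (model table, signal table, GLS/PGLS table, JSON provenance log), byte
  reproducible for a fixed config and seed.

## CLI

```bash
pcmkit fit-models --tree tree.nwk --traits traits.tsv --column genome_size \
    --models bm,ou,eb,lambda,trend,drift,white --out table1.tsv
pcmkit signal --tree tree.nwk --traits traits.tsv --column genome_size \
    --n-perm 999 --seed 42 --by-group phylum
pcmkit pgls --tree tree.nwk --traits traits.tsv \
    --formula "genome_size ~ dnds_median + rrn16s_copies" \
    --transforms kappa=ML,lambda=ML,delta=ML --out table2.tsv
pcmkit dnds-filter --pairs pairs.tsv --min-estimates 25 --out medians.tsv
pcmkit select-genomes --metadata meta.tsv --seed 7
pcmkit simulate --what trait --n-tips 200 --seed 1 --model bm --params sigma2=1
pcmkit run --config run.yaml     # end-to-end; see RunConfig fields
pcmkit validate --config run.yaml
```

## File formats

Newick trees (branch lengths required, polytomies allowed); TSV trait
tables (header row, first column = tip label); TSV pairwise tables
(`genus, genome_a, genome_b, dN, dS, omega`); TSV genome metadata
(`accession, genus, class, phylum, completeness, contamination, is_cpr`);
gap-free in-frame FASTA/plain codon sequences for the counting estimator.
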