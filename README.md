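# coexnet

Weighted gene coexpression network analysis for identifying
trait-associated hub genes, exercised end-to-end on synthetic data.

The pipeline takes a log2-scale gene × sample expression matrix and:

1. **preprocesses** it (quantile normalization; mean-collapse of probes to
   genes with a minimum-probe filter),
2. builds **coexpression networks** from pairwise Pearson correlations —
   a binary network via a hard threshold (|r| ≥ τ, default 0.7) and a
   weighted network via a power adjacency (|r|^β, default β = 7),
3. computes the **topological overlap matrix** (TOM) and clusters genes
   with average linkage on 1 − TOM, cutting the tree at a height cutoff
   (default 0.99) into color-named **modules** ("grey" = unassigned),
4. profiles **network topology**: degree/connectivity, betweenness and
   closeness centrality, clustering coefficients, and scale-free /
   exponentially-truncated power-law degree-distribution fits by log-log
   regression with R²,
5. selects **candidate genes** (top-degree hubs plus top-betweenness
   bottlenecks),
6. tests modules for gene-set **over-representation** (one-sided Fisher's
   exact test with Benjamini–Hochberg adjustment; GMT input), and
7. **validates** candidates against a quantitative trait (group
   means/SEM, fold change, covariate-adjusted OLS of trait on expression,
   expression–trait correlation, and PCA of the candidate expression
   matrix).

A synthetic-data module generates expression matrices with planted
correlated modules, designated hub genes, and a trait tied to a latent
factor, plus a two-group qPCR-style validation fixture — including the
published 12-steer cohort with its printed ages and intramuscular-fat
percentages — so every stage is testable without any downloads.

## CLI

Every subcommand accepts `--seed`; all stage parameters default to the
published analysis values (τ = 0.7, β = 7, height cutoff 0.99).

```sh
# synthetic inputs
coexnet simulate expression --n-genes 300 --n-samples 60 \
    --module-sizes 60,40,30 --seed 1 -o expr.tsv
coexnet simulate fixture --reference -o fixture.csv   # published cohort

# individual stages
coexnet preprocess --expr expr.tsv -o norm.tsv
coexnet network --expr norm.tsv --mode soft --beta 7 -o net/
coexnet modules --tom net/tom.tsv --adjacency net/adjacency_soft.tsv -o mods/
coexnet topology --adjacency net/adjacency_hard.tsv --fit power,truncated -o topo/
coexnet hubs --adjacency net/adjacency_hard.tsv --n-top-degree 6 --n-top-bc 5 -o hubs.tsv
coexnet enrich --modules mods/modules.tsv --gene-sets sets.gmt -o enrichment.tsv
coexnet validate --expr fixture.csv --genes TMEM60,DPYD -o validation.json

# or the whole pipeline with a JSON manifest
coexnet run-all --expr expr.tsv --traits fixture.csv --seed 1 -o run/
```

`run-all` writes per-stage outputs (normalized expression, correlation,
hard/soft edge lists, TOM, module assignment + summary, topology report,
candidates, optional enrichment/validation) and a `manifest.json`
recording parameters, input hashes, and per-stage counts; reruns with
identical inputs are byte-identical.

## Notes & conventions

- Hard-threshold connection is inclusive (|r| ≥ τ); both network modes
  use |r| (unsigned networks).
- Adjacency diagonal is 0 (self-connections excluded from connectivity);
  TOM diagonal is 1.
- Betweenness/closeness default to the binary network; a weighted mode
  uses edge lengths 1/a (or 1 − a). Betweenness is normalized by
  (n−1)(n−2) ordered pairs.
- Module colors are size-ranked: the largest module is always
  "turquoise". Tree cutting is a static height cut plus a minimum module
  size; branches below the size threshold are grey.
- Quantile normalization distorts correlations noticeably on very small
  gene sets (it is a per-sample rank remap against a reference built
  from few values); with realistic gene counts the effect is mild.
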