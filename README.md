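# seednet

Seed-gene subnetwork convergence analysis on tissue interactomes.

Given an expressed-gene universe, a protein–protein interaction (PPI)
edge list, a small expression matrix and seed gene lists (differentially
expressed genes plus disease/phenotype candidate sets), `seednet`
derives:

- the **tissue interactome** — the PPI graph restricted to expressed
  genes, cleaned of duplicates, self-loops and zero-degree nodes;
- a **co-expression layer** — Pearson correlation on FPKM at a hard
  cutoff (default |r| ≥ 0.75), attached to PPI edges as a support flag;
- **seed subnetworks** — seeds plus first neighbors recruited through
  dual-support (PPI ∧ co-expression) edges, with induced PPI edges;
- **node-shuffle permutation nulls** for subnetwork size (default
  1000 relabelings, add-one empirical p);
- **enrichment statistics** — seed fractions across gene universes with
  bootstrap standard errors (default 100 resamples) and exact
  two-tailed Fisher tests;
- **betweenness hub rankings** (unnormalized, exhaustive-oracle
  tested);
- **gene–pathway bipartite subnetworks** — one-sided hypergeometric
  over-representation per GMT pathway, kept at p < 1e−6 with ≥ 10 seed
  hits, plus converged modules and PPI-vs-bipartite pathway-list
  concordance;
- a **synthetic data generator** (scale-free PPI, negative-binomial
  counts with Gaussian-copula co-expression blocks, planted DEGs, seed
  sets with a planted enrichment odds ratio, planted enriched
  pathways) so the full pipeline runs and is testable without any
  external downloads.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the worked-example statistics and the
oracle/calibration/power property suites; the rest are per-module unit
and property tests.

## CLI

```sh
seednet simulate --seed 1 --outdir runs/inputs --n-genes 1200 --n-deg 150
seednet coexpr runs/inputs/fpkm.tsv --cutoff 0.75 --out coexpr.tsv
seednet build-interactome runs/inputs/ppi_edges.tsv expressed.txt --out net.tsv
seednet subnetwork net.tsv seeds.txt --out-edges sub_e.tsv --out-nodes sub_n.tsv
seednet null net.tsv seeds.txt --reps 1000 --seed 1 --out null.tsv
seednet betweenness sub_e.tsv -k 10
seednet enrich seeds.txt expressed.txt deg.txt subnet_nodes.txt --out panel.tsv
seednet bipartite pathways.gmt expressed.txt seeds.txt --out rows.tsv
seednet converge net.tsv seeds_a.txt seeds_b.txt --out-edges m_e.tsv --out-nodes m_n.tsv
seednet pathway-overlap list_a.txt list_b.txt
seednet demo-numbers
```

The full pipeline runs from a YAML config:

```sh
seednet run-all config.yaml
```

```yaml
# config.yaml — synthetic end-to-end run
seed: 1
outdir: runs/demo
synthetic:
  n_genes: 1200
  n_deg: 150
params:
  null_reps: 1000
  coexpr_cutoff: 0.75
```

Replace the `synthetic` block with an `inputs` block (paths to
`ppi`, `counts`, `samples`, `lengths`, `deg`, `seed_sets`, `gmt`) to
run on real files. Every run writes its artifacts plus a
`manifest.json` with input hashes, the seed and stage wall times.

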