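# mirmint

Integrated miRNA–mRNA expression analysis for two-group (tumor vs
normal) microarray cohorts, built around the workflow used in tongue
squamous cell carcinoma (TSCC) profiling studies:

1. **diffexpr** — log2 transformation, empirical-Bayes moderated
   two-group t-tests (with a no-shrinkage mode that reduces exactly to
   the pooled t), Benjamini–Hochberg adjustment, and threshold filters
   (default miRNA cuts: fold-change > 4, P < 0.01, FDR < 0.01, with
   `hsa-miR-923` blacklisted; mRNA cuts: P < 0.01, FDR < 0.01).
2. **clustering** — unsupervised hierarchical clustering with Pearson
   correlation distance and unweighted average linkage (UPGMA), plus a
   two-branch root cut for the two major sample clusters.
3. **seed_targets** — seed-match target prediction on 3′UTRs (8mer,
   7mer-m8, 7mer-A1 site classes, literal-A anchor, no G:U wobble), or
   import of precomputed prediction tables.
4. **integration** — intersection of predicted targets with the DE
   sets, keeping only anti-correlated pairs (opposite DE directions;
   the cohorts come from different patients, so sample-level
   correlation is not defined). Probe-level results collapse to gene
   level by max |log fold-change|.
5. **enrichment** — per-term Fisher exact and χ² tests, fold
   enrichment (nf/n)/(Nf/N), and the run-level paired-test
   FDR = 1 − Nk/T where Nk counts terms with Fisher P below χ² P.
6. **networks** — bipartite miRNA–GO and miRNA–mRNA networks with
   binary adjacency; node degree (edge count) ranks the key nodes.
7. **confirmation** — direction-of-change concordance of network genes
   in an independent cohort (detection requires platform presence only,
   not significance).
8. **synthetic_data** — cohort simulator with planted fold-changes, a
   planted anti-regulatory target map whose seed sites are implanted
   into target UTRs (and screened out of all others), and annotation
   sets enriched for the planted genes — ground truth for every stage.

## CLI

```sh
mirmint config-init --out config.yaml       # all defaults, documented
mirmint simulate --outdir sim --seed 1      # synthetic inputs + config
mirmint run-all --config sim/run_config.yaml
```

Individual stages (`de`, `cluster`, `targets`, `integrate`, `enrich`,
`network`, `confirm`) read their predecessors' outputs from the
configured output directory, so chaining them reproduces `run-all`
byte-for-byte. The machine-readable contract is `report.json` in the
output directory, with per-stage counts (DE features up/down, predicted
associations, filtered pairs, significant terms, network sizes,
concordance).

## Data files

`data/network_characteristics_mirna_go.tsv` and
`data/network_characteristics_mirna_mrna.tsv` are transcriptions of the
published TSCC network degree tables (node_type / name / degree); both
satisfy the bipartite degree-sum balance checked by the test suite.
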