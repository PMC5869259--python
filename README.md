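# rifnet

A tested, reusable pipeline for two-state (pre/post) transcriptome
analysis in a multi-tissue animal design:

1. **Normalization** — RPKM from read counts, expressed-gene filtering
   (mean RPKM ≥ 0.2), log2 transform, and an EM-REML mixed model
   `y = mu + library + gene + gene×animal×state×tissue + e`; normalized
   per-animal expression is the sum of the gene and interaction solutions.
2. **Differential expression** — per-gene fold change (post − pre on the
   normalized log2 scale) and a pooled-variance t-test; volcano and
   top-gene (|FC| ≥ 3, p ≤ 0.01) tables.
3. **RIF** — regulatory impact factors RIF1/RIF2 scoring every
   transcription factor against the DE gene set via state-wise
   correlations and differential wiring, z-standardized with |z| ≥ 1.96
   significance.
4. **PCIT** — co-expression network inference by exhaustive trio
   screening of partial correlations with a per-trio tolerance.
5. **Trio selection** — exhaustive search for the three TFs whose open
   neighborhoods span the most of the network with minimum redundancy.

A first-class synthetic-data generator (`rifnet.simulate`) emulates the
12-animal, two-state, five-tissue, 72-library design and plants DE genes
and differentially wired regulators with known ground truth, which is
what the test suite benchmarks against.

## CLI

```sh
# generate a synthetic fixture bundle with planted ground truth
rifnet simulate --seed 1 --n-genes 500 --n-tf 50 --out sim/

# run the whole pipeline
rifnet run-all --counts sim/counts.tsv --design sim/design.tsv \
    --tf-list sim/tf_list.txt --tissue t1 --out results/

# or stage by stage (each stage reads only the previous stage's files)
rifnet normalize --counts sim/counts.tsv --design sim/design.tsv --out results/
rifnet de       --design sim/design.tsv --out results/
rifnet rif      --design sim/design.tsv --tf-list sim/tf_list.txt --out results/
rifnet network  --design sim/design.tsv --out results/
rifnet trio     --out results/
```

All thresholds (RPKM ≥ 0.2, p < 0.05, |FC| ≥ 3 & p ≤ 0.01, |z| ≥ 1.96)
can be set in a YAML config passed with `--config`; every run writes the
resolved config, a manifest with per-stage counts, and TSV/SIF/YAML
outputs that are byte-identical across re-runs.

## File formats

- `counts.tsv` — `gene_id`, `exon_length_kb`, one integer column per sample.
- `design.tsv` — `sample_id`, `animal_id`, `state` (pre/post), `tissue`,
  `library_id`, `mapped_reads_millions`.
- `tf_list.txt` — one TF gene id per line.
- Networks — edge list TSV (`x`, `y`, `weight`), node attribute TSV, and
  SIF (`x co y`) loadable in Cytoscape-like tools.

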