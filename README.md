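# ppintegrate

Integrate heterogeneous protein–protein interaction (PPI) datasets into a
single weighted network, detect modules, and fit per-dataset confidence
weights so that the detected modules best match a reference set of
functional modules.

The pipeline:

1. **integrate** — each dataset carries one confidence score in [0, 1];
   the combined edge weight for a protein pair is the noisy-OR (naïve Bayes)
   combination `1 − Π(1 − w_p)` over the datasets containing the pair.
   Gold-standard datasets are pinned at weight 1.
2. **mcl** — a from-scratch Markov Cluster algorithm (expansion + inflation
   of the column-stochastic matrix to idempotence) partitions the weighted
   network into disjoint modules.
3. **similarity** — normalized mutual information between the detected
   partition and a reference module set (a cover-NMI variant is available
   for overlapping references).
4. **harmony** — a seeded harmony-search maximizer tunes the free dataset
   weights to maximize that NMI.
5. **analyze** — hub/central proteins (within-module degree > 2× module
   mean), co-expression overlay with an empirical cutoff, module↔complex
   mapping, and overlap reporting against an external interaction dataset.
6. **simulate** — a planted-complex benchmark generator (controlled
   true/false edge rates, latent-factor co-expression, perturbed reference
   modules) so everything is testable without downloads.

## CLI

```sh
# generate a synthetic benchmark
ppintegrate simulate --spec spec.yml --out bench/

# fit dataset weights (config lists the dataset roster and reference modules)
ppintegrate fit --config config.yml --iterations 300 --seed 1 --out results/

# integrate at fixed weights, cluster, analyze
ppintegrate integrate --config config.yml --weights results/weights.tsv --out net/
ppintegrate cluster --network net/network.tsv --inflation 2.0 --out modules/
ppintegrate analyze --network net/network.tsv --modules modules/modules.gmt \
    --expression bench/expression.tsv --complexes bench/truth_complexes.gmt \
    --external y2h.tsv --used-dataset bench/good.tsv --out analysis/
```

A fit config looks like:

```yaml
datasets:
  - {name: hu,   path: hu.tsv,   role: free}
  - {name: dip,  path: dip.tsv,  role: fixed_full_confidence}
reference: coexpression_modules.gmt
extra_references: [cofunction_modules.gmt]
mcl: {inflation: 2.0}
harmony: {memory_size: 100, iterations: 10000}
nmi_variant: partition
seed: 1
```

Every run writes a `metadata.json` (parameters, seed, input checksums);
re-running with the same config and seed reproduces all outputs byte for
byte. File formats are plain text: 2-column TSV edge lists, GMT gene sets,
TSV expression matrices, TSV weights/traces/networks.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(oracle equivalence for the evidence combination, MCL, and NMI; harmony
convergence; benchmark-scale parameter recovery; cutoff and hub rules; CLI
determinism). One parameter-recovery assertion is expected to fail: the
optimizer has no pressure to push informative dataset weights above 0.5 at
benchmark scale (the objective is insensitive to the absolute weight scale),
so that threshold is not met even though noise weights are correctly driven
toward zero and the planted complexes are recovered.

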