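# tadpole

Hierarchical TAD (topologically associating domain) calling from dense
intra-chromosomal Hi-C contact matrices, plus the companion statistics for
comparing and biologically validating genome partitions.

The caller works in three stages:

1. **Preprocessing** — read a dense tab-separated matrix, mask bad bins
   (empty diagonal, column sum below the 1st percentile), optionally split
   chromosome-scale matrices at the centromere (longest all-zero column
   run), transform to the Pearson-correlation matrix and reduce with PCA
   (first 200 components by default).
2. **Constrained clustering** — for every candidate PC count, build the
   Euclidean distance matrix of the scores and run adjacency-constrained
   incremental sum-of-squares agglomeration (CONISS); the broken-stick
   model bounds the number of significant hierarchy levels.
3. **Segmentation** — the Calinski-Harabasz index scores every
   (PC count, level) pair; the PC count with the highest mean CH over its
   significant levels wins and its maximum-CH level is the optimal
   partition. A permutation screen flags hierarchies that do not beat
   adjacency-destroyed replicates of the same data.

Companion modules: **MoC** (measure of concordance) and border **overlap
score** with permutation p-values; the **DiffT** score localizing
topological differences between two partitions with a per-bin permutation
test; boundary/body **enrichment** metrics from ChIP-seq peaks and signal
tracks (SPP profiles, fold change, occupancy, TAD-state test); and a
**synthetic** generator of nested block matrices with known ground truth.

## Library quick start

```python
from tadpole import (SyntheticSpec, generate_matrix, detect_bad_columns,
                     drop_masked, optimize)

spec = SyntheticSpec(n_bins=60, levels=((30,), (15, 30, 45)),
                     block_contrast=3.0, seed=7)
matrix, truth = generate_matrix(spec)
filtered, bin_map = drop_masked(detect_bad_columns(matrix))
hierarchy = optimize(filtered, bin_map=bin_map, n_pc_max=8)
print(hierarchy.n_pc_opt, hierarchy.n_tads_opt,
      hierarchy.optimal_partition.domains)
```

## CLI

```sh
# call the hierarchy on a dense matrix
tadpole call --matrix matrix.tsv --chrom chr6 --resolution 50000 --out run1

# generate a synthetic fixture
tadpole simulate --spec spec.json --out matrix.tsv --truth truth.bed

# compare two partitions
tadpole moc run1_domains.bed run2_domains.bed --level-a 3 --level-b 3
tadpole overlap fine.bed coarse.bed --resolution 10000 --nrand 10000

# localize topological differences
tadpole difft --a wt.bed --b mut.bed --level 9 --nsim 10000 --seed 1 --out d

# boundary enrichment from ChIP-seq peaks
tadpole enrich --domains run1_domains.bed --level 11 --peaks ctcf.bed \
    --resolution 10000 --out enr
```

`tadpole call` writes `<prefix>_domains.bed` (all levels),
`<prefix>_summary.tsv` and `<prefix>_result.json`. Exit codes: 0 success
(including a flagged "no hierarchy" result), 2 parameter error, 3 format
error, 4 validation error, 5 undefined metric.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: CONISS
equivalence against a brute-force oracle, closed-form metric checks,
planted-hierarchy recovery on synthetic matrices, and permutation-test
calibration.

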