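# swarmselect

Two-stage gene selection for binary-class gene-expression classification.

**Stage 1 (filter):** rank genes with a per-gene statistic — Welch-style
t-statistic, signal-to-noise ratio (prediction strength), or the variance
ratio F value — and keep the top *m* (typically 10, 50, or 100).

**Stage 2 (wrapper):** search subsets of those *m* genes with one of four
population optimizers — particle swarm optimization (`pso`), cuckoo search
(`cs`), shuffled frog leaping (`sfl`), or shuffled frog leaping with
Lévy-flight steps (`sfllf`). Candidates are continuous vectors in
[0,1]^m; components strictly greater than 0.5 switch a gene on. Each
decoded subset is scored by the mean accuracy (%) of a k-NN classifier
(k = 5, Euclidean distance) over seeded stratified 5-fold cross-validation.

The package also ships a synthetic-data generator that plants differentially
expressed genes on a noisy background, so the whole pipeline is testable
without external datasets.

## Command-line usage

```sh
# make a synthetic dataset (tab-delimited, labels in a "#labels" row)
swarmselect synth --out data.tsv --n-genes 1000 --n1 30 --n2 30 \
    --n-informative 10 --effect-size 2 --seed 7

# rank genes and write a report
swarmselect rank --data data.tsv --stat t --top-m 50 --out ranking.tsv

# one (statistic, algorithm, m) selection run
swarmselect select --data data.tsv --stat t --algo sfllf --top-m 50 --seed 1

# full 3 statistics x 4 algorithms x {10,50,100} grid
swarmselect run-grid --data data.tsv --seed 1 --out report.json --tsv report.tsv
```

Input format: delimited text, genes as rows; first header row holds sample
ids, labels either in a second `#labels` row or a two-column companion file
passed via `--labels`. Optimizer defaults (population 50, 200 generations,
w = 0.9, c1 = c2 = 2.1, α = 1, λ = 1.5, 10 memeplexes × 5 frogs,
20 shuffles) can be overridden through a YAML `--config` file, e.g.

```yaml
optimizer:
  pop_size: 20
  generations: 40
  shuffles: 10
  n_memeplexes: 5
  frogs_per_memeplex: 4
```

Every grid cell derives its own seed from the master `--seed` by a stable
hash of (statistic, algorithm, m), so reports are reproducible cell by cell.

## Notes on fidelity choices

* SNR uses the `s1 + s2` denominator by default; `--snr-denominator paper`
  gives the literal `s1 − s2` form behind an ε-guard.
* t and SNR rank by |score| by default; `--signed-ranking` restores signed
  ordering. F values rank ascending; `--f-rank two_tailed` ranks by
  deviation from 1 instead.
* Ranking is computed on the full dataset before cross-validation (the
  pipeline's published design); the resulting selection bias is inherent
  to that design and deliberately not corrected here.
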