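# pirnadev

Small-RNA library processing, piRNA signature statistics, and clonal
epigenetic-memory analysis on toy reference sequences.

The package covers two analysis tracks:

1. **Small-RNA track** — adapter trimming and 19–29 nt length filtering,
   read collapsing, exhaustive placement on toy references (0 or 1
   mismatch, best stratum, all hits on both strands), read
   categorisation (miscRNA > tRNA > miRNA > TE > other) with
   effective-depth and miRNA-based normalisation, and the locus/TE
   statistics: multimapping-weighted coverage, size distributions, 1U
   bias, sense/antisense 5′-overlap (ping-pong) histograms with a
   z-score summary, TE antisense RPKM, and knockdown comparison
   scatters.
2. **Clonal track** — gonad clone homogeneity classification, the
   closed-form probability of a homogeneous-clone tally under the
   independent-cell (plastic repression) null, ovariole phenotype
   classification (overlap / exclusion / mixed), and Monte-Carlo
   phenotype expectations under the lock and plastic models.

A first-class synthetic-data module generates toy genomes (with planted
repeats so multimapping reads exist), simulated piRNA libraries with
tunable ping-pong pairing, 1U bias, contaminants, multimapping and
per-region depletion — each read carrying a ground-truth record — and
simulated gonad lineages under either inheritance model. All downstream
stages are tested against these truth tables.

## Command line

```sh
pirnadev --help
```

Stage-by-stage subcommands:

- `simulate-reads`, `simulate-clones` — synthetic libraries / lineages
  (all randomness from `--seed`);
- `trim`, `align` — FASTQ → collapsed TSV → SAM;
- `annotate` — category tallies, effective depth, normalisation factors;
- `profile`, `pingpong`, `te-rpkm`, `compare-glkd` — signatures from SAM;
- `clone-test`, `simulate-ovarioles` — clonal classification and models.

End-to-end runs are driven by a YAML config:

```sh
pirnadev run config.yaml          # simulate → trim → align → annotate →
                                  # signatures → report.md
pirnadev run-clonal config.yaml   # observations/simulation → classification
                                  # → plastic-null probability
```

Example config:

```yaml
seed: 11
normalization: depth        # or mirna
control_library: control
test_library: knockdown
genome:
  regions:
    - {name: cluster, length: 5000, role: dual_strand_cluster}
    - {name: subtelomere, length: 2000, role: subtelomere}
    - {name: transgene, length: 1500, role: transgene}
libraries:
  control:   {n_reads: 3000, pingpong_fraction: 0.6, u1_bias: 0.7}
  knockdown: {n_reads: 3000, pingpong_fraction: 0.6, u1_bias: 0.7,
              depletion: {cluster: 0.1}}
clonal:
  simulate: {n_gonads: 200, r: 0.6647, model: lock, flipout_prob: 0.1}
```

Every output table carries the seed and a config hash in its header;
reruns with the same config are byte-identical.

## Conventions

- Coordinates are 0-based half-open internally; SAM conversion happens
  at the boundary. A `-` strand hit at `start` means the read's reverse
  complement matches `ref[start:start+length)`; its 5′ end is
  `start + length - 1`.
- 5′ overlap between a sense read (5′ at `s`) and an antisense read
  (5′ at `a`) is `o = a - s + 1`; ping-pong pairs sit at `o = 10`.
- Multimapping hits are weighted `count × norm_factor / n_hits`, so each
  read contributes its full (normalised) count exactly once.
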