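# srnakit

A small-RNA analysis toolkit for transposon-targeting small RNA
populations, with a planted-ground-truth read simulator. It covers the
computational stages used to dissect piRNA/siRNA content of somatic
*Drosophila*-like libraries:

- **synthetic data** (`srnakit.synthetic`) — deterministic generation of a
  reference bundle (TE family consensus sequences, diverged genomic
  insertions, piRNA-cluster-like regions with guaranteed-unique
  subsequences, miRNA precursors, blocklist decoys, a synthetic genome) and
  read libraries with controlled class mixture, strand bias, planted 10-nt
  5′-overlap ping-pong pairs, per-family siRNA multipliers, A→G editing,
  single-substitution errors, and library mixing/downsampling;
- **alignment** (`srnakit.align`) — ≤1-mismatch alignment on both strands
  with best-stratum semantics and `all` / `unique` / `random_one`
  reporting modes, blocklist filtering, size selection;
- **ping-pong signature** (`srnakit.pingpong`) — 5′-overlap pair counts for
  overlaps 5–15 nt, z-scores over the window, and the
  positive / negative / intermediate library call (z₁₀ ≥ 2 and > 20 pairs);
- **contamination QC** (`srnakit.contamination`) — spike-in simulation
  re-testing the signature, miRNA counting against precursors, exact
  conditional binomial / sign-test differential abundance with
  Benjamini–Hochberg adjustment, and the top-k contamination-signature
  overlap report;
- **siRNA quantification** (`srnakit.quant`) — size/strand profiles in
  counts per 10 million mapped reads (cp10m), per-family 21-nt antisense
  counts from unique alignments, miRNA-anchored median-of-ratios size
  factors, abundance filters, log2 fold changes, Mann–Whitney comparison
  (exact enumeration for n ≤ 8), and piRNA-cluster-exclusive read
  partitioning;
- **editing spectrum** (`srnakit.editing`) — the 12-way substitution-type
  frequency spectrum of 21-nt TE-aligned reads and the A→G excess score.

## CLI

```sh
srnakit simulate --config cfg.yaml --seed 1 --out-prefix out/demo
srnakit align --reads out/demo.reads.fasta --ref out/demo.families.fasta \
    --mode random-one --min-len 24 --max-len 28 --seed 1 --out demo.sam
srnakit pingpong --sam demo.sam --out signature.tsv
srnakit spike --head head.fasta --gonad gonad.fasta --te-ref families.fasta \
    --n-head 245000 --n-spike 5000 --seed 1 --out spike.json
srnakit mirna-de --counts counts.tsv --totals totals.tsv \
    --group-a l0,l1,l2 --group-b l3,l4,l5 --out de.tsv
srnakit contamination-report --sim-de sim.tsv --obs-de obs.tsv --out report.json
srnakit quant size-profile|families|normalize|fc|cluster-exclusive ...
srnakit mismatch --sam demo.sam --size 21 --out spectrum.tsv
```

`simulate` takes a YAML config with the library parameters (`n_reads`,
`class_mix`, `pingpong_rho`, `antisense_bias`, `sirna_fc`, `editing_rate`,
`seq_error_rate`, `mirna_profile`, `cluster_unique_frac`, `pirna_hotspots`)
plus an optional `reference:` section; see `tests/test_io_cli.py` for a
minimal example.

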