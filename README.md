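# repeatprobe

Design oligonucleotide FISH probes against intervals of **highly
repetitive DNA** — satellite arrays, pericentromeric repeats, and other
tandem-repeat targets that mainstream probe-design tools deliberately
filter out.

Repetitive intervals make superb FISH targets: one probe species binding
hundreds or thousands of clustered sites yields a large, bright signal at
minimal cost. But designing such probes inverts the usual specificity
problem. Instead of discarding any probe with more than one alignment,
the designer must find probes whose *many* binding sites fall
overwhelmingly inside the intended interval and not in the near-identical
repeat copies elsewhere in the genome. `repeatprobe` addresses this for
researchers building probe panels for chromosome enumeration,
repeat-biology, and spatial-genomics experiments.

## What it computes

1. **Repeat discovery.** All genomic k-mers (k = 18 by default) are
   counted strand-specifically. Per scaffold, a sliding window of W
   positions flags positions whose k-mer count exceeds a threshold T; a
   window is repeat-positive when the flagged fraction reaches the
   composition score C. Merged positive windows, trimmed to their flagged
   extent and extended by k − 1 bp, become target intervals.
2. **Candidate mining.** Each interval is scanned greedily for
   non-overlapping probes of 25–50 nt with formamide-adjusted
   nearest-neighbor Tm in 42–52 °C and GC in 20–80%.
3. **Ranking.** Per candidate, R_m (aggregate k-mer count within the
   target) and H_m (genome-wide) give the enrichment K_b = R_m/H_m, and
   candidates sort by the normalized rank
   `Nr = R_m/(max R_m · c1) + K_b/(max K_b · c2)`; a `mer_cutoff` filter
   drops candidates whose k-mers mostly repeat those of higher-ranked
   survivors.
4. **In silico specificity profiling.** Each candidate is aligned to the
   whole genome (seeded affine-gap local alignment, both strands, up to
   500 000 sites); every site's duplex probability *pDups* comes from a
   two-state nearest-neighbor equilibrium at 69.5 °C / 0.39 M Na⁺. Sites
   sum into On_T (inside the target), Off_T (outside), the binding
   proportion On_T/(On_T+Off_T), and per-bin genome aggregates. Probes
   failing per-probe floors, the per-bin off-target cull, or redundancy
   with already-accepted probes are rejected; selection stops when the
   requested aggregate on-target sum is reached.

Full model details, parameter tables, and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic genome with a planted satellite-like array (171-bp
monomer × 30 copies, 2% per-copy divergence, ~49 kb total) and run the
full discovery pipeline:

```bash
repeatprobe simulate --out fixture --seed 1
printf 'genome_windows: 1000\nthresh_windows: 1000\n' > fixture.yml
repeatprobe discover --fasta fixture/genome.fa \
    --chrom-sizes fixture/genome.chrom.sizes \
    --preset permissive --config fixture.yml --out run
# discovered 1 interval(s); wrote outputs to run
```

`run/repeat_intervals.bed` contains the discovered interval

```
sim1	21999	27130	0.7018
```

which matches the planted array (truth `sim1:22000-27130`) with Jaccard
overlap 0.9998; the fourth column is the composition (fraction of
positions whose 18-mer count exceeded T) at detection time.
`run/probes.tsv` holds the selected probe:

```
scaffold  start  end    sequence                                            tm       gc_percent  r_m  h_m  k_b  nr   on_t     off_t  binding_prop
sim1      22391  22441  TGTATAATTTCAAGTTAAGTTACTCGAGTTTGATATATACCGACAACAGC  42.5245  32.0        689  689  1.0  2.0  28.7319  0.0    1.0
```

Reading the numbers: every one of the probe's 18-mers occurs only inside
the target (`k_b = 1`, 689 aggregate occurrences), the probe is predicted
to bind 28.7 site-equivalents inside the array (`on_t`, roughly one
near-certain duplex per monomer copy) and nothing elsewhere
(`binding_prop = 1.0`), so this single probe already satisfies the
permissive preset's ≥ 25 aggregate on-target requirement
(`run/summary.tsv` records `termination_reason = target_sum_met`).
`run/binding_track_*.bedgraph` give the predicted binding per kilobase
bin, raw and normalized to 0–255, and `run/probe_log.tsv` records the
accept/reject verdict for every candidate examined.

`repeatprobe design` runs the same path from a user-supplied BED of
target intervals, and `repeatprobe analyze` re-profiles an existing probe
table under new hybridization conditions (e.g. a different temperature).

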