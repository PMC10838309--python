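# Methods

`repeatprobe` designs oligonucleotide FISH probes against intervals of
highly repetitive DNA. This note documents the models and procedures the
package implements, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Pipeline overview

Three entry points share one downstream path:

1. **Repeat discovery** — count all k-mers of the assembly, stream
   per-position counts per scaffold, and call repetitive intervals with a
   sliding-window rule.
2. **Probe design** — mine thermodynamically valid candidates from each
   target interval, deduplicate, score by target-specific k-mer
   enrichment, rank, and drop k-mer-redundant candidates.
3. **Specificity profiling and selection** — walk candidates in rank
   order; for each, enumerate putative binding sites by seeded local
   alignment, score every site with a two-state duplex model, aggregate
   on/off-target binding, and accept or reject against user criteria
   until the requested aggregate on-target binding is reached.

## Repeat discovery

k-mers (default k = 18) are counted strand-specifically on the forward
strand with no canonicalization; windows containing N contribute nothing.
This is deliberate and documented prominently because it changes the
k-mer aggregates R_m and H_m relative to canonicalized counting.

For each scaffold, position i carries the genome-wide count of the k-mer
starting at i. A position is *flagged* when its count strictly exceeds
the threshold T. A window of W consecutive positions (step 1, for maximal
sensitivity) is repeat-positive when the fraction of flagged positions in
it is at least the composition score C. Runs of positive windows are
merged, and each merged span is then **trimmed to its first and last
flagged positions** before the end is extended by k − 1 bp to cover the
final k-mer's footprint. Trimming keeps the reported interval anchored to
the repetitive sequence itself rather than to the window footprint, which
would otherwise overhang each side by up to W·(1 − C) positions; with the
default W = 3000 that overhang would dominate kilobase-scale arrays.

The composition rule has a second reading — mean window count ≥ C — which
is available via `mode="mean"`; the flagged-fraction rule is the default
because flagging then compositing is the natural sequence of the two
steps. Strict inequality is used for count > T and an inclusive ≥ for the
composition, stated here because either convention is defensible; both
choices only move single boundary cases.

Parameters: `window` (W, positions, default 3000), `threshold` (T, count,
default 10; 5 in the permissive preset), `composition` (C, fraction,
default 0.5), `file_start` (bp offset at which scanning begins, per
scaffold, default 0).

## Probe mining and ranking

Candidates are mined per target interval by a greedy left-to-right scan:
a window grows from `min_length` (25 nt) until its formamide-adjusted Tm
reaches `min_temp` (42 °C) or the window hits `max_length` (50 nt); a
window is emitted when all five constraints hold (length, Tm ≤ `max_temp`
= 52 °C, 20 ≤ GC% ≤ 80), and the scan resumes immediately after an
emitted probe, so candidates never overlap. Mining is forward-strand
only. Exact duplicate sequences are removed, first occurrence kept.

Each candidate is scored by its aggregate k-mer counts: R_m within the
target interval (direct scan of the target sequence), H_m genome-wide
(from the count table), and the enrichment K_b = R_m / H_m. Candidates
are ordered by the normalized rank

    Nr = R_m / (max(R_m)·c1) + K_b / (max(K_b)·c2)

with maxima over the target's own candidate set and user weights c1 = c2
= 1 by default. Ties break deterministically by genomic start, then
sequence. A redundancy filter then walks the ranked list keeping the set
union of accepted candidates' k-mers; a candidate is dropped when the
proportion of its k-mers already in that union exceeds `mer_cutoff`
(default 0.8). Sets, not multisets, define the overlap proportion, and
the overlap is always tested against the running union rather than only
the previous probe — storing the k-mers of every accepted probe is what
makes the filter catch period-shifted near-duplicates from later copies
of a tandem array.

## Hybridization thermodynamics

Probe Tm uses the unified nearest-neighbor ΔH/ΔS table (shipped as
`data/nn_params.tsv`) with both-end initiation terms, the entropic
monovalent-salt correction 0.368·(N−1)·ln[Na+], the CT/4 concentration
term for equal non-self-complementary strands (default 1 µM per strand),
and a linear formamide correction of 0.65 °C per percent formamide — the
standard hybridization-literature coefficient. Probe windowing evaluates
Tm at 0.39 M Na+ and 50% formamide, matching a 2×SSCT / 50% formamide
hybridization recipe.

Binding-site scoring uses a two-state (bound/unbound) duplex model rather
than a full partition-function ensemble. For an aligned probe/site pair,
ΔG° at the model temperature (default 69.5 °C, 0.39 M Na+) accumulates
nearest-neighbor stacks over consecutive matched columns plus initiation
at the terminal matched columns; every mismatched or gapped column incurs
a destabilizing penalty worth +1.0 kcal/mol at 69.5 °C. The penalty is
implemented entropically (ΔS = −2.918 cal/mol·K per penalized column,
ΔH = 0) so that the duplex probability is non-increasing in temperature
for every alignment pair, including stack-free ones; a temperature-
independent ΔG penalty would act as a positive effective enthalpy and
reverse that monotonicity for heavily mismatched pairs. The fraction
duplexed at equal strand concentrations c solves the mass-action
quadratic: with Kc = K·c,

    pDups = (2Kc + 1 − sqrt(4Kc + 1)) / (2Kc),

clamped to [0, 1]. The model preserves the orderings the pipeline relies
on (perfect > 1 mismatch > 2 mismatches; monotone in temperature; [0, 1]
scale for all downstream sums) but is not interchangeable with a
multi-state ensemble solver; absolute pDups values should be read as
calibrated scores, not physical occupancies. No divalent-salt correction
is implemented (the magnesium default is 0).

## Binding-site enumeration

Sites are enumerated natively by seed-and-extend local alignment. Every
probe substring of `seed_length` (default 15) — from the probe for +
strand sites and from its reverse complement for − strand sites — is
looked up in an exact-match index of genome seed positions; on small
genomes (< 10^7 indexed positions) all 1-mismatch variants of each seed
are probed as well, recovering sites whose exact seeds were destroyed by
divergence. Seed hits sharing a diagonal neighborhood cluster into locus
windows, each scanned with affine-gap Smith–Waterman (match +2, mismatch
−6, gap open −5, gap extend −3 per gapped base). An alignment qualifies
when its score reaches 1 + 4·ln(L) for a probe of length L. Qualifying
alignments within a window are enumerated by recursing into the flanks of
each reported site (this is what resolves every copy of a tandem array
whose period equals the probe length), and overlapping sites on the same
scaffold and strand collapse to the best-scoring one. Hits are reported
best score first, ties by scaffold order then start, capped at
`max_alignments` (default 500 000). The contract is recall on planted
fixtures, not hit-set identity with any external aligner; the scoring
constants mirror common local-mode alignment practice.

Minus-strand hits are reported in forward-strand coordinates, and their
stored target row is the reverse complement of the genomic slice, so the
two rows of every hit are directly hybridization-comparable: a matched
column carries equal characters.

## Specificity and selection

Genome bins of `genome_windows` bp tile every scaffold (final bin
truncated). A hit is on-target when it overlaps the target interval by at
least 1 bp; a hit straddling two bins belongs to the bin containing its
midpoint. Per probe: On_T and Off_T are the sums of pDups over on- and
off-target sites, the binding proportion is On_T / (On_T + Off_T), and a
probe is culled when any bin not overlapping the target aggregates more
than `off_bin_thresh` predicted binding (bins overlapping the target by
any amount are excluded from that test). Bin sums conserve the total:
ΣbinAggregates = On_T + Off_T to 1e−9.

Selection processes candidates strictly in rank order and accepts a
candidate iff On_T ≥ `min_on_target`, binding proportion ≥
`binding_prop`, the off-bin cull passes, and its predicted pairing with
every already-accepted probe — the best local alignment between the two
probe sequences scored with the same duplex model — does not exceed
`max_pdups_binding`. The loop stops when the aggregate On_T reaches
`target_sum`, the accepted set reaches `max_probe_return`, or candidates
are exhausted; the termination reason is recorded, and a per-candidate
accept/reject log (with the failing criterion) makes the greedy loop
auditable. The off-bin cull is applied per probe, not to the accepted
set's combined bins. Selection is greedy by construction; no global
optimization over probe subsets is attempted.

Two presets bundle the selection thresholds: `conservative`
(target_sum 500, min_on_target 50, binding_prop 0.9, off_bin_thresh 2,
max_pdups_binding 0.5, ≤ 10 probes) for large, extremely robust targets,
and `permissive` (target_sum 25, min_on_target 5, binding_prop 0.8,
off_bin_thresh 10, max_pdups_binding 0.8, ≤ 25 probes) for exhaustive
discovery of smaller targets. The named intents (≥ 500 vs ≥ 25 predicted
target sites) are fixed; the remaining values are repository defaults
chosen once to express them.

## Reporting

Per-bin predicted binding is emitted as bedGraph, both raw and min-max
normalized to integer 0–255 (rounding half-up; an all-equal track maps to
0 — the degenerate case must map somewhere, and 0 renders as "no signal
anywhere", which is the honest display). The imaging window for a target
is the smallest interval spanning every target-overlapping bin whose raw
sum exceeds `align_thresh`; no qualifying bin is an explicit error.
Ideogram rendering is deliberately replaced by these tabular tracks,
which any genome browser consumes. A two-sided Fisher exact test (sum of
tables at fixed margins with probability ≤ the observed table's) is
provided for contingency comparisons of probe performance counts; a
zero-margin table returns p = 1 by convention, with a logged warning.

## Synthetic fixtures

The generator plants a tandem array — by default a 171-bp random monomer
(the alpha-satellite monomer length) in 30 copies, each copy
independently substituted at 2% per base — inside i.i.d. random
background at 42% GC (a human-like base composition), ~22 kb per flank
for a ~49-kb genome. An optional decoy array with a stated monomer
identity to the first (e.g. 80%, alpha-satellite-like inter-array
similarity) exercises off-target discrimination. Ground-truth intervals
exactly delimit the planted arrays, and all randomness flows from a
single seed: identical specs are byte-identical.

The mutation model is substitution-only so that alignment oracles stay
exact; there is no indel mode in the default path, no higher-order repeat
structure, no transposable-element landscape, and no assembly artifacts
(gaps, collapsed duplications). Passing tests on these fixtures
demonstrate that each stage implements its stated rule and that the
stages compose: planted arrays are recovered (interval Jaccard ≈ 1
against truth) and selected probes achieve binding proportion ≈ 1 with
the expected on-target sums. They do not demonstrate performance on real
satellite DNA, where divergence structure is correlated, arrays interleave
with other repeat families, and near-identical arrays occur on multiple
chromosomes.

## Problem sizes and numerical choices

The tests and the acceptance script run on fixture genomes of tens of
kilobases with kilobase-scale bins (`genome_windows` = 1000 there; the
library default of 1 Mb reflects genome-scale use), sizes at which the
in-memory hash-table k-mer counter and the pure-Python aligner complete
in seconds; these are the package's intended validation scale, with
multi-megabase assemblies a documented but untested extrapolation.
Floating-point accumulation tolerances are 1e−9 on conservation
identities. All pipeline stages are deterministic pure functions of their
inputs; only the fixture generator consumes randomness.

## Known limitations

- The two-state duplex model ignores secondary structure, probe-probe
  dimers, and multi-state complexes; off-target predictions at sites with
  long gaps are correspondingly coarse.
- Forward-strand-only k-mer aggregation means R_m/H_m ignore
  reverse-complement occurrences; a palindromic-rich target would be
  under-counted.
- The seed-and-extend aligner guarantees recall only for sites retaining
  at least one exact or 1-mismatch seed; heavily diverged sites (> ~10%)
  can be missed.
- Candidate mining is non-overlapping and greedy; a denser tiling could
  find marginally better probes at higher compute cost.
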