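# Methods

This note documents the models, algorithms and design choices behind
`cfplant`, in the order the pipeline runs them.

## Synthetic studies and what they emulate

The generator (`cfplant.synthetic`) produces reference panels and whole
sequencing studies with full ground truth. It emulates the statistical
structure of deep plasma cfDNA sequencing at desk scale:

* **Panels.** Random i.i.d. genomes with group metadata. Foreign
  ("plastome") genomes are AT-rich (GC 0.36, the typical chloroplast
  composition), bacterial confounders GC 0.50, host and mammalian
  confounders ~0.41. Each foreign genome donates a conserved region
  (default 2% of its length, 2% diverged) to a bacterial confounder,
  emulating the rRNA-operon homology between chloroplasts and bacteria
  that makes homology triage necessary. Default lengths (host 100 kb,
  plastome analogs 20 kb) are roughly 1/30 000 and 1/8 of the real scales
  — large enough that chance 28-mer collisions between unrelated panels
  are essentially impossible, small enough to index in seconds.
* **Study design.** Per sample `i`: depth `N_i` drawn log-uniformly from
  `depth_range` (default 9 409–128 277, the real 0.94 M–12.8 M per-sample
  range scaled by 100; log-uniform matches that skew, linear-uniform is a
  flag); true concentration `c_i` (ppm) drawn log-normal with
  `(mu, sigma) = (0.4, 1.6)` in ln-ppm units, which puts the median near
  1.5 ppm and yields a realistic non-detect share at real depths; foreign
  read count `k_i ~ Binomial(N_i, c_i·10⁻⁶)` (probability capped at 1
  with a warning). Binomial rather than Poisson thinning so `k ≤ N` holds
  exactly. Foreign reads are apportioned over species by the subject's
  diet mixture; remaining reads come from the host panel. Reads are drawn
  strand-symmetrically, mutated base-wise at `error_rate` (default 0.005),
  and labelled with one of three fragment-size fractions (">10 kb",
  "200 bp–10 kb", "~200 bp" — metadata only, since only 36–100 nt reads
  are analyzed downstream; default read length 50 nt). Quality strings
  are constant and never used.
* **Not emulated:** PCR duplicates, indels, quality decay, platform
  color-space artifacts, genuine phylogenetic sequence similarity between
  foreign species (families are labels, not sequence signal), and real
  genome repeat structure. Passing tests therefore demonstrate the
  *logic* of the screening chain — subtraction, stringent matching,
  homology triage, censored modeling — under controlled conditions, not
  performance on real repetitive genomes.
* All operations take explicit integer seeds; a fixed seed reproduces a
  study byte-for-byte, including the FASTQ.

## Alignment policies

Two gapless policies over an exact k-mer seed index (both strands,
N never matches, k-mers containing N unindexed):

* **Permissive** (host subtraction): candidate loci from *any* exact
  seed-length window of the read at stride 1, accepted with ≤ 3
  mismatches over the full read. This is a deliberate superset of a
  quality-aware short-read aligner's `-n 3`-style behaviour: the
  quality-sum rule is dropped because synthetic qualities are constant,
  and erring on the side of discarding host-like reads only makes the
  foreign counts conservative. Note the exact-window condition is part of
  the policy's definition: an alignment with ≤ 3 mismatches but no
  mismatch-free 28-nt stretch is *not* reported (a read with errors at
  e.g. positions 10 and 30 of 50 has none).
* **Stringent** (foreign matching): exact match over the first 28 nt of
  the read, ≤ 2 mismatches in the tail (configurable). The exact-prefix
  lookup is exhaustive for this policy, so no heuristic loss exists.

Coordinates are 0-based half-open; `AlignmentHit.start` is the leftmost
*forward*-strand coordinate for both strands (so reverse-complementing a
read flips the strand and keeps the locus). SAM export is 1-based with
flag 16 and reverse-complemented SEQ for minus-strand hits. Multi-hit
reads keep all hits; deduplication to per-read presence happens in
quantification. Indels are out of scope: reads are short and gapped
chance alignments are exactly what the stringent policy exists to
suppress.

Both policies are verified against an independent brute-force scan of
every (locus, strand) in the test suite and the acceptance script.

## Quantification

* A read with stringent hits on several foreign references counts *once*
  toward the sample's foreign-read count `k`, but contributes to the
  coverage pileup of *every* reference it hits (pileups are
  per-reference).
* `ppm = k/N × 10⁶`. Display rounding is half-up to 3 decimals by
  default; a truncating mode exists because published tables are
  internally inconsistent about which convention they used (the same
  table can contain values produced by each). Whole-ppm display floors.
  Model fitting always uses the unrounded ratio.
* Fraction pooling sums counts and recomputes ppm from the sums — never
  averages per-fraction ppm.
* Homology triage: a foreign-matching read that also stringently hits a
  bacterial confounder is `also_bacteria`; a mammalian one,
  `also_mammalia`; bacteria take precedence when both match (reads
  matching both are not biologically interpretable here and the bacterial
  explanation is the more parsimonious for rRNA-like regions).
* Coverage smoothing is a centered moving average, default window
  1001 nt (odd; edges truncated to the available span). The host mean
  coverage used in `coverage_ratio` is host-matching bases divided by
  host panel length.

## Censored log-normal concentration model

`ln c ~ Normal(mu, sigma)` across samples; a sample of depth `N` has
detection limit `10⁶/N` ppm (the concentration at which one read is
expected). Two fitting routes:

* **Censored MLE** (preferred): detected samples contribute
  `ln f(ppm_i)`, censored samples `ln F(10⁶/N_i)`. Optimized with
  Nelder–Mead from the detected-sample moments (tolerance 1e-8, ≤ 10⁴
  evaluations); standard errors from a central-difference Hessian.
  This estimator treats the observed ppm of a detected sample as the
  concentration itself, which is accurate when depths are large relative
  to `10⁶/c` — at the emulated plasma depths (0.94 M–12.8 M reads) it
  recovers (mu, sigma) within ±0.15 in ≥ 90% of 903-sample studies. At
  depths two orders of magnitude smaller the one-read quantization
  (1 read = 10–100 ppm) breaks that approximation and no estimator of
  this form is consistent; the validation studies therefore run at the
  realistic depths, which costs nothing since only the latent layer is
  simulated.
* **CDF curve fit** (the graphical method, kept for comparability):
  least squares of the log-normal CDF against the empirical cumulative
  fraction computed over *all* samples — a non-detect observes 0 ppm and
  so counts below any positive x — restricted to observations above a
  global cutoff. The natural cutoff is the largest per-sample detection
  limit: above it no observation can have been censored, and the
  censored samples then stand in for exactly the model's below-limit
  mass. With a cutoff below some samples' limits the empirical curve is
  depleted and the fit biases upward.

The **simulation envelope** re-draws the fitted process (log-normal draw,
binomial thinning at the study's actual depths) `n_realizations = 300`
times and takes the pointwise min–max of the empirical CDFs of observed
nonzero ppm (normalized by the full sample count) on a log-spaced grid;
a 2.5–97.5% quantile band is available by flag. The min–max band
contains every realization, so data generated from the fitted model
should fall essentially entirely inside it. Note the band does *not*
shrink to zero width as depths grow: with `n` samples the empirical CDF
always fluctuates on the `√(F(1−F)/n)` scale; deeper sequencing removes
only the censoring distortion.

`predict_nondetect_fraction` evaluates `E_c[(1 − c·10⁻⁶)^N]` per sample
by Gauss–Hermite quadrature (201 nodes) over `ln c`.

## Diet matrix

Cell (s, j) counts distinct reads of subject j whose *best-hit* species
set (fewest total mismatches, all ties) includes s; a read tied across m
species increments m cells. Triage-ambiguous reads (`also_*`) are
excluded by default and includable by flag. Visibility filtering keeps
species rows with total ≥ 50 and subject columns with total ≥ 10
(at-least convention; totals computed on the unfiltered matrix; the two
masks applied jointly, once). Clustering is agglomerative with average
linkage and Euclidean distance on ln(1+count) — conventional choices for
count heatmaps, pinned by test rather than derived; dendrograms export
as Newick.

## Pipeline

Stages run simulate/load → subtract → match → screen → quantify/pileup →
model → cluster. Each stage logs an input/output tally; the per-sample
partition host + plants_only + also_bacteria + also_mammalia + unaligned
= total is asserted in tests. The model stage is skipped (with the reason
recorded) when fewer than 10 samples are detected; clustering is skipped
for matrices smaller than 2×2 after filtering. A `manifest.json` with
versions, seeds and the full configuration makes every run re-derivable;
a failed stage writes a `FAILED` marker naming the stage and leaves
partial outputs in place. Configuration comes from TOML, with CLI flags
overriding config values; exit codes are 0 (success), 2 (config error),
3 (stage failure).

## Validation scale

Test and acceptance workloads are sized for a single desktop CPU: oracle
equivalence on 10–20 kb panels with 300–1000 reads; read-level studies of
3–16 samples at depths of a few hundred to a few thousand reads;
latent-level model studies at the full 903-sample, 0.94 M–12.8 M-read
scale (no reads are generated there, so realistic depths are free). The
full suite runs in under two minutes; the acceptance script in about one.

## Known limitations

* The seed index is a plain hash map — appropriate for desk-scale panels,
  not for gigabase genomes (no FM-index).
* No indel handling; a true foreign read with an indel is lost.
* Family labels carry no sequence signal in synthetic panels, so
  cluster-recovery tests validate the counting and clustering chain, not
  the ability to resolve real phylogenetic relatedness.
* The censored MLE ignores binomial observation noise on detected
  samples; see above for when that matters.
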