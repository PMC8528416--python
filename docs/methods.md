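# Methods

This note documents the models and procedures `secircuit` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Coverage model

Aligned reads are reduced to 5′ positions, artificially extended to a fixed
fragment length (default 200 bp) in the strand direction, clipped at
chromosome ends, and accumulated into fixed-width bins (default 50 bp) tiling
each chromosome from coordinate 0; a read contributes 1 to every bin it
overlaps by at least one base. Depth normalization divides bins by millions
of mapped reads (RPM). All coordinates are internally 0-based half-open; BED,
narrowPeak and bedGraph are native, fixedStep WIG (1-based) is converted on
I/O, and exclusion-region config strings (`chrom:start-end`) are read as
1-based inclusive, genome-browser style. The 1-bp ambiguity this introduces
for externally quoted exclusion coordinates is irrelevant in practice because
exclusion acts at whole-peak granularity ("contact" = ≥ 1 bp overlap).

Region signal is the bin-value sum weighted by each bin's overlap fraction —
an integral in track-unit · bin units that is additive over any partition of
the region. Where regions of different lengths are compared against a fixed
floor (enrichment calls), the per-bin mean density (signal / width in bins)
is used instead, so the floor is length-invariant.

## Peak calling (plumbing)

The built-in caller marks bins whose raw count exceeds the smallest k with
P(Poisson(λ) ≥ k) ≤ p, where λ is a supplied background rate or the
genome-wide mean bin count (`auto`); maximal runs of marked bins at least
`min_len_bp` (default 100 bp) long become peaks, scored by mean signal. It is
deliberately minimal — no local background, duplicate handling or shift
model — because its role is to let the pipeline run end-to-end on simulated
tracks; externally called peak files are accepted interchangeably. The
two-stringency convention (strict p = 1e-9 and lenient p = 1e-4, union
collapsed) mirrors the common practice of seeding enhancer stitching with a
union of two caller parameterizations.

## Super-enhancer identification

Peaks fully contained in [TSS − t, TSS + t) of any gene are removed
(t = 1000 bp), survivors are stitched transitively while same-chromosome gaps
are ≤ s (s = 12 500 bp), and stitched regions are ranked by integrated RPM
signal (optionally control-subtracted, floored at 0 per region). With both
axes of the ascending rank-vs-signal curve rescaled to [0, 1], the cutoff is
placed at the point maximizing x − y — for a convex curve, the point where
the slope equals 1 — and regions strictly above the cutoff signal are
super-enhancers. Ties at the argmax break toward the higher signal (fewer
super-enhancers — conservative). The classification is invariant to positive
rescaling of all signals.

Numerical/degenerate choices:

* A flat curve (all signals equal) yields zero super-enhancers with a logged
  warning. A two-valued step curve is *not* treated as degenerate: its
  tangent point sits at the lower plateau, which is exactly what makes
  noiseless synthetic data (two signal levels: typical and super) recoverable.
* The cutoff is an order statistic of the observed signals, so the number of
  super-enhancer calls is *not* monotone under inserting equal-signal
  regions: inserting regions compresses the rank axis and can move the argmax
  to a lower-signal point. This is a property of the tangent rule itself, not
  of the implementation; the test suite asserts the properties that do hold
  (scale invariance, the closed-form tangent point of y = x⁴ at
  x = (1/4)^(1/3), and the flat-curve limit).
* Control subtraction is optional; both modes are supported.

## Expression proxy and gene assignment

A gene is "expressed" in a sample when its promoter coverage — RPM region
signal over [TSS − 500, TSS + 500) — is in the top two-thirds of all genes.
Concretely the threshold is the coverage at ascending rank ⌊n/3⌋ and ties at
the boundary are expressed, so at least ⌈2n/3⌉ genes qualify. Each enhancer
is assigned to the expressed gene minimizing |TSS − center|, with the
enhancer center the floor midpoint and equidistant ties going to the leftmost
TSS; chromosomes with no expressed gene yield an explicit non-assignment.
Single-sample analyses use that sample's expressed set; the differential
analysis uses the union of per-sample expressed sets ("expressed in any
sample"), mirroring the two distinct conventions of the workflow.

## Differential landscape

Super-enhancer regions identified separately per sample are overlap-merged
into one collapsed union. Per region and sample, RPM coverage is averaged
within each condition and compared as log₂((B + c)/(A + c)) with pseudocount
c = 1 RPM-unit per region (stabilizes empty regions: 0-vs-0 gives exactly 0,
never NaN). Status is gained when log₂FC ≥ log₂(f), lost when ≤ −log₂(f),
else stable, with f = 2 by default. The underlying experiment classifies the
scatter visually, so f is an explicit knob rather than a reproduced value;
swapping condition labels maps gained ↔ lost exactly.

## Occupancy matrix and circuit inference

A region is *enriched* for a target when its per-bin RPM density is ≥
`min_fold` (default 3) times the IgG control density, the control density
floored at 0.5 RPM per bin to keep near-empty controls from inflating ratios.
The source experiments state no numeric enrichment rule, so both knobs are
explicit configuration. The occupancy matrix keeps candidate regions enriched
for at least one non-control target and orders rows by descending integrated
H3K27ac.

A candidate TF is admissible in a condition when its gene is expressed there
and has at least one assigned super-enhancer. Edge i → j exists when TF i's
track is enriched at any super-enhancer assigned to TF j (multiple assigned
super-enhancers aggregate by "enriched at any"). The circuit is the largest
admissible set forming a complete directed subgraph including self-loops —
every member binds its own and every other member's super-enhancer. Because a
complete directed subgraph corresponds to a clique of the undirected
mutual-edge graph over self-loop nodes, and candidate sets are small (single
digits to low tens), membership is computed by exact clique enumeration
rather than a greedy heuristic; ties between equally large circuits break to
the lexicographically smallest member set, making inference deterministic. A
relaxed mode (every member bound by ≥ k members, iterative pruning) is
available as a configuration option. Cross-condition comparison reports
shared / lost / gained member sets and is symmetric under label swap.

## Spike-in expression analysis

Size factors are the median, over spike-in rows with nonzero counts in every
sample, of count / geometric-mean-across-samples, then rescaled so the
*median sample factor is 1*. The rescaling anchors the unperturbed majority
of samples: a sample whose counts are uniformly doubled receives a factor of
exactly 2, and normalized counts are invariant to per-sample rescaling
whenever a majority of samples is unperturbed (raw median-of-ratios factors
satisfy neither property, because the geometric-mean pseudo-reference itself
absorbs part of any single-sample scaling). TPM is computed as
rate = count/length, TPM = rate · 10⁶ / Σrates with spike-in rows excluded
from the denominator so TPM reflects the biological transcriptome; biological
TPM columns sum to 10⁶. Fold changes are computed on spike-in-scaled counts
with pseudocount 0.5 normalized counts, and the fold-change distribution is
restricted to highly expressed genes by the strict filter
base-mean TPM > 10. Differential-expression test statistics (dispersion
modeling, p-values) are out of scope: the analysis reports fold-change
distributions. Because spike-ins are added per cell, their factors track
sequencing depth but not biology, which is what lets a global transcriptome
shift survive normalization — library-size factors cancel it identically.

## Synthetic data generator

The generator emulates a two-condition regulatory study on a small genome:

* **Genome**: 2 chromosomes × 5 Mb, 60 genes at 150 kb spacing, 50-bp bins.
* **Enhancer geometry**: per gene, five 1-kb typical enhancers (stable across
  conditions, per-bin Poisson mean 5) placed ≥ 19 kb apart so nothing
  stitches across planted units; 30 genes host a super-enhancer cluster of
  three 1.5-kb constituents with 4-kb gaps (within stitch range; per-bin
  mean 20) starting 5 kb downstream of the TSS, so the nearest expressed TSS
  is the host's.
* **Condition structure**: 10 host genes lose their super-enhancer on
  treatment, 10 gain one, 10 keep it. Decommissioned/de novo regions drop
  to/rise from flat background rather than a partial remnant, matching the
  near-complete acetylation loss observed at decommissioned loci and keeping
  per-condition truth well defined. Expressed genes (promoter blocks, per-bin
  mean 10 over TSS ± 500 bp) are the 40 genes per condition whose state is
  active there; the remaining third are silent.
* **Circuit**: six candidate TFs (two lost, two gained, two stable hosts);
  each condition's four members bind their own and each other's
  super-enhancer spans at per-bin mean 15; non-members and IgG are flat
  background (mean 0.2).
* **Noise**: bin counts ~ Poisson(intensity × exposure), exposure 1 by
  default; an exact-mean mode replaces draws with rounded means for
  noiseless oracle tests. mapped_reads is the total bin count.
* **Expression**: 1000 biological genes (log-normal base means around 200),
  40 spike-ins, 3 replicates per condition with per-sample depths uniform in
  [0.8, 1.2]; 100 planted genes at 4× down-regulation, lost/gained TF genes
  at 8× down/up, and an optional global shift multiplying every biological
  gene in the treated condition while spike-ins see only depth.

Everything derives from a single seeded generator, so equal seeds give
byte-identical outputs. Features of real data deliberately *not* emulated:
sequence-level reads (FASTQ), fragment-size and GC bias, copy-number
structure, replicate structure for coverage tracks, repressive-mark
(H3K27me3) tracks (no in-scope computation consumes them), and biological
dispersion beyond Poisson counting noise. Passing recovery tests therefore
demonstrate correctness of the algorithms under the stated statistical
structure, not robustness to every artifact of real sequencing data.

## Problem sizes and defaults

End-to-end recovery studies use 20 independent seeds of the default design
(~1 s per study), the oracle-equivalence suites use ≥ 200 random small
instances per operation, and the spike-in head-to-head uses five studies of
1000 genes; these sizes give stable estimates while keeping the whole suite
fast. Key defaults: bin 50 bp, extension 200 bp, stitch 12 500 bp, TSS
exclusion 1000 bp, promoter ± 500 bp, expressed = top two-thirds, fold
threshold 2, differential pseudocount 1, enrichment fold 3 with floor 0.5
RPM/bin, expression pseudocount 0.5, TPM filter 10, exclusion region
`chr2:14817188-17228298`.

## Known limitations

* The peak caller is plumbing; for real data, use a dedicated caller and feed
  the peaks in.
* Enrichment thresholds, the differential fold threshold, and both
  pseudocounts are conventions, not estimated quantities; conclusions
  sensitive to them should be checked across settings.
* Super-enhancer counts from the tangent rule are sensitive to the shape of
  the typical-enhancer plateau (see the non-monotonicity note above).
* The expression module assumes spike-ins were added proportionally to cell
  number; factors inherit any pipetting/cell-count error.
* Gene assignment is proximity-based; contact-based (Hi-C) assignment is out
  of scope.
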