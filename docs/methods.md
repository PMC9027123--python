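# Methods

## Coordinate conventions

All intervals are 0-based half-open (BED). GTF input is shifted to
half-open on read. Chromosome names match literally — no "chr"
aliasing. Overlap requires ≥ 1 shared bp by default (configurable);
half-open abutment is not overlap. `merge(max_gap)` coalesces
transitively whenever `next.start − prev.end ≤ max_gap`, so a gap of
exactly the threshold merges. `nearest` distance is 0 for any overlap,
else the gap between closest edges; ties resolve to the subject with
the smaller start, with all tied subjects reported.

## Island calling

The genome is tiled from position 0 in fixed windows; a tag at
position p belongs to window ⌊p/w⌋. Two modes:

| mode | window | gap | island cutoff | use |
|---|---|---|---|---|
| broad | 200 bp | 600 bp | 1e−5 (H3K27ac-like) / 1e−10 (other marks) | histone marks |
| narrow | 50 bp | 0 | 1e−5 | transcription factors |

Standard calls (condition vs sequencing input) use a Poisson model.
The per-window rate is `(max(c_w, local_mean) + pseudocount) · s` where
`c_w` is the input count, `local_mean` averages the input over 1 kb
centred on the window (truncated at chromosome ends), the pseudocount
is 0.25 tags/window, and `s` is the ratio of treatment to input library
size. Taking the max of the window's own count and its neighbourhood
mean is the usual local-lambda guard: a control window that randomly
dips below its surroundings cannot manufacture an enrichment. A window
with at least one tag is eligible when its Poisson upper-tail p is
below 0.01 (the pre-aggregation threshold; the two-stage structure
follows window/gap island callers). Eligible windows are merged across
gaps up to the mode's gap parameter; each island is then re-scored as a
whole — count and expectation summed over every window in its span —
and kept only if the island-level Poisson upper tail beats the cutoff.

### Differential (condition-vs-condition) calls

Swapping the other condition in as the "control" changes the
statistical situation: that control is now itself a noisy sample
carrying real peaks, and three failure modes appear at strongly and
*equally* occupied sites if the standard machinery is reused verbatim:

1. a fixed-λ Poisson treats every downward fluctuation of the control
   as a real deficit;
2. total-count library scaling includes each condition's signal mass,
   biasing the expected proportion wherever occupancy does not scale
   with depth;
3. window selection before island scoring cherry-picks the windows
   where the treatment fluctuated high and the control low.

Differential mode therefore (i) scores windows and islands with the
conditional binomial test — under equal rates, t | t+c ~
Binomial(t + c, r/(1+r)) — the exact two-sample Poisson comparison;
(ii) estimates the depth ratio r from background windows only (windows
where neither sample exceeds 5× its genome-wide mean + 3), the
background-normalization idea standard in differential binding
analysis; and (iii) requires an island to contain at least two
eligible windows, since a single-window differential call is
indistinguishable from shot noise while any genuine occupancy change
spans at least a fragment length. Standard calls keep the plain
Poisson/total-scaling behaviour. Under the simulator's study
conditions the corrected differential caller recovers planted
gained/lost/stable classes exactly (30/30 seeds tested during
development), where the verbatim reuse of the standard machinery
produced a handful of spurious differential islands per run.

### Classification

DECREASE = control standard peaks overlapping a control-over-kd
differential peak; INCREASE = knockdown standard peaks overlapping a
kd-over-control differential peak; COMMON = control standard peaks
overlapping a knockdown standard peak (the control interval is
reported). If overlapping regions qualify for both differential
classes, the class whose differential peak covers more bp wins; exact
ties are flagged and dropped, so INCREASE and DECREASE never overlap.

## Annotation

Gene region: 1 kb upstream of the TSS through the TES, strand-aware,
clipped at chromosome bounds. TSS region: TSS ± 1 kb. A peak is
credited to *every* gene whose gene or TSS region it overlaps (no
winner-takes-all); peaks overlapping neither region of any gene are
dropped. The membership table does not distinguish the two rules in
the class column, but a provenance column records which fired.

## Expression integration

Significance: padj < 0.05 **and** |log2FC| > 0.58, both strict;
missing padj is never significant. "Repressed" genes are upregulated
after knockdown, "activated" genes downregulated. The six-way
comparison of two knockdown datasets requires concordant significant
change in both tables for the core categories and significance in one
with absence of that direction's significant change in the other for
the "X-not-Y" categories; genes significant in opposite directions
carry both applicable "not" labels in the boolean columns and are
marked `discordant` in the single-label column. The heatmap matrix
includes genes with padj < 0.05 in at least one table and zeroes any
cell with padj > 0.05 or |log2FC| < 0.58; rows are ordered by
descending first-column value (deterministic, no clustering), so the
matrix never contains a cell with 0 < |value| < 0.58.

## Permutation test

Basic set: significantly downregulated genes (padj < 0.05,
log2FC < −0.58) with a differential Smarca4 membership, split into
D(ECREASE) and I(NCREASE) groups; a gene carrying both memberships via
distinct peaks goes to the class with more supporting peaks and is
excluded on a tie. For each antibody × peak-class combination with k
signal-carrying genes among the N basic-set genes, each of B shuffles
places the k labels uniformly without replacement and counts the
D-side total — a Hypergeometric(N, k, n_D) draw, sampled directly once
per shuffle, independent across shuffles. Empirical tails use add-one
smoothing, p = (#{as-or-more-extreme} + 1)/(B + 1), so p > 0 always;
the two-sided p is min(1, 2·min(tails)). Direction is the sign of
x_obs − k·n_D/N. Tiers: *significant* when the smaller tail is at or
below tail_alpha/m (tail_alpha = 0.025, Bonferroni m = number of
combinations actually tested, recorded in the output); *highly
significant* when the observation lies strictly outside every shuffle
(the p < 1/(B+1) regime). One null sample serves both partitions of a
combination, which makes the I-group result the exact mirror
(x′ = k − x, identical two-sided p) of the D-group result.

## Enhancers

Anchors (1 bp; wider intervals centre-collapse) extend to 3001 bp
centred intervals — [c−1500, c+1501) — flagged when clipped at a
chromosome edge; an even target length is rejected as centreless.
Binding fractions are bound/total per peak set, with the integer
numerator and denominator reported alongside. Linkage uses nearest
gene-body distance with a 100 kb cap ("100.000 bp" in the source
convention = 10⁵ bp, consistent with "1.000.000" shuffles = 10⁶).
Enhancers overlapping gene bodies are retained. The per-class
expression summary reports up/down fractions over linked significant
genes and NaN when none is linked, next to the analogous gene-region
summary from the membership table.

## Profiles

Coverage matrices count 1 bp tags at each offset −2500..+2500 relative
to peak centres (interval midpoints, rounded down); out-of-bounds
offsets simply collect zero. Column means are smoothed with LOESS
(statsmodels lowess: local-linear, tricube weights), span 0.3 by
default — the span/degree were an open choice; local-linear was chosen
because it reproduces constant and exactly linear profiles unchanged,
which the tests pin to 1e−9.

## Synthetic data

The generator emulates the data shapes the pipeline consumes, not
sequencing itself (no reads, fragments, mappability or duplicates).

* **Genome**: two 1.6 Mb chromosomes, 200 genes of 1.5–3 kb placed
  constructively with ≥ 12 kb spacing (so neighbouring TSS enrichment
  windows can never fuse into one island), uniform random strand.
* **Tags**: homogeneous Poisson background at 0.008 tags/bp (the
  density of ~20 M single reads on a mouse-sized genome) plus
  fold-elevated rate over a 1 kb window centred on the TSS of every
  occupied gene (anchor of every bound enhancer, Smarca4 track only);
  default fold 50. `stable` genes are occupied in both conditions,
  `gained` only after knockdown, `lost` only in control; input carries
  background only.
* **Truth coupling**: Smarca4 classes drawn at
  none/stable/gained/lost = 0.45/0.25/0.15/0.15; `lost` genes are
  downregulated, `gained` genes upregulated with probability 0.7 and
  otherwise downregulated (the "repressed despite more binding"
  group). Activating marks (H3K27ac, H3K4me3) follow the expression
  direction and repressive ones (Ezh2, H3K27me3) oppose it, except in
  the down-with-Smarca4-gain group where the pattern flips — giving the
  permutation test a real contrast between basic-set partitions.
  Enhancer binding derives from the target gene: down → control-only,
  up → kd-only, neutral → both/neither.
* **Expression table**: planted genes get log2FC = ±2.0 + N(0, 0.2)
  and padj ~ U(0, 0.05); nulls get log2FC ~ N(0, 0.2) and
  padj ~ U(0.05, 1). P-values are assigned by class, not fitted from
  counts: only the filter semantics matter downstream. The requested
  tag budget is set through `background_rate` × genome size rather
  than an explicit total-count knob.
* **Enhancer placement**: each anchor sits 3–5.5 kb left of a dedicated
  gene's padded region, with the distance capped at half the upstream
  gap minus 1.2 kb so the target is strictly its nearest gene and the
  3001 bp extension clears both neighbouring gene regions.

What passing recovery tests therefore show: the pipeline's logic is
exact on clean, strongly separated signals. What they do not show:
robustness to fragment-length artefacts, copy-number or mappability
biases, antibody efficiency differences, or marginal fold changes —
real-data properties the generator deliberately omits.

## Determinism and problem sizes

A single run seed expands through `numpy.random.SeedSequence` into one
sub-seed per stochastic stage (all < 2³¹, recorded in the manifest);
reruns are byte-identical. The pipeline default of 10⁵ shuffles per
permutation combination (the `PermutationConfig` default is 10⁶, the
published setting) and the test suite's toy genomes (≤ 1.6 Mb, ≤ 50 kb
for brute-force oracles) are the package's chosen working sizes; every
statistic scales to larger inputs without code changes.

## Known limitations

* The island caller approximates both a MACS2-like narrow caller and a
  SICER-like broad caller with one window/gap machinery; it does not
  build fragment models or compute FDR-corrected island scores.
* Whether the island-level filter should use raw or FDR-adjusted p is
  an open question in the source procedure; raw island p is used
  (configurable cutoff).
* Gene-id merging is by exact string; no symbol-alias resolution.
* Enhancer catalogues are taken as given (no enhancer calling or
  super-enhancer stitching); coordinate lift-over between assemblies
  is out of scope.
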