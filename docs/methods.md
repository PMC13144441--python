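# Methods

## Scope and coordinate model

All per-family analysis happens in consensus coordinates. The projection of
a genomic position `g` inside a copy `[start, end)` is `g − start` on the
plus strand and `(end − 1) − g` on the minus strand; it is a bijection
between each copy and `[0, L)` (L = consensus length) and is therefore only
defined for copies whose length equals L. This is why the intactness rule
(length within `tolerance_bp` of the consensus length; default tolerance
0 bp, exposed as `--intact-tolerance`) is a precondition rather than a
quality filter: for a full-length copy a linear offset is an exact
alignment, while fragmented copies would need per-copy realignment, which
this package deliberately does not attempt. Real RepeatMasker annotations
fragment single insertions; users of fragmented annotations should either
raise the tolerance or merge fragments upstream. All internal coordinates
are 0-based half-open; strand "." in input is treated as "+" with a
warning.

L1-style elements are handled through their 5'UTR monomers: the monomer
consensus is scanned against the genome on both strands by Hamming
distance (default `max_mismatches` 2), and each accepted window becomes a
copy of a designated monomer family. Hamming rather than gapped alignment
keeps the scan exact and oracle-checkable; at desk scale this replaces a
read-aligner-based mapping step, and users with precomputed monomer BEDs
can supply them directly. Overlapping same-strand hits keep the
lower-distance window (ties leftmost).

## Insertion tracks and meta-profiles

Fragments are converted to cut sites as `start + 4` and `end − 1 − 5`
(the standard ATAC +4/−5 convention, both shifts exposed); single-base
insertion BEDs are accepted as-is. Library size is the genome-wide event
total — not the in-element total — so per-million profiles from the same
library are comparable across families and duplicating every fragment
leaves normalized profiles unchanged exactly. A cut belongs to an element
iff its position is in `[start, end)`. Duplicate removal and
mitochondrial filtering are upstream concerns; the track model assumes
pre-filtered input.

The raw meta-profile entry at consensus position `p` is the number of cuts
projecting to `p` over all intact copies; its sum equals the number of
in-element cuts (a conservation law asserted in the tests), and profiles
built copy-by-copy and summed equal the one-pass profile.

## Footprint statistic and caller

Published footprint identification on such profiles is visual. To make it
reproducible the package defines the depletion score
`D = (m_flank − m_center) / m_flank` (D = 0 by convention when
`m_flank = 0`) and a run-based caller on the smoothed per-million profile:

1. smooth with a centred moving average (window 3, edge-truncated);
2. flag positions whose value is below `(1 − d_min)` times the local flank
   mean — the mean over the surrounding ±F positions excluding the
   position itself (F = 25 bp), recomputed locally rather than globally so
   the rule is "relative to the flanking regions";
3. take maximal flagged runs, merge runs separated by less than
   `w_min / 2`, keep widths in `[w_min, w_max]` = [6, 30] bp and flank
   mean ≥ `c_min` = 0.5 per million; score with D; number left to right.

The statistic is a ratio, so calls and scores are invariant to scaling the
profile by any k > 0, and the rule is symmetric under profile reversal.
Defaults were chosen once for 6–30 bp TF footprints on the synthetic
calibration data and are all exposed in `FootprintCallParams`. The
depletion depth of real footprints is not quantified in the literature
this models; the synthetic protection factor ρ is likewise a calibration
choice, not an empirical value.

Footprints are called per stage and unified across stages: intervals with
≥ 50% reciprocal overlap merge into their union, D is recomputed per stage
on the unified interval, and the stage-specificity label is the set of
stages with `D ≥ d_min`. Sequences under (padded, clipped) footprints are
extracted from the consensus in both orientations because a motif may lie
on either strand.

## Motif matching

Footprint sequences become near-one-hot position frequency matrices
(`(one_hot + c) / (1 + 4c)`, pseudocount c = 0.1; ambiguity codes give
uniform columns). Alignment to a library PWM is ungapped over all integer
offsets with ≥ `min_overlap` = 4 aligned columns; the score is the mean
per-query-column Euclidean distance, with query columns overhanging the
target compared to the uniform column (0.25, 0.25, 0.25, 0.25). Overhang
penalization (rather than truncation) suppresses spurious partial
overlaps; the per-column mean makes scores comparable across motif widths.
Ties break by smaller |offset|, then negative offset, then plus strand.

The analytic null of the classical motif-comparison tool is replaced by a
permutation null: pseudo-targets of the target's width are drawn
column-wise with replacement from the pooled columns of the whole library
and aligned to the query; `p = (1 + #{null ≤ d*}) / (n_perm + 1)` with
n_perm = 999. This estimator is exactly calibratable (random queries
against a decoy library give uniform p-values, asserted by KS test) and
monotone in d*. Because the null depends on the target only through its
width, one null set per (query, width) serves every motif of that width —
an exact optimization. The null stream is seeded from the user seed and a
CRC of the query sequence, so the same sequence always receives the same
null regardless of scan order or strand labelling. `E = p ×
(number of library motifs)`; matches with `E < 30` are retained, computed
per (footprint-strand, motif) pair. E-values near the threshold are
sensitive to n_perm granularity; the threshold is deliberately loose and
the downstream expression filter carries the real specificity burden.

## Candidates

The expression filter applies to **raw** counts (≥ 2 reads in every mid-
and late-2-cell cell), while reported expression values are per-million
normalized; this asymmetry is intentional and documented because the two
operations are easy to conflate. No multiple-testing correction is applied
at the candidate stage — the E threshold and the expression rule are the
only filters. Per-family TF lists are unions over footprints, strands and
motifs; the merged list is the union over families, with Venn-region
counts computed by exclusive membership (they sum to the union size).
Family expression summaries sum per-embryo rpm over all insertions of the
family, optionally divided by per-embryo ERCC spike-in factors, with
per-stage means as the developmental trend line.

## Binding integration

bedGraph is the canonical track format (textual, diffable, testable);
bigWig support is intentionally out of the core. Bin values in both matrix
geometries are length-weighted mean coverage with gaps counting as zero
and fractional-base overlap at non-integer body-bin edges; bins upstream of
position 0 are zero-filled and the row flagged. Mean (not sum) per bin and
zero-fill are this package's documented choices where the upstream
convention is ambiguous. "Bound" rank uses the full row sum of the
scale-regions matrix; the top `⌈fraction × n⌉` rows (default 0.25) are
bound, ties keeping input order. TSS-to-insertion distance is the gap to
the half-open interval (0 inside), inclusive at the window boundary
(10 000 bp is in). The group comparison is a two-sided unpaired t-test,
Welch by default because group variances are unmodelled, with a
pooled-variance flag.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of the real inputs: a genome with
planted full-length and 3'-truncated copies (mutated i.i.d. at 2% per base
except at planted sites, which are never mutated), staged insertion data
(relative rate 1 in background, 20× inside elements, ×ρ inside occupied
sites; Poisson per position scaled to the stage depth), a motif library of
planted site motifs (peak probability 0.85) among Dirichlet(0.5) decoys,
and an expression matrix where planted TFs draw Poisson(10) in mid/late-2C
cells (rejection-resampled to guarantee ≥ 2; Poisson(10) already puts
P(count < 2) below 1e-3) and decoys Poisson(1). The standard study
conditions (`default_config`): two 300-bp families, 50 intact + 10
truncated copies each, five planted 14–15 bp sites, ρ = 0.15,
~15 000 insertions per stage (≈ 0.4/bp/copy in elements, i.e. ≈ 20/bp
aggregated over 50 copies), 30 library motifs. It does **not** model
sequence-dependent Tn5 bias, sequencing error, duplicates, nucleosomes, or
copy-specific chromatin: passing tests demonstrate correctness of the
pipeline's arithmetic and decision rules under the stated generative
model, not robustness to those real-data confounders.

Insertion events are generated directly as cut sites (the pipeline's
native unit); a converter pairs consecutive cuts into a BEDPE dialect
whose two blocks are the two cut bases, so fragment input under zero
shifts reproduces the cut-site track exactly. Because each fragment
carries two cuts, a stage with an odd Poisson total drops one uniformly
chosen event — a negligible perturbation that preserves the ρ = 0
exactness (dropping cannot add in-site events).

Determinism: every generator stage draws from `default_rng([seed, k])`
with a fixed stream id k, so identical configs give byte-identical files;
all file writers use fixed formats and orders. MEME output prints each row
with the last value as the complement of the first three at 6 decimals, so
the printed row sums to exactly 1.000000 and parse → renormalize → rewrite
is byte-stable.

## Problem sizes and numerical choices

The test suite and the acceptance script run the standard conditions above
(120 kb genome, 3 stages × ~15 000 events, 30 motifs, 999 permutations),
chosen as the smallest sizes at which aggregated profiles reach the
~20 insertions/bp regime where footprints of this depth are
unambiguous. Degenerate inputs are defined rather than crashed on:
`m_flank = 0 ⇒ D = 0`, empty candidate lists and empty match sets are
valid results, all-N footprints become uniform queries. Known limitations:
no per-copy realignment (fragmented annotations need pre-merging), no
gapped motif alignment, footprint boundaries inflate by roughly the
smoothing half-window, and the permutation E-value is not numerically
comparable to the analytic E-value of the classical tool even though the
same E < 30 retention rule is applied.
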