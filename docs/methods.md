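# Methods notes

## Scope and data model

`mirspot` analyses single-channel spotted miRNA arrays starting from the
extracted spot table (array id, probe id, replicate index, foreground and
background medians, quality flag) — image quantification is upstream of
the package. Probe annotations classify every spot as human, negative
control, spike-in, specificity control (perfect match / mismatch /
shuffled) or blank. Intensity matrices carry a processing-stage label that
may only advance along `raw → log2 → normalized → averaged → detected`,
which catches stage-order mistakes at run time.

## Pre-processing

* **Background subtraction** is median foreground minus median local
  background and may be non-positive; before the log2 transform values are
  floored at a configurable positive raw unit (default 1), so a fully
  background-dominated spot maps to log2 = 0 rather than −∞. The source
  workflow does not state its floor; ours is explicit and configurable.
* **TPT95** is the 95th percentile of an array's unflagged
  negative-control spot intensities. The percentile convention is nearest
  rank (`index = ceil(0.95 n)`) applied on the raw scale, then
  log2-transformed — deterministic and checkable against a brute-force
  sort-and-count oracle. Flagged negative controls are excluded, by
  symmetry with the flagged-spot omission rule used in averaging.
* **Normalization-probe qualification** works on triplicate-mean log2
  probe intensities: strictly above `TPT95 + margin` (margin default 1) in
  *every* array, across-array sample SD (n−1) strictly below 1.25. Both
  boundaries are exclusive, matching the "one log2 unit above" / "less
  than 1.25" phrasing of the protocol. Note that probes with modest true
  group effects (|Δ| ≈ 1) can pass the SD cutoff, making the factors
  weakly group-dependent; effects of ≥ 2 log2 units are excluded by the
  SD rule (SD = 0.87·|Δ| for a balanced three-group design).
* **The factor** `N_a` is the 20% trimmed mean with `floor(0.2 n)` values
  removed from *each* tail (the common per-tail convention; the protocol
  says only "20% trimmed mean"). Correction is `x − N_a + mean(N)`:
  a per-array additive constant, so all within-array contrasts are
  preserved exactly and the matrix as a whole moves by at most one global
  constant. Detection thresholds are shifted by the same per-array
  constants before the detection filter so both sides stay on one scale.
* **Averaging and detection.** Triplicates are averaged after dropping
  flagged spots; a probe whose replicates are all flagged becomes missing.
  Detection keeps probes strictly above `TPT95 + 1` in at least
  `ceil(0.10 K)` of the `K` arrays.
* The source analysis reports 729 detectable probes in clustering but 623
  in its differential-expression panel without explaining the difference;
  the pipeline exposes the detection filter's output and lets the caller
  run DE on any detected matrix, resolving nothing it cannot know.

## Differential expression

A pure fold-change rule: the contrast of group means of available values
must reach 1 log2 unit (inclusive — "at least 2-fold"). No variance or
multiple-testing machinery is applied, faithfully to the original design;
probes lacking a group mean are excluded and reported, not treated as
infinite fold changes.

## Clustering

Median-centered rows, centered Pearson correlation over pairwise-complete
positions (the Cluster 3.0 behaviour for missing values), unweighted
average linkage on `d = 1 − r`. Cluster-cluster similarity is maintained
as sums and counts of *defined* leaf-pair similarities, which reproduces
the plain mean while letting undefined (zero-variance) pairs drop out of
the average; a pair with no defined similarity at all joins last. Ties are
broken by the smallest (older, newer) cluster-id pair, and the similarity
matrix is symmetrized exactly (`(S + Sᵀ)/2`) so tie detection by equality
is well defined. Internal nodes list the older cluster first; the leaf
order follows. GTR files record the correlation at each join, which is
non-increasing (UPGMA reducibility); CDT rows follow the tree's leaf
order. No optimal leaf ordering is attempted.

## Enrichment

Association relations carry an evidence level
(`experimentally_observed > high_confidence_predicted > predicted`); the
stringent filter keeps relations at or above the requested level. Gene
symbols are upper-cased and trimmed; composite symbols ("IFNA1/IFNA13")
count as one gene but map into the universe on either token. The binomial
test uses `p = K_ref/N_ref`; the reported tail follows the direction of
`k_obs` against the expectation `n·p`, and Bonferroni multiplies by the
family size. The packaged reference sets `N_ref = 20,800` — back-derived
from the published expected counts (e.g. 78·97/20800 = 0.364) and
consistent across all six categories — and `family_size = 6`, the
packaged category family; the original tool's exact multiplier is not
recoverable, so published p-values are not asserted anywhere. The packaged
category memberships are synthetic stand-ins assigned by biological role
to match the published per-category counts, as are the three
unmappable-gene designations and the one filler relation that brings
miR-146a-5p to its published count of 47 (the printed gene list has 46
entries; the filler duplicates TNF so that 82 relations cover 81 unique
genes, as published).

## qPCR

Technical replicates are averaged per (sample, assay) before ΔCt, ΔΔCt is
taken between group means of per-sample ΔCt, and `FC = 2^−ΔΔCt`. The
t-test is the pooled-variance Student form (the default unpaired test of
the original software); zero pooled variance with unequal means is
reported as an infinite statistic with `p = 0` and a `degenerate` flag
rather than an exception.

## Synthetic data

The generator emulates the platform: 1209 human probes × 3 replicates,
96 negative controls, 11 spikes, 3 specificity sets, blanks padding each
array to 8816 features; three arrays per group for control /
overexpression / underexpression. The protocol text mentions 20 arrays in
passing, but describes biological triplicates of three groups; the
generator follows the design (9 arrays). Signal is additive on the log2
scale — `baseline + array offset + group effect + N(0, noise_sd)` — with
raw intensity `2^log2` plus an additive background draw, emitted so that
background subtraction recovers the signal exactly. Undetectable probes
sit at the negative-control location; negative controls keep their own
spread (log2 SD 0.5) even in "zero-noise" configurations so TPT95 is
well defined. Defaults are chosen once as realistic for this platform
class and are not fitted to anything: baselines uniform on 9–13 log2,
negative controls N(6, 0.5), background N(100, 10) raw units, array
offsets N(0, 0.3), replicate noise 0.25 log2 units, flag probability 1%,
729 detectable probes, 27 planted effects of 1–2.5 log2 units (opposite
sign in the under-expression group). Every generator is a pure function
of its configuration including the seed.

What zero-noise recovery does and does not establish: it verifies the
pipeline's algebra (thresholding, normalization cancellation, averaging,
fold-change calls) exactly, but says nothing about robustness to spatial
artifacts, intensity-dependent dye effects or heavy-tailed noise, none of
which the generator emulates. The Ct generator similarly plants a known
fold change around a U6-like reference (mean Ct 20, control ΔCt 4 cycles,
4 samples per group × 3 technical replicates, noise 0.1 cycles by
default) — values typical of miRNA qRT-PCR practice, not fitted to data.

## Numerical and design choices

* Percentile, trim and "at least 10%" conventions are as above;
  `min_fraction` uses `ceil`.
* Detection/qualification comparisons are strict (`>`, `<`); the DE
  threshold is inclusive (`≥`).
* Normalization-contrast preservation is asserted to 1e−9; UPGMA join
  monotonicity to 1e−9.
* The pipeline orchestrator writes a JSON manifest (parameters, input
  SHA-256 checksums, stage outputs); stage failures abort with the stage
  named, retaining partial outputs and a `failed_stage` marker.
* There is no command-line interface by design: the public API plus the
  `examples/` scripts are the interface, and `mirspot.pipeline` provides
  the one-call orchestration a CLI would wrap.

## Known limitations

* The 623- vs 729-probe panel discrepancy in the source workflow is
  surfaced, not resolved.
* Enrichment p-values depend on a family-size constant the original
  analysis did not publish; only counts, expected values and percentages
  are comparable.
* No amplification-efficiency correction (Pfaffl) in qPCR; no
  quantile/loess alternatives in normalization; arrays (columns) are not
  clustered.
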