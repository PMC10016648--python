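# Methods

This note documents the models, parameter choices and numerical decisions
behind `orthoflow`, and what the synthetic-data experiments do and do not
demonstrate about real measurements.

## Internal-standard genome size estimation

A flow-cytometry run of co-processed sample and standard nuclei is modelled
as a binned mixture: two Gaussian G0/G1 peaks plus an optional debris
background. Because genome size is estimated from the *ratio* of peak
positions, all gain-like distortions cancel; the estimator is exactly
linear in the sample peak position and invariant to rescaling both peaks
(tested as a property).

Peak fitting proceeds in three steps: a centered moving average (default 5
bins) smooths the counts; local maxima at least `min_height_frac` (default
0.1) of the tallest smoothed bin, and at least ~1 % of the channel range
apart, seed the peaks (the separation floor stops count jitter on one
physical peak from registering twice — two true peaks closer than that are
unresolvable by this design); a Gaussian is then least-squares fitted over
a ±3σ window per peak, windows truncated at the midpoint between adjacent
seeds so they never overlap. Smoothing affects detection only; the fit uses
raw counts. If the optimizer fails, windowed moment estimates are used.
On an exactly discretized Gaussian the fitted mean is within half a bin of
the analytic mean (tested).

Sample-vs-standard identity is **not** inferred from peak order: orthopteran
2C values straddle the pea standard, so the caller supplies the channel
window where instrument gain places the standard (`standard_window`). If no
fitted peak falls in the window the run fails loudly rather than guessing.

QC defaults — CV ≤ 5 % per peak, ≥ 3,000 recorded particles — accept
routine runs (median CVs of 2.31 % for DAPI and 3.81 % for PI; 3,500–5,000
particles) while flagging clearly degraded data. They are parameters, not
gates: flagged measurements are reported, never dropped silently.

Units: 1C = 2C/2 for every specimen regardless of sex (so X0 males simply
yield smaller values, and female−male differences estimate the X
chromosome); 1 pg = 0.978 Gbp.

## Dual-dye GC content

The published workflows compute GC from paired DAPI/PI runs with an
unpublished spreadsheet macro, so the functional form here is the standard
fluorochrome binding-length model: AT-selective dye signal ∝ genome size ×
(AT fraction)^n, intercalating signal ∝ genome size. The quotient of the
two sample/standard ratios then gives
p_s = p_st (r_AT/r_int)^(1/n). The binding length defaults to n = 4
(conventional for DAPI) and is configurable; n = 1 is the linear special
case. Inversion of the forward model is exact to machine precision
(property-tested across GC 20–60 % and n = 1–6). Noisy ratios can push the
raw AT fraction outside (0,1); such estimates are clipped and flagged
`GC_OUT_OF_RANGE` rather than raised, since they are legitimate data.
Specimens measured with the AT-selective dye alone carry only a *relative*
genome size (their signal confounds size with base composition); they are
flagged `RELATIVE` and excluded from GC estimation.

## Comparative statistics

Aggregation: dye replicates are averaged within specimen, then specimens
within species and sex; GC is averaged over all specimens of a species.
Group tests use scipy's implementations behind the module surface:
tie-corrected Kruskal–Wallis H with the chi-square approximation on k−1 df;
two-sided Mann–Whitney, exact when both groups have ≤ 8 tie-free values and
a tie-corrected normal approximation (no continuity correction) otherwise;
Pearson's r with the t-based p; one-way ANOVA for family GC contrasts. The
Bonferroni family size is the number of pairwise tests actually performed
after excluding groups below `min_group_size` (default 2). The test suite
checks H and the exact Mann–Whitney p against enumeration oracles written
from first principles.

## Brownian-motion ancestral states

Tip values are jointly normal with mean a·1 and covariance σ²C (C_ij =
shared root-to-MRCA path length). The implementation computes all node
estimates by Gaussian message passing: an upward sweep gives each subtree's
conditional mean and an "extra length" (the variance of that mean in branch
-length units), a downward sweep gives the complementary message, and each
node's ML state is the precision-weighted combination of its incident
messages — algebraically identical to re-rooting the GLS mean at every
node, which the tests verify against an explicit matrix oracle (and, on one
fixture, against `phytools::fastAnc` through Rscript). σ̂² is the ML
estimator (x−â1)ᵀC⁻¹(x−â1)/N; node variances are σ̂² times the node's
combined extra length; 95 % intervals are ±1.96 √variance.

Numerical choices: branch lengths are used as-is (non-ultrametric trees are
admissible under BM; no rate smoothing is applied — an externally
transformed tree can be supplied instead); polytomies need no resolution in
this formulation; zero-length *terminal* branches are floored at 1e-8 of
tree height to keep C invertible, and an all-zero-length tree is rejected
as degenerate. Species with several measurements enter as their arithmetic
mean, pooling sexes. Name matching between tree and trait table casefolds
and collapses underscores/whitespace before pruning unmatched tips (branch
lengths of suppressed degree-2 nodes are summed).

## Synthetic data: what it emulates, and what it does not

The histogram generator draws particle fluorescences from two normals
(sd = mean·CV/100) plus an exponential debris tail from channel zero, binned
to 1,024 channels, conserving particles exactly. Defaults mirror a routine
campaign: ~4,000 particles per run, CVs 2.31 %/3.81 %, pea standard. It does
*not* model cell-cycle (S/G2) populations, doublets, apoptotic fractions or
batch gain drift — so passing round-trip tests demonstrate estimator
correctness under the stated noise model, not robustness to every
instrumental artifact. The debris model is a coarse robustness fixture, not
a calibrated one.

The tree generator grows pure-birth (Yule) trees (exponential waiting times
with rate λ·k, uniform lineage choice) and evolves traits by recursive
normal increments. `scale_height` rescales a tree to fixed root-to-tip
height: unscaled Yule trees grow taller with more tips, which inflates
root-adjacent variance and makes accuracy comparisons across tree sizes
meaningless.

## Design of the simulation experiments

*Root-recovery experiment.* Accuracy versus taxon sampling is measured by
nested subsampling: each replicate simulates one 128-tip unit-height tree
with BM (root 6.19 pg, σ² = 1 per height), then re-estimates the root from
random tip subsets of 8, 16, 32, 64 and 128. Pairing the sizes within a
replicate removes between-tree noise from the comparison; with 200
replicates the RMSE sequence decreases monotonically, and σ̂² at 128 tips
is within 15 % of truth in median. (With independent unscaled trees per
size the trend is not monotone — documented here because it is easy to
trip over.)

*Rank-test calibration.* The null simulation uses 3 groups × 20 values;
at ~10 per group the chi-square approximation to H is visibly conservative,
at 20 the 5 %-level empirical rate sits within the 99 % binomial band
around 5 %.

*Histogram round trip.* 100 replicates at CV 3 % and 5,000 particles, with
true ratios drawn from [0.30, 0.75] ∪ [1.40, 4.00] — the excluded middle
band corresponds to a sample peak sitting on the standard peak, which no
window rule can disambiguate; in practice the standard is chosen to avoid
coincidence, and the pipeline generator excludes ratios in (0.8, 1.3) for
the same reason.

Problem sizes throughout (100-replicate round trips, 50 oracle trees,
200-replicate recovery, 1,000-table null) were chosen to make Monte-Carlo
error small relative to the tested effects while keeping the default suite
quick to run.

## Known limitations

- The GC binding-length model is the standard form, but published GC values
  derived from other macros may differ systematically; raw dye ratios are
  rarely published, so per-species GC can only be validated in aggregate.
- Survey-level reference statistics bundled here are species-level; the
  original per-specimen compilation (and its phylogenetic tree) is not
  redistributable, so multi-study statistics (e.g. the chromosome-number
  Kruskal–Wallis on ~146 species, ancestral estimates for named clades) are
  demonstrated on the measured subset and on simulations instead.
- FCS container parsing is not implemented; histograms enter as plain
  two-column TSV exports.
- No phylogenetically corrected regression (PGLS) and no OU/rate-shift
  models; the ASR is pure single-rate BM.
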