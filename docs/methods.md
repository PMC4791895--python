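# Methods

This note documents the statistical procedures, the simulator the tests
rely on, the package's numerical choices, and the places where the
design was genuinely open.

## Spot-level quality control

A spot is retained only if, in *both* channels, foreground ≥ 2 × local
background (inclusive at exactly 2×), foreground < the saturation level
(default 65,535, the 16-bit scanner ceiling), and the spot is unflagged.
The 2× rule is read literally as a ratio test against the local
background estimate, not as a background + 2σ test; both-channel
application is the stricter of the two possible readings and is the
default because a ratio needs a reliable numerator *and* denominator.
Background subtraction (foreground − background, floored at 1 count so
logs stay finite) is applied after QC.

## Intensity normalization

Log ratios M = log2(ch1/ch2) are corrected by a single global LOWESS fit
of M on A = ½(log2 ch1 + log2 ch2): M_norm = M − f(A).  Defaults: span
0.3, 3 robustness iterations, a `delta` speedup of 0.5% of the A range.
A constant offset is absorbed entirely; fewer than 50 spots is an error
because a local trend estimated from less has no meaning.  The same
normalizer serves both expression arrays and the ChIP ratio, so dye bias
never reaches the error model as a location shift.

## ChIP error model and probe-set filters

Per-probe confidence values come from an intensity-binned robust null:
probes are split at the deciles of A (bins under 20 probes are merged
into a neighbor), and within each bin z = (M − median)/(1.4826·MAD),
p = 1 − Φ(z).  The median/MAD pair keeps genuinely enriched probes from
inflating the null scale as long as they are a small minority of the
array, and the binning absorbs any residual intensity-dependent variance
or location the LOWESS pass left behind.  P values are floored at
1e−300.

Probe sets are sliding 3-probe windows (stride 1) along each chromosome;
a window requires both inter-probe gaps (end of one probe to start of
the next) to be ≤ `max_gap` (default 1,000 bp — promoter tiles are
~100–300 bp apart, so windows across annotation gaps are spurious).
Stouffer's equal-weight method combines the three single-point values;
the three z scores are summed in sorted order so the result is exactly
invariant under argument permutation.

Two filter rules, strict at every threshold:

* promoter rule: p_center < 0.001 ∧ min(p_flanks) < 0.01 ∧
  p_combined < 0.001;
* transcribed-region rule: p_center < 0.005 ∧ p_combined < 0.0001 ∧ at
  least one flanking probe whose *own* window has combined P < 0.001.
  A flank with no window (array edge, chromosome end, gap) fails the
  clause — the conservative resolution of an ambiguous rule.

A window passing either rule is bound.  Overlapping passing windows
(strict overlap, shared base pairs) are collapsed by interval union;
each region reports max enrichment = 2^max(M) over member probes and the
minimum combined P.

Gene assignment is nearest TSS to the region midpoint (ties: + strand
first, then lexicographically smaller gene id; distances are signed in
reading direction, negative upstream).  Nearest-ORF-boundary assignment
is available via `assign_mode="orf"` for users who read "closest ORF"
as the ORF body rather than its start.

## Binding-profile clustering

Bound genes are profiled by interpolating normalized probe ratios onto
20 equally spaced positions across the promoter window, oriented by
strand so + and − genes align.  Profiles are centered and scaled per
gene by their SD floored at 0.25 log2 units; without the floor, a
near-flat profile would be blown up into unit-norm noise and flat genes
would scatter across clusters.  K-means (10 restarts, fixed seed) with
k = 5 by default; labels are renumbered by descending cluster size so
repeated runs are comparable.  The five-group presentation is a
conventional choice for promoter-binding archetypes, not a model-derived
number.

## Differential expression

Replicate arrays are LOWESS-normalized individually; dye-swapped arrays
contribute −M_norm; probes of a gene are summarized by their median;
genes on fewer than 2 arrays are dropped.  Calls use the inclusive
±0.25 log2 threshold.  The selection rule is deliberately
fold-change-only; a plain per-gene t statistic is attached as annotation
but has no effect on calls, and no empirical-Bayes variance moderation
is performed.  By construction the procedure is exactly antisymmetric
under flipping every swap label.

## Integration and validation statistics

Venn partitions and bound×regulated crossing operate on harmonized ids
(case-folded, version suffix stripped).  Over-representation of a query
list in each gene set uses the hypergeometric upper tail P[X ≥ k] with
the user-supplied universe and Benjamini–Hochberg correction across
sets; only enrichment (not depletion) is tested.

qPCR relative expression is ΔΔCt with amplification efficiency fixed at
2 (configurable): fold = E^−(ΔCt − mean ΔCt of the control group).  The
identity "control = 1" holds exactly on the log scale (geometric mean);
the arithmetic mean of control folds exceeds 1 whenever control ΔCt
values differ, by Jensen's inequality.  ChIP-qPCR relative recruitment
is percent input divided by the IgG row's percent input at the same
locus, so IgG is exactly 1 in every calculation.  The Mann–Whitney U
test enumerates all C(n, n_a) group assignments of the pooled mid-ranks
while n_a·n_b ≤ 64 (ties therefore handled as an exact permutation
test); two-sided p = min(1, 2·min(P(U_a ≤ u), P(U_a ≥ u))).  Larger
samples use the normal approximation with tie and continuity
corrections.

## The simulator

The generator emulates an Agilent-style study: 1,000 promoters of 10
probes (45–60 bp) at 200 bp spacing for ChIP; 2,000 single-probe genes,
3 replicates with one dye swap, for expression.  Per spot and channel,
background is log-normal (median 100 counts) and foreground = background
+ signal, with a shared log-normal true signal (median 800 counts, SD
1.0 log2) multiplied per channel by 2^ε, ε ~ N(0, noise_sd/√2) — so the
background-subtracted log ratio carries Gaussian noise with SD
`noise_sd` (default 0.35, a calibration choice; the design it emulates
published no noise magnitudes).  Dye bias is a bounded quadratic in
standardized log signal (clipped at |z| = 2 and scaled so
`dye_bias_amplitude`, default 0.3 log2, is the maximum bias magnitude)
attached to the Cy5 channel; dye swapping inverts the biological ratio
but not the bias, exactly as physical dye exchange would.  Foregrounds
are clipped at saturation and 2% of spots are flagged.  Spiked bound
regions span 3–5 consecutive probes at log2(enrichment_fold) (default
4-fold) in 5% of promoters; the 3-probe minimum reflects that the
probe-set filters cannot detect shorter events.  All outputs, including
the ground truth, are bit-identical under a fixed seed.

What the simulator does *not* emulate: probe-sequence effects (GC bias,
cross-hybridization), spatial print-tip artifacts, correlated
backgrounds, partial or tapered enrichment profiles, and scanner image
noise.  Passing spike-in tests therefore demonstrates that the
statistics recover the events the model family describes — not that
real arrays are this clean; on real data the error model's bins absorb
what the simulator idealizes away, but sensitivity at a given fold
enrichment will be lower.

## Problem sizes used in tests and the acceptance script

The shipped checks run at the study's desk scale: 10 simulated ChIP
arrays of 10,000 probes for spike-in recovery; one 10,000-probe
spike-free array for null calibration (uniformity by Kolmogorov–Smirnov,
plus a 99% binomial band on the fraction of probes with p < 0.001);
10,000-spot arrays for the LOWESS check; 200 random arrays of up to 500
probes against the brute-force window-enumeration oracle; exhaustive
enumeration up to universe size 12 (hypergeometric) and group sizes 8
(Mann–Whitney).  These sizes were chosen so that each property is
measured with comfortable statistical resolution while the whole suite
runs in a few minutes on one core.

## Known limitations

* The error model is an intensity-binned robust z, not a re-derivation
  of the proprietary two-component error models of early commercial
  ChIP-chip pipelines; on their data the two will rank probes similarly
  but P values will differ in the extreme tail.
* Probe→gene mapping for expression arrays assumes a probe-id convention
  (`gene:k`) or a user-supplied mapping; no re-annotation is attempted.
* The exact Mann–Whitney enumeration is combinatorial; the n_a·n_b ≤ 64
  bound keeps it instant, and the asymptotic fallback is accurate at
  those sizes, but p values switch estimator families at the boundary.
* Gene-set enrichment tests overlap only; ranked (walk-statistic)
  enrichment is out of scope.
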