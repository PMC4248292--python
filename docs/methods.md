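# Methods

## Repertoire clonality

A TCRβ clone table assigns each distinct V(D)J rearrangement a read
count; frequencies are counts over total reads, optionally re-weighted by
a per-clone multiplicative table (the hook for vendor PCR amplification
bias correction; no correction algorithm is bundled). The detection
statistic is the **top replicated-clone frequency**: the maximum
frequency among clones seen at least twice. Singletons are excluded
because a count of one carries no evidence of clonal expansion. A sample
is called a detected lymphoma when this statistic reaches
`fold_threshold` (default 30) times the wild-type baseline mean (default
0.0011, i.e. 0.11% of reads); the boundary is inclusive so the threshold
value itself detects. Both defaults are overridable from data — the
baseline should be re-estimated as the mean top replicated frequency of
contemporaneous wild-type samples whenever those are available.

Histograms use half-open bins `[lower, upper)` with explicit under/over-
flow bins so that counts always sum to the unique-clone count; the
default edges are one-per-decade from 1e-6 to 1. A clone frequency of
exactly 1.0 (monoclonal sample) therefore lands in the overflow bin —
this is intentional, not loss. Group comparison of top frequencies is an
ordinary pooled-variance two-sample t-test (scipy); groups with zero
pooled variance are flagged `degenerate` rather than returning NaN.

## Depth-ratio model and CNV calling

For an exon with tumor depth `T` and normal depth `N`, the observable is
`log2((T·s + p)/(N + p))` with pseudocount `p = 0.5` (keeps biallelic
deletions, `T = 0`, finite) and library-size factor `s = ΣN/ΣT` when
normalization is on. Normalization is the right default for real
libraries sequenced to different depths, but it re-centers the genome-wide
mean: when simulated tumor and normal are drawn at matched mean depth and
a lesion spans most of the table, normalization absorbs part of the
signal, so those calibration checks pass `normalize=False`. With a lesion
occupying a modest fraction of a real exome the shift is a few
hundredths of a log2 unit and the default stands.

The admixture algebra assumes a diploid background and a single lesion
per locus: a fraction `f` of tumor cells with integer copy change `Δ`
gives expected ratio `1 + f·Δ/2`. Inversion `f = 2·(2^c − 1)/Δ` is exact;
values of `f` outside [0, 1] raise an out-of-model flag (e.g. a segment
mean of −1.2 cannot arise from a heterozygous deletion at any purity —
it needs `Δ = −2`). `c = 0` maps to `f = 0` for every `Δ`. Reported
percents round half away from zero, which is why the −0.3 and +0.2
cutoffs print as 38% and 30% (exact values 37.55 and 29.74). Sub-diploid
complexity — allele-specific states, overlapping subclonal lesions at one
locus, genome doubling — is outside the model.

### Segmentation

Per chromosome, the log2-ratio vector is segmented by recursive binary
splitting in the circular-binary-segmentation style: the candidate split
is the arc `x[i:j]` maximizing the pooled two-sample |t| between inside
and outside (the two flanks count as one segment, which is what makes the
statistic "circular"); its significance is assessed by permuting the
exon order `n_permutations` times (default 200) and recomputing the
max-|t|, with `p = (1 + #{perm ≥ obs})/(1 + n_permutations)`. Splits with
`p < alpha` (default 0.01) are accepted and the pieces re-segmented.
Consequences of these choices:

* the attainable p-value floor is `1/(n_permutations + 1)`, so `alpha`
  must exceed it for any split to be accepted;
* zero pooled variance with distinct means (noise-free steps) scores
  +inf and is always split at the exact breakpoint;
* `min_exons` (default 2) bounds the smallest piece a split may create;
* determinism: one `numpy` generator seeded by the caller drives all
  permutations, and argmax ties resolve in fixed row-major order.

The arc scan is vectorized over all `O(n²)` pairs; with permutations the
per-chromosome cost is `O(n_permutations · n²)`, comfortable to a few
thousand exons per chromosome. Calling applies the cutoffs to *segment
means* (the segmentation already averaged the exons), boundary inclusive
so the printed cutoffs are themselves callable. Called deletions/
amplifications get `f` inverted under `Δ = ∓1`; deeper events are left
flagged rather than silently re-modelled. Focal biallelic deletions are
detected separately as runs of ≥ `window_exons` (default 3) exons at or
below `log2(0.15)` — a heterozygous deletion would need `f > 1.7` to
reach that floor, so the two detectors cannot confuse each other.
Chromosome Y can be excluded for sex-mismatched matched normals.

## Ordering rule and rates

The three-way verdict formalizes a verbal argument as an inequality test
with tolerance `τ` (default 0.05, exposed as a flag): sequencing noise in
both the lesion's DNA-read fraction and the clone fractions makes exact
comparisons meaningless. `f_L` may be a raw DNA-read fraction or a cell
fraction inferred from the depth model; both enter the same rule. The
boundary `f_L = max clone` is assigned `post_rearrangement` (the lesion
is containable within the largest clone). The rule is monotone in `f_L`
by construction, which the property suite checks.

Rates are quotients with input echo: mutations per Mb of callable
sequence, and clones per day over a window. The 9→20 week observation
window is encoded as 77 days (11 × 7), which is what makes 10 clones
print as 0.13/day.

## Synthetic data

The repertoire generator assigns reads multinomially to the configured
dominant clones and a background pool, then conditions the background on
exactly `n_background_clones` realized clones with ≥ 1 read each; extra
background reads are spread with rank-power-law weights
`w_r ∝ r^(−background_dispersion)`. The default exponent 0.45 with
2×10^5 reads over 5×10^4 clones puts the top background clone near 0.11%
of reads — the wild-type calibration point — without claiming this is the
true repertoire law; it is a calibration choice. Rearrangements are
random 45-nt strings with labels drawn from small fixed mouse TRB V/D/J
pools, and in-frame status is Bernoulli with probability 1/3 (frame
preservation is a one-in-three event), making the expected
productive/nonproductive read ratio 0.5.

Coverage noise is Poisson by default (minimal model); a negative-binomial
option with size parameter `dispersion` (variance `m + m²/k`) represents
over-dispersed captures. Lesions may not overlap on an exon — the
expected ratio would be ambiguous — and the generator realizes expected
tumor depth `mean_depth · (1 + f·Δ/2)`. Mutation counts are Poisson with
mean `callable_mb · rate_per_mb`, positions uniform.

What the generator does **not** emulate: GC and mappability bias,
exon-length-dependent depth, PCR chemistry, correlated noise along the
genome, chromothripsis-style clustered rearrangements, and thymic
selection dynamics. Passing tests therefore demonstrate correctness of
the statistics and the inversion algebra under the stated sampling
models, not robustness to those real-data artifacts.

## Problem sizes and numerical choices

Monte-Carlo checks run at sizes chosen to keep the full suite in a few
minutes while leaving ≥ 3σ margins: 1000 replicate repertoires at 10^4
reads for binomial recovery, 100 seeds per cell-fraction recovery point
(median |f̂ − f| < 0.03 at 200× over 100 exons), 40 seeds for the
permutation-null calibration, 20 seeds per arm of the end-to-end
ordering check, and 5 pre-registered seeds for the −0.30 ± 0.02
segment-mean calibration (a single 100-exon realization at 200× has a
standard error ≈ 0.015, so the five-seed mean puts the band at ≈ 3 se).
The ≤ 12-exon segmentation oracle compares against an exhaustive O(n²)
arc scan, on inputs whose split decision is overwhelming so that two
independent permutation streams cannot disagree.

The pipeline report is a pure function of config + inputs + seed; run
timestamps are written to the log file only, so replaying a config
regenerates `report.json` byte-identically, and `validate_report`
re-derives every stored verdict and consistency invariant from the
report itself.

## Known limitations

* The depth model is single-lesion diploid-background; no allele-specific
  or LOH inference.
* The detection baseline default is a literature-scale constant; real
  studies should estimate it from their own wild-type samples.
* Segment cell fractions assume `Δ = ±1` unless a biallelic region is
  detected; mixed-Δ segments are only flagged, not decomposed.
* The clone-emergence rate divides a clone count by a window length; it
  does not model clone birth-death dynamics within the window.
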