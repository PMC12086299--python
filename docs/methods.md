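# Methods

## The analysis model

Resting-state EEG alternates between brief (~50–100 ms) periods of
quasi-stable scalp topography — microstates, classically labeled A–E. The
package implements the standard microstate measurement chain and the
paired pre/post statistical harness around it, together with a synthetic
generator that plants known microstate structure so that every stage can
be validated against ground truth.

### Preprocessing

Recordings are band-passed 2–20 Hz (4th-order Butterworth, zero-phase
forward–backward; only the band is methodologically fixed, the realization
is recorded in the output metadata), average-referenced, and screened for
artifacts: the recording is cut into fixed epochs (2 s default,
configurable — the statistic window is a package choice) and an epoch is
flagged when any of mean absolute amplitude, mean GFP, skewness or
kurtosis strictly exceeds its across-epoch mean + 5 SD (one-sided; with a
zero SD nothing can strictly exceed the threshold, so uniform recordings
produce no flags). The earliest unflagged epochs totaling the target
length (120 s default) are concatenated; every join between non-adjacent
epochs is recorded as a splice boundary, and no downstream run, GFP-peak
search, or transition ever crosses a splice. Channel subsetting re-applies
the average reference, since dropping rows breaks the zero channel mean.
ICA-based ocular artifact removal is out of scope; externally cleaned data
pass through unchanged.

### Clustering (modified k-means)

Template maps are fitted to the maps at GFP peaks (strict local maxima of
the spatial SD; no minimum distance or height by default, both
configurable). Cluster membership uses the squared spatial (Pearson)
correlation, making the fit polarity-invariant, and each centroid is
updated to the dominant eigenvector of its members — a plain-mean update
would not be polarity-invariant. Fit quality is the global explained
variance GEV = Σ gfp²·corr² / Σ gfp². Defaults: 20 restarts, tolerance
1e-7 on GEV, 200 iterations; an emptied cluster is re-seeded from the
worst-explained peak map.

### Alignment, grand mean, naming

Subjects' template sets are aligned by per-subject label permutation and
sign flips, maximizing the mean over classes and subjects of the squared
correlation between each subject map and its class's dominant-eigenvector
mean. The optimizer is coordinate ascent with optimal linear assignment
against leave-one-out class means; on small instances it reproduces the
exhaustive joint optimum exactly (tested on all 576 joint permutations of
two subjects at k = 4). The grand mean is the per-class eigenvector mean.
Classes are named A–E by one-to-one maximum-|correlation| assignment
against packaged canonical topographies — synthetic maps constructed from
the field's verbal descriptions (A/B: lateralized occipital-to-frontal
diagonals; C: anterior–posterior axis; D: fronto-central focus; E:
centro-parietal focus), not reproductions of any published figure. When a
k-range is fitted, the default pipeline fixes k = 5; the alternative rule
selects the smallest k whose canonical naming covers classes C and D with
similarity ≥ 0.6.

### Backfitting and parameters

Grand-mean templates are assigned at GFP peaks by maximal squared
correlation (ties to the lowest class index; zero-variance peaks are
unassigned), and labels spread to all samples by nearest-peak
interpolation (exact midpoints to the earlier peak; blocks without peaks
stay unassigned). Parameters per class: duration = mean run length (ms),
occurrence = runs per second of assigned data, contribution = fraction of
assigned samples. Runs touching a recording edge or splice are censored —
excluded from duration and occurrence by default (their length is
unobserved) but always counted in contribution; `include_edge_runs`
restores the naive behavior. Contribution is reported as a dimensionless
fraction of assigned time.

### Transition analysis

Transitions are events between successive runs. observed(a,b) is the
row-normalized count matrix; expected(a,b) = n_b/(N − n_a) with n_c the
class run counts — the proportion expected if successors were drawn purely
by occurrence; the deviation is their difference, with the C→D and D→C
cells of primary interest. The count-based expectation is the default
(transitions are events between runs); a time-coverage-based alternative
is provided for comparison. Per-recording deviations are averaged across
subjects rather than pooling counts, preserving the paired design. A
subtlety verified in the tests: the count-based correction is exactly
centered only when run counts are equal; under an unequal-weight
occurrence-proportional chain the asymptotic deviation has the closed form
w_b/(1−w_a) − π_b/(1−π_a) with π ∝ w(1−w), which the implementation
reproduces.

### Statistics

Pre/post comparisons use the exact Wilcoxon signed-rank test: zero
differences dropped, ties mid-ranked, V = sum of positive-difference
ranks, and the exact two-sided p from the full sign-assignment
distribution (computed by the standard rank-sum recursion, equivalent to
enumerating all 2^m assignments; an independent brute-force enumeration
oracle backs this in the tests). Above m = 25 nonzero differences the
tie-corrected normal approximation is used and flagged in the result.
Change-score associations use Pearson's r with t = r·√((n−2)/(1−r²)),
df = n − 2. p-values are Benjamini–Hochberg adjusted within each report
table (the family definition is configurable in principle; per-table is
the default and both raw and adjusted values are always emitted). The
degrees of freedom are always derived from the number of complete pairs.

## The synthetic generator

Each recording is built from (1) a semi-Markov label sequence — run
lengths geometric at sample resolution (default; keeps the run-level
Markov null exact for the transition analysis) or gamma (shape 2), with
per-class mean durations defaulting to (58, 56, 59, 73, 64) ms, the
five-class pre-stimulation scale of the study design it emulates;
successors drawn from a zero-diagonal row-stochastic matrix (uniform by
default); (2) the active class's template scaled by a rectified 10 Hz
sinusoid, putting GFP peaks at the empirically typical ~20/s; (3) additive
Gaussian noise with inter-electrode angular correlation (length scale 1
rad), scaled to noise_sd = 0.5 of the mean signal RMS — chosen once as a
moderate-SNR regime (the resulting pipeline GEV ≈ 0.88 is, if anything,
cleaner than typical empirical values); every sample is then
average-referenced. Electrode positions come from the standard 10-10
table, unit-normalized; the default 30-channel set is the conventional
completion of the target montage.

The paired-study generator produces n subjects × two sessions (DMPFC,
DLPFC) × pre/post, with subject-level template jitter and ~10% duration
variability, a plantable post-stimulation class-D duration increase
(default +6 ms), a per-subject D→C transition enrichment whose
pre-to-post change is correlated (default ρ = 0.6) with a STAI-S-like
state-anxiety change score (pre ≈ 47.5 ± 8.8, change ≈ −1.6 ± 5, clipped
to [20, 80] with clipping logged), and a MADRS-like severity score. The
study's base templates are canonical-anchored (canonical A–E + smooth
jitter, anchor similarity ≥ 0.75) so the planted class-D effect keeps its
identity through the pipeline's naming stage.

What the generator does **not** emulate: band-limited source dynamics
(the pre-filter signal jumps discontinuously at state switches), state
switching synchronized to GFP troughs, ocular/muscle artifacts beyond
amplitude bursts, or volume conduction. Passing tests therefore validate
the algorithmic chain against its own model, not the physiology of real
recordings.

## Known measurement bias (and an honest limitation)

Backfitting at ~20 GFP peaks/s cannot resolve runs shorter than the ~50 ms
inter-peak interval: in the noiseless, unfiltered limit the measured mean
duration is ≈ Δ/(1−e^(−Δ/d)) for true mean d and peak spacing Δ — a ~+50%
inflation at d ≈ 56 ms. Band-pass filtering partially offsets this by
mixing topographies at state boundaries (fragmenting long runs,
particularly class D via its similarity to class C). At the default SNR
the net group-mean duration errors are roughly +15% for the shortest
classes and −15% for class D, i.e. at the edge of a ±15% band, while
occurrences recover within ~10% and contributions within ~0.03. This
temporal-smoothing bias is a property of peak-level backfitting itself and
is shared by standard microstate toolchains; comparisons of the same
pipeline across conditions (the package's actual use) are unaffected by
its common-mode component.

## Problem sizes and numerical choices

Validation experiments run at sizes giving stable Monte-Carlo estimates on
one CPU: parameter recovery on 10 × 120 s recordings; the transition null
on 200 × 600-run sequences; enrichment detection on 40 × 60 s sequences;
statistics oracles on 50 random instances per test; power and type-I on
100 simulated 19-subject studies each, generated in the label-only mode
(parameters from ground-truth label sequences), which isolates the
statistical harness — the topographic measurement chain is validated by
the recovery experiment. Ties in peak assignment break to the lowest class
index; grand-mean eigenvector signs are fixed by making the
largest-amplitude channel positive; degenerate inputs (all-zero
differences, constant vectors, zero-variance maps) raise typed errors
rather than returning NaN.
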