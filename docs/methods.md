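# Methods

This note documents the models, parameter choices and limitations behind
`pilotcalls`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Detection conventions

Vocalizations are taken from manual label tracks; the package does not
detect calls automatically. Two labelled signals are one vocalization
unless at least 0.5 s of silence separates them (`merge_events`, applied
transitively). All clips are resampled to 22 050 Hz by polyphase
filtering — the lowest rate across typical source datasets — so every
spectrogram shares one geometry and the analysis band is capped at
(just above) 10 kHz. Intervals are half-open `[start_s, end_s)`;
multichannel files use a configurable channel (default 0).

## Spectrograms and prepared inputs

Spectrograms use 43 ms Hann windows with 80 % overlap, magnitude (not
power) scaling, FFT size the next power of two above the window, no
padding (frame count `floor((N − W)/hop) + 1`), and bins above 10 kHz
dropped. The call-level peak frequency is the argmax of the magnitude
summed over frames, ties broken toward the lower frequency.

The auto-encoder input is the spectrogram log1p-compressed, min–max
scaled to [0, 1] per call, resampled to 128 frequency bins, centrally
padded/cropped to 128 frames (~1.1 s at the 8.6 ms hop; the rare longer
call loses its edges), then Gaussian-smoothed with σ = (3 bins,
2 frames) and rescaled to [0, 1]. The smoothing is deliberate: the F0
ridge of a call is only one or two bins wide, so two same-type calls
whose fundamentals differ by a few percent have almost disjoint active
pixels, and a fully connected network then sees them as unrelated.
Widening the ridge restores overlap and makes embedding distance track
contour shape; without it the planted types in the validation bundle
fragment into micro-clusters. Both the target shape and σ are
configuration.

## Embedding and projection

The auto-encoder is a fully connected network, flattened input → 256 →
32 → 256 → output with ReLU hidden activations, trained with Adam
(lr 10⁻³, batch 32, 50 epochs, no weight penalty) on mean-squared
reconstruction error; the 32-unit bottleneck is the method's fixed
design point and the encoder half supplies the call representation. A
dense architecture was chosen over a convolutional one to keep the
dependency stack to scikit-learn; the Gaussian smoothing above buys back
some of the shift/scale tolerance a convolutional encoder would give.
Training is deterministic for a fixed seed and thread count, and the
loss history is recorded so a run can verify that training actually
reduced reconstruction error.

UMAP (n_neighbors 15, min_dist 0.1, fixed seed → single-threaded,
deterministic) reduces the 32-D embeddings to 2-D for clustering and
plotting.

## Clustering and the catalogue

HDBSCAN on the 2-D projection proposes clusters; −1 marks noise, which
is reported but never auto-assigned. `min_cluster_size` defaults to 10:
with natural (or simulated) frequency jitter a call type traces an
extended manifold in the projection, and smaller values split such
manifolds into micro-clusters (on the validation bundle,
`min_cluster_size = 5` yields ~15 clusters for 10 planted types, 10
yields the intended granularity). The value must stay well above the
3-occurrence floor below and is configuration.

Manual validation is captured as a plain-text review script — one
`merge`/`split`/`exclude`/`relabel` verb per line, applied in order with
a full audit log — so the human step is reproducible and diffable. The
final catalogue keeps only types occurring at least 3 times; rarer
clusters return to the unclassified pool. `recovery_score` reports the
adjusted Rand index between predicted and planted types (noise excluded,
counted separately) when ground truth exists.

## F0 contours and features

Contours are ordered `(time, frequency)` samples of the fundamental,
whatever density the annotation supplies; no smoothing or resampling is
imposed before measurement. `halve_harmonic` divides all frequencies by
two when a contour was traced on the first harmonic;
`check_harmonic_support` flags that situation by testing, per point,
whether the band 2·F0 ± 5 % holds more than 4× the frame's median
magnitude (the factor keeps the extreme order statistic of plain noise
bins below the bar). Calls without a second harmonic legitimately fail
this check — a documented blind spot.

Feature definitions and operating points:

| feature | definition | parameters (default) |
|---|---|---|
| Dur | last − first contour time, internal gaps included | — |
| BW | f_max − f_min of F0 | — |
| Peak | spectral-peak frequency from the spectrogram | — |
| Range | f_max / f_min | — |
| Trend | f_start / f_end | — |
| Segm | 1 + number of silent pauses | pause > 0.02 s splits; ≥ 0.5 s is an error (would be two vocalizations); the 0.1 s definitional bound is not enforced inside the 0.1–0.5 s dead band |
| El | 1 per segment + abrupt steps | relative jump > 25 % within ≤ 20 ms |
| Inflec | slope-sign reversals | 5-point running median per run, slopes < 100 Hz/s treated as flat |

Inflections are counted within segments and never across
quasi-instantaneous steps (the jump rule within ≤ 5 ms): a step between
elements is a discontinuity of the contour, not a reversal of its slope.
The 5 ms break window is deliberately tighter than the 20 ms element
window so that a genuine steep reversal annotated at ~10 ms point
spacing still counts. The mean frequency is time-weighted (trapezoidal
per segment) so irregular annotation density does not bias it; for
piecewise-linear contours the trapezoidal rule is exact, which the
oracle tests exploit. All thresholds are keyword arguments and recorded
in the run configuration.

## Statistics

Group comparisons are gated: Shapiro–Wilk on residuals pooled across
groups (values minus group means; per-group testing available) decides
at α = 0.05 between one-way ANOVA and Kruskal–Wallis (tie-corrected).
When the omnibus p ≤ α, all pairwise comparisons are attached —
two-sided t-tests on the normal branch, Mann–Whitney U otherwise — with
Bonferroni adjustment `min(1, p·m)`. Datasets enter the comparison only
through their exclusive call types, and only when they have at least 2
of them (`min_group_n`); types present in several datasets are labelled
"mixed". The empirical size of the gated procedure under a
three-group Gaussian null is checked by simulation in the test suite.
Type-level summaries use the n−1 standard deviation and report sd as
absent (not 0) for a single type. Spearman correlations are computed
for the (min,max), (min,mean), (mean,max) frequency pairs; constant
vectors yield an absent coefficient.

## Classification tree

The CART is grown greedily on exactly eight predictors (the auxiliary
min/max/start/end frequencies are rejected by the schema so the tree
classifies contour shape, not frequency position). Candidate thresholds
are midpoints between consecutive sorted unique values; the split
maximizing the decrease in Gini impurity wins, with deterministic
tie-breaks (predictor order Dur, BW, Peak, Range, Trend, Inflec, Segm,
El; then lower threshold), so refits are identical. Defaults: no
pruning, max depth 10, min leaf 1, minimum impurity decrease 0 (a split
must still strictly decrease impurity). The reported "global Gini
index" is the unweighted mean impurity over **all** nodes; because the
convention is ambiguous, internal-only, leaf-only and sample-weighted
variants are computed alongside and labelled.

## Synthetic calls

The generator defines the validation conditions. A prototype is an
ordered list of contour pieces — `constant`, `linear-sweep`, `parabolic`
(start/end at f_start, extremum f_end at the midpoint, hence exactly one
slope reversal), `element-boundary` (instantaneous step, rendered as a
2 ms offset) and `segment-gap` (silent pause < 0.5 s). Structural truth
comes from piece semantics alone (segments = 1 + gaps, elements =
segments + boundaries, inflections from the analytic slope-sign
sequence), independent of the rendering code, so feature extraction can
be tested against it honestly. Contours are sampled at 200 points/s;
jitter is multiplicative — one frequency scale and one duration scale
per call, normal with the configured fraction as σ, clipped at ±2.5 σ —
so it never changes structural truth.

Waveforms are harmonic stacks: harmonic *k* at amplitude 1/k, phase the
cumulative integral of the instantaneous frequency restarted per
segment, raised-cosine fades ≥ 5 ms, harmonics that would cross Nyquist
dropped with a warning. Noise is additive white Gaussian with unit
variance; each call's signal is scaled so the in-band SNR over its
support (signal band ≈ [0.8·f_min, 1.1·k_max·f_max], noise in-band power
σ²·bandwidth/Nyquist) equals the requested value. An independent
Welch-based estimator verifies the calibration to within ±1 dB for
SNRs 0–40 dB. The amplitude model is a stand-in for pulsed-call
structure, not a claim about pilot-whale sound production; sea-noise
coloration, propagation, clicks and whistles above 10 kHz are out of
scope.

The default bundle — the study conditions for all end-to-end checks —
plants 10 types spanning 1–4 segments, 1–4 elements and 0–9 inflections,
fundamentals ~1–7 kHz and durations 0.3–0.9 s, 30 calls per type at
20 dB SNR with 5 % jitter, split over two datasets (four exclusive types
each, two shared). Each dataset bundle draws from its own RNG stream
(`seed + dataset index`) so bundles regenerate independently and byte
deterministically.

What passing on this bundle does **not** show: robustness to real-sea
noise spectra, overlapping vocalizations, low-SNR boundary cases, graded
(non-discrete) call types, or annotator variability in contour tracing —
the synthetic contours are cleaner and better sampled than hand-drawn
ones.

## Reporting

Report percentages are rounded to integers for display with full
precision retained in JSON. The mean occurrence per type is always the
quotient `n_classified / n_types`. A single global seed fans out to
per-stage seeds by fixed offsets (+1 auto-encoder, +2 UMAP), and all
stage outputs are plain CSV/JSON written with fixed float formats, so an
identical configuration reproduces a run byte for byte.

## Problem sizes used in validation

The shipped validation uses 300 calls (10 × 30) for the end-to-end
recovery run, 100 contours for the feature oracle, 100 random samples
for the rank-formula check, 1000 replicates for the type-I-error
simulation, and a 30-call double run for the byte-determinism check.
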