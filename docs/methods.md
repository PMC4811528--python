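# Methods

This note documents the models, rules and numerical choices behind
`mousesong`, and what its synthetic tests do and do not establish.

## Contour extraction

USVs are represented by their peak-frequency contour: for each STFT
column the frequency of the loudest bin.  The spectrogram uses a
256-sample Hann window at 85% overlap on a 500 kHz stream (frame advance
`round(0.15 × 256) = 38` samples ≈ 0.076 ms) and is zero-padded to the
smallest power of two whose bin width is at most 0.49 kHz (nfft = 1024,
bin ≈ 0.488 kHz).  A column yields a frame only when its in-band
(20–250 kHz) peak rises at least 20 dB above the column's median in-band
level.  This noise floor is a package choice: the original workflow used
hardware triggering plus interactive visual correction, neither of which
an offline library can reproduce; an optional 3-frame median filter
(off by default) stands in for the manual correction pass.  On synthetic
input the extractor recovers a 70 kHz tone within one padded bin
(measured max deviation 0.176 kHz) and a 1 kHz/ms chirp slope within 1%.

## Trigger emulation and deduplication

The recorder opens an event at an in-band sound of ≥ 10 ms, prepends
200 ms of pre-trigger (clipped at the stream start) and holds the event
open until 1 s after the last whistle, merging whistles that arrive
within the hold.  One reconstructed constant: where one "whistle" ends
inside a frame stream.  We break a whistle run when the inter-frame gap
exceeds 10 ms (`run_gap`, configurable), the same gap that separates
syllables.  Cross-channel duplicates (two microphones per compartment
side) are resolved by keeping the longer of any temporally overlapping
pair; exact ties keep the lower channel id so the result is independent
of input order, and the operation is idempotent.

## Segmentation

Gaps are measured offset-of-previous to onset-of-next and compared
strictly: a gap of exactly 10 ms (syllables) or 500 ms (songs) does not
split.  Strictness at the boundary is a convention choice — the original
routine's comparison direction is not recorded — and is pinned by tests;
segmentation conserves frames and syllables and agrees with a
brute-force gap scan on randomized layouts by construction of both.

## Syllable features

- `slope` is the least-squares fit of frequency on time (an endpoint
  mode exists behind a flag); jitter-robust, unlike the endpoint
  difference.
- `freqCOG` is the amplitude-weighted mean frequency with linear
  amplitude weights (10^(dB/20)), falling back to the unweighted mean
  when amplitudes are missing.
- A **jump** is a frame-to-frame step of ≥ 10 kHz ("sudden" is not
  quantified in the field's descriptions; 10 kHz sits far above frame
  jitter and far below typical jump sizes, and is configurable).  Its
  position is the step midpoint as a fraction of syllable duration.
- A **turn** is a reversal of the contour's slope.  The contour is
  smoothed (5-frame moving average), split at jump positions (a jump is
  not a turn), and a reversal counts only when both flanking monotone
  stretches last ≥ 1 ms with overall |slope| ≥ 0.1 kHz/ms.  The guards
  exist so frame jitter cannot masquerade as modulation; all three
  constants are configurable.
- `soDur` runs from the first syllable onset to the last syllable
  offset (trailing silence excluded); the syllable rate `n/soDur` is
  undefined for one-syllable songs, which rate analyses drop.

## Syllable taxonomy

The decision tree is total and ordered: (1) mean frequency below 45 kHz
→ low-frequency syllable (LFS), regardless of modulation — the observed
frequency distribution is dichotomous with a split at 45 kHz; (2) any
jumps → jump types by count, direction and position (one jump:
early/late × up/down with the early/late boundary at 50% of duration;
two jumps: J2UD/J2DU by direction pattern; three or more: JPS); (3) any
turns → TUD/TDU by pattern, TRS for two or more; (4) otherwise Simple,
flat below |slope| = 0.05 kHz/ms, else up/down by sign.  Jumps take
priority over turns in mixed syllables, matching the Jump/Turn/Simple
hierarchy.  The early/late boundary and flat threshold are
reconstructions (the originating taxonomy does not print them) and are
configurable.  For count statistics the two rare two-jump subtypes merge
into one `JMP` category, giving 13 display labels.

## Context annotation

A song's region is read at its **onset** from the emitter's occupancy
track (half-open intervals; a boundary time belongs to the later
interval) — onset is the deterministic choice for songs that straddle a
region change.  The contact window (CW) is scored as a sub-zone of the
contact region: encounter typing keeps it (face when both animals are at
the window, non-face when the partner is elsewhere in the contact
region, solitary otherwise), while region count tables roll CW songs
into CR, whose printed form has no CW column.

## Count summaries and their policies

Night totals can include the male-bedding songs listed outside the
region columns (`include_mb`), which is what reconciles the night-4 mean
(44.17 over 6 pairs) with the count table plus its footnote.  Per-region
summaries use a drop-zero policy: a pair with no songs in a region-night
contributes no observation, which reconciles the contact-corner cell
(17.7 ± 9.66, n = 10) exactly.  Excluded pair-nights (a pair that opened
the contact window prematurely) are dropped everywhere; pairs on the
three-night protocol simply have no fourth-night row — an absent session
is not a zero.  Trial consistency correlates first-trial and repetition
totals over nights 1–3 only, the length of the repetition protocol.

## PERMANOVA with dyad-restricted permutations

Features mix units (ms, kHz, counts), so the default distance is
Euclidean on z-scored columns (Gower available).  The pseudo-F
partitions the squared inter-point distances into among-group and
residual components; for the Euclidean metric this is computed
equivalently from group centroids, which makes each permutation O(n·p)
instead of O(n²) — the two forms are algebraically identical and the
distance-matrix form remains in use for the Gower metric.  The null
distribution permutes group labels independently **within each dyad**
and never across dyads, respecting the repeated-measurements design;
the within-block label multiset is asserted on every draw.  With one
block, one feature and Euclidean distance the pseudo-F equals the
classical one-way ANOVA F to machine precision, and its type-I error
over 500 null simulations (199 permutations, α = 0.05) lies inside the
binomial band.  Blocks with a single observation contribute no
permutation; a design of only singleton blocks is an error.  p is
(#{F* ≥ F} + 1)/(n_perm + 1) and is bit-reproducible given (seed,
n_perm).

## Fisher LDA

Discriminants solve Sb·w = λ·Sw·w; loadings are scaled to unit pooled
within-group variance (the convention of the classical implementations),
and the proportion of trace is each eigenvalue's share of the total.  A
singular within-class scatter (e.g. duplicated features) is
ridge-regularized (ε = 1e-8 of the mean diagonal) with a warning.

## Synthetic data

The generator's defaults encode the study's conditions: 12 pairs; four
nights; night-1 region intensities (FR 4, NR 4, CC 15, CR 4 songs/pair)
matching the observed night-1 distribution; a night-2 novelty multiplier
of 4.5 (first direct contact) decaying by 0.5 per later night
(familiarization); a log-normal pair frailty with sd 1.2 on the log
scale, reproducing the up-to-100-fold differences between pairs; and
repetition trials whose frailty correlates at 0.95 with the first trial.
Syllable-type mixtures differ by context class: directed songs (contact
region/window from night 2 on) are dominated by low-frequency and
simple-down syllables, undirected contact-corner songs by jump and
simple-up types.  Archetype parameters keep every type-discriminating
feature at least 3× from the classifier's decision boundaries (30 kHz
jumps, ±1 kHz/ms slopes, 35 kHz LFS pitch), so noiseless round-trip
recovery is a fair test.  Sessions are rendered at a 0.5 ms frame step —
coarser than the STFT's 0.076 ms but far inside every decision
threshold — to keep simulation light; songs are placed with inter-song
gaps of 800–2000 ms and inter-syllable gaps of 20–200 ms, safely inside
the (10, 500] ms band.

What passing these tests shows: the pipeline's rules are implemented
correctly and invert the generator exactly in the noiseless case.  What
they do not show: robustness to real spectrogram artifacts (harmonics,
echoes, overlapping calls, amplitude-dependent contour dropouts), to
scoring errors in manual occupancy data, or to syllables near the
taxonomy's decision boundaries — real recordings sit closer to those
boundaries than the archetypes do by design.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
fixture summaries are exact arithmetic on 42 table rows; classifier
recovery uses 50 replicates per type; the segmentation oracle 1000
layouts; the PERMANOVA calibration 500 simulations × 199 permutations at
n = 24; pipeline tests simulate 2 pairs × 2 nights.  Full-scale
simulation (12 pairs × 4 nights, 5000 permutations) runs in seconds to a
few minutes through `mousesong simulate`.

## Known limitations

Linear mixed models of song counts (the night × region random-effects
analysis) are out of scope; the package exports the model-ready
long-format count table instead (`mousesong.context.counts_frame`).
Numeric cells of the syllable-parameter tables of the original study are
not reproducible from published material — they require the raw syllable
recordings — so the statistics machinery is validated on synthetic
ground truth instead.  The trigger's internal whistle-hold time, the
original freqCOG weighting, the jump threshold and the early/late
boundary are reconstructions, each surfaced as a configurable parameter.
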