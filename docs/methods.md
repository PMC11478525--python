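# Methods

This note records the model the package implements, the choices made
where the design was genuinely open, and what the synthetic fixtures do
and do not establish.

## Beat detection

The pipeline assumes a piece with an approximately constant tempo and
treats beat tracking as a trade-off between landing on strong onsets and
keeping near-regular spacing at the global beat period.

**Onset strength envelope.** Audio is averaged to mono and resampled to
8 kHz (beat structure lives far below 4 kHz; the decimation keeps the
spectrogram small). STFT frames use a 32 ms Hann window and a 4 ms hop
with no padding, so every frame lies fully inside the signal and the
edges produce no spurious onsets. Power spectra are pooled by 40
triangular Mel filters spanning 0–4000 Hz (HTK Mel scale, peak-1
triangles) and converted to dB relative to the maximum band energy with
a −80 dB floor. The envelope is the per-band first-order time difference
of the dB energies, half-wave rectified and summed over bands; because
the dB conversion turns gain into an additive constant, the envelope
responds to *proportional* energy increases and is invariant to overall
level. A first-order Butterworth high-pass at 0.4 Hz, applied
forward–backward (zero phase), removes drift so the local mean is ≈ 0; a
Gaussian smoother with σ = 20 ms (truncated at 4σ, unit sum) suppresses
frame-rate jitter; finally the envelope is divided by its own standard
deviation so the DP weight ω means the same thing across recordings.

*Timestamps.* Frames are stamped at the window center (the standard
STFT convention; the Hann window weights energy near the center most
strongly). Measured on the click fixtures, an isolated onset peaks one
hop (4 ms) early under this convention and tracked beats sit within
3–5 ms of the true click times.

*Degeneracy.* A genuine onset raises band energies by tens of dB within
one hop. If no frame shows even 1 dB of summed rise (digital silence, a
constant tone — whose only flux is sub-dB spectral-leakage wiggle), the
envelope is declared degenerate rather than normalized, since dividing
by a near-zero standard deviation would amplify numerical noise into
fake onsets.

**Tempo estimation.** TPS(τ) = W(τ)·Σₜ O(t)O(t−τ) is evaluated by FFT
autocorrelation over lags 0.2–2.0 s (30–300 BPM, configurable), with the
log-Gaussian perceptual weight W centered at τ₀ = 0.5 s (120 BPM) with
width σ_τ = 1 octave. A bare argmax of TPS systematically prefers the
slower metrical level for fast tempi: an ideal click train at period τ
correlates equally well at 2τ, and whenever τ < τ₀ the prior weights 2τ
higher, so e.g. a 180 BPM train would always be read as 90 BPM. The
estimator therefore resolves the metrical level the way the classic
dynamic-programming beat tracker family does: duple and triple
interpretations fold half (resp. a third) of the strength at 2τ (resp.
3τ) — taking the maximum over one neighboring lag to absorb grid
quantization — back onto τ, and the period is the argmax of the
better-supported interpretation. This recovers 60–180 BPM click tracks
at their true period while still resolving a 240 BPM train to the 0.5 s
level that the 120 BPM prior prefers. Ties break toward the lag closest
to τ₀.

**Dynamic programming.** With period τₚ, the recursion
C*(t) = O(t) + max{ω F(t−τ, τₚ) + C*(τ)} searches predecessors in
[t−2τₚ, t−τₚ/2], bounding every inter-beat interval to [τₚ/2, 2τₚ].
F uses the natural log; any other base only rescales F by a constant
that ω absorbs. ω defaults to 100: with a unit-variance envelope this
makes a one-hop deviation from the ideal spacing cost ~0.006 (invisible
next to a click peak of height ~5–10) while a half/double-period step
costs ~48, so beats snap to onsets without breaking regularity. Frames
earlier than τₚ/2 are chain starts (no predecessor); the final beat is
the argmax of C* over the last τₚ of the envelope; ties in the
predecessor argmax break toward the earliest candidate for determinism.
Exhaustive enumeration of all admissible chains on short envelopes
(≤ 36 frames, coarse 50 ms grid — small enough for the oracle to finish
in seconds, large enough for 3–4-beat chains) confirms the DP reaches
the same objective value.

Because the search window caps intervals at 2τₚ, the tracker *bridges*
silent stretches rather than stopping: a deleted click is interpolated,
and a multi-second silence is crossed by low-scoring beats. Long
beat-free stretches are therefore handled downstream (see keyframes),
operating on whatever beat sequence the caller trusts.

## Keyframes and gaps

Beat time tᵢ maps to frame index round(tᵢ·fps) (half away from zero,
0-based). Indices past the last frame are dropped with a warning;
duplicates (possible at high tempo / low fps) collapse keeping the first
beat's time. For a constant tempo B this selects a fraction B/(60·fps)
of all frames — at 24 fps, 59–148 BPM selects 4.1–10.3%.

Inter-beat intervals exceeding 2× the median interval (factor
configurable) are reported as gaps together with
round(gap/median) − 1 expected missing beats. The default strategy is to
*ignore* gaps — no keyframes are synthesized inside them, on the view
that a stretch without beats contributes no beat-aligned poses and
typically forms a small fraction of a piece. An alternative filler that
inserts median-spaced pseudo-beats inside gaps is available behind
`fill_gap_beats` / `--fill-gaps` for callers that need continuous
coverage.

## Pose features

Keypoints arrive in the OpenPose output layout (18-joint COCO or 25-joint
BODY_25 naming), one JSON per frame or a consolidated table. A keypoint
with confidence 0 is missing; with several detected people the one with
the highest mean confidence is kept (the pipeline assumes a single
dancer). Each keyframe becomes a vector of interior joint angles —
left/right elbow, shoulder, knee and hip by default (m = 8), trunk
inclination optional — computed with the atan2 form
degrees(atan2(|u×v|, u·v)), which is well conditioned near 0° and 180°
where the arccos form loses precision. Angles are invariant to
translation, rotation and uniform scaling of the keypoints, so scores do
not depend on camera placement or body size; they are *not* invariant to
out-of-plane rotation (see limitations). A feature is ABSENT (NaN)
exactly when one of its three joints is missing; missingness is data,
not an error.

## Scoring

**ASCS.** The per-feature similarity sⱼ is the cosine of the two n-long
angle sequences; ASCS is the mean of the sⱼ, as a percent. The same
report also carries per-frame similarities sᵢ (cosine of the two m-long
angle vectors of keyframe i): the per-feature axis is the one the
sequence-cosine definition acts on, while the per-frame axis feeds the
`per_frame` SMACR mode and diagnostics. ABSENT positions are deleted
pairwise (a `fail` policy is available); at least 2 retained positions
are required, otherwise the comparison is refused as insufficient data.

**SMACR.** Per-position scores are thresholded at `filter` (default
0.85, boundary inclusive — the filter is an *acceptable* level) into
tokens, the standard sequence binarized against itself is all ones, and
F_LCS = (1+β²)RP/(R+β²P) with R = P = LCS/n. In the default
`per_feature` mode the per-position score for feature j at frame i is
cos(θᵢⱼ − Θᵢⱼ) clamped to [0, 1] — the cosine similarity of the two
measured limb directions; a scalar cosine of the raw angle values would
be identically 1 and carries no information. The final SMACR averages
F_LCS over features. In `per_frame` mode the tokens come from the
per-frame vector cosines sᵢ, giving a single sequence. Against an
all-ones standard the LCS equals the count of passing tokens, so token
order cannot affect the score; the general LCS machinery is implemented
anyway and is exercised by an optional 3-level quantization
(`levels=3`, thresholds at filter and (1+filter)/2). β is echoed and
applied in the F formula but cannot change the result at equal lengths.

SMACR is harsher than averaging: a position that just misses the filter
loses its full 1/n credit while barely moving the mean similarity. This
ordering (SMACR below the per-frame mean similarity whenever positions
fail) holds throughout the noise regimes the fixtures exercise, but it
is not a theorem — with a solitary failing element at very low noise the
two statistics can sit within a fraction of a point of each other.

## Synthetic fixtures

The generators are pure functions of their spec (seed included).

*Click tracks*: 30 ms, 1 kHz sine bursts with 5 ms linear fades at exact
multiples of 60/bpm — sample-exact onsets, broadband enough for the
Mel-difference envelope, fully deterministic. Optional white noise at a
stated SNR (power ratio measured against the clean signal over its full
duration) and silent gaps; a click whose onset lies strictly inside an
open gap interval is dropped, boundary clicks are kept (a kept boundary
click's 30 ms body may spill into the gap). Default duration 30 s: long
enough for ~45–90 beats, the scale at which tempo autocorrelation and
F-measure are stable.

*Pose pairs*: per feature, the standard trajectory is a sum of 2–4
low-frequency sinusoids mapped into [20°, 175°] — smooth and bounded,
with the rough spectral character of repetitive movement; the evaluated
copy adds Gaussian angular noise, optional linear drift, and independent
entry dropout. Default n = 60 keyframes (30 s at 120 BPM) and m = 8
features.

What passing these fixtures does *not* show: clicks are not music (no
sustained harmonic energy, no syncopation, no tempo drift), so real
recordings can defeat the constant-tempo assumption; sinusoid
trajectories are not choreography, and angular Gaussian noise is not a
real dancer's error structure (which is correlated across joints and
time). The fixtures validate the algorithms' contracts, not field
performance.

## Problem sizes and tolerances

The shipped checks use 30 s click tracks at 60–180 BPM (5 tempi × 5
seeds, clean and at 20 dB SNR), beat matching within a ±70 ms window,
50 short random envelopes for the DP enumeration oracle, exhaustive LCS
verification for all binary pairs up to length 7 plus 1000 random pairs
up to length 30 against an independent memoized recurrence, and 100
seeded pose pairs per noise level. Floating-point identities are
asserted at 1e-9–1e-12; envelope normalization at 1e-9; the degenerate-
envelope threshold is 1 dB of maximum summed band rise.

## Known limitations

- One global tempo: no tempo drift, no downbeats, no meter.
- 2-D angles conflate out-of-plane rotation with joint flexion; a turn
  toward the camera changes apparent angles without any error by the
  dancer.
- The evaluated and standard sequences must have equal length and the
  same feature definition; no time-warping alignment is attempted
  (beat alignment is assumed to have done that job).
- Scores are relative to a single reference performance; they measure
  agreement, not artistic quality.
- WAV is the only audio input format; video decoding is out of scope —
  keyframes are exchanged as indices/CSV.
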