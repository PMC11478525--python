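# dancebeat

Beat-aligned evaluation of dance motion. Given a piece of music and
per-frame 2-D pose keypoints for a *standard* (reference) performance and
an *evaluated* performance, the toolkit:

1. detects musical beats by dynamic programming over an onset strength
   envelope, with a log-Gaussian perceptual prior centered on 120 BPM;
2. maps the beat instants to video **keyframes** (one frame per beat), so
   downstream pose matching touches only BPM/(60·fps) of the frames;
3. quantifies each keyframe as a vector of goniometric **joint angles**
   (elbows, shoulders, knees, hips) computed from OpenPose-layout
   keypoints;
4. scores the evaluated sequence against the standard one with two
   complementary statistics: **ASCS** for static accuracy and **SMACR**
   for movement continuity.

It is intended for dance-teaching and motion-assessment pipelines that
need an automatic, training-free score, and for anyone who wants a small,
transparent dynamic-programming beat tracker with ground-truthed test
fixtures.

## The model

**Beat tracking.** The onset strength envelope O(t) is the half-wave
rectified first difference of a 40-band Mel spectrogram in dB (8 kHz
analysis rate, 32 ms windows, 4 ms hops), high-passed at 0.4 Hz,
smoothed with a 20 ms Gaussian, and normalized to unit standard
deviation. The global beat period τₚ maximizes the tempo period strength

    TPS(τ) = W(τ) · Σₜ O(t) O(t−τ),   W(τ) = exp(−½ (log₂(τ/τ₀)/σ_τ)²)

with τ₀ = 0.5 s (120 BPM) and σ_τ = 1 octave, after a duple/triple
metrical resolution that folds the strength at 2τ and 3τ back onto τ.
Beats are the chain of frames maximizing

    C = Σᵢ O(tᵢ) + ω Σᵢ F(tᵢ−tᵢ₋₁, τₚ),   F(Δt, τₚ) = −(ln(Δt/τₚ))²

found by the left-to-right recursion C*(t) = O(t) + max over
τ ∈ [t−2τₚ, t−τₚ/2] of {ω F(t−τ, τₚ) + C*(τ)} with backtracking
(ω = 100 by default).

**Scoring.** With Qⱼ and Θⱼ the evaluated and standard n-long sequences
of feature j (j = 1..m joint angles),

    ASCS = mean over j of sⱼ,   sⱼ = (Qⱼ·Θⱼ) / (‖Qⱼ‖ ‖Θⱼ‖)

reported as a percent. SMACR thresholds per-position similarity scores
with a filter (0.85 by default) into a 0/1 sequence and computes the
ROUGE-L style ratio R_LCS = P_LCS = LCS(tokens, 1ⁿ)/n and
F_LCS = (1+β²)RP/(R+β²P); at equal lengths F_LCS = R_LCS for any β. A
run of near-misses that barely dents the average similarity shows up
here as broken continuity.

## Worked example

The `demo` subcommand generates a 20 s click track and a paired
standard/evaluated pose sequence, then runs the whole chain:

```
$ dancebeat demo --seed 7 --out-dir demo_out
tempo    : 120.00 BPM (40 beats, 40 true clicks)
keyframes: 40 of 480 frames (8.3%)
ASCS  (static accuracy) : 99.6%
SMACR (continuity)      : 100.0%
filter=0.85  beta=1.0  mode=per_feature
artifacts -> demo_out/
```

Reading the output: the tracker recovered the 120 BPM grid exactly (40
beats in 20 s); one keyframe per beat keeps 8.3% = 120/(60·24) of the
24 fps frames; the evaluated performance (8° angular noise, 2% keypoint
dropout) scores 99.6% on static accuracy and keeps full continuity at
the 0.85 filter. Individual stages are available as `beats`, `tempo`,
`keyframes`, `features`, `score`, and `simulate`; the same functionality
is importable from `dancebeat` as a library.

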