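"""Ground-truthed synthetic fixtures.

Two generators make the whole pipeline testable without external data:

* click tracks — short sinusoidal bursts at exact multiples of the beat
  period, optionally with additive white noise at a stated SNR and with
  silent gaps — together with the exact beat times;
* paired standard/evaluated pose-angle sequences, where the evaluated
  copy is the standard plus Gaussian angular noise, optional systematic
  drift, and random keypoint dropout.

Every generator is a pure function of its spec (seed included): identical
specs give bitwise-identical outputs.  The fixtures target the algorithms'
contracts, not realism — clicks are not music and sinusoid trajectories
are not choreography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import AudioSignal
from .errors import InvalidSpecError
from .pose import AngleFeatureDef, PoseDescriptionSequence, default_feature_def

CLICK_FREQ_HZ = 1000.0
CLICK_DUR_S = 0.030
CLICK_FADE_S = 0.005

ANGLE_LO = 20.0
ANGLE_HI = 175.0


@dataclass(frozen=True)
class ClickTrackSpec:
    """Parameters of a synthetic click track."""

    bpm: float = 120.0
    duration: float = 30.0
    sample_rate: int = 8000
    click_freq: float = CLICK_FREQ_HZ
    click_dur: float = CLICK_DUR_S
    noise_snr_db: float | None = None
    silent_gaps: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.bpm <= 0 or self.duration <= 0 or self.sample_rate <= 0:
            raise InvalidSpecError("bpm, duration and sample_rate must be positive")
        for start, end in self.silent_gaps:
            if not (0 <= start < end <= self.duration):
                raise InvalidSpecError(f"gap ({start}, {end}) outside [0, {self.duration}]")


@dataclass(frozen=True)
class PosePairSpec:
    """Parameters of a paired standard/evaluated pose sequence."""

    n_frames: int = 60
    feature_def: AngleFeatureDef = field(default_factory=default_feature_def)
    angle_noise_sd: float = 0.0   # degrees
    dropout_prob: float = 0.0
    drift: float = 0.0            # degrees per frame, systematic error
    beat_interval_s: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise InvalidSpecError("n_frames must be >= 1")
        if self.angle_noise_sd < 0 or self.drift < 0:
            raise InvalidSpecError("noise parameters must be >= 0")
        if not (0 <= self.dropout_prob <= 1):
            raise InvalidSpecError("dropout_prob must lie in [0, 1]")


def _click_burst(spec: ClickTrackSpec) -> np.ndarray:
    n = int(round(spec.click_dur * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    burst = np.sin(2 * np.pi * spec.click_freq * t)
    n_fade = int(round(CLICK_FADE_S * spec.sample_rate))
    if n_fade > 0:
        ramp = np.linspace(0.0, 1.0, n_fade, endpoint=False)
        burst[:n_fade] *= ramp
        burst[-n_fade:] *= ramp[::-1]
    return burst


def generate_click_track(spec: ClickTrackSpec) -> tuple[AudioSignal, np.ndarray]:
    """Synthesize a click track; returns the audio and the exact beat times.

    Click k starts at sample ``round(k * 60/bpm * sample_rate)``.  Clicks
    whose onset falls strictly inside an open silent-gap interval are
    dropped (boundary clicks are kept); noise is zeroed inside gaps.
    Returned beat times are the kept click onsets, sample-exact.
    """
    period = 60.0 / spec.bpm
    n_total = int(round(spec.duration * spec.sample_rate))
    burst = _click_burst(spec)
    samples = np.zeros(n_total)

    kept_times = []
    k = 0
    while True:
        t_k = k * period
        start = int(round(t_k * spec.sample_rate))
        if start >= n_total:
            break
        k += 1
        if any(lo < t_k < hi for lo, hi in spec.silent_gaps):
            continue
        end = min(start + len(burst), n_total)
        samples[start:end] += burst[: end - start]
        kept_times.append(start / spec.sample_rate)

    if spec.noise_snr_db is not None:
        p_signal = float(np.mean(samples ** 2))
        p_noise = p_signal / (10.0 ** (spec.noise_snr_db / 10.0))
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, np.sqrt(p_noise), n_total)
        for lo, hi in spec.silent_gaps:
            a = int(round(lo * spec.sample_rate))
            b = int(round(hi * spec.sample_rate))
            noise[a:b] = 0.0
        samples = samples + noise

    peak = float(np.abs(samples).max())
    if peak > 1.0:
        samples = samples / peak
    return AudioSignal(samples, spec.sample_rate), np.asarray(kept_times)


def _smooth_trajectories(spec: PosePairSpec, rng: np.random.Generator) -> np.ndarray:
    """Standard angles: 2-4 random low-frequency sinusoids per feature,
    mapped into [ANGLE_LO, ANGLE_HI]."""
    n, m = spec.n_frames, spec.feature_def.m
    t = np.arange(n)[:, None]
    angles = np.zeros((n, m))
    for j in range(m):
        n_comp = rng.integers(2, 5)
        freqs = rng.uniform(0.01, 0.08, n_comp)    # cycles per frame
        phases = rng.uniform(0, 2 * np.pi, n_comp)
        amps = rng.uniform(0.3, 1.0, n_comp)
        wave = (amps * np.sin(2 * np.pi * freqs * t + phases)).sum(axis=1)
        lo, hi = np.min(wave), np.max(wave)
        span = max(hi - lo, 1e-9)
        center = rng.uniform(60.0, 140.0)
        half_range = rng.uniform(20.0, 50.0)
        scaled = center + (2 * (wave - lo) / span - 1.0) * half_range
        angles[:, j] = np.clip(scaled, ANGLE_LO, ANGLE_HI)
    return angles


def generate_pose_pair(spec: PosePairSpec) -> tuple[PoseDescriptionSequence,
                                                    PoseDescriptionSequence]:
    """Generate (standard, evaluated) pose-description sequences.

    evaluated = standard + N(0, angle_noise_sd) + drift * frame, clipped
    to [0, 180], with each entry independently set ABSENT with
    probability ``dropout_prob``.
    """
    rng = np.random.default_rng(spec.seed)
    std_angles = _smooth_trajectories(spec, rng)
    noise = rng.normal(0.0, spec.angle_noise_sd, std_angles.shape) \
        if spec.angle_noise_sd > 0 else np.zeros_like(std_angles)
    drift = spec.drift * np.arange(spec.n_frames)[:, None]
    eval_angles = np.clip(std_angles + noise + drift, 0.0, 180.0)
    if spec.dropout_prob > 0:
        mask = rng.uniform(size=eval_angles.shape) < spec.dropout_prob
        eval_angles = eval_angles.copy()
        eval_angles[mask] = np.nan

    beat_times = np.arange(spec.n_frames) * spec.beat_interval_s
    std = PoseDescriptionSequence(std_angles, beat_times, spec.feature_def)
    ev = PoseDescriptionSequence(eval_angles, beat_times, spec.feature_def)
    return std, ev


def clicktrack_with_gap(bpm: float = 120.0, duration: float = 30.0,
                        gap: tuple[float, float] = (10.0, 15.0),
                        **kwargs) -> tuple[AudioSignal, np.ndarray]:
    """Convenience fixture: a click grid silenced over an interval."""
    spec = ClickTrackSpec(bpm=bpm, duration=duration, silent_gaps=(gap,), **kwargs)
    return generate_click_track(spec)
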