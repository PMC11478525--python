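"""End-to-end convenience wrappers and the run configuration.

``RunConfig`` gathers every tunable of the pipeline — DSP front end,
tempo prior, DP tracker, gap handling and scoring — with the defaults the
method was designed around (8 kHz analysis, 32 ms / 4 ms frames, 40 Mel
bands, 0.4 Hz high-pass, 20 ms smoothing, 120 BPM prior, filter 0.85).
Configs load from JSON or TOML; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .audio import DEFAULT_ANALYSIS_RATE, AudioSignal, resample_to_analysis_rate
from .envelope import (DEFAULT_HOP_S, DEFAULT_HP_CUTOFF_HZ, DEFAULT_N_MELS,
                       DEFAULT_SMOOTH_SIGMA_S, DEFAULT_WINDOW_S,
                       envelope_from_audio)
from .errors import ConfigError
from .keyframes import DEFAULT_GAP_FACTOR
from .scoring import DEFAULT_BETA, DEFAULT_FILTER, ScoringConfig
from .tempo import (DEFAULT_LAG_RANGE_S, DEFAULT_SIGMA_TAU_OCT, DEFAULT_TAU0_S,
                    TempoEstimate, TempoPrior, estimate_tempo)
from .tracker import DEFAULT_OMEGA, BeatSequence, BeatTrackerConfig, track_beats


@dataclass(frozen=True)
class RunConfig:
    """Merged parameter set for the whole pipeline."""

    analysis_rate: int = DEFAULT_ANALYSIS_RATE
    window_s: float = DEFAULT_WINDOW_S
    hop_s: float = DEFAULT_HOP_S
    n_mels: int = DEFAULT_N_MELS
    hp_cutoff_hz: float = DEFAULT_HP_CUTOFF_HZ
    smooth_sigma_s: float = DEFAULT_SMOOTH_SIGMA_S
    omega: float = DEFAULT_OMEGA
    tau0_s: float = DEFAULT_TAU0_S
    sigma_tau_oct: float = DEFAULT_SIGMA_TAU_OCT
    lag_range_s: tuple[float, float] = DEFAULT_LAG_RANGE_S
    window_lo_factor: float = 0.5
    window_hi_factor: float = 2.0
    gap_factor: float = DEFAULT_GAP_FACTOR
    filter: float = DEFAULT_FILTER
    beta: float = DEFAULT_BETA
    mode: str = "per_feature"

    @property
    def prior(self) -> TempoPrior:
        return TempoPrior(self.tau0_s, self.sigma_tau_oct)

    @property
    def tracker(self) -> BeatTrackerConfig:
        return BeatTrackerConfig(self.omega, self.window_lo_factor, self.window_hi_factor)

    @property
    def scoring(self) -> ScoringConfig:
        return ScoringConfig(filter=self.filter, beta=self.beta, mode=self.mode)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lag_range_s"] = list(d["lag_range_s"])
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix.lower() == ".toml":
            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "lag_range_s" in data:
            data = {**data, "lag_range_s": tuple(data["lag_range_s"])}
        return cls(**data)


def analyze_audio(audio: AudioSignal,
                  config: RunConfig = RunConfig()) -> tuple[TempoEstimate, BeatSequence]:
    """Full beat pipeline: resample -> envelope -> tempo -> DP tracking."""
    audio = resample_to_analysis_rate(audio, config.analysis_rate)
    env = envelope_from_audio(audio, config.window_s, config.hop_s, config.n_mels,
                              config.hp_cutoff_hz, config.smooth_sigma_s)
    tempo = estimate_tempo(env, config.prior, config.lag_range_s)
    beats = track_beats(env, tempo, config.tracker)
    return tempo, beats
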