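"""Beat-synchronous keyframe selection.

Each beat instant t_i maps to the video frame shown at that moment,
``round(t_i * fps)``; the resulting index sequence is the keyframe
sequence on which pose evaluation runs.  Because only one frame per beat
is kept, the fraction of frames processed downstream is BPM / (60 * fps).

Silent or beat-free stretches are reported, not filled: where consecutive
beats are much further apart than the median inter-beat interval the gap
is listed with the number of beats one would have expected inside it.
An optional filler synthesizes evenly spaced pseudo-beats inside gaps for
callers that prefer continuous coverage.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InsufficientDataError, InvalidInputError
from .tracker import BeatSequence

logger = logging.getLogger(__name__)

DEFAULT_GAP_FACTOR = 2.0


@dataclass(frozen=True)
class VideoMeta:
    """Frame rate and frame count of the companion video."""

    fps: float
    n_frames: int

    def __post_init__(self):
        if self.fps <= 0:
            raise InvalidInputError("fps must be positive")
        if self.n_frames < 0:
            raise InvalidInputError("n_frames must be non-negative")


@dataclass(frozen=True)
class KeyframeIndexSequence:
    """0-based frame indices selected at beat instants."""

    indices: np.ndarray           # strictly increasing ints
    source_beat_times: np.ndarray  # seconds, one per kept index
    fps: float

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class GapReport:
    """Beat-free stretches longer than factor x median interval."""

    gaps: list[tuple[float, float, int]]  # (start_s, end_s, n_missing_expected)
    median_interval_s: float


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def beats_to_frame_indices(beats: BeatSequence, meta: VideoMeta) -> KeyframeIndexSequence:
    """Map beat times to frame indices (round half away from zero, 0-based).

    Indices beyond ``n_frames - 1`` are dropped with a warning; duplicate
    indices (possible at high tempo / low frame rate) are collapsed,
    keeping the first beat's time.
    """
    if len(beats) == 0:
        raise InvalidInputError("empty beat sequence")
    raw = _round_half_away(beats.times * meta.fps).astype(np.int64)

    indices: list[int] = []
    times: list[float] = []
    for idx, t in zip(raw, beats.times):
        if idx >= meta.n_frames:
            logger.warning("beat at %.3f s maps to frame %d >= n_frames=%d; dropped",
                           t, idx, meta.n_frames)
            continue
        if indices and idx == indices[-1]:
            continue  # collapse duplicate, keep the first beat's time
        indices.append(int(idx))
        times.append(float(t))
    return KeyframeIndexSequence(np.asarray(indices, dtype=np.int64),
                                 np.asarray(times), meta.fps)


def find_beat_gaps(beats: BeatSequence, factor: float = DEFAULT_GAP_FACTOR) -> GapReport:
    """Report inter-beat intervals exceeding ``factor`` x the median interval.

    ``n_missing_expected = round(gap / median) - 1`` estimates how many
    beats a regular grid would have placed inside the gap.  No beats or
    keyframes are synthesized (gaps are simply skipped downstream).
    """
    if len(beats) < 2:
        raise InsufficientDataError("need at least 2 beats to measure intervals")
    if factor <= 1:
        raise InvalidInputError("gap factor must exceed 1")
    intervals = beats.intervals
    median = float(np.median(intervals))
    gaps = []
    for i, dt in enumerate(intervals):
        if dt > factor * median:
            n_missing = int(round(dt / median)) - 1
            gaps.append((float(beats.times[i]), float(beats.times[i + 1]), n_missing))
    return GapReport(gaps, median)


def fill_gap_beats(beats: BeatSequence, factor: float = DEFAULT_GAP_FACTOR) -> BeatSequence:
    """Alternative gap strategy: insert tau_p-spaced synthetic beats inside gaps.

    Each reported gap is filled with evenly spaced pseudo-beats at the
    median interval.  Off by default; the default pipeline ignores gaps.
    """
    report = find_beat_gaps(beats, factor)
    if not report.gaps:
        return beats
    times = list(beats.times)
    for start, end, _ in report.gaps:
        n_inner = int(math.floor((end - start) / report.median_interval_s + 1e-9)) - 1
        step = (end - start) / (n_inner + 1)
        times.extend(start + step * k for k in range(1, n_inner + 1))
    times = np.asarray(sorted(times))
    return BeatSequence(times, np.zeros_like(times), beats.tau_p)


def write_keyframes_csv(kf: KeyframeIndexSequence, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["beat_time_s", "frame_index"])
        for t, i in zip(kf.source_beat_times, kf.indices):
            writer.writerow([f"{t:.6f}", int(i)])


def write_keyframes_json(kf: KeyframeIndexSequence, path: str | Path,
                         gap_report: GapReport | None = None) -> None:
    doc = {
        "fps": kf.fps,
        "frame_indices": [int(i) for i in kf.indices],
        "beat_times_s": [round(float(t), 6) for t in kf.source_beat_times],
    }
    if gap_report is not None:
        doc["gaps"] = [{"start_s": s, "end_s": e, "n_missing_expected": m}
                       for s, e, m in gap_report.gaps]
        doc["median_interval_s"] = gap_report.median_interval_s
    Path(path).write_text(json.dumps(doc, indent=2))
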