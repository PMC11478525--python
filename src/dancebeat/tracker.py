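"""Dynamic-programming beat tracking.

Given the onset envelope O(t) and the global beat period tau_p, beats are
the chain of frames maximizing

    C = sum_i O(t_i) + omega * sum_i F(t_i - t_{i-1}, tau_p)

where F(dt, tau_p) = -(ln(dt / tau_p))^2 penalizes deviation from the
ideal spacing and omega balances onset strength against regularity.  The
recursion

    C*(t) = O(t) + max_{tau in [t - 2 tau_p, t - tau_p/2]} { omega F(t - tau, tau_p) + C*(tau) }

is evaluated left to right with backpointers P*(t); frames earlier than
tau_p/2 are chain starts (no predecessor), the final beat is the argmax of
C* over the last tau_p of the envelope, and the beat sequence is read off
by backtracking.  The search window bounds every inter-beat interval to
[tau_p/2, 2 tau_p].
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .envelope import OnsetEnvelope
from .errors import InsufficientDataError, InvalidInputError
from .tempo import TempoEstimate

DEFAULT_OMEGA = 100.0


@dataclass(frozen=True)
class BeatTrackerConfig:
    """DP weights and search window (multiples of tau_p)."""

    omega: float = DEFAULT_OMEGA
    window_lo_factor: float = 0.5
    window_hi_factor: float = 2.0

    def __post_init__(self):
        if self.omega <= 0:
            raise InvalidInputError("omega must be positive")
        if not (0 < self.window_lo_factor < 1 < self.window_hi_factor):
            raise InvalidInputError("require 0 < window_lo_factor < 1 < window_hi_factor")


@dataclass(frozen=True)
class BeatSequence:
    """Beat instants with their DP scores and the period used."""

    times: np.ndarray   # seconds, strictly increasing
    scores: np.ndarray  # C*(t_i)
    tau_p: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=np.float64))
        if len(times) < 1:
            raise InvalidInputError("a beat sequence holds at least one beat")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


def transition_cost(delta_t, tau_p: float):
    """F(dt, tau_p) = -(ln(dt / tau_p))^2.

    Zero exactly at dt == tau_p, negative elsewhere, symmetric in the
    log ratio (F(2 tau_p) == F(tau_p / 2)).  Accepts scalars or arrays.
    """
    delta_t = np.asarray(delta_t, dtype=np.float64)
    if np.any(delta_t <= 0) or tau_p <= 0:
        raise InvalidInputError("delta_t and tau_p must be positive")
    out = -np.log(delta_t / tau_p) ** 2
    return float(out) if out.ndim == 0 else out


def track_beats(env: OnsetEnvelope,
                tempo: TempoEstimate,
                config: BeatTrackerConfig = BeatTrackerConfig()) -> BeatSequence:
    """Find the beat chain maximizing the DP objective.

    Ties in the predecessor argmax break toward the earliest candidate.

    Raises
    ------
    InsufficientDataError
        If the envelope is shorter than one beat period.
    """
    tau_p = tempo.tau_p
    if tau_p <= 0:
        raise InvalidInputError("tau_p must be positive")
    hop = env.hop_seconds
    O = np.asarray(env.values, dtype=np.float64)
    n = len(O)
    period = int(round(tau_p / hop))
    if n <= period:
        raise InsufficientDataError(
            f"envelope ({n} frames) shorter than one beat period ({period} frames)")

    pmin = max(1, int(round(config.window_lo_factor * tau_p / hop)))
    pmax = max(pmin + 1, int(round(config.window_hi_factor * tau_p / hop)))
    # Transition scores for predecessor offsets pmin..pmax, ordered so that
    # larger offsets (earlier predecessors) come first: numpy argmax then
    # resolves ties toward the earliest candidate frame.
    offsets = np.arange(pmax, pmin - 1, -1)
    trans = config.omega * transition_cost(offsets * hop, tau_p)

    C = O.copy()
    P = np.full(n, -1, dtype=np.int64)
    for t in range(pmin, n):
        lo = max(0, t - pmax)
        hi = t - pmin
        # candidate predecessor frames lo..hi, aligned with trans tail
        cand = C[lo:hi + 1] + trans[len(offsets) - (hi - lo + 1):]
        k = int(np.argmax(cand))
        C[t] = O[t] + cand[k]
        P[t] = lo + k

    tail_start = max(0, n - period)
    end = tail_start + int(np.argmax(C[tail_start:]))

    chain = [end]
    while P[chain[-1]] >= 0:
        chain.append(int(P[chain[-1]]))
    chain.reverse()

    times = env.t0 + np.asarray(chain) * hop
    return BeatSequence(times, C[np.asarray(chain)], tau_p)


def write_beats_csv(beats: BeatSequence, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s"])
        for t in beats.times:
            writer.writerow([f"{t:.6f}"])


def write_beats_json(beats: BeatSequence, path: str | Path,
                     config: dict | None = None) -> None:
    doc = {
        "tempo_bpm": 60.0 / beats.tau_p,
        "tau_p_s": beats.tau_p,
        "beat_times_s": [round(float(t), 6) for t in beats.times],
        "config": config or {},
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_beats_json(path: str | Path) -> BeatSequence:
    doc = json.loads(Path(path).read_text())
    times = np.asarray(doc["beat_times_s"], dtype=np.float64)
    return BeatSequence(times, np.zeros_like(times), float(doc["tau_p_s"]))
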