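"""Beat-tracking accuracy metrics.

Standard F-measure evaluation: a detected beat matches a ground-truth
beat if it falls within a tolerance window (70 ms by default) and each
reference beat can be claimed at most once (greedy one-to-one matching in
time order).  The mean absolute error is computed over matched pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_WINDOW_S = 0.070


@dataclass(frozen=True)
class BeatEvaluation:
    f_measure: float
    precision: float
    recall: float
    n_matched: int
    mean_abs_error_s: float  # over matched pairs; NaN if none matched


def evaluate_beats(reference, detected, window_s: float = DEFAULT_WINDOW_S) -> BeatEvaluation:
    """Match detected beats to reference beats within ``window_s``."""
    ref = np.sort(np.asarray(reference, dtype=float))
    det = np.sort(np.asarray(detected, dtype=float))
    used = np.zeros(len(ref), dtype=bool)
    errors = []
    for t in det:
        if len(ref) == 0:
            break
        order = np.argsort(np.abs(ref - t))
        for j in order:
            if used[j]:
                continue
            if abs(ref[j] - t) <= window_s:
                used[j] = True
                errors.append(abs(ref[j] - t))
            break  # nearest unused candidate decides; no second chances
    n_matched = len(errors)
    precision = n_matched / len(det) if len(det) else 0.0
    recall = n_matched / len(ref) if len(ref) else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    mae = float(np.mean(errors)) if errors else float("nan")
    return BeatEvaluation(f, precision, recall, n_matched, mae)
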