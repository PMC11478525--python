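"""Performance scoring: ASCS and SMACR.

Two complementary statistics compare an evaluated pose-description
sequence Q (n keyframes x m joint angles) with the standard one Theta:

* **ASCS** (average score based on the cosine similarity of action
  sequences) measures *static accuracy*: for each feature j the cosine
  similarity s_j between the two n-long angle sequences Q_j and Theta_j,
  averaged over features, reported as a percent.

* **SMACR** (scoring method based on action contextual relationships)
  measures *continuity*: per-position similarity scores are thresholded
  by ``filter`` into a 0/1 token sequence, the standard binarized against
  itself is all ones, and the ROUGE-L style ratio
  R_LCS = P_LCS = LCS(tokens, ones) / n feeds
  F_LCS = (1 + beta^2) R P / (R + beta^2 P).  At equal lengths R = P so
  F_LCS = R_LCS regardless of beta.  A run of near-misses that would
  barely dent the average similarity shows up as broken continuity here.

The per-position score depends on the binarization axis: in
``per_feature`` mode (the default) each feature's token at frame i is
the cosine of the angular deviation, cos(theta_ij - Theta_ij), clamped
to [0, 1] — the cosine similarity of the two measured limb directions —
and the final SMACR averages F_LCS over features.  In ``per_frame`` mode
the token at frame i comes from the cosine similarity of the two m-long
angle vectors of that keyframe, giving a single token sequence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (InsufficientDataError, InvalidInputError,
                     UndefinedSimilarityError)
from .pose import PoseDescriptionSequence

DEFAULT_FILTER = 0.85
DEFAULT_BETA = 1.0
MIN_RETAINED = 2


@dataclass(frozen=True)
class ScoringConfig:
    """Threshold, F-measure beta, binarization axis, and ABSENT policy."""

    filter: float = DEFAULT_FILTER
    beta: float = DEFAULT_BETA
    mode: str = "per_feature"          # or "per_frame"
    absent_policy: str = "pairwise-delete"  # or "fail"
    levels: int = 2                    # 3 enables {0,1,2} quantization

    def __post_init__(self):
        if not (0 < self.filter <= 1):
            raise InvalidInputError("filter must lie in (0, 1]")
        if self.beta <= 0:
            raise InvalidInputError("beta must be positive")
        if self.mode not in ("per_feature", "per_frame"):
            raise InvalidInputError(f"unknown mode {self.mode!r}")
        if self.absent_policy not in ("pairwise-delete", "fail"):
            raise InvalidInputError(f"unknown absent_policy {self.absent_policy!r}")
        if self.levels not in (2, 3):
            raise InvalidInputError("levels must be 2 or 3")


@dataclass(frozen=True)
class SimilarityBreakdown:
    """Per-feature and per-frame cosine similarities with their mean."""

    s_per_feature: np.ndarray  # length m
    s_per_frame: np.ndarray    # length n
    mean_score: float          # mean of s_per_feature, in [0, 1]


@dataclass(frozen=True)
class BinarySequence:
    """Thresholded token sequence."""

    tokens: np.ndarray
    threshold_used: float


@dataclass(frozen=True)
class EvaluationReport:
    """ASCS + SMACR with breakdowns and the configuration used."""

    ascs: float    # percent
    smacr: float   # percent
    r_lcs: float
    p_lcs: float
    f_lcs: float
    breakdown: SimilarityBreakdown
    per_feature_f_lcs: dict[str, float] = field(default_factory=dict)
    config: ScoringConfig = field(default_factory=ScoringConfig)

    def to_dict(self) -> dict:
        return {
            "ascs_pct": round(self.ascs, 1),
            "smacr_pct": round(self.smacr, 1),
            "r_lcs": self.r_lcs,
            "p_lcs": self.p_lcs,
            "f_lcs": self.f_lcs,
            "per_feature": {k: round(v, 4) for k, v in self.per_feature_f_lcs.items()},
            "per_frame": [round(float(s), 4) for s in self.breakdown.s_per_frame],
            "per_feature_similarity": [round(float(s), 4)
                                       for s in self.breakdown.s_per_feature],
            "config": {"filter": self.config.filter, "beta": self.config.beta,
                       "mode": self.config.mode, "levels": self.config.levels},
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        return (f"ASCS  (static accuracy) : {self.ascs:.1f}%\n"
                f"SMACR (continuity)      : {self.smacr:.1f}%\n"
                f"filter={self.config.filter}  beta={self.config.beta}  "
                f"mode={self.config.mode}")


def _pairwise_present(q: np.ndarray, theta: np.ndarray,
                      policy: str) -> tuple[np.ndarray, np.ndarray]:
    mask = np.isfinite(q) & np.isfinite(theta)
    if policy == "fail" and not mask.all():
        raise InsufficientDataError("ABSENT entries present and absent_policy='fail'")
    if mask.sum() < MIN_RETAINED:
        raise InsufficientDataError(
            f"fewer than {MIN_RETAINED} positions present in both sequences")
    return q[mask], theta[mask]


def cosine_similarity_seq(q, theta, absent_policy: str = "pairwise-delete") -> float:
    """Cosine similarity (q . theta) / (|q| |theta|) with pairwise deletion of ABSENT."""
    q = np.asarray(q, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    if q.shape != theta.shape or q.ndim != 1 or len(q) == 0:
        raise InvalidInputError("sequences must be 1-D, non-empty and of equal length")
    q, theta = _pairwise_present(q, theta, absent_policy)
    nq = float(np.linalg.norm(q))
    nt = float(np.linalg.norm(theta))
    if nq == 0.0 or nt == 0.0:
        raise UndefinedSimilarityError("zero-norm vector: cosine similarity undefined")
    return float(np.dot(q, theta) / (nq * nt))


def _check_shapes(eval_seq: PoseDescriptionSequence, std_seq: PoseDescriptionSequence):
    if eval_seq.angles.shape != std_seq.angles.shape:
        raise InvalidInputError(
            f"shape mismatch: evaluated {eval_seq.angles.shape} vs standard {std_seq.angles.shape}")
    if eval_seq.feature_def.names != std_seq.feature_def.names:
        raise InvalidInputError("feature definitions differ between sequences")


def ascs_score(eval_seq: PoseDescriptionSequence, std_seq: PoseDescriptionSequence,
               config: ScoringConfig = ScoringConfig()) -> SimilarityBreakdown:
    """Per-feature (columns) and per-frame (rows) cosine similarities.

    The overall score is the mean of the per-feature similarities s_j.
    """
    _check_shapes(eval_seq, std_seq)
    q, theta = eval_seq.angles, std_seq.angles
    s_feat = np.array([cosine_similarity_seq(q[:, j], theta[:, j], config.absent_policy)
                       for j in range(q.shape[1])])
    s_frame = np.array([cosine_similarity_seq(q[i], theta[i], config.absent_policy)
                        for i in range(q.shape[0])])
    return SimilarityBreakdown(s_feat, s_frame, float(s_feat.mean()))


def angular_similarity(eval_deg, std_deg):
    """Elementwise cos(delta) of two angle arrays in degrees, clamped to [0, 1].

    This is the cosine similarity of the unit limb directions at the two
    measured angles; NaN propagates.
    """
    delta = np.radians(np.asarray(eval_deg, dtype=float) - np.asarray(std_deg, dtype=float))
    return np.clip(np.cos(delta), 0.0, 1.0)


def binarize_scores(scores, filter: float = DEFAULT_FILTER,
                    levels: int = 2) -> BinarySequence:
    """Threshold similarity scores into tokens; the boundary is inclusive.

    ``levels=2``: 1 iff score >= filter.  ``levels=3`` adds a top tier at
    (1 + filter) / 2, giving tokens in {0, 1, 2}.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if np.any((scores < 0) | (scores > 1)):
        raise InvalidInputError("scores must lie in [0, 1]")
    tokens = (scores >= filter).astype(np.int64)
    if levels == 3:
        tokens += (scores >= (1.0 + filter) / 2.0).astype(np.int64)
    return BinarySequence(tokens, filter)


def lcs_length(a, b) -> int:
    """Longest common subsequence length by O(|a||b|) dynamic programming."""
    a = list(a)
    b = list(b)
    if not a or not b:
        return 0
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    bv = np.asarray(b)
    for x in a:
        cur = np.empty_like(prev)
        cur[0] = 0
        match = prev[:-1] + (bv == x)
        np.maximum(match, prev[1:], out=cur[1:])
        np.maximum.accumulate(cur, out=cur)
        prev = cur
    return int(prev[-1])


def _f_lcs(r: float, p: float, beta: float) -> float:
    denom = r + beta * beta * p
    if denom == 0.0:
        return 0.0
    return (1.0 + beta * beta) * r * p / denom


def smacr_score(eval_seq: PoseDescriptionSequence, std_seq: PoseDescriptionSequence,
                config: ScoringConfig = ScoringConfig()) -> EvaluationReport:
    """Continuity score; also computes ASCS so the report carries both.

    Positions where either sequence is ABSENT are dropped pairwise before
    tokenization (so n is the retained count).  The standard sequence
    binarized against itself is all ones (all top-level tokens), hence
    R_LCS = P_LCS and F_LCS reduces to R_LCS independent of beta.
    """
    _check_shapes(eval_seq, std_seq)
    breakdown = ascs_score(eval_seq, std_seq, config)
    q, theta = eval_seq.angles, std_seq.angles
    top = 1 if config.levels == 2 else 2

    per_feature_f: dict[str, float] = {}
    if config.mode == "per_feature":
        fs = []
        for j, name in enumerate(eval_seq.feature_def.names):
            qj, tj = _pairwise_present(q[:, j], theta[:, j], config.absent_policy)
            scores = angular_similarity(qj, tj)
            tokens = binarize_scores(scores, config.filter, config.levels).tokens
            std_tokens = np.full(len(tokens), top, dtype=np.int64)
            r = lcs_length(tokens, std_tokens) / len(tokens)
            f = _f_lcs(r, r, config.beta)
            per_feature_f[name] = f
            fs.append(f)
        r_lcs = p_lcs = float(np.mean(fs))
        f_lcs = float(np.mean(fs))
    else:
        scores = np.clip(breakdown.s_per_frame, 0.0, 1.0)
        tokens = binarize_scores(scores, config.filter, config.levels).tokens
        std_tokens = np.full(len(tokens), top, dtype=np.int64)
        r_lcs = p_lcs = lcs_length(tokens, std_tokens) / len(tokens)
        f_lcs = _f_lcs(r_lcs, p_lcs, config.beta)

    return EvaluationReport(
        ascs=100.0 * breakdown.mean_score,
        smacr=100.0 * f_lcs,
        r_lcs=r_lcs, p_lcs=p_lcs, f_lcs=f_lcs,
        breakdown=breakdown,
        per_feature_f_lcs=per_feature_f,
        config=config,
    )


def evaluate(eval_seq: PoseDescriptionSequence, std_seq: PoseDescriptionSequence,
             config: ScoringConfig = ScoringConfig()) -> EvaluationReport:
    """Score an evaluated performance against the standard one.

    Returns a report with ASCS (static accuracy, percent), SMACR
    (continuity, percent), the LCS ratios, and the per-feature /
    per-frame similarity breakdown.  Deterministic.
    """
    return smacr_score(eval_seq, std_seq, config)
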