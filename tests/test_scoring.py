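import itertools
import math
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dancebeat import (AngleFeatureDef, InsufficientDataError, InvalidInputError,
                       PoseDescriptionSequence, ScoringConfig,
                       UndefinedSimilarityError, angular_similarity, ascs_score,
                       binarize_scores, cosine_similarity_seq, evaluate,
                       lcs_length)
from dancebeat.synthetic import PosePairSpec, generate_pose_pair


def two_feature_seq(columns):
    """Build a PoseDescriptionSequence from column lists."""
    angles = np.asarray(columns, dtype=float).T
    m = angles.shape[1]
    names = [f"f{j}" for j in range(m)]
    fdef = AngleFeatureDef(tuple((n, ("nose", "neck", "l_hip")) for n in names))
    return PoseDescriptionSequence(angles, np.arange(angles.shape[0]) * 0.5, fdef)


class TestCosineSimilarity:
    def test_identity(self):
        assert cosine_similarity_seq([3.0, 4.0], [3.0, 4.0]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity_seq([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_direct_formula(self):
        assert cosine_similarity_seq([1.0, 0.0], [1.0, 1.0]) == pytest.approx(
            1.0 / math.sqrt(2.0), rel=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            cosine_similarity_seq([0.0, 0.0], [1.0, 1.0])

    def test_all_absent_rejected(self):
        with pytest.raises(InsufficientDataError):
            cosine_similarity_seq([np.nan, np.nan], [1.0, 1.0])

    def test_pairwise_deletion(self):
        s = cosine_similarity_seq([1.0, np.nan, 0.0], [1.0, 5.0, 1.0])
        assert s == pytest.approx(1.0 / math.sqrt(2.0), rel=1e-12)


class TestASCS:
    def test_identity_is_100_percent(self):
        seq = two_feature_seq([[90, 90, 45], [10, 20, 30]])
        assert 100 * ascs_score(seq, seq).mean_score == pytest.approx(100.0)

    def test_worked_example(self):
        """m=2, n=2 hand example: s = (1 + 2/sqrt(5)) / 2 ~ 0.9472."""
        q = two_feature_seq([[90.0, 90.0], [90.0, 90.0]])
        theta = two_feature_seq([[90.0, 90.0], [45.0, 135.0]])
        bd = ascs_score(q, theta)
        # independent direct evaluation of the cosine formula
        expected_s2 = (90 * 45 + 90 * 135) / (
            math.sqrt(90**2 + 90**2) * math.sqrt(45**2 + 135**2))
        assert bd.s_per_feature[0] == pytest.approx(1.0, abs=1e-12)
        assert bd.s_per_feature[1] == pytest.approx(expected_s2, abs=1e-9)
        assert 100 * bd.mean_score == pytest.approx(94.7213595, abs=1e-5)

    def test_scale_invariance(self):
        q = two_feature_seq([[30, 60, 20], [15, 25, 35]])
        theta = two_feature_seq([[35, 55, 25], [10, 30, 30]])
        a = ascs_score(q, theta).s_per_feature
        q2 = PoseDescriptionSequence(q.angles * 2.0, q.beat_times, q.feature_def)
        t2 = PoseDescriptionSequence(theta.angles * 2.0, theta.beat_times,
                                     theta.feature_def)
        b = ascs_score(q2, t2).s_per_feature
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        q = two_feature_seq([[90, 90], [90, 90]])
        theta = two_feature_seq([[90, 90, 90], [90, 90, 90]])
        with pytest.raises(InvalidInputError):
            ascs_score(q, theta)


class TestBinarize:
    def test_threshold_rule(self):
        out = binarize_scores([0.90, 0.80, 0.86], 0.85)
        assert list(out.tokens) == [1, 0, 1]

    def test_boundary_inclusive(self):
        assert list(binarize_scores([0.85], 0.85).tokens) == [1]

    def test_all_perfect(self):
        assert list(binarize_scores([1.0, 1.0], 0.85).tokens) == [1, 1]

    def test_three_levels(self):
        out = binarize_scores([0.99, 0.90, 0.80], 0.85, levels=3)
        assert list(out.tokens) == [2, 1, 0]


def brute_force_lcs(a, b):
    """Oracle: enumerate all distinct subsequences of a, keep the longest
    that is also a subsequence of b."""
    def is_subseq(s, t):
        it = iter(t)
        return all(x in it for x in s)

    best = 0
    seen = set()
    for r in range(len(a), 0, -1):
        for comb in itertools.combinations(range(len(a)), r):
            s = tuple(a[i] for i in comb)
            if s in seen:
                continue
            seen.add(s)
            if is_subseq(s, b):
                return r
    return best


def memoized_lcs(a, b):
    """Independent top-down implementation of the LCS recurrence."""
    a, b = tuple(a), tuple(b)

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 or j == 0:
            return 0
        if a[i - 1] == b[j - 1]:
            return rec(i - 1, j - 1) + 1
        return max(rec(i - 1, j), rec(i, j - 1))

    return rec(len(a), len(b))


class TestLCS:
    def test_identity(self):
        assert lcs_length([1, 0, 1], [1, 0, 1]) == 3

    def test_known_instance(self):
        assert lcs_length([1, 0, 1, 0, 1], [1, 1, 1, 1, 1]) == 3

    def test_empty(self):
        assert lcs_length([], [1, 1]) == 0

    def test_exhaustive_small_binary_pairs(self):
        """All binary pairs with lengths up to 5 against the brute-force oracle."""
        for la in range(6):
            for lb in range(6):
                for a in itertools.product([0, 1], repeat=la):
                    for b in itertools.product([0, 1], repeat=lb):
                        assert lcs_length(a, b) == brute_force_lcs(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_pairs_against_memoized_recurrence(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            a = rng.integers(0, 2, rng.integers(1, 31))
            b = rng.integers(0, 2, rng.integers(1, 31))
            assert lcs_length(a, b) == memoized_lcs(a, b)

    @given(st.lists(st.integers(0, 1), max_size=20),
           st.lists(st.integers(0, 1), max_size=20))
    @settings(deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, a, b):
        l = lcs_length(a, b)
        assert l == lcs_length(b, a)
        assert l <= min(len(a), len(b))

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=10),
           st.lists(st.integers(0, 1), min_size=1, max_size=10),
           st.lists(st.integers(0, 1), min_size=1, max_size=10),
           st.lists(st.integers(0, 1), min_size=1, max_size=10))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_superadditive_under_concatenation(self, a1, b1, a2, b2):
        assert lcs_length(a1 + a2, b1 + b2) >= lcs_length(a1, b1) + lcs_length(a2, b2)


class TestSMACR:
    def test_identity_is_100_percent(self):
        std, ev = generate_pose_pair(PosePairSpec(angle_noise_sd=0.0, seed=3))
        report = evaluate(ev, std)
        assert report.ascs == pytest.approx(100.0)
        assert report.smacr == pytest.approx(100.0)

    def test_count_of_passes_against_all_ones_standard(self):
        """5 passing frames of 9 give 5/9 ~ 55.6% in per_frame terms."""
        tokens = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1])
        assert lcs_length(tokens, np.ones(9, int)) == 5
        assert 100 * lcs_length(tokens, np.ones(9, int)) / 9 == pytest.approx(55.6, abs=0.1)

    def test_beta_independence_at_equal_length(self):
        std, ev = generate_pose_pair(PosePairSpec(angle_noise_sd=25.0, seed=4))
        reports = [evaluate(ev, std, ScoringConfig(beta=b)) for b in (0.5, 1.0, 2.0)]
        assert reports[0].smacr == reports[1].smacr == reports[2].smacr
        assert reports[0].r_lcs == reports[0].p_lcs == reports[0].f_lcs

    def test_filter_limits(self):
        std, ev = generate_pose_pair(PosePairSpec(angle_noise_sd=30.0, seed=5))
        # per-frame cosine scores of positive angle vectors are strictly
        # positive, so a vanishing filter passes every frame
        loose = evaluate(ev, std, ScoringConfig(filter=1e-9, mode="per_frame"))
        assert loose.smacr == pytest.approx(100.0)
        strict = evaluate(ev, std, ScoringConfig(filter=1.0))
        assert strict.smacr < 100.0

    def test_monotone_in_token_flips(self):
        """Flipping any 0 token to 1 never decreases the LCS ratio."""
        rng = np.random.default_rng(0)
        tokens = rng.integers(0, 2, 20)
        ones = np.ones(20, int)
        base = lcs_length(tokens, ones)
        for i in np.flatnonzero(tokens == 0):
            flipped = tokens.copy()
            flipped[i] = 1
            assert lcs_length(flipped, ones) >= base

    @pytest.mark.parametrize("noise_sd", [20.0, 45.0])
    def test_smacr_below_mean_similarity_when_frames_fail(self, noise_sd):
        """Continuity penalizes failing positions harder than averaging does.

        Asserted at noise levels where failures are non-negligible; a
        solitary failing element at very low noise can leave the two
        statistics within a fraction of a point of each other.
        """
        found = 0
        for seed in range(20):
            std, ev = generate_pose_pair(PosePairSpec(angle_noise_sd=noise_sd, seed=seed))
            report = evaluate(ev, std)
            mean_sim_pct = 100.0 * float(np.mean(report.breakdown.s_per_frame))
            if report.smacr < 100.0:  # at least one position failed the filter
                found += 1
                assert report.smacr < mean_sim_pct
        assert found > 0

    def test_bounds_and_config_echo(self):
        std, ev = generate_pose_pair(PosePairSpec(angle_noise_sd=10.0, seed=6))
        cfg = ScoringConfig(filter=0.9, beta=2.0)
        report = evaluate(ev, std, cfg)
        assert 0 <= report.smacr <= 100.0
        assert 0 <= report.ascs <= 100.0
        assert report.config.filter == 0.9
        assert report.config.beta == 2.0
        d = report.to_dict()
        assert d["config"]["filter"] == 0.9

    def test_angular_similarity_basic(self):
        np.testing.assert_allclose(angular_similarity([90.0], [90.0]), [1.0])
        assert angular_similarity([150.0], [90.0])[0] == pytest.approx(0.5, abs=1e-12)
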