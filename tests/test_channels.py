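import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import emodec as em
from emodec.channels import STATISTICS
from emodec.errors import DegenerateSignalError, ValidationError


def brute_force_statistic(x, statistic):
    """Independent oracle: direct loops over the defining formulas."""
    n = len(x)
    mean = sum(x) / n
    if statistic == "mean":
        return mean
    if statistic == "rms":
        return math.sqrt(sum(v * v for v in x) / n)
    var = sum((v - mean) ** 2 for v in x) / n
    if statistic == "variance":
        return var
    sigma = math.sqrt(var)
    if statistic == "skewness":
        return sum(((v - mean) / sigma) ** 3 for v in x) / n
    return sum(((v - mean) / sigma) ** 4 for v in x) / n


class TestChannelStatistic:
    def test_worked_vector(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert em.channel_statistic(x, "mean") == 2.5
        assert em.channel_statistic(x, "variance") == 1.25
        assert em.channel_statistic(x, "rms") == pytest.approx(2.7386127875258306, rel=1e-12)
        assert em.channel_statistic(x, "skewness") == pytest.approx(0.0, abs=1e-12)
        assert em.channel_statistic(x, "kurtosis") == pytest.approx(1.64, rel=1e-12)

    @pytest.mark.parametrize("statistic", STATISTICS)
    def test_matches_brute_force_oracle(self, statistic, rng):
        for _ in range(50):
            x = rng.standard_normal(int(rng.integers(2, 513))) * rng.uniform(0.1, 50)
            expected = brute_force_statistic(list(x), statistic)
            assert em.channel_statistic(x, statistic) == pytest.approx(expected, rel=1e-10)

    def test_matches_scipy_population_moments(self, rng):
        from scipy import stats

        x = rng.standard_normal(1000)
        assert em.channel_statistic(x, "skewness") == pytest.approx(stats.skew(x, bias=True), rel=1e-10)
        assert em.channel_statistic(x, "kurtosis") == pytest.approx(
            stats.kurtosis(x, fisher=False, bias=True), rel=1e-10
        )

    def test_gaussian_kurtosis_is_three(self):
        x = np.random.default_rng(42).standard_normal(10**6)
        assert em.channel_statistic(x, "kurtosis") == pytest.approx(3.0, abs=0.05)

    def test_constant_signal(self):
        x = [5.0] * 4
        assert em.channel_statistic(x, "variance") == 0.0
        assert em.channel_statistic(x, "rms") == 5.0
        for statistic in ("skewness", "kurtosis"):
            with pytest.raises(DegenerateSignalError):
                em.channel_statistic(x, statistic, channel=3)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        x=arrays(np.float64, st.integers(4, 64), elements=st.floats(-100, 100)).filter(
            lambda a: np.var(a) > 1e-8
        ),
        a=st.floats(0.1, 10.0),
    )
    def test_scale_equivariance(self, x, a):
        assert em.channel_statistic(a * x, "mean") == pytest.approx(
            a * em.channel_statistic(x, "mean"), abs=1e-9 * a * 100
        )
        assert em.channel_statistic(a * x, "rms") == pytest.approx(
            a * em.channel_statistic(x, "rms"), rel=1e-9
        )
        assert em.channel_statistic(a * x, "variance") == pytest.approx(
            a * a * em.channel_statistic(x, "variance"), rel=1e-9
        )
        for statistic in ("skewness", "kurtosis"):
            assert em.channel_statistic(a * x, statistic) == pytest.approx(
                em.channel_statistic(x, statistic), rel=1e-7, abs=1e-9
            )


class TestScoreChannels:
    def test_spiky_channel_outranks_gaussian(self, rng):
        n, p = 20, 256
        noise = rng.standard_normal((n, p, 2))
        spikes = np.zeros((n, p))
        idx = rng.integers(0, p, size=n)
        spikes[np.arange(n), idx] = 25.0
        tensor = noise.copy()
        tensor[:, :, 0] += spikes
        segs = em.SegmentSet(tensor, np.zeros(n, int), np.array(["s"] * n, dtype=object), 256.0, ["spiky", "plain"])
        segs.labels[: n // 2] = 1
        ranking = em.score_channels(segs, "kurtosis")
        assert ranking.scores[0] > ranking.scores[1]
        assert list(ranking.order) == [0, 1]

    def test_all_zero_variance_falls_back_to_index_order(self):
        segs = em.SegmentSet(
            np.zeros((3, 8, 4)), np.array([0, 1, 0]), np.array(["s"] * 3, dtype=object), 32.0, list("abcd")
        )
        ranking = em.score_channels(segs, "variance")
        assert list(ranking.scores) == [0.0] * 4
        assert list(ranking.order) == [0, 1, 2, 3]

    def test_train_scope_equals_all_when_all_in_train(self, small_segments):
        full = em.score_channels(small_segments, "rms", scope="all")
        sub = em.score_channels(small_segments, "rms", scope="train_only", train_indices=range(12))
        np.testing.assert_array_equal(full.scores, sub.scores)

    def test_concatenated_scores_invariant_to_segment_order(self, small_segments):
        shuffled = small_segments.subset(np.random.default_rng(3).permutation(12))
        a = em.score_channels(small_segments, "variance").scores
        b = em.score_channels(shuffled, "variance").scores
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_degenerate_channel_named_or_tolerated(self, small_segments):
        small_segments.tensor[:, :, 2] = 7.0
        with pytest.raises(DegenerateSignalError, match="c2"):
            em.score_channels(small_segments, "kurtosis")
        ranking = em.score_channels(small_segments, "kurtosis", tolerate_degenerate=True)
        assert ranking.scores[2] == -np.inf
        assert ranking.order[-1] == 2


class TestSelection:
    def test_top_k_simple(self):
        r = _ranking([0.5, 2.0, 1.0])
        assert list(em.select_top_k(r, 2).selected) == [1, 2]

    def test_tie_breaks_to_lower_index(self):
        r = _ranking([1.0, 1.0, 0.9])
        assert list(em.select_top_k(r, 1).selected) == [0]

    def test_k_equals_c_is_permutation(self):
        r = em.select_top_k(_ranking([0.3, 0.9, 0.1, 0.5]), 4)
        assert sorted(r.selected) == [0, 1, 2, 3]

    def test_k_out_of_range_rejected(self):
        r = _ranking([1.0, 2.0])
        for k in (0, 3):
            with pytest.raises(ValidationError):
                em.select_top_k(r, k)

    def test_idempotent_and_deterministic(self):
        r = _ranking([0.3, 0.9, 0.1, 0.5])
        once = em.select_top_k(r, 2)
        twice = em.select_top_k(once, 2)
        assert list(once.selected) == list(twice.selected) == [1, 3]

    def test_apply_selection_reduces_channels(self, small_segments):
        ranking = em.select_top_k(em.score_channels(small_segments, "variance"), 3)
        out = em.apply_selection(small_segments, ranking)
        assert out.tensor.shape == (12, 64, 3)
        assert out.channel_labels == [small_segments.channel_labels[i] for i in ranking.selected]
        np.testing.assert_array_equal(out.tensor, small_segments.tensor[:, :, ranking.selected])

    def test_selection_composes(self, small_segments):
        """Selecting k then k' < k equals one selection with the composed subset."""
        r5 = em.select_top_k(em.score_channels(small_segments, "rms"), 4)
        step1 = em.apply_selection(small_segments, r5)
        r2 = em.select_top_k(em.score_channels(step1, "rms"), 2)
        two_step = em.apply_selection(step1, r2)
        direct = em.apply_selection(
            small_segments, em.select_top_k(em.score_channels(small_segments, "rms"), 2)
        )
        np.testing.assert_array_equal(two_step.tensor, direct.tensor)
        assert two_step.channel_labels == direct.channel_labels

    def test_mismatched_channel_count_rejected(self, small_segments):
        ranking = em.select_top_k(_ranking([1.0, 0.5]), 1)
        with pytest.raises(ValidationError):
            em.apply_selection(small_segments, ranking)


def _ranking(scores):
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    return em.ChannelRanking(
        statistic="variance",
        scores=scores,
        order=order,
        channel_labels=tuple(f"c{i}" for i in range(len(scores))),
    )
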