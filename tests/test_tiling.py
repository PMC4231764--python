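"""Per-probe signal estimation: quantile normalization, Hodges-Lehmann
pseudo-median and the signed-rank change P-value, checked against
brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from tilechip._stats import hodges_lehmann, wilcoxon_signed_rank_p
from tilechip.tiling import ProbeTrack, quantile_normalize, smooth_track


def hl_oracle(values):
    """Walsh-average enumeration by explicit nested loops."""
    walsh = [
        (values[i] + values[j]) / 2.0
        for i in range(len(values))
        for j in range(i, len(values))
    ]
    return float(np.median(walsh))


def signed_rank_oracle(values):
    """One-sided P by full 2^n enumeration of sign assignments."""
    x = np.array([v for v in values if v != 0], dtype=float)
    n = len(x)
    ranks = scipy.stats.rankdata(np.abs(x))
    w_obs = ranks[x > 0].sum()
    count = sum(
        1
        for signs in itertools.product([0, 1], repeat=n)
        if ranks[np.array(signs, dtype=bool)].sum() >= w_obs - 1e-12
    )
    return count / 2**n


class TestQuantileNormalize:
    def test_rank_means_hand_example(self):
        track = ProbeTrack("chrI", [100, 200, 300], [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        out = quantile_normalize(track)
        np.testing.assert_allclose(out.values[0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.values[1], [2.5, 3.5, 4.5])

    def test_handles_discordant_orderings(self):
        track = ProbeTrack("chrI", [1, 2, 3], [[3.0, 1.0, 2.0], [10.0, 30.0, 20.0]])
        out = quantile_normalize(track)
        # rank-matched means: (1+10)/2, (2+20)/2, (3+30)/2
        np.testing.assert_allclose(sorted(out.values[0]), [5.5, 11.0, 16.5])
        # each replicate keeps its own ordering of ranks
        assert out.values[0].argsort().tolist() == [1, 2, 0]
        assert out.values[1].argsort().tolist() == [0, 2, 1]

    def test_identical_replicates_are_fixed_point(self):
        track = ProbeTrack("chrI", [1, 2, 3], [[1.0, 5.0, 2.0], [1.0, 5.0, 2.0]])
        out = quantile_normalize(track)
        np.testing.assert_allclose(out.values, track.values)

    def test_single_replicate_is_identity_with_warning(self):
        track = ProbeTrack("chrI", [1, 2], [[1.0, 2.0]])
        with pytest.warns(UserWarning, match="single replicate"):
            out = quantile_normalize(track)
        np.testing.assert_allclose(out.values, track.values)

    def test_list_in_list_out(self):
        singles = [
            ProbeTrack("chrI", [1, 2], [[1.0, 2.0]]),
            ProbeTrack("chrI", [1, 2], [[3.0, 4.0]]),
        ]
        out = quantile_normalize(singles)
        assert isinstance(out, list) and len(out) == 2
        np.testing.assert_allclose(out[0].values[0], [2.0, 3.0])

    def test_mismatched_grids_error_names_position(self):
        singles = [
            ProbeTrack("chrI", [1, 2, 3], [[1.0, 2.0, 3.0]]),
            ProbeTrack("chrI", [1, 5, 9], [[1.0, 2.0, 3.0]]),
        ]
        with pytest.raises(ValueError, match="first discordance at 2"):
            quantile_normalize(singles)


class TestEstimators:
    def test_hodges_lehmann_hand_example(self):
        # Walsh averages of {1,2,3}: {1, 1.5, 2, 2, 2.5, 3} -> median 2
        assert hodges_lehmann([1.0, 2.0, 3.0]) == 2.0

    def test_signed_rank_all_positive_n3(self):
        # all 2^3 sign assignments, one reaches W+ = 6 -> P = 1/8
        assert wilcoxon_signed_rank_p([1.0, 2.0, 3.0]) == pytest.approx(0.125)

    def test_all_zero_window(self):
        assert hodges_lehmann([0.0, 0.0, 0.0]) == 0.0
        assert wilcoxon_signed_rank_p([0.0, 0.0, 0.0]) == 1.0

    def test_single_value_window_conventional_p(self):
        with pytest.warns(UserWarning, match="single"):
            assert wilcoxon_signed_rank_p([2.0]) == 1.0

    @given(
        st.lists(
            st.integers(-20, 20).map(lambda v: v / 4.0), min_size=2, max_size=12
        )
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_enumeration_oracles(self, values):
        # ties and zeros included on purpose: same midrank/zero conventions
        assert hodges_lehmann(values) == pytest.approx(hl_oracle(values))
        nonzero = [v for v in values if v != 0]
        if len(nonzero) >= 2:
            assert wilcoxon_signed_rank_p(values) == pytest.approx(
                signed_rank_oracle(values)
            )

    def test_matches_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(0.3, 1.0, size=10)
            expected = scipy.stats.wilcoxon(x, alternative="greater", mode="exact").pvalue
            assert wilcoxon_signed_rank_p(x) == pytest.approx(expected)

    @pytest.mark.parametrize("n", [20, 22, 25])
    def test_normal_approximation_close_to_exact(self, n):
        rng = np.random.default_rng(n)
        for _ in range(25):
            x = rng.normal(rng.uniform(-0.3, 0.3), 1.0, size=n)
            exact = wilcoxon_signed_rank_p(x, exact_max_n=25)
            approx = wilcoxon_signed_rank_p(x, exact_max_n=0)
            assert abs(exact - approx) < 0.01


class TestSmoothTrack:
    def _track(self, positions, values):
        return ProbeTrack("chrI", positions, values)

    def test_window_pools_replicates_and_neighbours(self):
        track = self._track([0, 100, 200], [[1.0, 2.0, 3.0]])
        out = smooth_track(track, bandwidth_bp=100)
        # middle probe window holds {1,2,3} -> HL = 2, P = 1/8
        assert out.signal[1] == pytest.approx(2.0)
        assert out.p_value[1] == pytest.approx(0.125)

    def test_bandwidth_zero_keeps_probes_independent(self):
        track = self._track([0, 100], [[1.5, -0.5]])
        out = smooth_track(track, bandwidth_bp=0)
        np.testing.assert_allclose(out.signal, [1.5, -0.5])
        np.testing.assert_allclose(out.p_value, [1.0, 1.0])  # lone-probe convention

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(10_000, size=50, replace=False))
        vals = rng.normal(0, 1, size=(2, 50))
        a = smooth_track(self._track(pos, vals))
        b = smooth_track(self._track(pos + 777, vals))
        np.testing.assert_allclose(a.signal, b.signal)
        np.testing.assert_allclose(a.p_value, b.p_value)

    def test_constant_shift_adds_to_signal(self):
        rng = np.random.default_rng(2)
        pos = np.arange(0, 2500, 50)
        vals = rng.normal(0, 1, size=(2, pos.size))
        a = smooth_track(self._track(pos, vals))
        b = smooth_track(self._track(pos, vals + 0.7))
        np.testing.assert_allclose(b.signal, a.signal + 0.7, atol=1e-12)


class TestProbeTrack:
    def test_positions_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ProbeTrack("chrI", [10, 10, 20], [[1.0, 2.0, 3.0]])

    def test_intensities_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            ProbeTrack.from_intensities("chrI", [1, 2], [[1.0, 0.0]], [[1.0, 1.0]])

    def test_log_ratio_formed_from_intensities(self):
        track = ProbeTrack.from_intensities("chrI", [1], [[8.0]], [[2.0]])
        assert track.values[0, 0] == pytest.approx(2.0)  # log2(8/2)
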