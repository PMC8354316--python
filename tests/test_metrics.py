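"""Synchrony and FAA metric contracts: identities, invariances, and the
windowed-correlation primitive."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegsync.containers import ValidationError
from eegsync.metrics import (
    MetricError,
    SynchronyConfig,
    aggregate_faa,
    attach_engagement,
    compute_faa,
    faa_frame,
    neural_synchrony,
    window_correlation,
)
from eegsync.simulate import StudyConfig, simulate_outcomes, make_ground_truth

from conftest import make_band_power


def _rng_series(rng, n_frames=12, n_ch=3):
    return rng.standard_normal((n_frames, n_ch)) ** 2 + 0.5


class TestWindowCorrelation:
    def test_identical_series_r_is_one(self):
        rng = np.random.default_rng(0)
        v = _rng_series(rng)
        a = make_band_power("s1", v)
        b = make_band_power("s2", v.copy())
        assert window_correlation(a, b, t=5) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("scale, expected", [(2.5, 1.0), (-1.5, -1.0)])
    def test_affine_image_r_is_sign_of_slope(self, scale, expected):
        rng = np.random.default_rng(1)
        v = _rng_series(rng)
        a = make_band_power("s1", v)
        b = make_band_power("s2", scale * v + 3.0)
        assert window_correlation(a, b, t=5) == pytest.approx(expected, abs=1e-12)

    def test_fixed_windows_match_hand_computed_pearson(self):
        """Two frozen 15-value windows reproduce the directly evaluated
        Pearson formula."""
        x = np.array([2, 4, 4, 4, 5, 5, 7, 9, 1, 3, 5, 2, 8, 6, 4], float)
        y = np.array([1, 3, 2, 5, 4, 6, 8, 7, 2, 4, 6, 1, 9, 5, 3], float)
        # window flattening is frame-major: reshape to (5 frames, 3 electrodes)
        a = make_band_power("s1", x.reshape(5, 3))
        b = make_band_power("s2", y.reshape(5, 3))
        assert window_correlation(a, b, t=2) == pytest.approx(
            0.8732093843138641, abs=1e-12
        )

    def test_zero_variance_window_is_nan(self):
        a = make_band_power("s1", np.ones((8, 3)))
        b = make_band_power("s2", _rng_series(np.random.default_rng(2), 8))
        assert np.isnan(window_correlation(a, b, t=3))

    def test_out_of_range_frame_rejected(self):
        a = make_band_power("s1", _rng_series(np.random.default_rng(3), 8))
        with pytest.raises(MetricError, match="outside"):
            window_correlation(a, a, t=0)


class TestNeuralSynchrony:
    def test_identical_subjects_score_100(self):
        rng = np.random.default_rng(4)
        v = _rng_series(rng, 20)
        series = [make_band_power(f"s{i}", v.copy()) for i in range(5)]
        res = neural_synchrony(series)
        assert res.synchrony == pytest.approx(100.0, abs=1e-6)

    def test_sign_flipped_pair_scores_100(self):
        """|r| makes an anti-correlated pair perfectly synchronous."""
        rng = np.random.default_rng(5)
        v = _rng_series(rng, 20)
        series = [
            make_band_power("s1", v),
            make_band_power("s2", 10.0 - 2.0 * v),
        ]
        assert neural_synchrony(series).synchrony == pytest.approx(100.0, abs=1e-6)

    def test_fewer_than_two_subjects_rejected(self):
        v = _rng_series(np.random.default_rng(6))
        with pytest.raises(MetricError, match="2 subjects"):
            neural_synchrony([make_band_power("s1", v)])

    def test_all_frames_invalid_raises_with_diagnostics(self):
        rng = np.random.default_rng(7)
        series = [
            make_band_power(
                f"s{i}", _rng_series(rng), frame_valid=np.zeros(12, bool)
            )
            for i in range(3)
        ]
        with pytest.raises(MetricError, match="invalid"):
            neural_synchrony(series)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        series = [make_band_power(f"s{i}", _rng_series(rng, 15)) for i in range(6)]
        base = neural_synchrony(series).synchrony
        perm = neural_synchrony(series[::-1]).synchrony
        assert perm == pytest.approx(base, abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n_sub=st.integers(2, 5),
        n_frames=st.integers(6, 15),
    )
    def test_bounds_zero_to_100(self, seed, n_sub, n_frames):
        rng = np.random.default_rng(seed)
        series = [
            make_band_power(f"s{i}", _rng_series(rng, n_frames)) for i in range(n_sub)
        ]
        res = neural_synchrony(series)
        assert 0.0 <= res.synchrony <= 100.0 + 1e-9

    def test_replacing_subjects_with_noise_lowers_synchrony(self):
        """Swapping coupled subjects for independent noise never raises
        expected synchrony (paired over 20 seeds)."""
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            common = rng.standard_normal((30, 3))
            coupled = [
                make_band_power(f"s{i}", common + 0.7 * rng.standard_normal((30, 3)))
                for i in range(6)
            ]
            base = neural_synchrony(coupled).synchrony
            replaced = list(coupled)
            for i in range(3):
                replaced[i] = make_band_power(
                    f"s{i}", rng.standard_normal((30, 3))
                )
            diffs.append(base - neural_synchrony(replaced).synchrony)
        assert np.mean(diffs) > 0
        assert np.sum(np.array(diffs) > 0) >= 18

    def test_zero_variance_pair_frames_skipped_and_counted(self):
        rng = np.random.default_rng(9)
        flat = np.ones((12, 3))
        series = [
            make_band_power("s1", _rng_series(rng, 12)),
            make_band_power("s2", _rng_series(rng, 12)),
            make_band_power("s3", flat),  # zero variance everywhere
        ]
        res = neural_synchrony(series)
        assert res.n_skipped_pair_frames > 0
        assert np.isfinite(res.synchrony)

    def test_edge_frames_skipped_no_padding(self):
        rng = np.random.default_rng(10)
        series = [make_band_power(f"s{i}", _rng_series(rng, 12)) for i in range(3)]
        res = neural_synchrony(series)
        # T_effective = T - 2*half_width
        assert res.n_valid_frames == 12 - 4


class TestFAA:
    def test_equal_hemisphere_power_gives_zero(self):
        v = np.column_stack([np.full(10, 3.0), np.full(10, 3.0)])
        bp = make_band_power("s1", v, channels=("F3", "F4"))
        assert compute_faa(bp).faa == 0.0

    def test_e_fold_right_power_gives_exactly_one(self):
        f3 = np.abs(np.random.default_rng(11).standard_normal(10)) + 0.5
        v = np.column_stack([f3, np.e * f3])
        bp = make_band_power("s1", v, channels=("F3", "F4"))
        assert compute_faa(bp).faa == pytest.approx(1.0, abs=1e-12)

    def test_channel_swap_negates(self):
        rng = np.random.default_rng(12)
        v = _rng_series(rng, 10, 2)
        bp = make_band_power("s1", v, channels=("F3", "F4"))
        swapped = make_band_power("s1", v[:, ::-1], channels=("F3", "F4"))
        assert compute_faa(swapped).faa == pytest.approx(-compute_faa(bp).faa)

    def test_nonpositive_power_frames_excluded_and_counted(self):
        v = np.column_stack([np.ones(10), np.full(10, np.e)])
        v[3, 0] = 0.0
        bp = make_band_power("s1", v, channels=("F3", "F4"))
        res = compute_faa(bp)
        assert res.n_frames_dropped == 1
        assert res.n_frames_used == 9
        assert res.faa == pytest.approx(1.0, abs=1e-12)

    def test_missing_frontal_channel_rejected(self):
        bp = make_band_power("s1", np.ones((10, 3)))  # C3/Cz/C4 labels
        with pytest.raises(MetricError, match="F3"):
            compute_faa(bp)

    def test_group_aggregate_is_mean_over_subjects(self):
        results = []
        for i, val in enumerate([0.2, 0.4, 0.9]):
            v = np.column_stack([np.ones(8), np.exp(val) * np.ones(8)])
            bp = make_band_power(f"s{i}", v, channels=("F3", "F4"), stimulus="stimA")
            results.append(compute_faa(bp))
        agg = aggregate_faa(results)
        assert agg["stimA"] == pytest.approx(np.mean([0.2, 0.4, 0.9]), abs=1e-12)


class TestAttachEngagement:
    def _table(self):
        cfg = StudyConfig(n_subjects=3, n_stimuli=2, seed=13)
        return cfg, simulate_outcomes(make_ground_truth(cfg), cfg)

    def test_constant_scores_give_constant_group_means(self):
        cfg, table = self._table()
        scores = pd.DataFrame(
            0.5, index=table.ratings.index, columns=table.ratings.columns
        )
        out = attach_engagement(table, scores)
        assert (out.engagement.mean(axis=0) == 0.5).all()

    def test_missing_pair_rejected_with_key(self):
        cfg, table = self._table()
        scores = {
            (s, k): 0.5 for s in table.subject_ids for k in table.stimulus_ids
        }
        del scores[("s02", "stim01")]
        with pytest.raises(ValidationError, match=r"s02.*stim01"):
            attach_engagement(table, scores)

    def test_out_of_range_score_rejected(self):
        cfg, table = self._table()
        scores = pd.DataFrame(
            0.5, index=table.ratings.index, columns=table.ratings.columns
        )
        scores.iloc[0, 0] = 1.5
        with pytest.raises(ValidationError, match="outside"):
            attach_engagement(table, scores)

    def test_simulated_engagement_joins_without_loss(self):
        cfg, table = self._table()
        out = attach_engagement(table, table.engagement)
        assert out.engagement.shape == table.ratings.shape
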