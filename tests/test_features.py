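"""Inter-IMFCC, IMF statistics, pair schemes and feature assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imfcc.emd import SiftConfig
from imfcc.features import (
    FeatureMatrix,
    entropy,
    extra_stat,
    extract_feature_matrix,
    extract_features,
    inter_imfcc,
    resolve_pairs,
    rms,
    std,
)
from tests.conftest import make_frame, eeg_like_signal


def brute_force_pearson(u, v):
    """Direct evaluation of the covariance-ratio definition, 1/(N-1)."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    n = len(u)
    mu, mv = sum(u) / n, sum(v) / n
    cuv = sum((a - mu) * (b - mv) for a, b in zip(u, v)) / (n - 1)
    cuu = sum((a - mu) ** 2 for a in u) / (n - 1)
    cvv = sum((b - mv) ** 2 for b in v) / (n - 1)
    return cuv / math.sqrt(cuu * cvv)


class TestInterImfcc:
    def test_identical_inputs_give_one(self, rng):
        u = rng.standard_normal(100)
        assert inter_imfcc(u, u) == 1.0

    def test_negated_input_gives_minus_one(self, rng):
        u = rng.standard_normal(100)
        assert inter_imfcc(u, -u) == -1.0

    def test_hand_worked_example(self):
        assert inter_imfcc([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            inter_imfcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 200))
    def test_matches_brute_force_pearson(self, seed, n):
        rng = np.random.default_rng(seed)
        u, v = rng.standard_normal(n), rng.standard_normal(n)
        assert inter_imfcc(u, v) == pytest.approx(
            brute_force_pearson(u, v), abs=1e-12
        )
        assert abs(inter_imfcc(u, v)) <= 1.0

    def test_symmetric_in_arguments(self, rng):
        u, v = rng.standard_normal(50), rng.standard_normal(50)
        assert inter_imfcc(u, v) == inter_imfcc(v, u)

    def test_affine_invariance_and_sign_flip(self, rng):
        u, v = rng.standard_normal(50), rng.standard_normal(50)
        r = inter_imfcc(u, v)
        assert inter_imfcc(3.5 * u + 2.0, v) == pytest.approx(r, abs=1e-12)
        assert inter_imfcc(-2.0 * u + 1.0, v) == pytest.approx(-r, abs=1e-12)


class TestStatistics:
    @pytest.mark.parametrize(
        "u, expected",
        [([2, 2, 2], 2.0), ([1, -1, 1, -1], 1.0),
         ([1, 2, 3], math.sqrt(14 / 3))],
    )
    def test_rms(self, u, expected):
        assert rms(u) == pytest.approx(expected)

    def test_rms_scale_equivariant(self, rng):
        u = rng.standard_normal(40)
        assert rms(-2.5 * u) == pytest.approx(2.5 * rms(u))

    def test_std_uses_population_normalisation(self):
        assert std([1, 2, 3]) == pytest.approx(math.sqrt(2 / 3))
        assert std([7, 7, 7]) == 0.0

    def test_std_shift_invariant(self, rng):
        u = rng.standard_normal(40)
        assert std(u + 123.0) == pytest.approx(std(u), abs=1e-10)

    def test_entropy_of_constant_is_zero(self):
        assert entropy([4.2] * 10) == 0.0

    def test_entropy_of_balanced_binary_is_one_bit(self):
        assert entropy([0.0, 1.0] * 8) == pytest.approx(1.0)

    def test_entropy_three_one_split(self):
        # counts {3, 1} over N=4: -(3/4)log2(3/4) - (1/4)log2(1/4)
        assert entropy([0.0, 0.0, 0.0, 1.0]) == pytest.approx(0.811278, abs=1e-6)

    def test_entropy_bounded_by_log2_n(self, rng):
        u = rng.standard_normal(64)
        assert 0.0 <= entropy(u) <= math.log2(64)

    @pytest.mark.parametrize(
        "name, u, expected",
        [
            ("avg", [1, 2, 3], 2.0),
            ("med", [1, 2, 9], 2.0),
            ("max", [1, 5, 3], 5.0),
            ("min", [1, 5, 3], 1.0),
            ("skew", [-1, 0, 1], 0.0),
            ("kurt", [-1, 1, -1, 1], 1.0),
        ],
    )
    def test_extra_stats(self, name, u, expected):
        assert extra_stat(np.asarray(u, float), name) == pytest.approx(expected)

    def test_mode_is_most_frequent_smallest_on_tie(self):
        u = np.array([0.0, 0.0, 1.0, 1.0, 0.5])
        # levels of 0.0 and 1.0 tie with count 2 -> smallest level wins
        assert extra_stat(u, "mod") < 0.5

    def test_unknown_stat_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            extra_stat(np.ones(5), "variance")


class TestPairSchemes:
    LABELS = ("C3", "C4", "P3", "P4", "O1", "O2")

    def test_all_pairs_resolves_to_15(self):
        assert resolve_pairs(self.LABELS, "all_pairs").n_pairs == 15

    def test_cross_hemisphere_lists_the_nine_pairs(self):
        scheme = resolve_pairs(self.LABELS, "cross_hemisphere")
        assert scheme.resolved_pairs == (
            ("C3", "C4"), ("C3", "P4"), ("C3", "O2"),
            ("P3", "C4"), ("P3", "P4"), ("P3", "O2"),
            ("O1", "C4"), ("O1", "P4"), ("O1", "O2"),
        )

    @pytest.mark.parametrize("region, first", [
        ("parietal", ("P3", "C3")),
        ("central", ("C3", "P3")),
        ("occipital", ("O1", "C3")),
    ])
    def test_region_reference_resolves_to_8(self, region, first):
        scheme = resolve_pairs(self.LABELS, "region_reference",
                               reference_region=region)
        assert scheme.n_pairs == 8
        assert scheme.resolved_pairs[0] == first

    def test_occipital_reference_pairs_match_listing(self):
        scheme = resolve_pairs(self.LABELS, "region_reference",
                               reference_region="occipital")
        assert set(scheme.resolved_pairs) == {
            ("O1", "C3"), ("O1", "C4"), ("O1", "P3"), ("O1", "P4"),
            ("O2", "C3"), ("O2", "C4"), ("O2", "P3"), ("O2", "P4"),
        }

    def test_region_reference_without_region_rejected(self):
        with pytest.raises(ValueError, match="reference_region"):
            resolve_pairs(self.LABELS, "region_reference")

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            resolve_pairs(("C3", "XX"), "cross_hemisphere")


class TestExtractFeatures:
    def test_headline_dimension_is_99(self, eeg_frame):
        row, names = extract_features(eeg_frame)
        assert row.shape == (99,)
        assert len(names) == 99
        assert len(set(names)) == 99

    def test_single_stat_dimension_is_63(self, eeg_frame):
        row, names = extract_features(eeg_frame, stats=("std",))
        assert row.shape == ((15 + 6) * 3,)

    def test_stats_only_dimension_is_18(self, eeg_frame):
        scheme = resolve_pairs(eeg_frame.channel_labels, "all_pairs")
        scheme.resolved_pairs = ()
        row, names = extract_features(eeg_frame, scheme=scheme,
                                      stats=("rms",))
        assert row.shape == (18,)

    def test_extraction_is_bit_deterministic(self, eeg_frame):
        row1, _ = extract_features(eeg_frame)
        row2, _ = extract_features(eeg_frame)
        np.testing.assert_array_equal(row1, row2)

    def test_manifest_order_imf_major_pairs_first(self, eeg_frame):
        _, names = extract_features(eeg_frame)
        assert names[0].startswith("imf1:cc:")
        assert names[15].startswith("imf1:std:")
        assert names[33].startswith("imf2:cc:")

    def test_insufficient_imfs_raise(self):
        # a pure slow tone cannot support 3 IMFs
        t = np.arange(250) / 250
        sig = np.vstack([np.sin(2 * np.pi * 3 * t)] * 6)
        sig += 1e-6 * np.sin(2 * np.pi * 30 * t)  # avoid exact degeneracy
        frame = make_frame(sig)
        with pytest.raises(ValueError, match="IMFs"):
            extract_features(frame, SiftConfig(max_imfs=3))

    def test_unknown_stat_rejected(self, eeg_frame):
        with pytest.raises(ValueError, match="unknown statistics"):
            extract_features(eeg_frame, stats=("std", "nope"))


class TestFeatureMatrix:
    def test_round_trip_through_csv(self, rng, tmp_path):
        fm = FeatureMatrix(
            values=rng.standard_normal((4, 3)),
            feature_names=("a", "b", "c"),
            labels=("M", "M", "R", "R"),
            provenance={"extractor": "test"},
        )
        path = fm.to_csv(tmp_path / "fm.csv")
        back = FeatureMatrix.from_csv(path)
        np.testing.assert_allclose(back.values, fm.values, rtol=1e-12)
        assert back.feature_names == fm.feature_names
        assert back.labels == fm.labels
        assert back.provenance["extractor"] == "test"

    def test_matrix_extraction_labels_follow_frames(self, rng):
        frames = [
            make_frame(np.vstack([eeg_like_signal(rng) for _ in range(6)]),
                       task=task)
            for task in ("M", "R")
        ]
        fm = extract_feature_matrix(frames)
        assert fm.labels == ("M", "R")
        assert fm.n_features == 99
        assert fm.provenance["n_imfs"] == 3
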