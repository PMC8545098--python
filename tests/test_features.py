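"""Depth-table parsing, profile normalization, extrema and feature extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sipgrade.features import (
    FEATURE_NAMES,
    DepthTableError,
    ObservedProfile,
    ZeroDepthProfile,
    extract_features,
    local_extrema,
    normalize_profile,
    parse_depth_table,
)
from sipgrade.gradient import LabelState, bd_mixture, expected_profile, simulate_null_profile
from sipgrade.synthetic import BenchmarkConfig, generate_depth_table


def _oracle_extrema(x):
    """Independent re-derivation: plateau-aware neighbour comparison."""
    n = len(x)
    maxima, minima = [], []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        left = x[i - 1] if i > 0 else None
        right = x[j + 1] if j + 1 < n else None
        neighbours = [v for v in (left, right) if v is not None]
        if neighbours and all(x[i] > v for v in neighbours):
            maxima.append(i)
        elif neighbours and all(x[i] < v for v in neighbours):
            minima.append(i)
        i = j + 1
    return maxima, minima


class TestLocalExtrema:
    @pytest.mark.parametrize(
        "profile,maxima,minima",
        [
            ([1, 3, 2, 5, 1], [1, 3], [0, 2, 4]),
            ([1, 4, 4, 1], [1], [0, 3]),
            ([1, 1, 1, 1], [], []),
        ],
    )
    def test_hand_cases(self, profile, maxima, minima):
        got_max, got_min = local_extrema(np.array(profile, dtype=float))
        assert got_max == maxima
        assert got_min == minima

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            local_extrema(np.array([1.0]))

    @given(st.lists(st.integers(0, 4), min_size=2, max_size=10))
    @settings(max_examples=300)
    def test_matches_oracle_including_plateaus(self, values):
        x = np.array(values, dtype=float)
        assert local_extrema(x) == tuple(_oracle_extrema(values))


class TestNormalizeProfile:
    def test_example(self):
        np.testing.assert_allclose(
            normalize_profile(np.array([5, 5, 10, 0.0])), [0.25, 0.25, 0.5, 0]
        )

    def test_all_zero_raises_condition(self):
        with pytest.raises(ZeroDepthProfile):
            normalize_profile(np.zeros(3))

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=8).filter(lambda v: sum(v) > 1e-6))
    def test_sums_to_one(self, values):
        assert normalize_profile(np.array(values)).sum() == pytest.approx(1.0, abs=1e-12)


class TestParseDepthTable:
    def _write(self, tmp_path, df):
        path = tmp_path / "depths.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path

    def test_three_row_fixture(self, tmp_path, layout):
        cols = {"contigName": ["a", "b", "c"], "contigLen": [3000, 4000, 5000],
                "totalAvgDepth": [10.0, 12.0, 0.0]}
        for f in layout.sequenced_window:
            cols[f"F{f}"] = [1.0, 2.0, 0.0]
            cols[f"F{f}-var"] = [9.9, 9.9, 9.9]
        profiles = parse_depth_table(self._write(tmp_path, pd.DataFrame(cols)), layout)
        assert len(profiles) == 3
        assert all(p.depths.size == layout.window_size for p in profiles)
        assert profiles[1].contig_id == "b" and profiles[1].length == 4000

    def test_missing_total_column_named_in_error(self, tmp_path):
        df = pd.DataFrame({"contigName": ["a"], "contigLen": [3000], "F6": [1.0]})
        with pytest.raises(DepthTableError, match="totalAvgDepth"):
            parse_depth_table(self._write(tmp_path, df))

    def test_round_trip_with_generator(self, tmp_path, layout):
        config = BenchmarkConfig()
        truth = pd.DataFrame(
            {
                "contig_id": ["x1", "x2"],
                "length": [5000, 8000],
                "gc": [0.55, 0.65],
                "atom_excess": [0.8, 0.0],
                "labeled_fraction": [1.0, 0.0],
                "abundance": [1.0, 1.2],
                "true_class": ["strong", "unenriched"],
            }
        )
        path = tmp_path / "d.tsv"
        written = generate_depth_table(truth, layout, config, seed=7, path=path)
        parsed = parse_depth_table(path, layout)
        for i, prof in enumerate(parsed):
            expected = written.iloc[i][[f"F{f}" for f in layout.sequenced_window]].to_numpy(float)
            np.testing.assert_allclose(prof.depths, expected)


def _profile_pair(layout, gc, length, excess, w, depths=None):
    null_full = simulate_null_profile(gc, length, layout)
    null_win = null_full[layout.window_slice]
    if depths is None:
        mix = bd_mixture(gc, length, LabelState(excess, w))
        depths = 50 * expected_profile(mix, layout)[layout.window_slice]
    obs = ObservedProfile("c", np.asarray(depths, float), float(np.sum(depths)), int(length), gc)
    return obs, null_win


class TestExtractFeatures:
    def test_fixed_length_and_finiteness(self, layout):
        obs, null = _profile_pair(layout, 0.6, 10_000, 0.5, 0.5)
        feats = extract_features(obs, null)
        assert list(feats.index) == list(FEATURE_NAMES)
        assert len(feats) == 24
        assert np.all(np.isfinite(feats.to_numpy()))

    def test_observed_equals_null_gives_zero_shift(self, layout):
        null = simulate_null_profile(0.65, 10_000, layout)[layout.window_slice]
        obs = ObservedProfile("c", 100 * null, float(100 * null.sum()), 10_000, 0.65)
        feats = extract_features(obs, null)
        assert feats["mean_fraction_shift"] == pytest.approx(0.0, abs=1e-9)

    def test_strong_label_shifts_heavy(self, layout):
        """Full labelling moves mass toward heavier (lower-index) fractions."""
        obs, null = _profile_pair(layout, 0.5, 10_000, 0.85, 1.0)
        feats = extract_features(obs, null)
        assert feats["mean_fraction_shift"] < 0

    def test_scale_invariance_except_log_depth(self, layout):
        obs, null = _profile_pair(layout, 0.6, 10_000, 0.5, 0.5)
        scaled = ObservedProfile("c", obs.depths * 7.5, obs.total_depth * 7.5, obs.length, obs.gc)
        f1, f2 = extract_features(obs, null), extract_features(scaled, null)
        np.testing.assert_allclose(
            f1.drop("log_total_depth").to_numpy(),
            f2.drop("log_total_depth").to_numpy(),
            rtol=1e-12, atol=1e-12,
        )
        assert f2["log_total_depth"] > f1["log_total_depth"]

    def test_reversal_changes_argmax(self, layout):
        obs, null = _profile_pair(layout, 0.6, 10_000, 0.8, 1.0)
        rev = ObservedProfile("c", obs.depths[::-1].copy(), obs.total_depth, obs.length, obs.gc)
        f1, f2 = extract_features(obs, null), extract_features(rev, null)
        assert f1["argmax_obs"] != f2["argmax_obs"]

    def test_null_features_depend_only_on_gc_and_length(self, layout):
        obs1, null = _profile_pair(layout, 0.62, 9_000, 0.8, 1.0)
        obs2, null2 = _profile_pair(layout, 0.62, 9_000, 0.0, 0.0)
        np.testing.assert_array_equal(null, null2)
        f1, f2 = extract_features(obs1, null), extract_features(obs2, null2)
        null_cols = [c for c in FEATURE_NAMES if c.startswith("null") or c == "argmax_null"]
        pd.testing.assert_series_equal(f1[null_cols], f2[null_cols])

    def test_window_mismatch_rejected(self, layout):
        obs, null = _profile_pair(layout, 0.6, 10_000, 0.5, 0.5)
        with pytest.raises(ValueError, match="window mismatch"):
            extract_features(obs, null[:-1])

    def test_zero_depth_profile_flagged_not_nan(self, layout):
        obs, null = _profile_pair(layout, 0.6, 10_000, 0.0, 0.0, depths=np.zeros(8))
        feats = extract_features(obs, null)
        assert np.all(np.isfinite(feats.to_numpy()))
        assert feats["log_total_depth"] == 0.0
        assert feats["argmax_obs"] == -1
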