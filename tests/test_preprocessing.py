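"""Normalization, segmentation, AAMI mapping, balancing and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ecgcompress.io import BeatDataset, ECGRecord
from ecgcompress.preprocessing import (
    SplitConfig,
    balance_dataset,
    map_aami,
    normalize_beat,
    segment_beats,
    split_train_test,
)


class TestNormalize:
    def test_min_max_endpoints(self):
        np.testing.assert_allclose(normalize_beat([0, 5, 10]), [0.0, 0.5, 1.0])

    def test_constant_sequence_maps_to_zeros(self):
        np.testing.assert_array_equal(normalize_beat([3, 3, 3]), [0.0, 0.0, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        hnp.arrays(
            np.float64,
            st.integers(1, 50),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_idempotent_and_bounded(self, x):
        y = normalize_beat(x)
        assert y.min() >= 0.0 and y.max() <= 1.0
        np.testing.assert_allclose(normalize_beat(y), y, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_beat([])


class TestSegmentation:
    def _record(self, n=1000, annotations=()):
        rng = np.random.default_rng(1)
        return ECGRecord("t", 360.0, rng.standard_normal(n), list(annotations))

    def test_window_arithmetic(self):
        record = self._record(1000, [(500, "N")])
        result = segment_beats(record, half_width=130, normalize=False)
        assert result.dataset.beats.shape == (1, 260)
        np.testing.assert_array_equal(result.dataset.beats[0], record.signal[370:630])

    def test_boundary_beat_skipped_and_counted(self):
        record = self._record(1000, [(50, "N"), (500, "N")])
        result = segment_beats(record, half_width=130)
        assert len(result.dataset) == 1
        assert result.skipped_boundary == 1

    def test_right_boundary_skipped(self):
        record = self._record(600, [(480, "N")])
        result = segment_beats(record, half_width=130)
        assert len(result.dataset) == 0 and result.skipped_boundary == 1

    def test_non_beat_and_unknown_symbols_tallied(self):
        record = self._record(1000, [(400, "+"), (500, "N"), (600, "B")])
        # 'B' is a beat symbol mapped under N; '+' is a rhythm mark
        result = segment_beats(record, half_width=100)
        assert result.non_beat == 1
        assert len(result.dataset) == 2

    def test_beats_are_normalized_by_default(self):
        record = self._record(1000, [(300, "N"), (600, "V")])
        result = segment_beats(record, half_width=50)
        assert result.dataset.beats.min() >= 0.0
        assert result.dataset.beats.max() <= 1.0

    def test_half_width_sets_beat_length(self):
        record = self._record(1000, [(500, "N")])
        result = segment_beats(record, half_width=80)
        assert result.dataset.beat_length == 160


class TestAAMIMapping:
    @pytest.mark.parametrize(
        "symbol,expected",
        [
            ("/", "N"),   # paced beat
            ("f", "N"),   # fusion of paced and normal
            ("L", "N"),
            ("A", "S"),   # atrial premature contraction
            ("J", "S"),
            ("a", "S"),
            ("V", "V"),
            ("E", "V"),   # ventricular escape
            ("r", "V"),   # R-on-T PVC
            ("F", "F"),
            ("Q", "Q"),
        ],
    )
    def test_table_assignments(self, symbol, expected):
        labels, unmapped = map_aami([symbol])
        assert labels == [expected]
        assert unmapped == {}

    def test_non_beat_symbols_excluded_without_tally(self):
        labels, unmapped = map_aami(["+", "~", "|"])
        assert labels == [None, None, None]
        assert unmapped == {}

    def test_unknown_beat_symbol_tallied(self):
        labels, unmapped = map_aami(["N", "\x01"])
        assert labels == ["N", None]
        assert unmapped == {"\x01": 1}


def _labelled_dataset(counts: dict[str, int], beat_length=8, seed=3) -> BeatDataset:
    rng = np.random.default_rng(seed)
    labels = sum(([name] * n for name, n in counts.items()), [])
    return BeatDataset(
        rng.random((len(labels), beat_length)), labels, beat_length, list(counts)
    )


class TestBalance:
    def test_exact_counts_and_class_drop(self):
        ds = _labelled_dataset({"N": 30, "V": 20, "Q": 5})
        out = balance_dataset(ds, {"N": 10, "V": 7}, seed=0)
        assert out.class_counts() == {"N": 10, "V": 7}
        assert "Q" not in out.class_names

    def test_deterministic_under_seed(self):
        ds = _labelled_dataset({"A": 5})
        first = balance_dataset(ds, {"A": 2}, seed=0)
        second = balance_dataset(ds, {"A": 2}, seed=0)
        np.testing.assert_array_equal(first.beats, second.beats)

    def test_full_targets_give_a_permutation(self):
        ds = _labelled_dataset({"N": 12, "V": 9})
        out = balance_dataset(ds, {"N": 12, "V": 9}, seed=1)
        for name in ("N", "V"):
            orig = np.sort(ds.beats[ds.labels == name], axis=0)
            got = np.sort(out.beats[out.labels == name], axis=0)
            np.testing.assert_array_equal(orig, got)

    def test_shortfall_names_class_and_amount(self):
        ds = _labelled_dataset({"F": 3})
        with pytest.raises(ValueError, match="'F'.*short by 2"):
            balance_dataset(ds, {"F": 5}, seed=0)


class TestSplit:
    def test_ten_beats_at_point_eight(self):
        ds = _labelled_dataset({"N": 10})
        train, test = split_train_test(ds, SplitConfig(0.8, 0))
        assert len(train) == 8 and len(test) == 2

    def test_rounding_rule_on_3802(self):
        ds = _labelled_dataset({"N": 3802}, beat_length=4)
        train, test = split_train_test(ds, SplitConfig(0.8, 0))
        # round-half-to-even on 3041.6 -> 3042
        assert len(train) == 3042 and len(test) == 760

    def test_disjoint_exhaustive_and_deterministic(self):
        ds = _labelled_dataset({"N": 17, "V": 13})
        a_train, a_test = split_train_test(ds, SplitConfig(0.8, 5))
        b_train, b_test = split_train_test(ds, SplitConfig(0.8, 5))
        np.testing.assert_array_equal(a_train.beats, b_train.beats)
        combined = np.vstack([a_train.beats, a_test.beats])
        np.testing.assert_array_equal(
            np.sort(combined, axis=0), np.sort(ds.beats, axis=0)
        )

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitConfig(train_fraction=1.2)
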