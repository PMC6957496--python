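"""Beat windows, timing vectors, splitting and median resampling."""

import numpy as np
import pytest

import equibeat as eb
from equibeat.beat_dataset import (TIMING_LEN, TIMING_SUBSAMPLE, median_target,
                                   samples_to_arrays)


def _record_with_beats(indices, n=30000, labels=None):
    sig = np.random.default_rng(0).normal(scale=0.01, size=(2, n))
    labels = labels or ["N"] * len(indices)
    ann = list(zip(indices, labels))
    return eb.EcgRecord(500.0, ["II", "I"], sig, annotations=ann, name="t")


class TestExtractBeats:
    def test_single_central_beat(self):
        rec = _record_with_beats([15000])
        (s,) = eb.extract_beats(rec, [15000], ["N"])
        assert s.timing.sum() == 1
        assert s.timing[TIMING_LEN // 2] == 1
        assert s.morphology.shape == (2, 500)

    def test_neighbours_at_one_second(self):
        det = [14500, 15000, 15500]
        rec = _record_with_beats(det)
        samples = eb.extract_beats(rec, det, ["N"] * 3)
        center = TIMING_LEN // 2
        mid = samples[1]
        assert mid.timing[center] == 1
        assert mid.timing[center - 100] == 1 and mid.timing[center + 100] == 1
        assert mid.timing.sum() == 3

    def test_edge_window_zero_padded(self):
        """A beat 0.2 s into the record zero-pads the first 150 samples."""
        rec = _record_with_beats([100])
        (s,) = eb.extract_beats(rec, [100], ["N"])
        assert np.all(s.morphology[:, :150] == 0)
        assert np.any(s.morphology[:, 150:] != 0)

    def test_timing_sum_matches_interval_count(self):
        """Oracle: direct count of detections in each +/- 10 s span."""
        rec = eb.generate_record(
            eb.equine_template(),
            eb.RhythmSpec(base_heart_rate=80, duration=60, seed=8, vpc_rate=3))
        det = rec.annotation_indices()
        samples = eb.extract_beats(rec, det, rec.annotation_labels())
        center = TIMING_LEN // 2
        for s in samples:
            offs = det // TIMING_SUBSAMPLE - s.beat_index // TIMING_SUBSAMPLE
            expected = int(np.sum((offs >= -center) & (offs <= TIMING_LEN - 1 - center)))
            assert int(s.timing.sum()) == expected

    def test_order_and_count_preserved(self):
        det = [2000, 7000, 12000, 20000]
        rec = _record_with_beats(det, labels=["N", "APC", "VPC", "A"])
        samples = eb.extract_beats(rec, det, ["N", "APC", "VPC", "A"])
        assert [s.beat_index for s in samples] == det
        assert [s.label for s in samples] == ["N", "APC", "VPC", "A"]

    def test_padded_512_2048_variant(self):
        rec = _record_with_beats([15000])
        (s,) = eb.extract_beats(rec, [15000], ["N"], morph_width=512,
                                timing_len=2048)
        assert s.morphology.shape == (2, 512)
        assert np.all(s.morphology[:, :6] == 0) and np.all(s.morphology[:, -6:] == 0)
        assert s.timing.size == 2048
        # 24-sample symmetric zero margins around the canonical 2000 span
        assert np.all(s.timing[:24] == 0) and np.all(s.timing[-24:] == 0)
        assert s.timing.sum() == 1

    def test_input_contracts(self):
        rec = _record_with_beats([15000])
        bad_rate = eb.EcgRecord(360.0, ["II", "I"], rec.signal)
        with pytest.raises(ValueError, match="500"):
            eb.extract_beats(bad_rate, [100], ["N"])
        one_lead = eb.EcgRecord(500.0, ["II"], rec.signal[:1])
        with pytest.raises(ValueError, match="2-lead"):
            eb.extract_beats(one_lead, [100], ["N"])


class TestSplit:
    def test_60_20_20_sizes(self):
        parts = eb.split_dataset(list(range(100)), eb.SplitSpec(seed=0))
        assert [len(p) for p in parts] == [60, 20, 20]

    def test_seeded_reproducibility(self):
        a = eb.split_dataset(list(range(57)), eb.SplitSpec(seed=4))
        b = eb.split_dataset(list(range(57)), eb.SplitSpec(seed=4))
        assert a == b

    def test_degenerate_all_train(self):
        tr, va, te = eb.split_dataset(list(range(10)),
                                      eb.SplitSpec(1.0, 0.0, 0.0, seed=0))
        assert len(tr) == 10 and not va and not te

    def test_partition_property(self):
        items = list(range(83))
        tr, va, te = eb.split_dataset(items, eb.SplitSpec(seed=11))
        assert sorted(tr + va + te) == items

    def test_empty_input(self):
        assert eb.split_dataset([], eb.SplitSpec()) == ([], [], [])

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            eb.SplitSpec(0.5, 0.2, 0.2)


class TestMedianResample:
    def test_published_mitbih_training_counts(self):
        """186874/11799/37153/1878 resample to 24476 per class, 97904 total."""
        counts = [186874, 11799, 37153, 1878]
        assert median_target(counts) == 24476
        labels = np.repeat(list("NAVX"), counts)
        idx = eb.median_resample_indices(labels, seed=0)
        assert idx.size == 97904
        for c in "NAVX":
            assert int(np.sum(labels[idx] == c)) == 24476

    def test_published_eecg_training_counts(self):
        """15991/1087/3699/375 resample to 2393 per class, 9572 total."""
        counts = [15991, 1087, 3699, 375]
        assert median_target(counts) == 2393
        labels = np.repeat(["N", "APC", "VPC", "A"], counts)
        idx = eb.median_resample_indices(labels, seed=1)
        assert idx.size == 4 * 2393

    def test_balanced_input_is_permutation(self):
        samples = [eb.BeatSample(np.zeros((2, 4)), np.zeros(8, dtype=np.uint8),
                                 lbl, "r", i)
                   for i, lbl in enumerate(np.repeat(["N", "APC", "VPC", "A"], 10))]
        out = eb.median_resample(samples, seed=3)
        assert sorted(s.beat_index for s in out) == sorted(s.beat_index for s in samples)

    def test_oversampling_with_replacement(self):
        labels = ["N"] * 9 + ["VPC"] * 3 + ["APC"] * 5 + ["A"] * 7
        idx = eb.median_resample_indices(labels, seed=0)
        target = median_target([9, 3, 5, 7])  # (5+7)/2 = 6
        assert target == 6
        arr = np.asarray(labels)[idx]
        assert all(int(np.sum(arr == c)) == 6 for c in ("N", "APC", "VPC", "A"))

    def test_odd_class_count_median(self):
        assert median_target([3, 5, 7]) == 5


def test_labels_from_annotations_matching():
    ann = [(1000, "N"), (2000, "VPC"), (3000, "N")]
    labels = eb.labels_from_annotations([998, 2010, 2600, 3005], ann, 500.0)
    assert labels == ["N", "VPC", "A", "N"]


def test_dataset_h5_round_trip(tmp_path):
    rec = eb.generate_record(
        eb.equine_template(),
        eb.RhythmSpec(base_heart_rate=60, duration=30, seed=3, vpc_rate=3))
    det = rec.annotation_indices()
    samples = eb.extract_beats(rec, det, rec.annotation_labels())
    tr, va, te = eb.split_dataset(samples, eb.SplitSpec(seed=0))
    from equibeat.beat_dataset import load_dataset, save_dataset

    path = tmp_path / "ds.h5"
    save_dataset(path, {"train": tr, "validation": va, "test": te},
                 {"seed": 0})
    back, manifest = load_dataset(path)
    assert manifest == {"seed": 0}
    assert [len(back[k]) for k in ("train", "validation", "test")] == \
        [len(tr), len(va), len(te)]
    m0, t0, y0 = samples_to_arrays(tr)
    m1, t1, y1 = samples_to_arrays(back["train"])
    assert np.array_equal(m0, m1) and np.array_equal(t0, t1) and np.array_equal(y0, y1)
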