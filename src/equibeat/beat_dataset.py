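"""Turn detected beats into classifier inputs and balanced training splits.

Each classified unit pairs a morphology window — the two filtered leads for
0.5 s either side of the detected S peak, 2 x 500 samples at 500 Hz — with a
binary timing vector marking every detected beat 10 s before and after it,
subsampled to 100 Hz (2000 samples).  Training sets are balanced by median
resampling: every class is randomly under-sampled (without replacement) or
over-sampled (with replacement) to the median class count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .records import BEAT_CLASSES, EcgRecord

__all__ = [
    "BeatSample",
    "SplitSpec",
    "extract_beats",
    "labels_from_annotations",
    "split_dataset",
    "median_resample",
    "median_resample_indices",
    "median_target",
    "samples_to_arrays",
    "save_dataset",
    "load_dataset",
]

MORPH_WIDTH = 500   # +/- 0.5 s at 500 Hz
TIMING_LEN = 2000   # 20 s at 100 Hz
TIMING_SUBSAMPLE = 5  # 500 Hz -> 100 Hz


@dataclass
class BeatSample:
    """One classified unit: morphology window + timing vector + label."""

    morphology: np.ndarray  # (2, W) float, mV
    timing: np.ndarray      # (T,) uint8 in {0, 1}
    label: str
    source_record: str = ""
    beat_index: int = 0


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.6
    validation: float = 0.2
    test: float = 0.2
    seed: int = 0
    resample_training: bool = False

    def __post_init__(self) -> None:
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train, self.validation, self.test) < 0:
            raise ValueError("split fractions must be >= 0")


def extract_beats(record: EcgRecord, detections, labels,
                  morph_width: int = MORPH_WIDTH,
                  timing_len: int = TIMING_LEN) -> list[BeatSample]:
    """One BeatSample per detection, in order.

    ``detections`` are sorted 500 Hz sample indices; ``labels`` the per-beat
    classes (same length).  Windows crossing the record edges are
    zero-padded.  Widths other than the canonical 500/2000 (e.g. 512/2048)
    zero-pad symmetrically around the same physical spans.
    """
    if len(record.leads) != 2:
        raise ValueError(f"need a 2-lead record, got {len(record.leads)} leads")
    if abs(record.sample_rate - 500.0) > 1e-9:
        raise ValueError(
            f"record must be at 500 Hz (got {record.sample_rate} Hz); resample first")
    det = np.asarray(detections, dtype=int)
    if det.size != len(labels):
        raise ValueError("detections and labels must align")
    if np.any(np.diff(det) <= 0):
        raise ValueError("detections must be strictly increasing")

    half = MORPH_WIDTH // 2
    pad_m = (morph_width - MORPH_WIDTH) // 2
    pad_t = (timing_len - TIMING_LEN) // 2
    if pad_m < 0 or pad_t < 0:
        raise ValueError("window widths below the canonical 500/2000 are not supported")
    n = record.n_samples
    center = TIMING_LEN // 2
    coarse = det // TIMING_SUBSAMPLE  # 500 Hz index -> 100 Hz bin
    samples: list[BeatSample] = []
    for peak, label in zip(det, labels):
        morph = np.zeros((2, morph_width))
        lo, hi = peak - half, peak + half
        src_lo, src_hi = max(0, lo), min(n, hi)
        morph[:, pad_m + (src_lo - lo): pad_m + (src_hi - lo)] = \
            record.signal[:, src_lo:src_hi]
        timing = np.zeros(timing_len, dtype=np.uint8)
        offsets = coarse - peak // TIMING_SUBSAMPLE
        inside = (offsets >= -center) & (offsets <= TIMING_LEN - 1 - center)
        timing[pad_t + center + offsets[inside]] = 1
        samples.append(BeatSample(morph, timing, label, record.name, int(peak)))
    return samples


def labels_from_annotations(detections, annotations, rate: float,
                            tolerance: float = 0.050,
                            unmatched: str = "A") -> list[str]:
    """Label detected peaks from reference annotations matched at ``tolerance``.

    Detections with no reference beat within the tolerance (false positives at
    dataset-building time) default to the artefact class.
    """
    det = np.asarray(detections, dtype=float)
    ref = np.asarray([i for i, _ in annotations], dtype=float)
    classes = [c for _, c in annotations]
    tol = tolerance * rate
    labels = []
    j = 0
    for d in det:
        while j < ref.size - 1 and ref[j] < d - tol:
            j += 1
        if ref.size and abs(ref[j] - d) <= tol:
            labels.append(classes[j])
        else:
            labels.append(unmatched)
    return labels


def split_dataset(samples: list, spec: SplitSpec | None = None):
    """Random, seeded 60/20/20 partition (by beat) into train/val/test."""
    spec = spec or SplitSpec()
    n = len(samples)
    if n == 0:
        return [], [], []
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_train = int(round(spec.train * n))
    n_val = int(round(spec.validation * n))
    n_val = min(n_val, n - n_train)
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train:n_train + n_val]]
    test = [samples[i] for i in order[n_train + n_val:]]
    return train, val, test


def median_target(class_counts) -> int:
    """Median of the class counts; for an even number of classes the mean of
    the two middle counts, rounded to the nearest integer."""
    counts = sorted(int(c) for c in class_counts)
    if not counts:
        raise ValueError("need at least one class")
    m = len(counts)
    if m % 2:
        return counts[m // 2]
    mid = (counts[m // 2 - 1] + counts[m // 2]) / 2.0
    return int(np.floor(mid + 0.5))


def median_resample_indices(labels, seed: int = 0) -> np.ndarray:
    """Indices realizing the median resampling of a label sequence.

    Each class present is brought to the median class count: under-sampled
    without replacement or over-sampled with replacement.  Output size is
    target x number of classes present.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    present = set(labels.tolist())
    classes = [c for c in BEAT_CLASSES if c in present] + \
        sorted(present - set(BEAT_CLASSES))
    counts = [int(np.sum(labels == c)) for c in classes]
    target = median_target(counts)
    out: list[np.ndarray] = []
    for c, cnt in zip(classes, counts):
        idx = np.flatnonzero(labels == c)
        if cnt >= target:
            out.append(rng.choice(idx, size=target, replace=False))
        else:
            out.append(rng.choice(idx, size=target, replace=True))
    picked = np.concatenate(out)
    return picked[rng.permutation(picked.size)]


def median_resample(training: list, seed: int = 0) -> list:
    """Median-balanced training list (see :func:`median_resample_indices`)."""
    labels = [s.label for s in training]
    idx = median_resample_indices(labels, seed)
    return [training[i] for i in idx]


# ---------------------------------------------------------------------------
# array packing + persistence


def samples_to_arrays(samples: list):
    """Pack BeatSamples into (morphology, timing, one-hot-index labels)."""
    if not samples:
        w, t = MORPH_WIDTH, TIMING_LEN
        return (np.zeros((0, 2, w)), np.zeros((0, t), dtype=np.uint8),
                np.zeros(0, dtype=int))
    morph = np.stack([s.morphology for s in samples]).astype(np.float32)
    timing = np.stack([s.timing for s in samples]).astype(np.uint8)
    y = np.array([BEAT_CLASSES.index(s.label) for s in samples], dtype=int)
    return morph, timing, y


def save_dataset(path, splits: dict, manifest: dict | None = None) -> None:
    """Persist named splits (lists of BeatSample) into one HDF5 container."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["manifest"] = json.dumps(manifest or {})
        fh.attrs["classes"] = json.dumps(list(BEAT_CLASSES))
        for name, samples in splits.items():
            grp = fh.create_group(name)
            morph, timing, y = samples_to_arrays(samples)
            grp.create_dataset("morphology", data=morph)
            grp.create_dataset("timing", data=timing)
            grp.create_dataset("label", data=y)
            grp.create_dataset("source", data=np.array(
                [s.source_record for s in samples], dtype="S64"))
            grp.create_dataset("beat_index", data=np.array(
                [s.beat_index for s in samples], dtype=int))


def load_dataset(path) -> tuple[dict, dict]:
    """Load splits saved by :func:`save_dataset`; returns (splits, manifest)."""
    import h5py

    splits: dict[str, list[BeatSample]] = {}
    with h5py.File(path, "r") as fh:
        manifest = json.loads(fh.attrs.get("manifest", "{}"))
        for name, grp in fh.items():
            morph = grp["morphology"][...]
            timing = grp["timing"][...]
            y = grp["label"][...]
            src = [s.decode() for s in grp["source"][...]]
            bi = grp["beat_index"][...]
            splits[name] = [
                BeatSample(morph[i], timing[i], BEAT_CLASSES[y[i]], src[i], int(bi[i]))
                for i in range(len(y))
            ]
    return splits, manifest
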