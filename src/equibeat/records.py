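"""Core record container shared by the generator, readers and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical beat classes, in fixed order (normal, atrial premature,
#: ventricular premature, artefact).
BEAT_CLASSES = ("N", "APC", "VPC", "A")

#: Sample rate every downstream pipeline stage expects, in Hz.
PIPELINE_RATE = 500.0


@dataclass
class EcgRecord:
    """A multi-lead sampled ECG with ground-truth beat annotations.

    Parameters
    ----------
    sample_rate:
        Sampling frequency in Hz.
    leads:
        Ordered lead labels, one per signal row (e.g. ``["II", "I"]``;
        the first lead is the detection lead).
    signal:
        ``(n_leads, n_samples)`` float array of amplitudes in mV.
    annotations:
        ``(sample_index, beat_class)`` pairs, strictly increasing in index,
        with ``beat_class`` one of :data:`BEAT_CLASSES`.
    name:
        Optional record identifier used for provenance.
    """

    sample_rate: float
    leads: list[str]
    signal: np.ndarray
    annotations: list[tuple[int, str]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a (n_leads, n_samples) matrix")
        if len(self.leads) != self.signal.shape[0] or not self.leads:
            raise ValueError("need one lead label per signal row (>= 1 lead)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n = self.signal.shape[1]
        prev = -1
        for idx, cls in self.annotations:
            if not 0 <= idx < n:
                raise ValueError(f"annotation index {idx} outside [0, {n})")
            if idx <= prev:
                raise ValueError("annotation indices must be strictly increasing")
            if cls not in BEAT_CLASSES:
                raise ValueError(f"unknown beat class {cls!r}")
            prev = idx

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.signal.shape[1] / self.sample_rate

    def lead(self, label: str) -> np.ndarray:
        """Return the signal row for a lead label."""
        try:
            return self.signal[self.leads.index(label)]
        except ValueError:
            raise KeyError(f"record has no lead {label!r} (has {self.leads})") from None

    def annotation_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.annotations], dtype=int)

    def annotation_labels(self) -> list[str]:
        return [c for _, c in self.annotations]
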