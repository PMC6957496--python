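"""Baseline-wander removal and wavelet denoising for single-lead ECGs.

Baseline estimation follows the dual median-filter scheme: a 200 ms median
removes P waves and QRS complexes, a subsequent 600 ms median removes
T waves; what remains is the baseline, which is subtracted from the input.
Residual high-frequency noise is suppressed by multilevel DWT decomposition,
detail-coefficient thresholding and reconstruction.  The default wavelet is
Daubechies-8 with Coiflet-2 selectable; the default threshold is the
universal threshold sigma*sqrt(2 ln n) applied softly per detail level, with
sigma estimated from the median absolute deviation of the finest level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import median_filter

__all__ = ["FilterConfig", "remove_baseline", "denoise", "filter_record"]


@dataclass(frozen=True)
class FilterConfig:
    median_width_1: float = 0.200  # s: removes P waves and QRS complexes
    median_width_2: float = 0.600  # s: removes T waves
    denoise_wavelet: str = "db8"   # or "coif2"
    denoise_level: int = 4
    threshold_rule: str = "universal_soft"  # universal_soft | universal_hard | fixed
    fixed_threshold: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.median_width_1 < self.median_width_2:
            raise ValueError("need 0 < median_width_1 < median_width_2")
        if self.denoise_level < 1:
            raise ValueError("denoise_level must be >= 1")
        if self.threshold_rule not in ("universal_soft", "universal_hard", "fixed"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")
        if self.threshold_rule == "fixed" and self.fixed_threshold is None:
            raise ValueError("threshold_rule 'fixed' needs fixed_threshold")


def _odd_window(width_s: float, rate: float) -> int:
    w = int(round(width_s * rate))
    return max(3, w | 1)  # force odd so the median is centred


def remove_baseline(signal: np.ndarray, rate: float,
                    cfg: FilterConfig | None = None) -> np.ndarray:
    """Subtract the dual-median baseline estimate from a 1-lead signal.

    Reflect padding at the edges keeps the output the same length as the
    input.  Adding a constant to the input does not change the output.
    """
    cfg = cfg or FilterConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("remove_baseline expects a single lead")
    if x.size <= cfg.median_width_2 * rate:
        raise ValueError(
            f"signal of {x.size} samples is shorter than the {cfg.median_width_2} s "
            "baseline median window")
    w1 = _odd_window(cfg.median_width_1, rate)
    w2 = _odd_window(cfg.median_width_2, rate)
    baseline = median_filter(median_filter(x, size=w1, mode="reflect"),
                             size=w2, mode="reflect")
    return x - baseline


def denoise(signal: np.ndarray, rate: float,
            cfg: FilterConfig | None = None) -> np.ndarray:
    """DWT detail-coefficient thresholding; output length equals input length."""
    cfg = cfg or FilterConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("denoise expects a single lead")
    wavelet = pywt.Wavelet(cfg.denoise_wavelet)
    if x.size < wavelet.dec_len:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one {cfg.denoise_wavelet} "
            f"filter ({wavelet.dec_len} taps)")
    level = min(cfg.denoise_level, pywt.dwt_max_level(x.size, wavelet))
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    details = coeffs[1:]
    if cfg.threshold_rule == "fixed":
        thresholds = [float(cfg.fixed_threshold)] * len(details)
        mode = "soft"
    else:
        # noise scale from the MAD of the finest detail level
        sigma = float(np.median(np.abs(details[-1]))) / 0.6745 if details else 0.0
        thr = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))
        thresholds = [thr] * len(details)
        mode = "soft" if cfg.threshold_rule == "universal_soft" else "hard"
    new_details = [pywt.threshold(d, t, mode=mode) if t > 0 else d
                   for d, t in zip(details, thresholds)]
    rec = pywt.waverec([coeffs[0]] + new_details, wavelet, mode="symmetric")
    return rec[: x.size]


def filter_record(record, cfg: FilterConfig | None = None):
    """Apply baseline removal + denoising to every lead of a record."""
    from .records import EcgRecord

    cfg = cfg or FilterConfig()
    filtered = np.vstack([
        denoise(remove_baseline(row, record.sample_rate, cfg), record.sample_rate, cfg)
        for row in record.signal
    ])
    return EcgRecord(record.sample_rate, list(record.leads), filtered,
                     list(record.annotations), record.name)
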