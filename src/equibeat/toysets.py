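"""Small synthetic beat sets for smoke-training and ablation checks.

Two constructions:

* :func:`separable_beat_set` — four well-separated template classes, each a
  distinct morphology/timing combination, learnable to near-perfect training
  accuracy in a few hundred optimizer steps.
* :func:`timing_only_set` — N and APC share the *identical* morphology and
  differ only in the timing vector (regular vs premature spacing).  Any model
  without the timing pathway can at best guess between them, so APC recall
  separates the parallel network from its timing-ablated variant.
"""

from __future__ import annotations

import numpy as np

from .synthetic import equine_template, vpc_variant

__all__ = ["separable_beat_set", "timing_only_set"]

_W = 500
_T = 2000


def _window(waveform: np.ndarray, peak_offset: int) -> np.ndarray:
    """Center a template waveform in a +/- 0.5 s morphology window."""
    w = np.zeros(_W)
    start = _W // 2 - peak_offset
    lo, hi = max(0, start), min(_W, start + waveform.size)
    w[lo:hi] = waveform[lo - start: hi - start]
    return w


def _timing_vector(rr_s: float, premature: bool = False) -> np.ndarray:
    """Binary 20 s beat raster at 100 Hz centred on the indexed beat."""
    t = np.zeros(_T, dtype=float)
    step = int(round(rr_s * 100))
    center = _T // 2
    for k in range(-_T // (2 * step) - 2, _T // (2 * step) + 3):
        pos = center + k * step
        if 0 <= pos < _T:
            t[pos] = 1.0
    if premature:
        # the centre beat arrives early: shift its mark ~40% of RR leftward
        t[center] = 0.0
        t[center - int(0.4 * step)] = 1.0
    return t


def separable_beat_set(n: int = 200, seed: int = 0, noise_sd: float = 0.02):
    """Four distinct morphology/timing classes; returns (morph, timing, y).

    N: equine beat, regular rhythm.  APC: same QRS but half-amplitude P and
    premature timing.  VPC: widened inverted-QRS morphology.  A: a
    high-frequency noise burst.  Classes are balanced (n is rounded up to a
    multiple of 4).
    """
    rng = np.random.default_rng(seed)
    tpl = equine_template()
    vpc = vpc_variant(tpl)
    base_n = _window(tpl.waveform, tpl.peak_offset)
    base_vpc = _window(vpc.waveform, vpc.peak_offset)
    burst_env = np.exp(-0.5 * ((np.arange(_W) - _W // 2) / 20.0) ** 2)

    per = -(-n // 4)
    morphs, timings, ys = [], [], []
    for label in range(4):
        for _ in range(per):
            if label == 0:  # N
                m = base_n.copy()
                t = _timing_vector(1.0)
            elif label == 1:  # APC: near-normal shape, premature timing
                m = base_n * rng.uniform(0.95, 1.05)
                t = _timing_vector(1.0, premature=True)
            elif label == 2:  # VPC
                m = base_vpc.copy()
                t = _timing_vector(1.0, premature=True)
            else:  # A: burst
                m = 1.5 * burst_env * rng.standard_normal(_W)
                t = _timing_vector(1.0)
            lead2 = m + noise_sd * rng.standard_normal(_W)
            lead1 = 0.55 * m + noise_sd * rng.standard_normal(_W)
            morphs.append(np.stack([lead2, lead1]))
            timings.append(t)
            ys.append(label)
    order = rng.permutation(len(ys))
    return (np.stack(morphs)[order].astype(np.float32),
            np.stack(timings)[order].astype(np.float32),
            np.asarray(ys)[order])


def timing_only_set(n: int = 200, seed: int = 0, noise_sd: float = 0.02):
    """Like :func:`separable_beat_set` but APC morphology is *identical* to N
    (no amplitude jitter): only the timing vector distinguishes them.

    N is twice as frequent as each other class, as in real rhythm strips.
    This makes the measurement sharp: a model without timing information
    resolves the N/APC morphology ambiguity toward the majority class N, so
    its held-out APC recall collapses, while a timing-aware model keeps it.
    """
    rng = np.random.default_rng(seed)
    tpl = equine_template()
    vpc = vpc_variant(tpl)
    base_n = _window(tpl.waveform, tpl.peak_offset)
    base_vpc = _window(vpc.waveform, vpc.peak_offset)
    burst_env = np.exp(-0.5 * ((np.arange(_W) - _W // 2) / 20.0) ** 2)

    share = -(-n // 5)  # N gets a double share
    morphs, timings, ys = [], [], []
    for label in range(4):
        for _ in range(2 * share if label == 0 else share):
            if label in (0, 1):
                m = base_n.copy()
                t = _timing_vector(1.0, premature=(label == 1))
            elif label == 2:
                m = base_vpc.copy()
                t = _timing_vector(1.0, premature=True)
            else:
                m = 1.5 * burst_env * rng.standard_normal(_W)
                t = _timing_vector(1.0)
            lead2 = m + noise_sd * rng.standard_normal(_W)
            lead1 = 0.55 * m + noise_sd * rng.standard_normal(_W)
            morphs.append(np.stack([lead2, lead1]))
            timings.append(t)
            ys.append(label)
    order = rng.permutation(len(ys))
    return (np.stack(morphs)[order].astype(np.float32),
            np.stack(timings)[order].astype(np.float32),
            np.asarray(ys)[order])
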