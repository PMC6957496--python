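"""Synthetic two-lead ECG generator with known beat locations and classes.

Beats are synthesized analytically as sums of Gaussian deflections
(P, Q, R, S, T), placed by a jittered renewal process at a requested heart
rate.  Equine-style templates carry a deep negative S wave and a tall T wave
(the morphology produced by the modified base-apex electrode configuration);
human-style templates carry the familiar dominant positive R wave.  Premature
beats and artefact bursts are injected at configurable rates, so every
downstream stage — filtering, S-peak detection, dataset assembly, beat
classification — can be exercised against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import EcgRecord, PIPELINE_RATE

__all__ = [
    "BeatTemplate",
    "RhythmSpec",
    "NoiseSpec",
    "equine_template",
    "human_template",
    "vpc_variant",
    "generate_record",
    "ideal_annotations",
    "NOISE_PRESETS",
]


@dataclass(frozen=True)
class BeatTemplate:
    """One analytic P-QRS-T beat shape sampled at 500 Hz.

    ``waveform`` spans the whole beat; ``peak_offset`` is the index of the
    dominant deflection (S trough for equine, R peak for human) within it.
    """

    species_style: str  # "equine" | "human"
    waveform: np.ndarray  # amplitude samples, mV, at 500 Hz
    dominant_peak: str  # "S" | "R"
    qrs_width: float  # seconds
    peak_offset: int

    def __post_init__(self) -> None:
        if self.species_style not in ("equine", "human"):
            raise ValueError("species_style must be 'equine' or 'human'")
        wf = np.asarray(self.waveform, dtype=float)
        if not np.all(np.isfinite(wf)):
            raise ValueError("waveform must be finite")
        object.__setattr__(self, "waveform", wf)
        peak = wf[self.peak_offset]
        if self.dominant_peak == "S" and peak >= 0:
            raise ValueError("equine-style S templates need a negative dominant deflection")
        if self.dominant_peak == "R" and peak <= 0:
            raise ValueError("human-style R templates need a positive dominant deflection")


@dataclass(frozen=True)
class RhythmSpec:
    """Beat-timing process: base rate, jitter and ectopic/artefact rates.

    Rates are events per minute; prematurity is the fraction of the mean RR
    interval by which an ectopic beat arrives early.
    """

    base_heart_rate: float = 40.0  # bpm
    rr_jitter: float = 0.03  # fraction of RR, sd of the renewal jitter
    apc_rate: float = 0.0  # events / minute
    vpc_rate: float = 0.0
    artefact_rate: float = 0.0
    apc_prematurity: float = 0.25  # fraction of mean RR
    vpc_prematurity: float = 0.30
    duration: float = 60.0  # seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if not 20.0 <= self.base_heart_rate <= 240.0:
            raise ValueError("base_heart_rate must lie in [20, 240] bpm")
        for r in (self.apc_rate, self.vpc_rate, self.artefact_rate):
            if r < 0:
                raise ValueError("event rates must be >= 0")
        for p in (self.apc_prematurity, self.vpc_prematurity):
            if not 0.0 < p < 1.0:
                raise ValueError("prematurity fractions must lie in (0, 1)")
        if self.rr_jitter < 0:
            raise ValueError("rr_jitter must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: baseline wander, white noise, optional mains hum."""

    baseline_wander_amplitude: float = 0.0  # mV
    baseline_wander_freq: float = 0.3  # Hz, must stay below 1 Hz
    white_noise_sd: float = 0.0  # mV
    powerline_freq: float | None = None  # Hz
    powerline_amplitude: float = 0.02  # mV

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_wander_freq < 1.0:
            raise ValueError("baseline_wander_freq must lie in (0, 1) Hz")
        if self.baseline_wander_amplitude < 0 or self.white_noise_sd < 0:
            raise ValueError("noise amplitudes must be >= 0")


#: Named noise conditions: a quiet resting recording, a routine clinical
#: recording with breathing wander, and an exercise recording with heavy
#: movement artefact.
NOISE_PRESETS: dict[str, NoiseSpec] = {
    "clean": NoiseSpec(),
    "clinic": NoiseSpec(baseline_wander_amplitude=0.15, baseline_wander_freq=0.25,
                        white_noise_sd=0.02),
    "exercise": NoiseSpec(baseline_wander_amplitude=0.40, baseline_wander_freq=0.35,
                          white_noise_sd=0.05),
}


def _gauss_sum(t: np.ndarray, components: list[tuple[float, float, float]]) -> np.ndarray:
    out = np.zeros_like(t)
    for center, width, amp in components:
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def _build_template(species: str, components: list[tuple[float, float, float]],
                    qrs_width: float, rate: float, span: tuple[float, float]) -> BeatTemplate:
    t = np.arange(round(span[0] * rate), round(span[1] * rate)) / rate
    wf = _gauss_sum(t, components)
    peak_offset = int(-round(span[0] * rate))  # component centers are relative to the dominant peak
    dominant = "S" if species == "equine" else "R"
    return BeatTemplate(species_style=species, waveform=wf, dominant_peak=dominant,
                        qrs_width=qrs_width, peak_offset=peak_offset)


def equine_template(rate: float = PIPELINE_RATE, s_amplitude: float = 1.2,
                    t_amplitude: float = 0.55, t_width: float = 0.055) -> BeatTemplate:
    """Equine base-apex beat: small P and r, deep S trough, tall T.

    The tall T wave is a deliberate, physiological feature: base-apex eECG
    T waves can rival the QRS in amplitude and, when peaked (small
    ``t_width``), carry enough band-passed energy to trip amplitude-based
    QRS detectors tuned to human morphology.
    """
    comps = [
        (-0.22, 0.030, 0.10),            # P
        (-0.028, 0.010, 0.18),           # small r
        (0.0, 0.013, -abs(s_amplitude)), # dominant S trough
        (0.035, 0.012, 0.12),            # terminal positive deflection
        (0.33, t_width, abs(t_amplitude)),
    ]
    return _build_template("equine", comps, qrs_width=0.10, rate=rate, span=(-0.32, 0.55))


def tall_t_equine_template(rate: float = PIPELINE_RATE) -> BeatTemplate:
    """The peaked, near-QRS-amplitude T variant seen in some base-apex
    recordings — the morphology on which Pan-Tompkins produces T-wave
    false positives while the wavelet detector does not."""
    return equine_template(rate=rate, t_amplitude=1.0, t_width=0.030)


def human_template(rate: float = PIPELINE_RATE, r_amplitude: float = 1.0) -> BeatTemplate:
    """Human lead-II beat: P, narrow dominant R, modest S and T."""
    comps = [
        (-0.16, 0.022, 0.12),           # P
        (-0.022, 0.008, -0.10),         # Q
        (0.0, 0.011, abs(r_amplitude)), # dominant R
        (0.024, 0.009, -0.22),          # S
        (0.22, 0.045, 0.28),            # T
    ]
    return _build_template("human", comps, qrs_width=0.08, rate=rate, span=(-0.28, 0.45))


@dataclass(frozen=True)
class Waveshape:
    """A placed-beat waveform that need not satisfy the template polarity
    invariant (VPCs deliberately invert the dominant deflection)."""

    waveform: np.ndarray
    peak_offset: int
    qrs_width: float


def vpc_variant(template: BeatTemplate, widen: float = 1.6,
                rate: float = PIPELINE_RATE) -> Waveshape:
    """Ventricular-ectopic morphology derived from a normal template.

    The QRS is widened by ``widen`` (>= 1.5) and the dominant deflection is
    inverted relative to the template, the classic appearance of a
    ventricular premature contraction; the T wave turns discordant.
    """
    if widen < 1.5:
        raise ValueError("VPC widening factor must be >= 1.5")
    if template.species_style == "equine":
        comps = [
            (-0.22, 0.030, 0.10),
            (-0.028 * widen, 0.010 * widen, -0.15),
            (0.0, 0.013 * widen, 1.3),   # inverted dominant: upright instead of S trough
            (0.035 * widen, 0.012 * widen, -0.12),
            (0.36, 0.060, -0.35),        # discordant T
        ]
        span = (-0.34, 0.58)
    else:
        comps = [
            (-0.16, 0.022, 0.12),
            (-0.022 * widen, 0.008 * widen, 0.10),
            (0.0, 0.011 * widen, -1.15),  # inverted dominant R
            (0.024 * widen, 0.009 * widen, 0.22),
            (0.24, 0.050, 0.30),          # discordant (positive vs inverted QRS)
        ]
        span = (-0.30, 0.50)
    t = np.arange(round(span[0] * rate), round(span[1] * rate)) / rate
    wf = _gauss_sum(t, comps)
    return Waveshape(wf, int(-round(span[0] * rate)), template.qrs_width * widen)


def _place_beats(rhythm: RhythmSpec, rng: np.random.Generator) -> tuple[list[float], list[str]]:
    """Jittered renewal process with premature ectopics.

    A VPC is followed by a full compensatory pause (the two intervals around
    it sum to two mean RR intervals); an APC resets the rhythm.
    """
    rr_mean = 60.0 / rhythm.base_heart_rate
    # per-beat probability = events/minute * minutes/beat
    p_vpc = min(rhythm.vpc_rate * rr_mean / 60.0, 0.45)
    p_apc = min(rhythm.apc_rate * rr_mean / 60.0, 0.45)
    # leave room for the widest template: 0.35 s before the first peak,
    # 0.6 s after the last (a 60 s record at 60 bpm holds exactly 60 beats)
    start_margin, margin = 0.35, 0.6
    times: list[float] = []
    classes: list[str] = []
    t = start_margin
    pending_pause: float | None = None
    while True:
        if pending_pause is not None:
            rr = pending_pause
            cls = "N"
            pending_pause = None
        else:
            u = rng.random()
            if u < p_vpc:
                cls = "VPC"
                prem = rhythm.vpc_prematurity
            elif u < p_vpc + p_apc:
                cls = "APC"
                prem = rhythm.apc_prematurity
            else:
                cls = "N"
            if cls == "N":
                eps = float(np.clip(rng.standard_normal(), -2.0, 2.0))
                rr = rr_mean * (1.0 + rhythm.rr_jitter * eps)
            else:
                # strictly shorter than (1 - prematurity) x mean RR
                rr = rr_mean * (1.0 - prem) * rng.uniform(0.85, 0.93)
        if not times:
            t_next = t
        else:
            t_next = times[-1] + rr
        if t_next > rhythm.duration - margin:
            break
        times.append(t_next)
        classes.append(cls)
        if cls == "VPC":
            pending_pause = 2.0 * rr_mean - rr
    if not times:
        raise ValueError(
            f"duration {rhythm.duration} s too short to hold one beat at "
            f"{rhythm.base_heart_rate} bpm")
    return times, classes


def _place_artefacts(rhythm: RhythmSpec, beat_times: list[float],
                     rng: np.random.Generator) -> list[float]:
    n = rng.poisson(rhythm.artefact_rate * rhythm.duration / 60.0)
    placed: list[float] = []
    occupied = np.array(beat_times)
    for _ in range(int(n)):
        for _attempt in range(200):
            t = rng.uniform(0.6, rhythm.duration - 0.6)
            busy = np.concatenate([occupied, np.array(placed)]) if placed else occupied
            if busy.size == 0 or np.min(np.abs(busy - t)) > 0.18:
                placed.append(t)
                break
    return sorted(placed)


def _artefact_burst(rng: np.random.Generator, rate: float, amplitude: float) -> np.ndarray:
    """High-amplitude, high-frequency burst: white noise under a Gaussian envelope."""
    half = int(round(0.06 * rate))
    t = np.arange(-half, half + 1) / rate
    envelope = np.exp(-0.5 * (t / 0.025) ** 2)
    return amplitude * envelope * rng.standard_normal(t.size)


def _add_at(signal: np.ndarray, center: int, waveform: np.ndarray, peak_offset: int) -> None:
    start = center - peak_offset
    lo = max(0, start)
    hi = min(signal.size, start + waveform.size)
    if hi > lo:
        signal[lo:hi] += waveform[lo - start:hi - start]


def generate_record(template: BeatTemplate, rhythm: RhythmSpec,
                    noise: NoiseSpec | None = None, name: str = "") -> EcgRecord:
    """Generate a two-lead 500 Hz record with exact beat annotations.

    Lead ordering is ``["II", "I"]``: lead II (the detection lead) carries the
    template at full amplitude, lead I a scaled projection of it.  The same
    seed always yields the bit-identical record.
    """
    noise = noise or NoiseSpec()
    rate = PIPELINE_RATE
    rng = np.random.default_rng(rhythm.seed)
    beat_times, beat_classes = _place_beats(rhythm, rng)
    artefact_times = _place_artefacts(rhythm, beat_times, rng)

    n = int(round(rhythm.duration * rate))
    sig = np.zeros((2, n))
    vpc_tpl = vpc_variant(template)
    lead_gain = (1.0, 0.55)

    events: list[tuple[int, str]] = []
    for t, cls in zip(beat_times, beat_classes):
        idx = int(round(t * rate))
        tpl = vpc_tpl if cls == "VPC" else template
        for li, g in enumerate(lead_gain):
            _add_at(sig[li], idx, g * tpl.waveform, tpl.peak_offset)
        events.append((idx, cls))
    peak_amp = float(np.max(np.abs(template.waveform)))
    for t in artefact_times:
        idx = int(round(t * rate))
        burst = _artefact_burst(rng, rate, 1.6 * peak_amp)
        for li, g in enumerate(lead_gain):
            _add_at(sig[li], idx, g * burst, burst.size // 2)
        events.append((idx, "A"))
    events.sort(key=lambda e: e[0])
    # artefact placement keeps >= 0.18 s clearance, so indices are unique
    for (i0, _), (i1, _) in zip(events, events[1:]):
        if i1 <= i0:
            raise RuntimeError("event placement produced non-increasing indices")

    ts = np.arange(n) / rate
    if noise.baseline_wander_amplitude > 0:
        for li in range(2):
            phase = rng.uniform(0, 2 * math.pi)
            sig[li] += noise.baseline_wander_amplitude * np.sin(
                2 * math.pi * noise.baseline_wander_freq * ts + phase)
    if noise.white_noise_sd > 0:
        sig += noise.white_noise_sd * rng.standard_normal(sig.shape)
    if noise.powerline_freq is not None:
        for li in range(2):
            phase = rng.uniform(0, 2 * math.pi)
            sig[li] += noise.powerline_amplitude * np.sin(
                2 * math.pi * noise.powerline_freq * ts + phase)

    return EcgRecord(sample_rate=rate, leads=["II", "I"], signal=sig,
                     annotations=events, name=name or f"sim-{rhythm.seed}")


def ideal_annotations(record: EcgRecord) -> list[tuple[int, str]]:
    """Ground-truth beat list of a generated record (detector scoring, labels)."""
    return list(record.annotations)


def clinic_record(seed: int, duration: float = 120.0, heart_rate: float = 60.0,
                  apc_rate: float = 2.0, vpc_rate: float = 2.0,
                  artefact_rate: float = 1.0) -> EcgRecord:
    """Convenience: an equine record under the 'clinic' noise preset."""
    rhythm = RhythmSpec(base_heart_rate=heart_rate, duration=duration, seed=seed,
                        apc_rate=apc_rate, vpc_rate=vpc_rate, artefact_rate=artefact_rate)
    return generate_record(equine_template(), rhythm, NOISE_PRESETS["clinic"])
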