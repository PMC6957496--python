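"""Shared fixtures; the expensive trainings run once per session."""

import numpy as np
import pytest

import equibeat as eb
from equibeat import network as nw
from equibeat.toysets import separable_beat_set, timing_only_set

#: Conditions for the 10-record detector-quality benchmark: two-minute
#: equine records under the "clinic" noise preset, heart rates spanning
#: 40-76 bpm, a couple of ectopics per minute and occasional artefacts.
CLINIC_BENCH = [
    dict(base_heart_rate=40 + 4 * seed, duration=120.0, seed=seed,
         apc_rate=2.0, vpc_rate=2.0, artefact_rate=1.0)
    for seed in range(10)
]


def make_clinic_record(**kwargs) -> eb.EcgRecord:
    return eb.generate_record(eb.equine_template(), eb.RhythmSpec(**kwargs),
                              eb.NOISE_PRESETS["clinic"])


def filtered_lead(record: eb.EcgRecord, lead: str = "II") -> np.ndarray:
    x = record.lead(lead)
    return eb.denoise(eb.remove_baseline(x, record.sample_rate), record.sample_rate)


@pytest.fixture(scope="session")
def clinic_scores():
    """SWT and Pan-Tompkins detection tallies over the 10-record benchmark."""
    swt = {"tp": 0, "fp": 0, "fn": 0}
    pt = {"tp": 0, "fp": 0, "fn": 0}
    for cond in CLINIC_BENCH:
        rec = make_clinic_record(**cond)
        f = filtered_lead(rec)
        ref = np.array([i for i, c in rec.annotations if c != "A"])
        for tally, result in (
            (swt, eb.detect_speaks(f, rec.sample_rate)),
            (pt, eb.pan_tompkins(f, rec.sample_rate)),
        ):
            s = eb.score_detections(result.peak_indices, ref, rec.sample_rate, 0.05)
            tally["tp"] += s.true_positive
            tally["fp"] += s.false_positive
            tally["fn"] += s.false_negative
    return swt, pt


@pytest.fixture(scope="session")
def trained_separable():
    """Parallel network trained on the 200-sample separable 4-class set."""
    Xm, Xt, y = separable_beat_set(200, seed=0)
    model = nw.build_network(nw.table_eecg_config(), seed=0)
    nw.train(model, (Xm, Xt, y), None,
             nw.TrainConfig(epochs=20, batch_size=20, seed=0))
    return model, (Xm, Xt, y)


@pytest.fixture(scope="session")
def ablation_recalls():
    """APC recall of the parallel vs timing-ablated network on the set where
    only timing separates APC from N.

    Recall is measured on a held-out draw of the same construction: N and APC
    morphologies are identical in distribution, so morphological noise
    memorized from the training samples cannot help on fresh ones.
    """
    Xm, Xt, y = timing_only_set(200, seed=1)
    Hm, Ht, hy = timing_only_set(200, seed=2)
    out = {}
    for use_timing in (True, False):
        model = nw.build_network(
            nw.table_eecg_config(use_timing_path=use_timing), seed=0)
        nw.train(model, (Xm, Xt, y), None,
                 nw.TrainConfig(epochs=20, batch_size=20, seed=0))
        _, pred = nw.predict(model, (Hm, Ht if use_timing else None))
        cm = eb.confusion([eb.BEAT_CLASSES[i] for i in hy],
                          [eb.BEAT_CLASSES[i] for i in pred])
        out[use_timing] = eb.compute_metrics(cm).per_class["APC"]["recall"]
    return out


@pytest.fixture
def tiny_net_config():
    """A miniature parallel architecture for fast unit tests."""
    return nw.NetworkConfig(
        morph_path_1=(nw.ConvBlockSpec(4, 3, 3), nw.ConvBlockSpec(2, 2, 4)),
        morph_path_2=(nw.ConvBlockSpec(2, 2, 2), nw.ConvBlockSpec(4, 3, 3)),
        timing_path=(nw.ConvBlockSpec(8, 4, 3), nw.ConvBlockSpec(4, 3, 2)),
        dense_units=8, final_dense_units=5, dropout=0.1, l2_lambda=1e-4,
        morph_width=40, timing_len=80)


def tiny_toy_data(n=32, seed=0, morph_width=40, timing_len=80):
    """Four separable classes at miniature input sizes."""
    rng = np.random.default_rng(seed)
    means_m = np.stack([np.sin(np.linspace(0, (k + 1) * np.pi, morph_width))
                        for k in range(4)])
    means_t = np.stack([np.roll(np.repeat([1.0, 0, 0, 0], timing_len // 4), 7 * k)
                        for k in range(4)])
    y = np.tile(np.arange(4), -(-n // 4))[:n]
    Xm = np.stack([np.stack([means_m[k], 0.5 * means_m[k]]) for k in y])
    Xm = Xm + 0.05 * rng.standard_normal(Xm.shape)
    Xt = means_t[y] + 0.05 * rng.standard_normal((n, timing_len))
    return Xm, Xt, y
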