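"""Reading and writing WFDB-style records and the 4-class label map.

Supports the subset of the WFDB conventions the pipeline needs: headers
(``.hea``), signal formats 16 (16-bit little-endian) and 212 (packed 12-bit,
the MIT-BIH arrhythmia format), and MIT annotation files (``.atr``), plus a
plain-CSV dialect for generated records.  Native beat symbols are mapped onto
the four pipeline classes — normal (N), atrial premature contraction (APC),
ventricular premature contraction (VPC) and artefact (A) — by underlying
mechanism: supraventricular prematures become APC, ventricular ectopy VPC,
and fusion/paced/unclassifiable/noise events A.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .records import BEAT_CLASSES, EcgRecord

__all__ = [
    "ClassMap",
    "default_class_map",
    "read_record",
    "read_record_csv",
    "write_record_wfdb",
    "write_record_csv",
    "resample_record",
]

# MIT annotation type codes <-> display symbols (the subset that occurs in
# beat-annotated records).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    22: '"', 24: "p", 25: "B", 27: "t", 28: "+", 30: "?", 31: "!", 32: "[",
    33: "]", 34: "e", 35: "n", 37: "x", 38: "f", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

_DEFAULT_MAP = {
    # normal conduction (bundle-branch blocks and escapes conduct a full beat)
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    # supraventricular prematures
    "A": "APC", "a": "APC", "J": "APC", "S": "APC",
    # ventricular ectopy
    "V": "VPC", "E": "VPC",
    # fusion / paced / unclassifiable / noise
    "F": "A", "f": "A", "/": "A", "Q": "A", "~": "A", "|": "A",
    # non-beat annotations
    "+": "ignore", '"': "ignore", "s": "ignore", "T": "ignore", "p": "ignore",
    "t": "ignore", "?": "ignore", "!": "ignore", "[": "ignore", "]": "ignore",
    "x": "ignore", "B": "ignore", "n": "ignore", "r": "ignore",
}


@dataclass
class ClassMap:
    """Total map from native WFDB beat symbols to the 4 classes or ``ignore``."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values()} - set(BEAT_CLASSES) - {"ignore"}
        if bad:
            raise ValueError(f"targets must be one of {BEAT_CLASSES} or 'ignore', got {bad}")

    def __getitem__(self, symbol: str) -> str:
        try:
            return self.mapping[symbol]
        except KeyError:
            raise KeyError(
                f"annotation symbol {symbol!r} is not covered by the class map; "
                "add it (or map it to 'ignore')") from None

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassMap":
        with open(path) as fh:
            return cls(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.mapping, fh, indent=1, sort_keys=True)


def default_class_map() -> ClassMap:
    """The documented default symbol-to-class assignment (editable via JSON)."""
    return ClassMap(dict(_DEFAULT_MAP))


# ---------------------------------------------------------------------------
# header + signal


def _parse_header(hea_path: Path):
    lines = [ln.split("#")[0].strip() for ln in hea_path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    rec_name, nsig, fs, *rest = lines[0].split()
    nsig = int(nsig)
    fs = float(fs.split("/")[0])
    nsamp = int(rest[0]) if rest else 0
    sigs = []
    for ln in lines[1:1 + nsig]:
        tok = ln.split()
        fname, fmt = tok[0], int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, 0
        if len(tok) > 2:
            g = tok[2].split("/")[0]
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) or 200.0
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(sigs)}"
        sigs.append({"file": fname, "fmt": fmt, "gain": gain,
                     "baseline": baseline, "desc": desc})
    return rec_name, fs, nsamp, sigs


def _read_dat(path: Path, fmt: int, nsig: int) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == 16:
        adus = np.frombuffer(raw, dtype="<i2")
        n = adus.size // nsig
        return adus[: n * nsig].reshape(n, nsig).T.astype(float)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int32)
        s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s1[s1 > 2047] -= 4096
        s2[s2 > 2047] -= 4096
        flat = np.empty(2 * b.shape[0], dtype=np.int32)
        flat[0::2], flat[1::2] = s1, s2
        n = flat.size // nsig
        return flat[: n * nsig].reshape(n, nsig).T.astype(float)
    raise ValueError(f"unsupported WFDB signal format {fmt} (supported: 16, 212)")


def _read_atr(path: Path) -> list[tuple[int, str]]:
    words = np.frombuffer(path.read_bytes(), dtype="<u2")
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i < words.size:
        w = int(words[i])
        code, interval = w >> 10, w & 0x3FF
        i += 1
        if code == 0 and interval == 0:  # end of file
            break
        if code == _SKIP:
            t += (int(words[i]) << 16) | int(words[i + 1])
            i += 2
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += (interval + 1) // 2
            continue
        t += interval
        sym = _CODE_TO_SYMBOL.get(code)
        if sym is None:
            raise ValueError(f"unknown annotation type code {code} in {path.name}")
        out.append((t, sym))
    return out


def read_record(path: str | Path, class_map: ClassMap | None = None,
                annotation_ext: str = "atr") -> EcgRecord:
    """Read a WFDB record + annotations, mapping symbols through ``class_map``.

    ``path`` is the record path without extension.  The native sample rate is
    preserved; symbols mapped to ``ignore`` are dropped; a symbol missing from
    the map raises, naming the symbol (the map must be total).
    """
    path = Path(path)
    class_map = class_map or default_class_map()
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing WFDB header {hea}")
    rec_name, fs, nsamp, sigs = _parse_header(hea)
    fmt = sigs[0]["fmt"]
    adus = _read_dat(path.parent / sigs[0]["file"], fmt, len(sigs))
    signal = np.empty_like(adus)
    for ch, s in enumerate(sigs):
        signal[ch] = (adus[ch] - s["baseline"]) / s["gain"]
    if nsamp:
        signal = signal[:, :nsamp]

    atr = path.with_suffix(f".{annotation_ext}")
    if not atr.exists():
        raise FileNotFoundError(
            f"record {path.name} has no annotation file {atr.name}")
    native = _read_atr(atr)
    annotations = []
    for idx, sym in native:
        target = class_map[sym]
        if target != "ignore" and 0 <= idx < signal.shape[1]:
            annotations.append((idx, target))
    leads = [s["desc"] for s in sigs]
    return EcgRecord(sample_rate=fs, leads=leads, signal=signal,
                     annotations=annotations, name=rec_name)


def write_record_wfdb(record: EcgRecord, path: str | Path, gain: float = 1000.0) -> Path:
    """Write a record as .hea + .dat (format 16) + .atr.

    Amplitudes are quantized to ``round(mV * gain)`` ADC units; 1000 adu/mV
    keeps quantization error at 0.5 uV.  Annotation classes are stored under
    their native MIT symbols (N, A, V, ~).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name
    adus = np.clip(np.round(record.signal * gain), -32768, 32767).astype("<i2")
    inter = adus.T.reshape(-1)
    inter.tofile(path.with_suffix(".dat"))
    lines = [f"{name} {len(record.leads)} {record.sample_rate:g} {record.n_samples}"]
    for ch, lead in enumerate(record.leads):
        cksum = int(np.sum(adus[ch], dtype=np.int16))
        first = int(adus[ch, 0]) if adus.shape[1] else 0
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 {first} {cksum} 0 {lead}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")

    to_native = {"N": "N", "APC": "A", "VPC": "V", "A": "~"}
    words = bytearray()
    t_prev = 0
    for idx, cls in record.annotations:
        dt = idx - t_prev
        code = _SYMBOL_TO_CODE[to_native[cls]]
        if dt > 1023:
            words += int((_SKIP << 10)).to_bytes(2, "little")
            words += int(dt >> 16).to_bytes(2, "little")
            words += int(dt & 0xFFFF).to_bytes(2, "little")
            dt = 0
        words += int((code << 10) | dt).to_bytes(2, "little")
        t_prev = idx
    words += b"\x00\x00"
    path.with_suffix(".atr").write_bytes(bytes(words))
    return path


# ---------------------------------------------------------------------------
# CSV dialect


def write_record_csv(record: EcgRecord, path: str | Path) -> Path:
    """Write ``<path>.csv`` (one column per lead, '# sample_rate=' header) and
    ``<path>.annotations.csv`` (sample_index,label).  Full float precision, so
    the round trip is bit-exact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sig_path = path.with_suffix(".csv")
    with open(sig_path, "w", newline="") as fh:
        fh.write(f"# sample_rate={record.sample_rate:.17g}\n")
        w = csv.writer(fh)
        w.writerow(record.leads)
        for row in record.signal.T:
            w.writerow([f"{v:.17g}" for v in row])
    with open(path.parent / (path.stem + ".annotations.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_index", "label"])
        for idx, cls in record.annotations:
            w.writerow([idx, cls])
    return sig_path


def read_record_csv(path: str | Path) -> EcgRecord:
    """Read the CSV dialect written by :func:`write_record_csv`."""
    path = Path(path)
    sig_path = path.with_suffix(".csv")
    with open(sig_path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# sample_rate="):
            raise ValueError(f"{sig_path} lacks the '# sample_rate=' header")
        rate = float(header.split("=", 1)[1])
        reader = csv.reader(fh)
        leads = next(reader)
        rows = [[float(v) for v in row] for row in reader if row]
    signal = np.array(rows).T if rows else np.zeros((len(leads), 0))
    ann_path = path.parent / (path.stem + ".annotations.csv")
    annotations: list[tuple[int, str]] = []
    if ann_path.exists():
        with open(ann_path) as fh:
            reader = csv.reader(fh)
            next(reader)
            annotations = [(int(r[0]), r[1]) for r in reader if r]
    return EcgRecord(sample_rate=rate, leads=leads, signal=signal,
                     annotations=annotations, name=path.stem)


# ---------------------------------------------------------------------------
# resampling


def resample_record(record: EcgRecord, target_rate: float) -> EcgRecord:
    """Band-limited (polyphase) resampling to ``target_rate``.

    Annotation indices are rescaled by ``target/source`` and rounded half-up,
    preserving annotation times to within one sample; the sample count becomes
    ``round(n * target/source)``.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    ratio = Fraction(target_rate) / Fraction(record.sample_rate)
    ratio = ratio.limit_denominator(10 ** 6)
    if ratio == 1:
        return EcgRecord(record.sample_rate, list(record.leads),
                         record.signal.copy(), list(record.annotations), record.name)
    n_out = int(round(record.n_samples * float(ratio)))
    sig = resample_poly(record.signal, ratio.numerator, ratio.denominator, axis=1)
    if sig.shape[1] > n_out:
        sig = sig[:, :n_out]
    elif sig.shape[1] < n_out:
        sig = np.pad(sig, ((0, 0), (0, n_out - sig.shape[1])))
    annotations = []
    prev = -1
    for idx, cls in record.annotations:
        j = int(np.floor(idx * float(ratio) + 0.5))
        j = min(max(j, prev + 1), n_out - 1)  # keep strictly increasing in-range
        annotations.append((j, cls))
        prev = j
    return EcgRecord(sample_rate=target_rate, leads=list(record.leads),
                     signal=sig, annotations=annotations, name=record.name)
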