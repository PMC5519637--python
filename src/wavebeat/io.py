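"""Reading and writing WFDB-family ECG records, annotations and feature tables.

The reader understands the subset of the WFDB conventions the pipeline
needs: single-segment headers (``.hea``), signal formats 16 (little-endian
int16) and 212 (packed 12-bit pairs, the MIT-BIH arrhythmia layout), and
the MIT binary beat-annotation stream (``.atr``).  An rdann-style
plain-text annotation table is accepted as well so that fixtures can stay
human-readable.  Amplitudes are converted to physical units (millivolts)
using the per-signal gain and baseline from the header.

Only beats whose annotation symbol maps to one of the six morphology
classes (A, L, N, P, R, V) carry a label; everything else is kept with
``label=None`` until :func:`keep_labeled` drops it.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ChannelError, LabelError, ReadError

logger = logging.getLogger(__name__)

#: The six beat morphology classes, in canonical (alphabetical) order.
CLASSES: tuple[str, ...] = ("A", "L", "N", "P", "R", "V")

#: MIT annotation-code <-> symbol table (subset of the WFDB code map).
_CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

# pseudo-annotation codes in the binary stream
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass(frozen=True)
class EcgRecord:
    """One lead of a sampled ECG trace.

    Attributes
    ----------
    record_id : str
        Record name (e.g. ``"100"``).
    fs : float
        Sampling frequency in samples/second; must be positive.
    samples : numpy.ndarray
        Amplitudes in millivolts, one value per sample.
    lead_name : str
        Name of the lead this channel carries (e.g. ``"MLII"``).
    """

    record_id: str
    fs: float
    samples: np.ndarray
    lead_name: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if samples.size == 0:
            raise ValueError("record has no samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("record contains non-finite samples")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated beat: R-peak sample index, raw symbol, mapped label."""

    sample_index: int
    symbol: str
    label: str | None = None


@dataclass(frozen=True)
class LabelMap:
    """Mapping from annotation symbols to the six class labels.

    The default translates the MIT-BIH dialect: the paced-beat symbol is
    ``'/'`` on disk but the class is written ``P``.  Symbols outside the
    map yield no label.
    """

    mapping: Mapping[str, str] = field(
        default_factory=lambda: {
            "N": "N", "L": "L", "R": "R", "A": "A", "V": "V", "/": "P",
        }
    )

    def __post_init__(self) -> None:
        values = list(self.mapping.values())
        if len(set(values)) != len(values):
            raise ValueError("label map must be injective")
        for lab in values:
            if lab not in CLASSES:
                raise LabelError(f"label {lab!r} is not one of {CLASSES}")

    def label_of(self, symbol: str) -> str | None:
        return self.mapping.get(symbol)


DEFAULT_LABEL_MAP = LabelMap()


# --------------------------------------------------------------------------
# header parsing

@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    adc_zero: int
    description: str


def _parse_header(hea_path: Path) -> tuple[str, float, int, list[_SignalSpec]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ReadError(f"empty header file: {hea_path}")
    head = lines[0].split()
    record_id = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    specs: list[_SignalSpec] = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        file_name = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, adc_zero = 200.0, None, 0
        if len(tok) > 2:
            g = tok[2].split("/")[0]
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) or 200.0
        if len(tok) > 4:
            adc_zero = int(tok[4])
        if baseline is None:
            baseline = adc_zero
        description = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(specs)}"
        specs.append(_SignalSpec(file_name, fmt, gain, baseline, adc_zero, description))
    return record_id, fs, n_samples, specs


def _read_digital(dat_path: Path, fmt: int, n_sig: int) -> np.ndarray:
    """Return an (n_samples, n_sig) int array of raw ADC values."""
    raw = dat_path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        data = data[: (data.size // n_sig) * n_sig]
        return data.reshape(-1, n_sig).astype(np.int64)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int64)
        first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        flat = np.empty(b.shape[0] * 2, dtype=np.int64)
        flat[0::2], flat[1::2] = first, second
        flat = flat[: (flat.size // n_sig) * n_sig]
        return flat.reshape(-1, n_sig)
    raise ReadError(f"unsupported signal format {fmt} in {dat_path}")


def read_record(path: str | Path, channel: str | int | None = None) -> EcgRecord:
    """Read one channel of a WFDB-family record as physical millivolts.

    Parameters
    ----------
    path : str or Path
        Record path with or without the ``.hea`` extension.
    channel : str, int or None
        Lead selector.  A string selects by lead description, an integer
        by position.  ``None`` selects the lead named ``"MLII"`` when
        present and otherwise falls back to channel 0 with a warning.

    Raises
    ------
    ReadError
        If the header or signal file is missing or malformed.
    ChannelError
        If the requested lead does not exist; the message lists the
        available lead names.
    """
    hea_path = Path(path)
    if hea_path.suffix != ".hea":
        hea_path = hea_path.with_suffix(".hea")
    if not hea_path.exists():
        raise ReadError(f"header not found: {hea_path}")
    try:
        record_id, fs, n_samples, specs = _parse_header(hea_path)
    except (ValueError, IndexError) as exc:
        raise ReadError(f"malformed header {hea_path}: {exc}") from exc

    names = [s.description for s in specs]
    if channel is None:
        if "MLII" in names:
            idx = names.index("MLII")
        else:
            logger.warning(
                "record %s has no MLII lead (available: %s); using channel 0",
                record_id, names,
            )
            idx = 0
    elif isinstance(channel, int):
        if not 0 <= channel < len(specs):
            raise ChannelError(
                f"channel {channel} out of range; available leads: {names}"
            )
        idx = channel
    else:
        if channel not in names:
            raise ChannelError(
                f"no lead named {channel!r}; available leads: {names}"
            )
        idx = names.index(channel)

    spec = specs[idx]
    dat_path = hea_path.parent / spec.file_name
    if not dat_path.exists():
        raise ReadError(f"signal file not found: {dat_path}")
    # all signals of this record sharing one .dat file (the common layout)
    same_file = [s for s in specs if s.file_name == spec.file_name]
    col = [s.description for s in same_file].index(spec.description)
    digital = _read_digital(dat_path, spec.fmt, len(same_file))
    if n_samples:
        digital = digital[:n_samples]
    physical = (digital[:, col] - spec.baseline) / spec.gain
    return EcgRecord(record_id=record_id, fs=fs, samples=physical,
                     lead_name=spec.description)


def write_record(record: EcgRecord, directory: str | Path,
                 gain: float = 200.0, fmt: int = 16) -> Path:
    """Write a single-lead record as a ``.hea`` + format-16 ``.dat`` pair.

    Amplitudes are quantized to integer ADC units at the given gain, so a
    round trip reproduces the samples to within 1/(2*gain) mV.
    """
    if fmt != 16:
        raise ValueError("only format 16 writing is supported")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    digital = np.clip(np.rint(record.samples * gain), -32768, 32767).astype("<i2")
    dat_name = f"{record.record_id}.dat"
    (directory / dat_name).write_bytes(digital.tobytes())
    lead = record.lead_name or "MLII"
    fs_txt = f"{record.fs:g}"
    header = (
        f"{record.record_id} 1 {fs_txt} {len(record)}\n"
        f"{dat_name} 16 {gain:g}(0)/mV 16 0 {int(digital[0])} 0 0 {lead}\n"
    )
    hea_path = directory / f"{record.record_id}.hea"
    hea_path.write_text(header)
    return hea_path


# --------------------------------------------------------------------------
# annotations

def _read_binary_annotations(path: Path) -> list[tuple[int, str]]:
    raw = path.read_bytes()
    if len(raw) % 2:
        raw = raw[:-1]
    words = struct.unpack(f"<{len(raw) // 2}H", raw)
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i < len(words):
        w = words[i]
        code, interval = w >> 10, w & 0x3FF
        if w == 0:  # EOF
            break
        if code == _SKIP:
            if i + 2 >= len(words):
                break
            long_iv = (words[i + 1] << 16) | words[i + 2]
            if long_iv >= 1 << 31:
                long_iv -= 1 << 32
            t += long_iv
            i += 3
            continue
        if code == _AUX:
            i += 1 + (interval + 1) // 2
            continue
        if code in (_NUM, _SUB, _CHN):
            i += 1
            continue
        t += interval
        out.append((t, _CODE_TO_SYMBOL.get(code, "?")))
        i += 1
    return out


def _read_text_annotations(path: Path) -> list[tuple[int, str]]:
    out: list[tuple[int, str]] = []
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        tok = ln.split()
        out.append((int(tok[0]), tok[1]))
    return out


def read_annotations(path: str | Path,
                     label_map: LabelMap = DEFAULT_LABEL_MAP) -> list[BeatAnnotation]:
    """Read beat annotations, sorted by sample index, with mapped labels.

    ``.txt``/``.tsv`` files are parsed as two-column text
    (``sample_index symbol``); anything else as the MIT binary stream.
    """
    path = Path(path)
    if not path.exists():
        raise ReadError(f"annotation file not found: {path}")
    try:
        if path.suffix in (".txt", ".tsv"):
            pairs = _read_text_annotations(path)
        else:
            pairs = _read_binary_annotations(path)
    except (ValueError, IndexError, struct.error) as exc:
        raise ReadError(f"malformed annotation file {path}: {exc}") from exc
    pairs.sort(key=lambda p: p[0])
    return [
        BeatAnnotation(sample_index=t, symbol=sym, label=label_map.label_of(sym))
        for t, sym in pairs
    ]


def write_annotations(annotations: Sequence[BeatAnnotation],
                      path: str | Path) -> Path:
    """Write annotations; ``.txt``/``.tsv`` as text, otherwise MIT binary."""
    path = Path(path)
    anns = sorted(annotations, key=lambda a: a.sample_index)
    if path.suffix in (".txt", ".tsv"):
        lines = [f"{a.sample_index}\t{a.symbol}" for a in anns]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return path
    words: list[int] = []
    t = 0
    for a in anns:
        code = _SYMBOL_TO_CODE.get(a.symbol)
        if code is None:
            raise LabelError(f"symbol {a.symbol!r} has no annotation code")
        dt = a.sample_index - t
        if dt < 0:
            raise ValueError("annotations must be non-decreasing in time")
        if dt > 0x3FF:
            words += [_SKIP << 10, (dt >> 16) & 0xFFFF, dt & 0xFFFF, code << 10]
        else:
            words.append((code << 10) | dt)
        t = a.sample_index
    words.append(0)  # EOF
    path.write_bytes(struct.pack(f"<{len(words)}H", *words))
    return path


def keep_labeled(annotations: Iterable[BeatAnnotation]) -> list[BeatAnnotation]:
    """Return only the annotations whose symbol mapped to a class label."""
    return [a for a in annotations if a.label is not None]


# --------------------------------------------------------------------------
# feature tables

def save_features(path: str | Path, record_ids: Sequence[str],
                  labels: Sequence[str], features: np.ndarray) -> Path:
    """Persist a feature matrix as CSV: record_id, label, f1..fk."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or len(record_ids) != features.shape[0] \
            or len(labels) != features.shape[0]:
        raise ValueError("record_ids, labels and feature rows must align")
    cols = [f"f{i + 1}" for i in range(features.shape[1])]
    frame = pd.DataFrame(features, columns=cols)
    frame.insert(0, "label", list(labels))
    frame.insert(0, "record_id", list(record_ids))
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def load_features(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Load a feature CSV written by :func:`save_features`."""
    path = Path(path)
    if not path.exists():
        raise ReadError(f"feature file not found: {path}")
    frame = pd.read_csv(path, dtype={"record_id": str, "label": str})
    if "record_id" not in frame.columns or "label" not in frame.columns:
        raise ReadError(f"{path} is not a feature table (missing header columns)")
    X = frame.drop(columns=["record_id", "label"]).to_numpy(dtype=np.float64)
    return list(frame["record_id"]), list(frame["label"]), X
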