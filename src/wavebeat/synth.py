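"""Synthetic multi-subject ECG generator with six beat morphology classes.

Each beat is a sum of Gaussian bumps, one per named wave (P, Q, R, S, T),
on a millivolt scale.  Class templates modify a base (normal) morphology:

* **N** — the base morphology itself.
* **V** (premature ventricular) — widened R complex (about 3x), absent P
  wave, inverted T wave.
* **L / R** (bundle branch block) — widened, two-lobed R complex; the two
  classes place the secondary lobe on opposite sides of the R-peak.
* **A** (atrial premature) — reduced P-wave amplitude and a shortened gap
  to the preceding beat.
* **P** (paced) — a narrow high-amplitude pacing spike at the annotation
  point followed by a wide slurred complex; no P wave.

Subject-level variation: each record (one synthetic patient) draws its
own multiplicative perturbation of every wave amplitude, width and centre
offset, with spread ``between_subject_sd`` (tau).  Beats within a record
share the subject's morphology; white noise and sinusoidal baseline
wander are added on top.  The class mix is heavily imbalanced by default
(70% N), matching the class distribution the pipeline is meant to face.

All randomness flows from one seed; record ``i`` uses the substream
``(seed, i)``, so datasets are bit-reproducible and records independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import (BeatAnnotation, EcgRecord, write_annotations, write_record)

#: Wave-parameter table of the base (normal) morphology.
#: amplitude in mV, centre offset in seconds relative to the R-peak,
#: width (Gaussian sigma) in seconds.
BASE_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.15, -0.16, 0.022),
    "Q": (-0.10, -0.026, 0.009),
    "R": (1.20, 0.0, 0.012),
    "S": (-0.25, 0.030, 0.011),
    "T": (0.35, 0.22, 0.055),
}


@dataclass(frozen=True)
class Wave:
    amplitude: float
    center: float
    width: float


@dataclass(frozen=True)
class SubjectMorphology:
    """One subject's realized wave parameters (amplitude/centre/width)."""

    waves: Mapping[str, Wave]


@dataclass(frozen=True)
class BeatClassTemplate:
    """Deterministic class-specific modification of a subject's morphology.

    ``amp_scale`` and ``width_scale`` multiply the subject's wave
    parameters; ``center_shift`` adds seconds; ``extra`` adds waves not in
    the base set (pacing spike, second bundle-branch lobe).
    ``pre_gap_scale`` shortens the preceding RR interval (atrial
    prematurity is a rhythm feature, not a wave feature).
    """

    label: str
    amp_scale: Mapping[str, float] = field(default_factory=dict)
    width_scale: Mapping[str, float] = field(default_factory=dict)
    center_shift: Mapping[str, float] = field(default_factory=dict)
    extra: Mapping[str, Wave] = field(default_factory=dict)
    pre_gap_scale: float = 1.0

    def apply(self, subject: SubjectMorphology) -> dict[str, Wave]:
        waves: dict[str, Wave] = {}
        for name, w in subject.waves.items():
            a = w.amplitude * self.amp_scale.get(name, 1.0)
            if a == 0.0:
                continue
            waves[name] = Wave(
                amplitude=a,
                center=w.center + self.center_shift.get(name, 0.0),
                width=w.width * self.width_scale.get(name, 1.0),
            )
        # extra waves inherit the subject's R-wave perturbation so they
        # carry a subject signature too
        r_ref = subject.waves["R"]
        r_base = BASE_WAVES["R"]
        amp_f = r_ref.amplitude / r_base[0]
        width_f = r_ref.width / r_base[2]
        for name, w in self.extra.items():
            waves[name] = Wave(w.amplitude * amp_f, w.center, w.width * width_f)
        return waves


CLASS_TEMPLATES: dict[str, BeatClassTemplate] = {
    "N": BeatClassTemplate(label="N"),
    "V": BeatClassTemplate(
        label="V",
        amp_scale={"P": 0.0, "R": 0.85, "T": -0.8, "Q": 0.0},
        width_scale={"R": 3.0, "S": 1.8},
    ),
    "L": BeatClassTemplate(
        label="L",
        amp_scale={"R": 0.9, "S": 0.5},
        width_scale={"R": 1.8},
        extra={"R2": Wave(0.65, 0.045, 0.020)},
    ),
    "R": BeatClassTemplate(
        label="R",
        amp_scale={"R": 0.9, "S": 0.5},
        width_scale={"R": 1.8},
        extra={"R2": Wave(0.65, -0.045, 0.020)},
    ),
    "A": BeatClassTemplate(
        label="A",
        amp_scale={"P": 0.4},
        center_shift={"P": 0.02},
        pre_gap_scale=0.7,
    ),
    "P": BeatClassTemplate(
        label="P",
        amp_scale={"P": 0.0, "Q": 0.0, "R": 0.75, "S": 0.6, "T": 0.7},
        width_scale={"R": 2.5},
        center_shift={"R": 0.055},
        extra={"SPK": Wave(1.40, 0.0, 0.004)},
    ),
}


def _default_proportions() -> dict[str, float]:
    rest = 0.30 / 5
    return {"N": 0.70, "A": rest, "L": rest, "P": rest, "R": rest, "V": rest}


@dataclass(frozen=True)
class SynthConfig:
    """Dataset-level knobs: size, rate, class mix, variation and noise."""

    n_records: int = 20
    beats_per_record: int = 150
    fs: float = 360.0
    class_proportions: Mapping[str, float] = field(
        default_factory=_default_proportions)
    between_subject_sd: float = 0.2   #: tau — subject morphology spread
    noise_sd: float = 0.03            #: white-noise amplitude, mV
    baseline_amp: float = 0.05        #: baseline-wander amplitude, mV
    baseline_hz: float = 0.3          #: baseline-wander frequency, Hz
    mean_rr: float = 0.8              #: mean beat spacing, s (75 bpm)
    rr_jitter: float = 0.05           #: SD of beat spacing, s
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if self.between_subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("spread and noise SDs must be >= 0")


def _record_rng(cfg: SynthConfig, record_index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, record_index])


def sample_subject(cfg: SynthConfig, record_index: int,
                   rng: np.random.Generator | None = None) -> SubjectMorphology:
    """Draw one subject's morphology around the base hyper-means.

    Amplitudes, centres and widths are perturbed multiplicatively
    (1 + tau*z); widths are clipped to stay positive and the R amplitude
    to stay above 0.2 mV.  Deterministic given (seed, record_index).
    """
    rng = _record_rng(cfg, record_index) if rng is None else rng
    tau = cfg.between_subject_sd
    waves: dict[str, Wave] = {}
    for name, (amp, center, width) in BASE_WAVES.items():
        f_amp, f_width, f_center = 1.0 + tau * rng.standard_normal(3)
        waves[name] = Wave(
            amplitude=(max(amp * f_amp, 0.2) if name == "R" else amp * f_amp),
            center=center * max(f_center, 0.2),
            width=max(width * f_width, 0.25 * width),
        )
    return SubjectMorphology(waves=waves)


def render_beat(template: BeatClassTemplate, subject: SubjectMorphology,
                fs: float, t1: float = 0.25, t2: float = 0.45) -> np.ndarray:
    """Render one beat window (R-peak at sample round(t1*fs)) noise-free."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    pre = int(round(t1 * fs))
    post = int(round(t2 * fs))
    t = (np.arange(pre + post) - pre) / fs
    waves = template.apply(subject)
    y = np.zeros_like(t)
    for w in waves.values():
        y += w.amplitude * np.exp(-0.5 * ((t - w.center) / w.width) ** 2)
    return y


def _draw_labels(cfg: SynthConfig, rng: np.random.Generator, n: int) -> list[str]:
    labels = sorted(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[c] for c in labels])
    return [labels[i] for i in rng.choice(len(labels), size=n, p=probs)]


def generate_record(cfg: SynthConfig, record_index: int
                    ) -> tuple[EcgRecord, list[BeatAnnotation]]:
    """Generate one synthetic subject's record plus its beat annotations."""
    rng = _record_rng(cfg, record_index)
    subject = sample_subject(cfg, record_index, rng)
    labels = _draw_labels(cfg, rng, cfg.beats_per_record)

    # R-peak times: base spacing with jitter; A beats shorten their
    # preceding gap (premature atrial origin)
    gaps = cfg.mean_rr + cfg.rr_jitter * rng.standard_normal(cfg.beats_per_record)
    gaps = np.clip(gaps, 0.4, None)
    for i, lab in enumerate(labels):
        gaps[i] *= CLASS_TEMPLATES[lab].pre_gap_scale
    r_times = 1.0 + np.cumsum(gaps)  # 1 s lead-in so every beat is feasible
    # snap R-peaks to the sample grid so annotations mark the exact
    # rendered R sample
    r_times = np.round(r_times * cfg.fs) / cfg.fs

    duration = r_times[-1] + 1.0
    n_samples = int(round(duration * cfg.fs))
    signal = np.zeros(n_samples)
    t_axis = np.arange(n_samples) / cfg.fs

    annotations: list[BeatAnnotation] = []
    for r_time, lab in zip(r_times, labels):
        waves = CLASS_TEMPLATES[lab].apply(subject)
        r_idx = int(round(r_time * cfg.fs))
        # paint each wave over +-5 sigma only (records are long); the cut
        # is taken relative to the R sample so equal beats paint equally
        for w in waves.values():
            c = r_time + w.center
            lo = max(r_idx + int(np.floor((w.center - 5 * w.width) * cfg.fs)), 0)
            hi = min(r_idx + int(np.ceil((w.center + 5 * w.width) * cfg.fs)) + 1,
                     n_samples)
            tt = t_axis[lo:hi]
            signal[lo:hi] += w.amplitude * np.exp(-0.5 * ((tt - c) / w.width) ** 2)
        symbol = "/" if lab == "P" else lab
        annotations.append(BeatAnnotation(sample_index=r_idx, symbol=symbol,
                                          label=lab))

    if cfg.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += cfg.baseline_amp * np.sin(2 * np.pi * cfg.baseline_hz * t_axis
                                            + phase)
    if cfg.noise_sd > 0:
        signal += cfg.noise_sd * rng.standard_normal(n_samples)

    record = EcgRecord(record_id=f"S{record_index:03d}", fs=cfg.fs,
                       samples=signal, lead_name="MLII")
    return record, annotations


def generate_dataset(cfg: SynthConfig
                     ) -> list[tuple[EcgRecord, list[BeatAnnotation]]]:
    """Generate the full multi-record dataset (one subject per record)."""
    if cfg.n_records < 1 or cfg.beats_per_record < 1:
        raise ValueError("need at least one record and one beat per record")
    return [generate_record(cfg, i) for i in range(cfg.n_records)]


def write_dataset(dataset: Sequence[tuple[EcgRecord, Sequence[BeatAnnotation]]],
                  directory: str | Path) -> list[Path]:
    """Write every record as .hea/.dat/.atr so the io module can re-read it."""
    directory = Path(directory)
    paths = []
    for record, anns in dataset:
        hea = write_record(record, directory)
        write_annotations(list(anns), directory / f"{record.record_id}.atr")
        paths.append(hea)
    return paths
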