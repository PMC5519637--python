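"""Fixed-window beat segmentation anchored on annotated R-peaks.

Each labeled beat is cut into a window spanning ``t1`` seconds before and
``t2`` seconds after its R-peak, long enough to cover the P wave, QRS
complex and T wave of a beat at typical resting rates (60-80 bpm).  With
the defaults (0.25 s / 0.45 s) a 360 Hz record yields 252-sample windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import BoundaryError
from .io import BeatAnnotation, EcgRecord


@dataclass(frozen=True)
class SegmentationConfig:
    """Window extents in seconds relative to the R-peak."""

    t1: float = 0.25  #: seconds before the R-peak
    t2: float = 0.45  #: seconds after the R-peak

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("t1 and t2 must be positive")

    def pre_samples(self, fs: float) -> int:
        """Samples before the R-peak (half-to-even rounding of t1*fs)."""
        return int(round(self.t1 * fs))

    def post_samples(self, fs: float) -> int:
        """Samples at and after the R-peak (half-to-even rounding of t2*fs)."""
        return int(round(self.t2 * fs))

    def window_length(self, fs: float) -> int:
        return self.pre_samples(fs) + self.post_samples(fs)


@dataclass(frozen=True)
class BeatSegment:
    """A verbatim slice of the record around one R-peak."""

    values: np.ndarray
    label: str | None
    record_id: str
    r_index_in_window: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class SkipTally:
    """Counts of boundary beats dropped during segmentation."""

    before_start: int = 0
    past_end: int = 0
    skipped_indices: list[int] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.before_start + self.past_end


def segment_beat(record: EcgRecord, r_index: int,
                 cfg: SegmentationConfig = SegmentationConfig(),
                 label: str | None = None) -> BeatSegment:
    """Cut the half-open window ``[r - pre, r + post)`` around one R-peak.

    Raises
    ------
    BoundaryError
        If the window would extend past either record boundary.
    """
    pre = cfg.pre_samples(record.fs)
    post = cfg.post_samples(record.fs)
    start, stop = r_index - pre, r_index + post
    if start < 0:
        raise BoundaryError(
            f"beat at sample {r_index} needs {pre} samples before the R-peak "
            f"but only {r_index} exist"
        )
    if stop > len(record):
        raise BoundaryError(
            f"beat at sample {r_index} needs {post} samples after the R-peak "
            f"but only {len(record) - r_index} exist"
        )
    return BeatSegment(
        values=record.samples[start:stop].copy(),
        label=label,
        record_id=record.record_id,
        r_index_in_window=pre,
    )


def segment_record(record: EcgRecord, annotations: Sequence[BeatAnnotation],
                   cfg: SegmentationConfig = SegmentationConfig(),
                   ) -> tuple[list[BeatSegment], SkipTally]:
    """Segment every annotated beat, skipping (and counting) boundary beats.

    The annotations are expected to be pre-filtered to labeled beats; the
    labels travel with the segments.
    """
    pre = cfg.pre_samples(record.fs)
    post = cfg.post_samples(record.fs)
    n = len(record)
    segments: list[BeatSegment] = []
    tally = SkipTally()
    for ann in annotations:
        if ann.sample_index - pre < 0:
            tally.before_start += 1
            tally.skipped_indices.append(ann.sample_index)
            continue
        if ann.sample_index + post > n:
            tally.past_end += 1
            tally.skipped_indices.append(ann.sample_index)
            continue
        segments.append(segment_beat(record, ann.sample_index, cfg, ann.label))
    return segments, tally
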