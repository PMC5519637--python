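"""Wavelet multiresolution analysis (WMRA) of beat segments.

Each beat window is decomposed by an 8-level dyadic discrete wavelet
transform (default wavelet ``bior6.8``, symmetric half-point extension).
Level *j* halves the band of level *j-1*: the detail coefficients cDj
cover [fs/2^(j+1), fs/2^j] and the final approximation cAJ covers
[0, fs/2^(J+1)].  At 360 Hz and 8 levels the retained details cD1..cD8
span 0.70-180 Hz — the diagnostically relevant ECG band — while cA8
(0-0.70 Hz) holds baseline drift and is discarded.  The raw feature
vector is the concatenation cD1 || cD2 || ... || cD8.

The transform is computed one level at a time so that input lengths per
level are tracked exactly; the inverse walk reconstructs the segment to
floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt

from .errors import DepthError
from .segment import BeatSegment


@dataclass(frozen=True)
class WaveletConfig:
    """Wavelet family member, decomposition depth and boundary policy."""

    wavelet_name: str = "bior6.8"
    levels: int = 8
    extension_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        pywt.Wavelet(self.wavelet_name)  # raises for unknown names

    @property
    def filter_length(self) -> int:
        return pywt.Wavelet(self.wavelet_name).dec_len


DEFAULT_WAVELET = WaveletConfig()


@dataclass(frozen=True)
class DecompositionResult:
    """Coefficients of one decomposition: details cD1..cDJ plus cAJ."""

    details: tuple[np.ndarray, ...]      # cD1 first, cDJ last
    approx: np.ndarray                   # cAJ
    level_lengths: tuple[int, ...]       # len(cDj) for j = 1..J
    input_lengths: tuple[int, ...]       # signal length entering each level

    @property
    def levels(self) -> int:
        return len(self.details)


def coefficient_lengths(n: int, cfg: WaveletConfig = DEFAULT_WAVELET) -> list[int]:
    """Per-level detail lengths for an n-sample input.

    Under symmetric (and the other full-extension) modes each DWT stage
    maps a length-m input to floor((m + filter_len - 1) / 2) coefficients.
    """
    flen = cfg.filter_length
    out = []
    for _ in range(cfg.levels):
        n = (n + flen - 1) // 2
        out.append(n)
    return out


def max_feasible_level(n: int, cfg: WaveletConfig = DEFAULT_WAVELET) -> int:
    """Deepest level at which every stage still sees >= filter_length samples."""
    flen = cfg.filter_length
    level = 0
    while n >= flen and level < cfg.levels:
        level += 1
        n = (n + flen - 1) // 2
    return level


def decompose(segment: BeatSegment | np.ndarray,
              cfg: WaveletConfig = DEFAULT_WAVELET) -> DecompositionResult:
    """Run the level-by-level DWT on one beat segment.

    Raises
    ------
    DepthError
        If the segment is too short for the requested depth; the message
        states the maximum feasible level.
    """
    x = segment.values if isinstance(segment, BeatSegment) else np.asarray(segment)
    x = np.asarray(x, dtype=np.float64)
    feasible = max_feasible_level(x.size, cfg)
    if feasible < cfg.levels:
        raise DepthError(
            f"segment of length {x.size} supports at most {feasible} "
            f"levels with {cfg.wavelet_name} (requested {cfg.levels})"
        )
    details: list[np.ndarray] = []
    input_lengths: list[int] = []
    approx = x
    for _ in range(cfg.levels):
        input_lengths.append(approx.size)
        approx, detail = pywt.dwt(approx, cfg.wavelet_name, mode=cfg.extension_mode)
        details.append(detail)
    return DecompositionResult(
        details=tuple(details),
        approx=approx,
        level_lengths=tuple(len(d) for d in details),
        input_lengths=tuple(input_lengths),
    )


def reconstruct(result: DecompositionResult,
                cfg: WaveletConfig = DEFAULT_WAVELET) -> np.ndarray:
    """Invert :func:`decompose` exactly (up to floating-point error)."""
    approx = result.approx
    for detail, n in zip(reversed(result.details), reversed(result.input_lengths)):
        approx = pywt.idwt(approx, detail, cfg.wavelet_name, mode=cfg.extension_mode)
        approx = approx[:n]  # extension modes can overshoot by one sample
    return approx


def assemble_raw_features(result: DecompositionResult) -> np.ndarray:
    """Concatenate cD1 || ... || cDJ into the raw feature vector (cAJ dropped)."""
    return np.concatenate(result.details)


@dataclass(frozen=True)
class SubbandSpec:
    """Nominal frequency band of one coefficient sequence."""

    level: int
    low_hz: float
    high_hz: float
    kind: str = "detail"  # "detail" or "approx"


def subband_ranges(fs: float, levels: int) -> list[SubbandSpec]:
    """Dyadic subband bookkeeping: details 1..J then the final approximation.

    Detail level j spans [fs/2^(j+1), fs/2^j]; the approximation spans
    [0, fs/2^(J+1)].  Together they partition [0, fs/2].
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    bands = [
        SubbandSpec(level=j, low_hz=fs / 2 ** (j + 1), high_hz=fs / 2 ** j)
        for j in range(1, levels + 1)
    ]
    bands.append(SubbandSpec(level=levels, low_hz=0.0,
                             high_hz=fs / 2 ** (levels + 1), kind="approx"))
    return bands


def raw_feature_length(segment_length: int,
                       cfg: WaveletConfig = DEFAULT_WAVELET) -> int:
    """Realized raw-vector length for a given window length and config."""
    return sum(coefficient_lengths(segment_length, cfg))
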