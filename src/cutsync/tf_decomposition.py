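"""Block band power and sliding analysis windows.

Each 2-s model signal is band-limited to one of the 15 frequency ranges
and reduced to *block power*: the mean squared amplitude over consecutive
non-overlapping blocks of 8 samples (31.25 ms at 256 Hz), giving 64 power
values per epoch.  Statistical comparisons then run over sliding windows
of 6 consecutive blocks (187.5 ms); the central window holds the last 3
pre-cut and the first 3 post-cut blocks and is labelled 0 ms.

The block-power operator is pluggable so an FFT-magnitude variant can be
swapped in without touching the window bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .bands import BandDefinition, get_band, band_limit

__all__ = ["BandPowerSeries", "AnalysisWindow", "block_power",
           "band_power_series", "sliding_windows", "window_value_matrix",
           "DEFAULT_BLOCK_LEN", "DEFAULT_WINDOW_WIDTH"]

DEFAULT_BLOCK_LEN = 8
DEFAULT_WINDOW_WIDTH = 6

#: Reflective context added around a bare epoch before band filtering, in
#: seconds.  The slow delta ranges need context beyond the 2-s epoch; when
#: the continuous parent signal is available, filter it instead and slice.
EPOCH_REFLECT_PAD_S = 0.5


@dataclass
class BandPowerSeries:
    """Block-power time course of one model signal in one band."""

    band: BandDefinition
    block_len: int
    sampling_rate: float
    values: np.ndarray          # (n_blocks,), mean squared uV per block
    electrode: str | None = None
    film_id: str | None = None
    kind: str | None = None     # "ASF" | "ASC"
    taxon: str | None = None

    @property
    def n_blocks(self) -> int:
        return len(self.values)

    @property
    def block_duration_ms(self) -> float:
        return 1000.0 * self.block_len / self.sampling_rate


@dataclass(frozen=True)
class AnalysisWindow:
    """One sliding window of consecutive power blocks."""

    start_block: int
    width: int
    center_label_ms: float
    block_duration_ms: float

    @property
    def span_ms(self) -> float:
        return self.width * self.block_duration_ms

    @property
    def stop_block(self) -> int:
        return self.start_block + self.width


def block_power(band_limited: np.ndarray,
                block_len: int = DEFAULT_BLOCK_LEN) -> np.ndarray:
    """Mean squared amplitude per non-overlapping block (last axis = time)."""
    band_limited = np.asarray(band_limited, dtype=float)
    n = band_limited.shape[-1]
    if block_len <= 0 or n % block_len:
        raise ValueError(
            f"block_len {block_len} must divide the signal length {n}")
    shaped = band_limited.reshape(*band_limited.shape[:-1],
                                  n // block_len, block_len)
    return np.mean(shaped ** 2, axis=-1)


def band_power_series(samples: np.ndarray, band: "str | BandDefinition",
                      sampling_rate: float,
                      block_len: int = DEFAULT_BLOCK_LEN,
                      power_op: "Callable[[np.ndarray, int], np.ndarray] | None" = None,
                      *, already_band_limited: bool = False,
                      **meta) -> BandPowerSeries:
    """Band-limit an epoch and reduce it to block power.

    ``samples`` is one model-signal vector (e.g. 512 samples for a 2-s
    epoch at 256 Hz).  Bare epochs are reflect-padded by 0.5 s before the
    zero-phase band-pass; pass ``already_band_limited=True`` when the
    epoch was sliced out of a filtered continuous signal.
    """
    band_def = get_band(band)
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1:
        raise ValueError("band_power_series expects a single epoch vector")
    if samples.shape[-1] % block_len:
        raise ValueError(
            f"block_len {block_len} does not divide epoch length "
            f"{samples.shape[-1]}")
    if already_band_limited:
        limited = samples
    else:
        limited = band_limit(samples, band_def, sampling_rate,
                             reflect_pad_s=EPOCH_REFLECT_PAD_S)
    op = power_op or block_power
    return BandPowerSeries(band=band_def, block_len=block_len,
                           sampling_rate=sampling_rate,
                           values=op(limited, block_len), **meta)


def sliding_windows(n_blocks: int, block_duration_ms: float,
                    width: int = DEFAULT_WINDOW_WIDTH,
                    step: int = 1) -> "list[AnalysisWindow]":
    """All sliding windows over an epoch of ``n_blocks`` power blocks.

    Center labels are signed milliseconds relative to the cut, which sits
    at the block boundary ``n_blocks / 2``; the window with equally many
    pre- and post-cut blocks is labelled 0 ms.
    """
    if width > n_blocks:
        raise ValueError(f"window width {width} exceeds {n_blocks} blocks")
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    windows = []
    for start in range(0, n_blocks - width + 1, step):
        center = (start + width / 2.0 - n_blocks / 2.0) * block_duration_ms
        windows.append(AnalysisWindow(start_block=start, width=width,
                                      center_label_ms=center,
                                      block_duration_ms=block_duration_ms))
    return windows


def window_value_matrix(series: BandPowerSeries,
                        windows: "list[AnalysisWindow]") -> np.ndarray:
    """Stack window slices of a series into an (n_windows, width) matrix."""
    return np.stack([series.values[w.start_block:w.stop_block]
                     for w in windows])
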