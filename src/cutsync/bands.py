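"""Frequency-range table and band-limiting filters.

The analysis decomposes every model signal into 15 frequency ranges: the
five classical EEG bands (delta, theta, alpha, beta, gamma) plus the low
and high half of each band.  Band limiting uses a zero-phase 4th-order
Butterworth band-pass (applied forward and backward), so band power is
assigned without phase distortion of the cut-locked waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["BandDefinition", "BAND_TABLE", "BANDS_BY_NAME", "get_band",
           "band_filter_sos", "band_limit", "PARENT_BANDS"]


@dataclass(frozen=True)
class BandDefinition:
    """One analysis frequency range.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"theta"`` or ``"low_theta"``.
    f_low, f_high : float
        Pass-band edges in Hz.
    parent_band : str
        The classical band this range belongs to (a full band is its own
        parent).
    """

    name: str
    f_low: float
    f_high: float
    parent_band: str

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got ({self.f_low}, {self.f_high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    @property
    def is_full_band(self) -> bool:
        return self.name == self.parent_band


PARENT_BANDS = ("delta", "theta", "alpha", "beta", "gamma")

# The 15 ranges: 5 full bands and their low/high halves.
BAND_TABLE: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 3.0, "delta"),
    BandDefinition("theta", 3.0, 7.0, "theta"),
    BandDefinition("alpha", 7.0, 14.0, "alpha"),
    BandDefinition("beta", 14.0, 32.0, "beta"),
    BandDefinition("gamma", 32.0, 42.0, "gamma"),
    BandDefinition("low_delta", 0.5, 1.5, "delta"),
    BandDefinition("high_delta", 1.5, 3.0, "delta"),
    BandDefinition("low_theta", 3.0, 5.0, "theta"),
    BandDefinition("high_theta", 5.0, 7.0, "theta"),
    BandDefinition("low_alpha", 7.0, 10.5, "alpha"),
    BandDefinition("high_alpha", 10.5, 14.0, "alpha"),
    BandDefinition("low_beta", 14.0, 23.0, "beta"),
    BandDefinition("high_beta", 23.0, 32.0, "beta"),
    BandDefinition("low_gamma", 32.0, 37.0, "gamma"),
    BandDefinition("high_gamma", 37.0, 42.0, "gamma"),
)

BANDS_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in BAND_TABLE}


def get_band(band: "str | BandDefinition") -> BandDefinition:
    """Resolve a band given by name or definition; raise for unknown names."""
    if isinstance(band, BandDefinition):
        return band
    try:
        return BANDS_BY_NAME[band]
    except KeyError:
        raise KeyError(
            f"unknown frequency range {band!r}; known: {sorted(BANDS_BY_NAME)}"
        ) from None


def band_filter_sos(band: "str | BandDefinition", rate: float,
                    order: int = 4) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass for ``band``."""
    b = get_band(band)
    nyq = rate / 2.0
    if b.f_high >= nyq:
        raise ValueError(
            f"band {b.name} upper edge {b.f_high} Hz >= Nyquist {nyq} Hz"
        )
    return sps.butter(order, [b.f_low, b.f_high], btype="bandpass",
                      fs=rate, output="sos")


def band_limit(samples: np.ndarray, band: "str | BandDefinition",
               rate: float, *, reflect_pad_s: float = 0.0,
               order: int = 4) -> np.ndarray:
    """Zero-phase band-pass ``samples`` (last axis = time).

    ``reflect_pad_s`` seconds of reflected signal are prepended/appended
    before filtering and cropped afterwards; short epochs need this context
    for the slow delta ranges.
    """
    samples = np.asarray(samples, dtype=float)
    npad = int(round(reflect_pad_s * rate))
    if npad > 0:
        npad = min(npad, samples.shape[-1] - 1)
        pad = [(0, 0)] * (samples.ndim - 1) + [(npad, npad)]
        padded = np.pad(samples, pad, mode="reflect")
    else:
        padded = samples
    sos = band_filter_sos(band, rate, order=order)
    out = sps.sosfiltfilt(sos, padded, axis=-1)
    if npad > 0:
        out = out[..., npad:-npad]
    return out
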