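"""Minimal EDF writer and header inspection.

Writes plain EDF (16-bit, one 1-second data record per signal block),
enough to round-trip multichannel EEG in microvolts.  Reading full files
is delegated to :func:`mne.io.read_raw_edf`; this module only parses the
fixed-layout ASCII header for validation that is cheaper (and stricter)
than a full load.
"""

from __future__ import annotations

import datetime as _dt
import os

import numpy as np

_HDR_FIXED = 256
_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    raw = str(value).encode("ascii")
    if len(raw) > width:
        raw = raw[:width]
    return raw.ljust(width)


def write_edf(path: "str | os.PathLike", data_uv: np.ndarray, rate: float,
              labels: "list[str]", *, patient: str = "X",
              recording_id: str = "cutsync synthetic",
              start: "_dt.datetime | None" = None) -> None:
    """Write ``data_uv`` (channels x samples, microvolts) as EDF.

    The signal is quantized to 16 bits over a symmetric per-channel
    physical range; the trailing partial second, if any, is zero-padded
    to a whole data record.
    """
    data_uv = np.atleast_2d(np.asarray(data_uv, dtype=float))
    n_ch, n_samp = data_uv.shape
    if n_ch != len(labels):
        raise ValueError(f"{n_ch} channels but {len(labels)} labels")
    if rate <= 0 or abs(rate - round(rate)) > 1e-9:
        raise ValueError(f"EDF writer requires a positive integer rate, got {rate}")
    spr = int(round(rate))                       # samples per 1-s record
    n_rec = int(np.ceil(n_samp / spr))
    if n_rec * spr != n_samp:
        data_uv = np.hstack([data_uv, np.zeros((n_ch, n_rec * spr - n_samp))])

    phys_max = np.ceil(np.maximum(np.abs(data_uv).max(axis=1), 1.0) * 10) / 10
    start = start or _dt.datetime(2000, 1, 1)

    hdr = bytearray()
    hdr += _field("0", 8)
    hdr += _field(patient, 80)
    hdr += _field(recording_id, 80)
    hdr += _field(start.strftime("%d.%m.%y"), 8)
    hdr += _field(start.strftime("%H.%M.%S"), 8)
    hdr += _field(_HDR_FIXED * (n_ch + 1), 8)
    hdr += _field("", 44)
    hdr += _field(n_rec, 8)
    hdr += _field("1", 8)
    hdr += _field(n_ch, 4)
    for lab in labels:
        hdr += _field(lab, 16)
    hdr += _field("", 80) * n_ch                 # transducer
    hdr += b"".join(_field("uV", 8) for _ in labels)
    hdr += b"".join(_field("%g" % -p, 8) for p in phys_max)
    hdr += b"".join(_field("%g" % p, 8) for p in phys_max)
    hdr += _field(_DIG_MIN, 8) * n_ch
    hdr += _field(_DIG_MAX, 8) * n_ch
    hdr += _field("", 80) * n_ch                 # prefiltering
    hdr += _field(spr, 8) * n_ch
    hdr += _field("", 32) * n_ch

    scale = (_DIG_MAX - _DIG_MIN) / (2.0 * phys_max)
    digital = np.clip(np.round(data_uv * scale[:, None]),
                      _DIG_MIN, _DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def read_edf_header(path: "str | os.PathLike") -> dict:
    """Parse the EDF header fields needed for validation."""
    with open(path, "rb") as fh:
        fixed = fh.read(_HDR_FIXED)
        if len(fixed) < _HDR_FIXED:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            n_rec = int(fixed[236:244].decode("ascii").strip())
            rec_dur = float(fixed[244:252].decode("ascii").strip())
            n_sig = int(fixed[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed EDF header ({exc})") from exc
        if n_sig <= 0:
            raise ValueError(f"{path}: EDF header declares {n_sig} signals")
        var = fh.read(n_sig * 256)
        if len(var) < n_sig * 256:
            raise ValueError(f"{path}: truncated EDF signal headers")

    def block(offset: int, width: int) -> list[str]:
        base = offset * n_sig
        return [var[base + i * width: base + (i + 1) * width]
                .decode("ascii", "replace").strip() for i in range(n_sig)]

    labels = block(0, 16)
    # layout after labels: transducer(80) dim(8) pmin(8) pmax(8) dmin(8)
    # dmax(8) prefilter(80) spr(8)
    off = 16 * n_sig + 80 * n_sig
    dims = [var[off + i * 8: off + (i + 1) * 8].decode("ascii").strip()
            for i in range(n_sig)]
    off2 = off + 8 * n_sig * 5 + 80 * n_sig
    try:
        spr = [int(var[off2 + i * 8: off2 + (i + 1) * 8].decode("ascii").strip())
               for i in range(n_sig)]
    except ValueError as exc:
        raise ValueError(f"{path}: malformed samples-per-record field") from exc
    return {"n_records": n_rec, "record_duration_s": rec_dur,
            "n_signals": n_sig, "labels": labels, "dims": dims,
            "samples_per_record": spr}
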