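"""External formats: EEG recordings, cut tables, montages, result tables.

Signals travel as EDF (read through :mod:`mne`, written by the bundled
minimal writer) or as a documented plain-text table; cut annotations,
montages and results are CSV/text.  Readers validate and reject invalid
enum or unit values instead of coercing them.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf

logger = logging.getLogger(__name__)

__all__ = [
    "SHOT_SCALES", "CutAnnotation", "Recording", "Montage",
    "DEFAULT_MONTAGE", "UnsupportedFormatError", "MalformedFileError",
    "InconsistentChannelsError",
    "read_recording", "write_recording", "read_cut_table", "write_cut_table",
    "read_montage", "write_montage", "write_results", "read_results",
]

#: Closed shot-scale vocabulary (framing size).
SHOT_SCALES = ("close_up", "medium", "full", "wide")

CUT_TABLE_COLUMNS = ("film_id", "cut_id", "onset_s", "pre_scale",
                     "post_scale", "angle_delta_deg")


class UnsupportedFormatError(ValueError):
    """File extension/format not handled by any reader."""


class MalformedFileError(ValueError):
    """Header or row content that cannot be parsed or validated."""


class InconsistentChannelsError(ValueError):
    """Channels of one recording disagree in length or sampling."""


@dataclass(frozen=True)
class CutAnnotation:
    """One shot change by cut.

    ``onset_s`` is 0-based seconds from the first sample of the film
    excerpt; the cut sample index is ``floor(onset_s * rate)``.
    ``angle_delta_deg`` is the camera-axis variation across the cut.
    """

    film_id: str
    cut_id: str
    onset_s: float
    pre_scale: str
    post_scale: str
    angle_delta_deg: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise MalformedFileError(
                f"cut {self.film_id}/{self.cut_id}: negative onset {self.onset_s}")
        for which, scale in (("pre_scale", self.pre_scale),
                             ("post_scale", self.post_scale)):
            if scale not in SHOT_SCALES:
                raise MalformedFileError(
                    f"cut {self.film_id}/{self.cut_id}: unknown {which} token "
                    f"{scale!r} (expected one of {SHOT_SCALES})")
        if not 0 <= self.angle_delta_deg <= 180:
            raise MalformedFileError(
                f"cut {self.film_id}/{self.cut_id}: angle_delta_deg "
                f"{self.angle_delta_deg} outside [0, 180]")


@dataclass
class Recording:
    """One subject's EEG for one film excerpt (channels x samples, uV)."""

    subject_id: str
    film_id: str
    sampling_rate: float
    electrode_labels: list[str]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if len(self.electrode_labels) != len(set(self.electrode_labels)):
            raise ValueError("electrode labels must be unique")
        if self.samples.shape[0] != len(self.electrode_labels):
            raise InconsistentChannelsError(
                f"{self.samples.shape[0]} channels but "
                f"{len(self.electrode_labels)} labels")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.electrode_labels.index(label)]


@dataclass(frozen=True)
class Montage:
    """Electrode labels with optional 2-D layout positions."""

    labels: tuple[str, ...]
    positions: "dict[str, tuple[float, float]]" = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)


# 31 scalp sites from the 10-20 system with modified combinatorial
# nomenclature.  The exact montage of any given study is configurable;
# this default covers the frontal/central/parietal/occipital sites that
# cut-locked effects are typically reported on.
DEFAULT_MONTAGE = Montage(labels=(
    "Fp1", "Fp2", "AFz", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "P9", "P10", "O1", "Oz", "O2",
))


# ---------------------------------------------------------------------------
# recordings

_PLAIN_TABLE_EXTS = (".csv", ".txt", ".tsv")


def write_recording(recording: Recording, path: "str | os.PathLike") -> None:
    """Write a recording as EDF (``.edf``) or plain table (``.csv``/``.txt``).

    The plain-table fallback is a CSV whose first line is a ``#``
    metadata comment (``subject_id``, ``film_id``, ``sampling_rate_hz``)
    followed by one column per electrode, one row per sample, microvolts.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".edf":
        _edf.write_edf(path, recording.samples, recording.sampling_rate,
                       list(recording.electrode_labels),
                       recording_id=f"{recording.subject_id} {recording.film_id}")
    elif ext in _PLAIN_TABLE_EXTS:
        sep = "\t" if ext == ".tsv" else ","
        with open(path, "w") as fh:
            fh.write(f"# subject_id={recording.subject_id} "
                     f"film_id={recording.film_id} "
                     f"sampling_rate_hz={recording.sampling_rate:g}\n")
            pd.DataFrame(recording.samples.T,
                         columns=list(recording.electrode_labels)).to_csv(
                fh, sep=sep, index=False, float_format="%.6f")
    else:
        raise UnsupportedFormatError(
            f"cannot write recording to {ext!r} (use .edf or .csv/.txt/.tsv)")


def _read_recording_edf(path: Path) -> Recording:
    hdr = _edf.read_edf_header(path)      # strict validation before mne
    spr = hdr["samples_per_record"]
    if len(set(spr)) != 1:
        raise InconsistentChannelsError(
            f"{path}: channels have differing samples per record {spr}; "
            "all channels must share one length/rate")
    import mne
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6        # mne loads EEG in volts
    rate = float(raw.info["sfreq"])
    subject_id, _, film_id = path.stem.partition("__")
    return Recording(subject_id=subject_id or path.stem,
                     film_id=film_id or "unknown",
                     sampling_rate=rate,
                     electrode_labels=list(raw.ch_names),
                     samples=data_uv)


def _read_recording_table(path: Path) -> Recording:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise MalformedFileError(
            f"{path}: plain-table recording must start with a '# key=value' "
            "metadata line")
    meta = {}
    for token in first.lstrip("#").split():
        if "=" in token:
            k, _, v = token.partition("=")
            meta[k] = v
    try:
        rate = float(meta["sampling_rate_hz"])
    except (KeyError, ValueError):
        raise MalformedFileError(
            f"{path}: missing/invalid sampling_rate_hz in metadata line") from None
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, comment="#", sep=sep)
    return Recording(subject_id=meta.get("subject_id", path.stem),
                     film_id=meta.get("film_id", "unknown"),
                     sampling_rate=rate,
                     electrode_labels=list(df.columns),
                     samples=df.to_numpy().T)


def read_recording(path: "str | os.PathLike") -> Recording:
    """Read an EDF or plain-table recording; values in microvolts."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext == ".edf":
        return _read_recording_edf(path)
    if ext in _PLAIN_TABLE_EXTS:
        return _read_recording_table(path)
    raise UnsupportedFormatError(
        f"{path}: unknown recording extension {ext!r} "
        "(use .edf or .csv/.txt/.tsv)")


def recording_filename(subject_id: str, film_id: str, ext: str = ".edf") -> str:
    """Canonical per subject-x-film file name (``<subject>__<film>.edf``)."""
    return f"{subject_id}__{film_id}{ext}"


# ---------------------------------------------------------------------------
# cut tables

def write_cut_table(annotations, path: "str | os.PathLike") -> None:
    rows = [dataclasses.asdict(a) for a in annotations]
    df = pd.DataFrame(rows, columns=list(CUT_TABLE_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6g")


def read_cut_table(path: "str | os.PathLike") -> "list[CutAnnotation]":
    """Read and validate a cut-annotation CSV; rows sorted by onset."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"film_id": str, "cut_id": str})
    missing = [c for c in CUT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedFileError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("%s: cut table has a header but no rows", path)
        return []
    annotations = []
    for i, row in df.iterrows():
        try:
            annotations.append(CutAnnotation(
                film_id=str(row["film_id"]), cut_id=str(row["cut_id"]),
                onset_s=float(row["onset_s"]),
                pre_scale=str(row["pre_scale"]),
                post_scale=str(row["post_scale"]),
                angle_delta_deg=float(row["angle_delta_deg"])))
        except MalformedFileError as exc:
            raise MalformedFileError(f"{path} row {i}: {exc}") from None
    keys = [(a.film_id, a.cut_id) for a in annotations]
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise MalformedFileError(f"{path}: duplicate (film_id, cut_id) {dupes}")
    return sorted(annotations, key=lambda a: a.onset_s)


# ---------------------------------------------------------------------------
# montages

def write_montage(montage: Montage, path: "str | os.PathLike") -> None:
    with open(path, "w") as fh:
        for lab in montage.labels:
            pos = montage.positions.get(lab)
            if pos is None:
                fh.write(f"{lab}\n")
            else:
                fh.write(f"{lab},{pos[0]:g},{pos[1]:g}\n")


def read_montage(path: "str | os.PathLike") -> Montage:
    labels, positions = [], {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.replace("\t", ",").split(",")]
            labels.append(parts[0])
            if len(parts) == 3:
                try:
                    positions[parts[0]] = (float(parts[1]), float(parts[2]))
                except ValueError:
                    raise MalformedFileError(
                        f"{path} line {ln}: bad position {parts[1:]!r}") from None
            elif len(parts) != 1:
                raise MalformedFileError(
                    f"{path} line {ln}: expected 'label' or 'label,x,y'")
    return Montage(labels=tuple(labels), positions=positions)


# ---------------------------------------------------------------------------
# result tables

def write_results(results, path: "str | os.PathLike",
                  columns: "list[str] | None" = None) -> None:
    """Write result records (dicts/dataclasses/DataFrame) as CSV.

    Column order is stable (taken from ``columns`` or the first record);
    floats keep at least 6 significant digits.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
                for r in results]
        if rows:
            cols = columns or list(rows[0].keys())
        else:
            cols = columns or []
        df = pd.DataFrame(rows, columns=cols)
    try:
        df.to_csv(path, index=False, float_format="%.8g")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: "str | os.PathLike") -> pd.DataFrame:
    return pd.read_csv(path)
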