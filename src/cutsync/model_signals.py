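"""Grand averaging, cut-centered epochs, and ASF/ASC model signals.

The analysis averages the recordings of all subjects for one film
excerpt sample-by-sample (the stimulus is time-locked for everyone),
slices a 2-s epoch around every cut (1 s pre + 1 s post, cut at the
central instant), and averages epochs into model signals:

* **ASF** (average signal per film): mean over *all* cuts of one film,
  one per electrode and film.
* **ASC** (average signal per cut type): mean over the cuts of one film
  sharing one taxonomy category, up to one per (electrode, film, taxon).

Because every step is a sample-wise mean, averaging subjects first and
epochs second equals epoching per subject and averaging across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import CutAnnotation, Recording

logger = logging.getLogger(__name__)

__all__ = ["Epoch", "ModelSignal", "grand_average", "cut_sample_index",
           "extract_epochs", "epoch_matrix", "build_asf", "build_asc"]


@dataclass
class Epoch:
    """One cut-centered 2-s slice for one electrode.

    ``cut_index`` is the index of the first post-cut sample within
    ``samples`` and always equals the sampling rate (1 s of pre-cut
    signal precedes it).
    """

    film_id: str
    cut_id: str
    electrode: str
    samples: np.ndarray
    cut_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("epoch samples must be a vector")
        if len(self.samples) != 2 * self.cut_index:
            raise ValueError(
                f"epoch length {len(self.samples)} != 2 x cut_index "
                f"{self.cut_index}")


@dataclass
class ModelSignal:
    """ASF or ASC: an averaged cut-centered signal for one electrode."""

    kind: str                   # "ASF" | "ASC"
    film_id: str
    electrode: str
    n_cuts_averaged: int
    samples: np.ndarray
    sampling_rate: float
    taxon: str | None = None
    taxonomy: str | None = None  # "G1" | "G2" | "scale" for ASCs

    def __post_init__(self) -> None:
        if self.kind not in ("ASF", "ASC"):
            raise ValueError(f"kind must be ASF or ASC, got {self.kind!r}")
        if self.kind == "ASF" and self.taxon is not None:
            raise ValueError("ASF model signals carry no taxon")
        if self.kind == "ASC" and self.taxon is None:
            raise ValueError("ASC model signals require a taxon")
        if self.n_cuts_averaged < 1:
            raise ValueError("n_cuts_averaged must be >= 1")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def cut_index(self) -> int:
        return len(self.samples) // 2


def grand_average(recordings: "list[Recording]",
                  *, truncate: bool = True) -> Recording:
    """Sample-wise mean across subjects for one film.

    All recordings must share the film, rate and electrode set (in
    order).  Lengths may differ by recording jitter; with ``truncate``
    they are cut to the shortest.
    """
    if len(recordings) < 2:
        raise ValueError("grand average needs at least 2 recordings")
    first = recordings[0]
    for rec in recordings[1:]:
        if rec.film_id != first.film_id:
            raise ValueError(
                f"mixed films in grand average: {rec.film_id} vs {first.film_id}")
        if rec.sampling_rate != first.sampling_rate:
            raise ValueError(
                f"mixed sampling rates: {rec.sampling_rate} vs "
                f"{first.sampling_rate}")
        if list(rec.electrode_labels) != list(first.electrode_labels):
            extra = set(rec.electrode_labels) ^ set(first.electrode_labels)
            raise ValueError(
                f"electrode sets differ between subjects "
                f"{rec.subject_id} and {first.subject_id}: "
                f"symmetric difference {sorted(extra) or 'same set, different order'}")
    lengths = {rec.n_samples for rec in recordings}
    if len(lengths) > 1:
        if not truncate:
            raise ValueError(f"recording lengths differ: {sorted(lengths)}")
        n = min(lengths)
        logger.info("truncating %d recordings to %d samples", len(recordings), n)
    else:
        n = lengths.pop()
    mean = np.mean([rec.samples[:, :n] for rec in recordings], axis=0)
    return Recording(subject_id="grand_average", film_id=first.film_id,
                     sampling_rate=first.sampling_rate,
                     electrode_labels=list(first.electrode_labels),
                     samples=mean)


def cut_sample_index(onset_s: float, rate: float) -> int:
    """Sample index of a cut: floor of onset time times rate."""
    return int(np.floor(onset_s * rate))


def _epoch_bounds(cut: CutAnnotation, rate: float, n_samples: int):
    half = int(round(rate))
    center = cut_sample_index(cut.onset_s, rate)
    start, stop = center - half, center + half
    if start < 0 or stop > n_samples:
        return None
    return start, stop


def extract_epochs(signal: Recording,
                   cut_table: "list[CutAnnotation]") -> "list[Epoch]":
    """One Epoch per cut per electrode from an (averaged) recording.

    Cuts with less than 1 s of signal on either side are skipped with a
    warning.  Epochs of nearby cuts may overlap in source time.
    """
    rate = signal.sampling_rate
    half = int(round(rate))
    epochs: list[Epoch] = []
    for cut in cut_table:
        bounds = _epoch_bounds(cut, rate, signal.n_samples)
        if bounds is None:
            logger.warning(
                "cut %s/%s at %.3f s too close to the excerpt edge; skipped",
                cut.film_id, cut.cut_id, cut.onset_s)
            continue
        start, stop = bounds
        for ch, label in enumerate(signal.electrode_labels):
            epochs.append(Epoch(film_id=cut.film_id, cut_id=cut.cut_id,
                                electrode=label,
                                samples=signal.samples[ch, start:stop],
                                cut_index=half))
    return epochs


def epoch_matrix(signal_samples: np.ndarray, rate: float,
                 cut_table: "list[CutAnnotation]"):
    """Vectorized epoch slicing: (n_kept_cuts, n_channels, 2*rate) array.

    Returns ``(matrix, kept_cut_ids, skipped_cut_ids)``; used by the
    pipeline where per-object Epoch instances would be wasteful.
    """
    signal_samples = np.atleast_2d(signal_samples)
    n = signal_samples.shape[1]
    slices, kept, skipped = [], [], []
    for cut in cut_table:
        bounds = _epoch_bounds(cut, rate, n)
        if bounds is None:
            skipped.append(cut.cut_id)
            continue
        slices.append(signal_samples[:, bounds[0]:bounds[1]])
        kept.append(cut.cut_id)
    matrix = (np.stack(slices) if slices
              else np.empty((0, signal_samples.shape[0], 2 * int(round(rate)))))
    return matrix, kept, skipped


def build_asf(epochs: "list[Epoch]", *, sampling_rate: float) -> ModelSignal:
    """Average all epochs of one (film, electrode) into the ASF."""
    if not epochs:
        raise ValueError("cannot build an ASF from zero epochs")
    _check_same_source(epochs)
    mean = np.mean([e.samples for e in epochs], axis=0)
    e0 = epochs[0]
    return ModelSignal(kind="ASF", film_id=e0.film_id, electrode=e0.electrode,
                       n_cuts_averaged=len(epochs), samples=mean,
                       sampling_rate=sampling_rate)


def build_asc(epochs: "list[Epoch]",
              taxon_assignment: "dict[str, frozenset | set | str]",
              taxon: str, *, sampling_rate: float,
              taxonomy: str | None = None) -> "ModelSignal | None":
    """Average the epochs whose cut carries ``taxon`` into an ASC.

    ``taxon_assignment`` maps cut_id to its label (G1) or label set (G2).
    Returns None (logged) when no cut of this film carries the taxon.
    """
    def matches(cut_id: str) -> bool:
        labels = taxon_assignment.get(cut_id)
        if labels is None:
            return False
        if isinstance(labels, str):
            return labels == taxon
        return taxon in labels

    selected = [e for e in epochs if matches(e.cut_id)]
    if not selected:
        e0 = epochs[0] if epochs else None
        logger.info("no cuts of taxon %r in film %s; no ASC built",
                    taxon, e0.film_id if e0 else "?")
        return None
    _check_same_source(selected)
    mean = np.mean([e.samples for e in selected], axis=0)
    e0 = selected[0]
    return ModelSignal(kind="ASC", film_id=e0.film_id, electrode=e0.electrode,
                       n_cuts_averaged=len(selected), samples=mean,
                       sampling_rate=sampling_rate, taxon=taxon,
                       taxonomy=taxonomy)


def _check_same_source(epochs: "list[Epoch]") -> None:
    films = {e.film_id for e in epochs}
    electrodes = {e.electrode for e in epochs}
    if len(films) > 1 or len(electrodes) > 1:
        raise ValueError(
            f"epochs mix films {sorted(films)} / electrodes "
            f"{sorted(electrodes)}; average one (film, electrode) at a time")
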