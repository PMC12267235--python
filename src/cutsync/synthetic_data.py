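"""Synthetic multi-subject film-viewing EEG with known cut-locked responses.

Stands in for a real study: 21 subjects x 4 film excerpts x 31
electrodes at 256 Hz by default, each recording a 1/f background with
optional cut-locked band-power modulations whose ground truth (band,
latency, direction, electrodes, taxon condition) is fully known, so the
whole analysis pipeline can be verified end to end.

Background noise is synthesized in the frequency domain (Gaussian
spectral coefficients with amplitude proportional to f^(-exponent/2),
random phases) and inverse-transformed, giving exact control of the
spectral slope.

Injected responses come in two mechanisms, chosen by direction:

* **ERS** (power increase): a cut-locked, *phase-locked* band-limited
  sinusoidal burst (cosine-tapered, 10% taper) added on the listed
  electrodes.  Phase locking matters: the analysis grand-averages
  subjects in the time domain, so only phase-locked energy survives
  averaging — exactly the component event-locked averaging is built to
  recover.
* **ERD** (power decrease): multiplicative suppression of the subject's
  own band component inside the response window, implemented as an
  additive, tapered, band-filtered correction term (so the injection is
  still testable by subtracting a no-response run).

Per-subject response amplitudes are jittered from a stream keyed by
(seed, subject) so adding subjects never changes existing subjects'
data; everything is bit-reproducible from (spec, seeds).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .bands import get_band, band_limit
from .io_formats import (DEFAULT_MONTAGE, CutAnnotation, Montage, Recording,
                         SHOT_SCALES, recording_filename, write_cut_table,
                         write_recording)
from . import taxonomy as _taxonomy

logger = logging.getLogger(__name__)

__all__ = ["NoiseModel", "ResponseTemplate", "FilmSpec", "SyntheticStudySpec",
           "generate_cut_table", "generate_recording", "generate_study",
           "default_study_spec", "reference_response_templates",
           "load_study_config", "study_spec_from_dict",
           "THETA_RESPONSE_ELECTRODES", "DELTA_RESPONSE_ELECTRODES"]

#: Fraction of the response window covered by the two cosine edge tapers.
EDGE_TAPER_FRACTION = 0.10

#: Minimum spacing between consecutive synthetic cuts, in seconds.  Real
#: excerpts reach ~27 cuts/min, so epochs overlap freely; only sub-shot
#: spacings are excluded.
MIN_CUT_GAP_S = 0.5

_EDGE_MARGIN_S = 1.0   # cuts need 1 s of signal on both sides


@dataclass(frozen=True)
class NoiseModel:
    """1/f background: power ~ 1/f^spectral_exponent, RMS amplitude in uV."""

    spectral_exponent: float = 1.0
    amplitude_scale: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spectral_exponent < 0:
            raise ValueError("spectral_exponent must be >= 0")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be > 0")


@dataclass(frozen=True)
class ResponseTemplate:
    """One injected cut-locked band-power modulation (the ground truth).

    ``relative_power_change`` is the fractional band-power change inside
    [onset_ms, offset_ms] relative to the background band power:
    positive for ERS (e.g. 1.0 doubles band power), negative for ERD
    (e.g. -0.8 suppresses 80%).  With ``taxon_condition`` set, only cuts
    carrying that taxonomy label (G1, G2 or scale-variation group)
    receive the response.
    """

    band: str
    onset_ms: float
    offset_ms: float
    direction: str                       # "ERS" | "ERD"
    relative_power_change: float
    electrodes: tuple[str, ...]
    taxon_condition: str | None = None

    def __post_init__(self) -> None:
        if not self.onset_ms < self.offset_ms:
            raise ValueError("onset_ms must be < offset_ms")
        if not (-1000 <= self.onset_ms and self.offset_ms <= 1000):
            raise ValueError("response window must lie within [-1000, 1000] ms")
        if self.direction not in ("ERS", "ERD"):
            raise ValueError("direction must be 'ERS' or 'ERD'")
        if self.relative_power_change <= -1:
            raise ValueError("relative_power_change must be > -1")
        if self.direction == "ERS" and self.relative_power_change < 0:
            raise ValueError("an ERS template needs a positive power change")
        if self.direction == "ERD" and self.relative_power_change > 0:
            raise ValueError("an ERD template needs a negative power change")
        get_band(self.band)


@dataclass(frozen=True)
class FilmSpec:
    film_id: str
    duration_s: float
    cuts: tuple[CutAnnotation, ...]


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Complete description of one synthetic study."""

    films: tuple[FilmSpec, ...]
    n_subjects: int = 21
    sampling_rate: float = 256.0
    electrodes: Montage = DEFAULT_MONTAGE
    noise: NoiseModel = field(default_factory=NoiseModel)
    responses: tuple[ResponseTemplate, ...] = ()
    subject_variability: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        for film in self.films:
            for cut in film.cuts:
                if not (_EDGE_MARGIN_S < cut.onset_s
                        < film.duration_s - _EDGE_MARGIN_S):
                    raise ValueError(
                        f"cut {film.film_id}/{cut.cut_id} at {cut.onset_s} s "
                        f"violates the 1-s edge margins of a "
                        f"{film.duration_s}-s film")
        known = set(self.electrodes.labels)
        for resp in self.responses:
            unknown = set(resp.electrodes) - known
            if unknown:
                raise ValueError(
                    f"response template names electrodes {sorted(unknown)} "
                    "absent from the montage")

    @property
    def film_ids(self) -> tuple[str, ...]:
        return tuple(f.film_id for f in self.films)

    def film(self, film_id: str) -> FilmSpec:
        for f in self.films:
            if f.film_id == film_id:
                return f
        raise KeyError(f"unknown film {film_id!r}")

    def subject_ids(self) -> tuple[str, ...]:
        return tuple(f"sub{i:02d}" for i in range(self.n_subjects))


# ---------------------------------------------------------------------------
# cut tables

def generate_cut_table(film_id: str, duration_s: float, n_cuts: int,
                       taxon_mix: "dict | None" = None,
                       seed: int = 0) -> "list[CutAnnotation]":
    """Random cut annotations with strictly increasing onsets.

    Onsets are uniform over (1 s, duration - 1 s) subject to a minimum
    spacing of 0.5 s; epochs of neighbouring cuts may overlap, matching
    the density of fast-edited excerpts.  ``taxon_mix`` may provide
    ``scale_pairs`` ({(pre, post): probability}) and ``p_ge30`` (the
    probability of an angle variation >= 30 degrees); the default is
    uniform over scale pairs with p_ge30 = 0.5.
    """
    if n_cuts < 1:
        raise ValueError("n_cuts must be >= 1")
    usable = duration_s - 2 * _EDGE_MARGIN_S
    if usable <= 0 or (n_cuts - 1) * MIN_CUT_GAP_S >= usable:
        raise ValueError(
            f"cannot place {n_cuts} cuts with 1-s margins and "
            f"{MIN_CUT_GAP_S}-s spacing in a {duration_s}-s film")
    rng = np.random.default_rng([seed, 0x0C07])
    # sample gaps, then rescale the slack uniformly: sorted, min-gap spaced
    slack = usable - (n_cuts - 1) * MIN_CUT_GAP_S
    points = np.sort(rng.uniform(0, slack, size=n_cuts))
    onsets = _EDGE_MARGIN_S + points + MIN_CUT_GAP_S * np.arange(n_cuts)

    if taxon_mix is None:
        taxon_mix = {}
    pairs = taxon_mix.get("scale_pairs")
    if pairs:
        keys = list(pairs)
        probs = np.array([pairs[k] for k in keys], dtype=float)
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("scale_pairs probabilities must sum to 1")
        for pre, post in keys:
            if pre not in SHOT_SCALES or post not in SHOT_SCALES:
                raise ValueError(f"unknown scales in pair {(pre, post)}")
    else:
        keys = [(a, b) for a in SHOT_SCALES for b in SHOT_SCALES]
        probs = np.full(len(keys), 1.0 / len(keys))
    p_ge30 = float(taxon_mix.get("p_ge30", 0.5))

    cuts = []
    for i, onset in enumerate(onsets):
        pre, post = keys[rng.choice(len(keys), p=probs)]
        if rng.random() < p_ge30:
            angle = float(rng.uniform(30.0, 180.0))
        else:
            angle = float(rng.uniform(0.0, 30.0))
        cuts.append(CutAnnotation(film_id=film_id, cut_id=f"cut{i:03d}",
                                  onset_s=float(onset), pre_scale=pre,
                                  post_scale=post, angle_delta_deg=angle))
    return cuts


# ---------------------------------------------------------------------------
# recordings

def _one_over_f_noise(rng: np.random.Generator, n_channels: int,
                      n_samples: int, rate: float,
                      noise: NoiseModel) -> np.ndarray:
    """Gaussian noise with power ~ 1/f^exponent, exact per-channel RMS."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-noise.spectral_exponent / 2.0)
    coef = (rng.standard_normal((n_channels, len(freqs)))
            + 1j * rng.standard_normal((n_channels, len(freqs)))) * amp
    coef[:, 0] = 0.0
    x = np.fft.irfft(coef, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x * (noise.amplitude_scale / rms)


def _cut_labels(cut: CutAnnotation) -> set:
    labels = set(_taxonomy.classify_g2(cut))
    g1 = _taxonomy.classify_g1(cut)
    if g1 is not None:
        labels.add(g1)
    labels.add(_taxonomy.scale_variation_group(cut))
    return labels


def _response_window(template: ResponseTemplate, cut_sample: int,
                     rate: float, n_samples: int):
    a = cut_sample + int(round(template.onset_ms / 1000.0 * rate))
    b = cut_sample + int(round(template.offset_ms / 1000.0 * rate))
    a, b = max(a, 0), min(b, n_samples)
    return (a, b) if b - a > 4 else None


def _taper(length: int) -> np.ndarray:
    """Unit plateau with 10% raised-cosine edges on both sides."""
    ramp = max(1, int(round(EDGE_TAPER_FRACTION * length)))
    win = np.ones(length)
    edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    win[:ramp] = edge
    win[-ramp:] = edge[::-1]
    return win


def generate_recording(spec: SyntheticStudySpec, subject_id: str,
                       film_id: str) -> Recording:
    """One subject's recording for one film, bit-reproducible from seeds."""
    subjects = spec.subject_ids()
    if subject_id not in subjects:
        raise KeyError(f"unknown subject {subject_id!r}")
    s_idx = subjects.index(subject_id)
    film_ids = spec.film_ids
    if film_id not in film_ids:
        raise KeyError(f"unknown film {film_id!r}")
    f_idx = film_ids.index(film_id)
    film = spec.film(film_id)

    rate = spec.sampling_rate
    n_samples = int(round(film.duration_s * rate))
    n_ch = len(spec.electrodes)
    noise_rng = np.random.default_rng(
        [spec.noise.seed, spec.seed, 0x5109A1, s_idx, f_idx])
    x = _one_over_f_noise(noise_rng, n_ch, n_samples, rate, spec.noise)

    if spec.responses:
        # one jitter draw per (subject, template), independent of films
        jitter_rng = np.random.default_rng([spec.seed, 0x71773E, s_idx])
        jitters = 1.0 + spec.subject_variability * jitter_rng.standard_normal(
            len(spec.responses))
        jitters = np.clip(jitters, 0.1, None)
        label_cache = {cut.cut_id: _cut_labels(cut) for cut in film.cuts}
        ch_index = {lab: i for i, lab in enumerate(spec.electrodes.labels)}
        for t_idx, template in enumerate(spec.responses):
            chans = [ch_index[lab] for lab in template.electrodes]
            if not chans:
                continue
            cuts = [c for c in film.cuts
                    if template.taxon_condition is None
                    or template.taxon_condition in label_cache[c.cut_id]]
            if not cuts:
                continue
            eff = template.relative_power_change * jitters[t_idx]
            eff = float(np.clip(eff, -0.99, None))
            band = get_band(template.band)
            band_comp = band_limit(x[chans], band, rate)
            sigma2 = np.mean(band_comp ** 2, axis=1)      # background band power
            for cut in cuts:
                cut_sample = int(np.floor(cut.onset_s * rate))
                win = _response_window(template, cut_sample, rate, n_samples)
                if win is None:
                    continue
                a, b = win
                taper = _taper(b - a)
                if template.direction == "ERS":
                    tau = (np.arange(a, b) - cut_sample) / rate
                    carrier = np.sin(2 * np.pi * band.center * tau)
                    amp = np.sqrt(2.0 * max(eff, 0.0) * sigma2)
                    x[chans, a:b] += amp[:, None] * (taper * carrier)[None, :]
                else:
                    gain = (math.sqrt(1.0 + eff) - 1.0) * taper
                    x[chans, a:b] += gain[None, :] * band_comp[:, a:b]

    return Recording(subject_id=subject_id, film_id=film_id,
                     sampling_rate=rate,
                     electrode_labels=list(spec.electrodes.labels),
                     samples=x)


def generate_study(spec: SyntheticStudySpec,
                   out_dir: "str | Path | None" = None,
                   *, file_format: str = ".edf"):
    """Yield (or write) every subject x film recording plus cut tables.

    With ``out_dir`` set, recordings are written one file per subject x
    film and cut tables one CSV per film; returns the output directory.
    Without it, returns an iterator of Recordings (memory-light).
    """
    if out_dir is None:
        return (generate_recording(spec, s, f)
                for f in spec.film_ids for s in spec.subject_ids())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for film in spec.films:
        write_cut_table(film.cuts, out / f"cuts_{film.film_id}.csv")
        for subject in spec.subject_ids():
            rec = generate_recording(spec, subject, film.film_id)
            write_recording(rec, out / recording_filename(
                subject, film.film_id, file_format))
    return out


# ---------------------------------------------------------------------------
# default study conditions and config files

#: Editing rhythm of the four study excerpts, cuts per minute.
DEFAULT_CUT_RATES = {"filmA": 27.24, "filmB": 4.79,
                     "filmC": 21.89, "filmD": 14.45}

#: Parietal/centro-parietal sites carrying the canonical theta response.
THETA_RESPONSE_ELECTRODES = ("Pz", "P3", "P4", "CP1", "CP2", "P7")
#: Frontal/frontocentral midline sites carrying the canonical delta response.
DELTA_RESPONSE_ELECTRODES = ("Fz", "AFz", "FC1", "FC2", "Cz")


def reference_response_templates(
        theta_electrodes: tuple = THETA_RESPONSE_ELECTRODES,
        delta_electrodes: tuple = DELTA_RESPONSE_ELECTRODES,
        *, ers_change: float = 1.0, erd_change: float = -0.9,
        evoked_delta_change: float = 2.0) -> tuple[ResponseTemplate, ...]:
    """The canonical cut-locked response pattern used as recovery ground
    truth: theta synchronization 0-200 ms, theta desynchronization
    200-500 ms, delta desynchronization 500-700 ms, and theta
    synchronization 650-1000 ms.

    A sustained cut-locked evoked delta wave spans the whole epoch on the
    delta electrodes: a desynchronization can only be *observed* by an
    analysis that time-domain-averages subjects if there is phase-locked
    band energy to suppress, so the delta ERD is modelled as suppression
    of that evoked component (plus the 1/f background).
    """
    return (
        ResponseTemplate("delta", -1000.0, 1000.0, "ERS",
                         evoked_delta_change, tuple(delta_electrodes)),
        ResponseTemplate("theta", 0.0, 200.0, "ERS", ers_change,
                         tuple(theta_electrodes)),
        ResponseTemplate("theta", 200.0, 500.0, "ERD", erd_change,
                         tuple(theta_electrodes)),
        ResponseTemplate("delta", 500.0, 700.0, "ERD", erd_change,
                         tuple(delta_electrodes)),
        ResponseTemplate("theta", 650.0, 1000.0, "ERS", ers_change,
                         tuple(theta_electrodes)),
    )


def default_study_spec(seed: int = 0, *, n_subjects: int = 21,
                       film_duration_s: float = 60.0,
                       responses: tuple[ResponseTemplate, ...] = (),
                       noise: "NoiseModel | None" = None,
                       subject_variability: float = 0.1,
                       electrodes: Montage = DEFAULT_MONTAGE
                       ) -> SyntheticStudySpec:
    """The default synthetic study: 21 subjects, 4 films whose editing
    rhythms mirror the study excerpts (27.24/4.79/21.89/14.45 cuts per
    minute), 31 electrodes at 256 Hz."""
    films = []
    for f_idx, (film_id, rate_cpm) in enumerate(sorted(DEFAULT_CUT_RATES.items())):
        n_cuts = max(1, int(round(rate_cpm * film_duration_s / 60.0)))
        cuts = generate_cut_table(film_id, film_duration_s, n_cuts,
                                  seed=seed * 1000 + f_idx)
        films.append(FilmSpec(film_id=film_id, duration_s=film_duration_s,
                              cuts=tuple(cuts)))
    return SyntheticStudySpec(
        films=tuple(films), n_subjects=n_subjects,
        noise=noise or NoiseModel(seed=seed),
        responses=tuple(responses),
        subject_variability=subject_variability,
        electrodes=electrodes, seed=seed)


def study_spec_from_dict(cfg: dict) -> SyntheticStudySpec:
    """Build a study spec from a plain mapping (the YAML config layout)."""
    seed = int(cfg.get("seed", 0))
    noise_cfg = cfg.get("noise", {})
    noise = NoiseModel(
        spectral_exponent=float(noise_cfg.get("spectral_exponent", 1.0)),
        amplitude_scale=float(noise_cfg.get("amplitude_scale", 20.0)),
        seed=int(noise_cfg.get("seed", seed)))
    responses = tuple(
        ResponseTemplate(
            band=r["band"], onset_ms=float(r["onset_ms"]),
            offset_ms=float(r["offset_ms"]), direction=r["direction"],
            relative_power_change=float(r["relative_power_change"]),
            electrodes=tuple(r["electrodes"]),
            taxon_condition=r.get("taxon_condition"))
        for r in cfg.get("responses", []))
    electrodes = (Montage(labels=tuple(cfg["electrodes"]))
                  if "electrodes" in cfg else DEFAULT_MONTAGE)
    if "films" in cfg:
        films = []
        for f_idx, f in enumerate(cfg["films"]):
            film_id = f["film_id"]
            duration = float(f["duration_s"])
            if "cuts" in f:
                cuts = tuple(CutAnnotation(
                    film_id=film_id, cut_id=str(c["cut_id"]),
                    onset_s=float(c["onset_s"]), pre_scale=c["pre_scale"],
                    post_scale=c["post_scale"],
                    angle_delta_deg=float(c["angle_delta_deg"]))
                    for c in f["cuts"])
            else:
                cuts = tuple(generate_cut_table(
                    film_id, duration, int(f["n_cuts"]),
                    f.get("taxon_mix"), seed=seed * 1000 + f_idx))
            films.append(FilmSpec(film_id=film_id, duration_s=duration,
                                  cuts=cuts))
        return SyntheticStudySpec(
            films=tuple(films),
            n_subjects=int(cfg.get("n_subjects", 21)),
            sampling_rate=float(cfg.get("sampling_rate", 256.0)),
            electrodes=electrodes, noise=noise, responses=responses,
            subject_variability=float(cfg.get("subject_variability", 0.1)),
            seed=seed)
    base = default_study_spec(
        seed=seed, n_subjects=int(cfg.get("n_subjects", 21)),
        film_duration_s=float(cfg.get("film_duration_s", 60.0)),
        responses=responses, noise=noise,
        subject_variability=float(cfg.get("subject_variability", 0.1)),
        electrodes=electrodes)
    return replace(base, sampling_rate=float(cfg.get("sampling_rate", 256.0)))


def load_study_config(path: "str | Path") -> SyntheticStudySpec:
    """Read a YAML study config (see docs/methods.md for the layout)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return study_spec_from_dict(cfg)
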