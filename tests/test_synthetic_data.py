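"""Synthetic study generator: determinism, spectra, injection locality."""

import numpy as np
import pytest
from scipy import signal as sps

from cutsync.bands import band_limit
from cutsync.io_formats import DEFAULT_MONTAGE, Montage
from cutsync.synthetic_data import (FilmSpec, NoiseModel, ResponseTemplate,
                                    SyntheticStudySpec, default_study_spec,
                                    generate_cut_table, generate_recording,
                                    load_study_config, study_spec_from_dict)

RATE = 256.0
SMALL_MONTAGE = Montage(labels=("Cz", "Pz", "Oz", "F3"))


def _spec(responses=(), seed=11, duration=30.0, n_subjects=3,
          variability=0.1):
    films = tuple(
        FilmSpec(film_id=f, duration_s=duration,
                 cuts=tuple(generate_cut_table(f, duration, 6,
                                               seed=seed + i)))
        for i, f in enumerate(("filmA", "filmB")))
    return SyntheticStudySpec(films=films, n_subjects=n_subjects,
                              electrodes=SMALL_MONTAGE,
                              noise=NoiseModel(seed=seed),
                              responses=tuple(responses),
                              subject_variability=variability, seed=seed)


# --- cut tables -------------------------------------------------------------

def test_single_cut_respects_margins():
    (cut,) = generate_cut_table("filmA", 60.0, 1, seed=7)
    assert 1.0 < cut.onset_s < 59.0


def test_dense_cut_table_sorted_and_reproducible():
    cuts = generate_cut_table("filmA", 60.0, 27, seed=1)
    again = generate_cut_table("filmA", 60.0, 27, seed=1)
    assert len(cuts) == 27
    onsets = [c.onset_s for c in cuts]
    assert onsets == sorted(onsets)
    assert all(b > a for a, b in zip(onsets, onsets[1:]))
    assert cuts == again
    assert generate_cut_table("filmA", 60.0, 27, seed=2) != cuts


def test_too_short_film_errors():
    with pytest.raises(ValueError, match="cannot place"):
        generate_cut_table("filmA", 2.5, 5, seed=0)


def test_taxon_mix_probabilities():
    mix = {"scale_pairs": {("close_up", "close_up"): 1.0}, "p_ge30": 1.0}
    cuts = generate_cut_table("filmA", 120.0, 40, taxon_mix=mix, seed=3)
    assert all(c.pre_scale == c.post_scale == "close_up" for c in cuts)
    assert all(c.angle_delta_deg >= 30.0 for c in cuts)
    with pytest.raises(ValueError, match="sum to 1"):
        generate_cut_table("filmA", 60.0, 5,
                           taxon_mix={"scale_pairs":
                                      {("close_up", "medium"): 0.4}})


# --- recordings -------------------------------------------------------------

def test_recording_determinism_and_unknown_ids():
    spec = _spec()
    a = generate_recording(spec, "sub00", "filmA")
    b = generate_recording(spec, "sub00", "filmA")
    assert np.array_equal(a.samples, b.samples)
    with pytest.raises(KeyError):
        generate_recording(spec, "sub99", "filmA")
    with pytest.raises(KeyError):
        generate_recording(spec, "sub00", "filmZ")


def test_adding_subjects_preserves_existing_data():
    small = _spec(n_subjects=3)
    big = _spec(n_subjects=6)
    for sid in ("sub00", "sub02"):
        assert np.array_equal(generate_recording(small, sid, "filmA").samples,
                              generate_recording(big, sid, "filmA").samples)


def test_noise_rms_and_spectral_slope():
    spec = _spec(duration=64.0)
    rec = generate_recording(spec, "sub00", "filmA")
    rms = np.sqrt(np.mean(rec.samples ** 2, axis=1))
    assert rms == pytest.approx(spec.noise.amplitude_scale, rel=1e-9)
    f, psd = sps.welch(rec.samples[0], fs=RATE, nperseg=4096)
    mask = (f >= 1.0) & (f <= 40.0)
    slope = np.polyfit(np.log10(f[mask]), np.log10(psd[mask]), 1)[0]
    assert slope == pytest.approx(-spec.noise.spectral_exponent, abs=0.2)


def test_pure_noise_has_balanced_pre_post_power():
    """Without injected responses, post-cut band power matches pre-cut
    power up to sampling error."""
    spec = _spec(duration=60.0)
    rec = generate_recording(spec, "sub00", "filmA")
    theta = band_limit(rec.samples[0], "theta", RATE)
    pre, post = [], []
    for cut in spec.films[0].cuts:
        k = int(cut.onset_s * RATE)
        pre.append(np.mean(theta[k - 256:k] ** 2))
        post.append(np.mean(theta[k:k + 256] ** 2))
    assert np.mean(post) == pytest.approx(np.mean(pre), rel=0.5)


def _difference(spec_with, spec_without, subject="sub00", film="filmA"):
    with_ = generate_recording(spec_with, subject, film).samples
    without = generate_recording(spec_without, subject, film).samples
    return with_ - without


def test_ers_injection_elevates_band_power_locally():
    """Oracle: band-pass the generated array and compare mean squared
    amplitude inside vs outside the response window, per cut."""
    tpl = ResponseTemplate("theta", 0.0, 188.0, "ERS", 0.5, ("Cz", "Pz"))
    spec = _spec(responses=(tpl,), duration=60.0, variability=0.0)
    rec = generate_recording(spec, "sub00", "filmA")
    theta = band_limit(rec.samples[0], "theta", RATE)     # Cz
    inside, outside = [], []
    for cut in spec.films[0].cuts:
        k = int(cut.onset_s * RATE)
        inside.append(np.mean(theta[k:k + 48] ** 2))
        outside.append(np.mean(theta[k - 304:k - 256] ** 2))
    # +50% band power inside the window (tapered edges cost a little)
    ratio = np.mean(inside) / np.mean(outside)
    assert ratio == pytest.approx(1.5, rel=0.25)


def test_injection_locality_channels_and_time():
    """Templates change only their electrodes, and only near their window."""
    tpl = ResponseTemplate("theta", 0.0, 200.0, "ERS", 1.0, ("Cz",))
    diff = _difference(_spec(responses=(tpl,)), _spec())
    assert np.abs(diff[1:]).max() == 0.0          # Pz, Oz, F3 untouched
    changed = np.flatnonzero(np.abs(diff[0]) > 1e-12)
    cuts = _spec().films[0].cuts
    for idx in changed:
        dist = min(abs(idx - c.onset_s * RATE) for c in cuts)
        assert dist <= 0.25 * RATE                # within the 0-200 ms window


def test_erd_injection_suppresses_band_component():
    tpl = ResponseTemplate("theta", 0.0, 400.0, "ERD", -0.8, ("Cz",),)
    spec0 = _spec(duration=60.0, variability=0.0)
    spec1 = _spec(responses=(tpl,), duration=60.0, variability=0.0)
    rec = generate_recording(spec1, "sub00", "filmA")
    base = generate_recording(spec0, "sub00", "filmA")
    theta1 = band_limit(rec.samples[0], "theta", RATE)
    theta0 = band_limit(base.samples[0], "theta", RATE)
    ratios = []
    for cut in spec0.films[0].cuts:
        k = int(cut.onset_s * RATE)
        mid = slice(k + 26, k + 77)               # plateau, clear of tapers
        ratios.append(np.mean(theta1[mid] ** 2) / np.mean(theta0[mid] ** 2))
    # -80% power, diluted by filter ringing from the unsuppressed
    # surroundings leaking into the window
    assert np.mean(ratios) < 0.5


def test_taxon_conditioned_injection_targets_matching_cuts_only():
    tpl = ResponseTemplate("theta", 0.0, 200.0, "ERS", 2.0, ("Cz",),
                           taxon_condition="var_ge30")
    diff = _difference(_spec(responses=(tpl,)), _spec())[0]
    for cut in _spec().films[0].cuts:
        k = int(cut.onset_s * RATE)
        touched = np.abs(diff[k:k + 51]).max() > 1e-9
        assert touched == (cut.angle_delta_deg >= 30.0)


# --- spec validation and config ---------------------------------------------

def test_spec_validation():
    with pytest.raises(ValueError, match="n_subjects"):
        _spec(n_subjects=1)
    with pytest.raises(ValueError, match="margins"):
        films = (FilmSpec("f", 10.0, (generate_cut_table("f", 10.0, 1,
                                                         seed=0)[0],)),)
        bad_cut = type(films[0].cuts[0])(
            film_id="f", cut_id="x", onset_s=0.5, pre_scale="medium",
            post_scale="medium", angle_delta_deg=0.0)
        SyntheticStudySpec(films=(FilmSpec("f", 10.0, (bad_cut,)),),
                           n_subjects=2)
    with pytest.raises(ValueError, match="absent from the montage"):
        _spec(responses=(ResponseTemplate("theta", 0, 100, "ERS", 1.0,
                                          ("Nope",)),))


def test_response_template_validation():
    with pytest.raises(ValueError):
        ResponseTemplate("theta", 200, 100, "ERS", 1.0, ("Cz",))
    with pytest.raises(ValueError):
        ResponseTemplate("theta", 0, 100, "ERS", -0.5, ("Cz",))
    with pytest.raises(ValueError):
        ResponseTemplate("theta", 0, 100, "ERD", 0.5, ("Cz",))
    with pytest.raises(ValueError):
        ResponseTemplate("theta", 0, 100, "ERD", -1.5, ("Cz",))
    with pytest.raises(KeyError):
        ResponseTemplate("sigma", 0, 100, "ERS", 1.0, ("Cz",))


def test_default_study_mirrors_study_conditions():
    spec = default_study_spec(seed=0)
    assert spec.n_subjects == 21
    assert len(spec.films) == 4
    assert spec.sampling_rate == 256.0
    assert len(spec.electrodes) == 31
    # editing rhythms of the four excerpts, cuts per minute
    per_min = sorted(60.0 * len(f.cuts) / f.duration_s for f in spec.films)
    assert per_min == pytest.approx([4.79, 14.45, 21.89, 27.24], abs=0.5)


def test_yaml_config_round_trip(tmp_path):
    cfg = tmp_path / "study.yaml"
    cfg.write_text("""
seed: 4
n_subjects: 3
film_duration_s: 30.0
noise: {spectral_exponent: 1.2, amplitude_scale: 15.0}
responses:
  - band: theta
    onset_ms: 0
    offset_ms: 200
    direction: ERS
    relative_power_change: 1.0
    electrodes: [Cz, Pz]
    taxon_condition: var_ge30
""")
    spec = load_study_config(cfg)
    assert spec.n_subjects == 3
    assert spec.noise.spectral_exponent == 1.2
    assert spec.responses[0].taxon_condition == "var_ge30"
    assert spec.responses[0].electrodes == ("Cz", "Pz")
    # dict route gives the identical spec
    import yaml
    assert study_spec_from_dict(yaml.safe_load(cfg.read_text())) == spec
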