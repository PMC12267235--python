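# Methods

## The analysis

`cutsync` asks whether film editing cuts elicit a *common* neural
response in spectator EEG, and whether that response *varies* with the
kind of cut. Both questions are answered in the frequency domain, on
model signals averaged across subjects and cuts.

### Model signals

All subjects watch the same excerpts, so their recordings are
time-locked to the stimulus. For each film the subjects' recordings are
averaged sample-by-sample (grand average); a 2-s epoch — 1 s pre-cut,
1 s post-cut, the cut at the central instant — is sliced around every
annotated cut. Averaging the epochs of *all* cuts of one film gives the
**ASF** (average signal per film, one per electrode and film; four films
give four ASFs per electrode). Averaging only the cuts sharing one
taxonomy category gives the **ASC** (average signal per cut type, up to
one per electrode, film and category).

Because grand averaging and epoch averaging are both sample-wise means,
the order of the two operations is irrelevant (tested as an identity).
The important consequence of time-domain averaging is that only
*phase-locked* (evoked) activity survives it; induced, non-phase-locked
power changes shrink as 1/N. The synthetic-data design below takes this
seriously.

### Frequency decomposition

Each model signal is decomposed into 15 frequency ranges: delta 0.5–3,
theta 3–7, alpha 7–14, beta 14–32 and gamma 32–42 Hz, plus the low/high
half of each. Band limiting uses a 4th-order Butterworth band-pass
applied forward and backward (zero phase). The band-limited epoch is
reduced to **block power**: the mean squared amplitude over consecutive
non-overlapping blocks of 8 samples — 31.25 ms at 256 Hz — giving 64
power values per 2-s epoch. An 8-sample Fourier transform at 256 Hz
cannot resolve delta from theta (bin spacing 32 Hz), so the band-pass +
block mean-square operator is the declared block-power contract; it
preserves every structural number (8-sample blocks, 64 values per
epoch, 6-block windows of 187.5 ms) and the operator is pluggable.

Filter context: when the continuous grand-average signal is available
(the pipeline path), it is filtered *before* epoch slicing, so slow
ranges get real context beyond the epoch; a bare 512-sample epoch is
reflect-padded by 0.5 s instead. Reflection transients of the narrow
ranges can still reach a few percent into a bare epoch's central
blocks, which is why closed-form block-power tests carry 5–10 %
tolerances.

### Stage 1 — conjunction detection of a common response

Statistical comparisons run over sliding windows of 6 consecutive
blocks (187.5 ms, step 1 block = 31.25 ms; 59 windows per epoch). The
central window holds the last 3 pre-cut and first 3 post-cut blocks and
is labelled 0 ms. For each electrode, band and window, the four
per-film ASF profiles are compared pairwise — 6 pairs — with

* Spearman rank correlation (average ranks for ties), threshold
  rho > 0.5, and
* a one-sided exact permutation test of positive correlation: all
  6! = 720 orderings of one profile are enumerated and
  p = #{rho_perm >= rho_obs}/720, identity included, so p >= 1/720.
  (Windows wider than 8 blocks would fall back to seeded Monte Carlo.)

A window counts as a cut-locked response only if **all six** pairs show
rho > 0.5 *and* p < 0.05. No further multiple-testing correction is
applied across windows, electrodes or bands: the six-way conjunction is
the stringency mechanism, raw p values are reported, and the measured
null pass rate per window is ~0.003, an order of magnitude below the
single-test alpha.

Sidedness was an open choice; one-sided (positive association) is
declared, since the detection rule requires significant *positive*
correlation. The permutation shuffles one member of the pair within
the window.

### Stage 2 — cut-type variation

At windows that pass the conjunction, per-category ASC profiles are
compared across the two taxonomies:

* **G1** — post-cut shot only: {medium, close-up, wide} x {angle
  variation >= 30 deg, on axis} plus full shot with variation (7
  categories; a full shot on axis has no category and is surfaced as
  unclassified rather than guessed).
* **G2** — the relation between both shots: close-up→close-up,
  medium→medium, wide→wide, any→close-up, any→wide,
  close-up/medium→full/wide, full/wide→close-up/medium, variation
  < 30 deg, variation >= 30 deg. Categories overlap by construction and
  a cut contributes its epoch to every matching ASC.

The omnibus test is a tie-corrected Kruskal–Wallis rank ANOVA
(chi-square approximation, k−1 df, p < 0.05), followed by a
Tukey–Kramer post hoc on rank-transformed values (studentized-range
criterion at alpha = 0.05, unequal group sizes allowed; a parametric
variant on raw values is a flag away).

**Replicate structure.** Each category's replicates are its per-film
window means: one value per film that has an ASC for the category
(>= 2 films required). An earlier candidate — pooling the six raw
blocks of each film's window into <= 24 "replicates" — was measured to
flag ~80 % of windows under *random* regroupings of the same cuts: the
blocks of a window are strongly autocorrelated, and treating them as
independent pseudo-replicates destroys calibration. With per-film means
the random-regrouping rate is ~0.2–4 %, while a category-conditioned
injected response is detected in essentially every window it covers.

Post hoc differences between G2 categories are additionally regrouped
by shot-scale variation (same / increased / reduced, using the framing
order close-up < medium < full < wide; the order between full and wide
is a declared convention) and tallied per latency bin (0–125, 250–375,
500–1000 ms).

### ERD/ERS quantification

Every window is quantified as

    ERD% = (Baseline − Test) / Baseline × 100

with Baseline the mean block power of the 32 pre-cut blocks of the same
model signal and Test the mean over the window's 6 blocks. Positive
values are desynchronization (power drop), negative values
synchronization (power rise). The baseline is the film's own pre-cut
second, not a resting state — the quantity of interest is the change
the cut causes within the film's temporal continuum. The pipeline
reports the across-film mean of the per-film ASF values. The ratio is
undefined (an error) for a non-positive baseline and invariant under
power rescaling.

## The synthetic study generator

The generator emulates the study conditions so the full chain is
verifiable without human data: 21 subjects x 4 film excerpts x 31
electrodes (10–20 system, modified combinatorial nomenclature) at
256 Hz, with per-film editing rhythms of 27.24, 21.89, 14.45 and 4.79
cuts per minute. Excerpt duration defaults to 60 s — a desk-scale
choice; the rhythm (cuts per minute), not the excerpt length, is what
the analysis is sensitive to. Cut tables draw shot-scale pairs and
angle variations from a configurable mix (default: uniform scale pairs,
P(angle >= 30 deg) = 0.5), with a 0.5-s minimum spacing; epochs of
neighbouring cuts overlap freely, as they must at 27 cuts/min.

**Background noise** is 1/f Gaussian noise synthesized in the frequency
domain (spectral coefficients with amplitude ∝ f^(−exponent/2), random
phases), inverse-transformed and normalized to an exact per-channel RMS
(default 20 uV, exponent 1). Frequency-domain synthesis gives exact
control of the spectral slope, which is verified by Welch regression.

**Injected responses** are the ground truth for recovery tests. Two
mechanisms, chosen by direction:

* *ERS* (power increase): a cut-locked, phase-locked band-limited
  sinusoidal burst (carrier at the band center, fixed phase relative to
  the cut, 10 % raised-cosine edge tapers) whose power is
  `relative_power_change` times the channel's background band power.
  Phase locking is deliberate: time-domain grand averaging suppresses
  everything else, so a simulator of purely induced (random-phase)
  responses would generate data in which the analysis can find nothing
  — by construction, not by defect.
* *ERD* (power decrease): multiplicative suppression of the channel's
  own band component inside the window, implemented as an additive,
  tapered, band-filtered correction term — so an injection is always
  testable by subtracting a no-response run, and is local in time, band
  and electrode.

A template with a `taxon_condition` applies only to cuts carrying that
G1/G2/scale-group label. Per-subject amplitude jitter (default 10 %
multiplicative) is drawn from a stream keyed by (seed, subject), so
adding subjects never changes existing subjects' data; everything is
bit-reproducible from (spec, seeds).

The canonical recovery pattern (`reference_response_templates`) is:
theta synchronization 0–200 ms, theta desynchronization 200–500 ms,
delta desynchronization 500–700 ms, theta synchronization 650–1000 ms —
theta on parietal sites, delta on frontal/frontocentral midline sites.
The delta desynchronization is only observable against phase-locked
delta energy (see above), so the pattern includes a sustained
cut-locked evoked delta wave spanning the epoch, which the 500–700 ms
ERD suppresses. Default magnitudes: ERS +100 % of background band
power, ERD −90 %, evoked delta +200 %; desk-scale but within the range
of event-related band-power changes reported for naturalistic stimuli
once averaging gain is accounted for.

**What the generator does not emulate** — and what passing recovery
tests therefore do not show about real data: ocular/muscle artifacts
and their manual removal, electrode drift, volume-conduction topography
(channels are independent), film-content-driven ongoing activity,
inter-subject latency jitter of the responses, and induced band-power
changes without any phase-locked component (which this analysis cannot
see in principle).

## Numerical choices

* Epoch convention: the cut sample is `floor(onset_s * rate)`; it is
  the first post-cut sample, pre-cut second = samples [0, 256), post
  = [256, 512). Cuts with less than 1 s of signal on a side are
  skipped with a warning, not an error.
* Rank ties: average ranks everywhere; a constant window profile has
  undefined correlation (`None`, never a number) and fails the
  conjunction.
* Permutation count includes the identity, so p is never 0; float
  comparisons of rho use a 1e-12 tolerance so re-orderings that tie
  the observed value are counted.
* Kruskal–Wallis on all-identical data returns (H = 0, p = 1) instead
  of an error; Tukey–Kramer with zero within-group variance flags any
  pair whose means differ.
* The studentized-range quantile is cached per (alpha, k, df) — the
  `sf`-per-pair route costs minutes over thousands of windows, the
  cached critical-value route seconds.
* EDF output quantizes to 16 bits over a symmetric per-channel physical
  range (round-trip error < 0.01 uV at typical amplitudes); recordings
  are padded to whole 1-s records.
* The 30-deg angle threshold, rho threshold 0.5, alpha 0.05, block
  length 8, window width 6 and step 1 are configuration knobs with
  these defaults.

## Problem sizes

Unit and property tests run on 2–5 subject studies of 20–60 s. The
end-to-end recovery checks use the full 21-subject x 4-film design at
60-s excerpts (120 s for the taxon-discrimination check, where the
number of cuts per category bounds the resolution of the group stage),
with the analysis restricted to the six delta/theta ranges plus an
alpha control band and the eleven response electrodes plus two
controls. These sizes are the package's reference desk-scale
conditions; the pipeline itself has no size limits.

## Known limitations

* The block-power operator is a declared stand-in for an 8-sample
  frequency-domain magnitude whose exact original form is not
  recoverable; the operator is pluggable for that reason.
* The group stage has at most 4 replicates per category (one per
  film), so its power is bounded; with fewer than 2 films carrying a
  category, the category is dropped from the test.
* ERD/ERS of a window that also contains filter ringing from an
  adjacent large response reflects that ringing; latency edges are
  smeared by the band filter's impulse response, most strongly in the
  delta ranges.
* G1 classification of a full shot on axis is undefined by the
  category table; such cuts are excluded from G1 ASCs and counted in
  the run report.
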