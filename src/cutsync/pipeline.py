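"""End-to-end orchestration: data in, window verdicts and reports out.

A run walks the full chain: obtain recordings (synthetic or from disk)
-> grand-average subjects per film -> band-limit the continuous average
and slice cut-centered epochs -> ASF/ASC block-power series ->
conjunction detection across the four films -> ERD/ERS of every window
-> taxon-variance tests at the detected windows -> CSV/JSON reports.

Everything is deterministic given the config and seed; the run report
records a config hash alongside the stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bands import BAND_TABLE, get_band, band_limit
from .io_formats import (CutAnnotation, Recording, read_cut_table,
                         read_recording, write_results)
from .model_signals import epoch_matrix, grand_average
from .statistics import (asf_conjunction, erd_ers, kruskal_wallis,
                         tukey_kramer)
from .synthetic_data import SyntheticStudySpec, generate_recording
from .taxonomy import (classification_report, classify_g1, classify_g2,
                       g2_scale_group, G1_LABELS, G2_LABELS)
from .tf_decomposition import block_power, sliding_windows

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run", "analyze_films",
           "summarize_conjunction", "summarize_group_tests",
           "scale_group_crosstab"]

#: Post-cut latency bins (ms) used for the cross-tab of post hoc
#: differences by scale-variation group.
CROSSTAB_BINS_MS = ((0.0, 125.0), (250.0, 375.0), (500.0, 1000.0))


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one input source must be set."""

    synthetic: SyntheticStudySpec | None = None
    input_dir: str | Path | None = None
    out_dir: str | Path = "results"
    bands: tuple[str, ...] | None = None        # None = all 15 ranges
    electrodes: tuple[str, ...] | None = None   # None = all montage channels
    block_len: int = 8
    window_width: int = 6
    window_step: int = 1
    rho_threshold: float = 0.5
    alpha: float = 0.05
    taxonomies: tuple[str, ...] = ("G1", "G2")
    min_films_per_taxon: int = 2
    seed: int = 0
    write_recordings: bool = False

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError(
                "configure exactly one of synthetic spec or input_dir")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.rho_threshold <= 1:
            raise ValueError("rho_threshold must be in (0, 1]")
        if self.window_width < 3:
            raise ValueError("window_width must be >= 3")
        for t in self.taxonomies:
            if t not in ("G1", "G2"):
                raise ValueError(f"unknown taxonomy {t!r}")


@dataclass
class RunReport:
    """Stage counts and provenance of one pipeline run."""

    n_subjects: int
    n_films: int
    n_electrodes: int
    n_bands: int
    n_cuts_total: int
    n_cuts_epoched: int
    n_cuts_skipped_edge: int
    n_cuts_unclassified_g1: int
    n_windows_tested: int
    n_windows_passing: int
    n_group_tests: int
    n_group_tests_significant: int
    seed: int
    config_hash: str
    version: str = __version__
    outputs: dict = field(default_factory=dict)

    def validate(self) -> None:
        assert self.n_windows_passing <= self.n_windows_tested
        assert (self.n_cuts_epoched + self.n_cuts_skipped_edge
                == self.n_cuts_total)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name and entity."""

    def __init__(self, stage: str, entity: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {entity!r}: {cause}")
        self.stage, self.entity = stage, entity


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (Path, np.floating, np.integer)):
            return str(o)
        if isinstance(o, tuple):
            return list(o)
        return repr(o)
    fields = dataclasses.asdict(config)
    fields.pop("out_dir", None)          # destination is not provenance
    payload = json.dumps(fields, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# input acquisition

def _load_synthetic(spec: SyntheticStudySpec):
    """Grand-average each film's subjects streamingly; returns
    (averages_by_film, cut_tables, n_subjects)."""
    averages, cut_tables = {}, {}
    for film in spec.films:
        acc = None
        for subject in spec.subject_ids():
            rec = generate_recording(spec, subject, film.film_id)
            acc = rec.samples if acc is None else acc + rec.samples
        averages[film.film_id] = Recording(
            subject_id="grand_average", film_id=film.film_id,
            sampling_rate=spec.sampling_rate,
            electrode_labels=list(spec.electrodes.labels),
            samples=acc / spec.n_subjects)
        cut_tables[film.film_id] = list(film.cuts)
    return averages, cut_tables, spec.n_subjects


def _load_from_dir(input_dir: Path):
    """Read ``<subject>__<film>.edf`` recordings and ``cuts_<film>.csv``."""
    by_film: dict[str, list[Recording]] = defaultdict(list)
    for path in sorted(input_dir.glob("*.edf")) + sorted(
            input_dir.glob("*.csv")):
        if path.name.startswith("cuts_"):
            continue
        if "__" not in path.stem:
            continue
        rec = read_recording(path)
        by_film[rec.film_id].append(rec)
    cut_tables = {}
    for path in sorted(input_dir.glob("cuts_*.csv")):
        film_id = path.stem[len("cuts_"):]
        cut_tables[film_id] = read_cut_table(path)
    if set(by_film) != set(cut_tables):
        raise ValueError(
            f"films with recordings {sorted(by_film)} != films with cut "
            f"tables {sorted(cut_tables)}")
    n_subjects = {len(v) for v in by_film.values()}
    averages = {film: grand_average(recs) if len(recs) > 1 else recs[0]
                for film, recs in by_film.items()}
    return averages, cut_tables, max(n_subjects)


# ---------------------------------------------------------------------------
# core analysis

def _taxon_assignments(cut_tables: "dict[str, list[CutAnnotation]]",
                       taxonomies: tuple[str, ...]):
    """Per taxonomy: film -> cut_id -> label set."""
    out: dict[str, dict[str, dict[str, frozenset]]] = {}
    for taxonomy in taxonomies:
        per_film = {}
        for film, cuts in cut_tables.items():
            assign = {}
            for cut in cuts:
                if taxonomy == "G1":
                    label = classify_g1(cut)
                    assign[cut.cut_id] = (frozenset((label,))
                                          if label else frozenset())
                else:
                    assign[cut.cut_id] = classify_g2(cut)
            per_film[film] = assign
        out[taxonomy] = per_film
    return out


def analyze_films(averages: "dict[str, Recording]",
                  cut_tables: "dict[str, list[CutAnnotation]]",
                  config: PipelineConfig,
                  assignments: "dict | None" = None):
    """Band decomposition + model-signal power series for every film.

    Returns ``(asf_power, asc_power, electrodes, counts)`` where
    ``asf_power[band][film]`` is an (n_electrodes, n_blocks) array and
    ``asc_power[(taxonomy, taxon)][band][film]`` likewise (films lacking
    the taxon are absent).  ``assignments`` overrides the taxonomy
    labelling (taxonomy -> film -> cut_id -> label set), e.g. to rerun
    the group stage under a random regrouping of the same cuts.
    """
    films = sorted(averages)
    ref = averages[films[0]]
    electrodes = list(config.electrodes or ref.electrode_labels)
    ch_idx = [ref.electrode_labels.index(e) for e in electrodes]
    band_names = [get_band(b).name for b in (config.bands or
                                             [b.name for b in BAND_TABLE])]
    rate = ref.sampling_rate
    if assignments is None:
        assignments = _taxon_assignments(cut_tables, config.taxonomies)

    asf_power: dict[str, dict[str, np.ndarray]] = defaultdict(dict)
    asc_power: dict[tuple, dict[str, dict[str, np.ndarray]]] = defaultdict(
        lambda: defaultdict(dict))
    counts = {"cuts_total": 0, "cuts_epoched": 0, "cuts_skipped": 0}

    for film in films:
        avg = averages[film]
        sub = avg.samples[ch_idx]
        cuts = cut_tables[film]
        counts["cuts_total"] += len(cuts)
        kept_ids = None
        for band in band_names:
            limited = band_limit(sub, band, rate)
            epochs, kept, skipped = epoch_matrix(limited, rate, cuts)
            if kept_ids is None:
                kept_ids = kept
                counts["cuts_epoched"] += len(kept)
                counts["cuts_skipped"] += len(skipped)
            if not kept:
                raise StageError("model_signals", film,
                                 ValueError("no epochable cuts"))
            asf = epochs.mean(axis=0)                      # (n_ch, 512)
            asf_power[band][film] = block_power(asf, config.block_len)
            for taxonomy in config.taxonomies:
                assign = assignments[taxonomy][film]
                taxa = (G1_LABELS if taxonomy == "G1" else G2_LABELS)
                for taxon in taxa:
                    mask = np.array([taxon in assign[cid] for cid in kept])
                    if not mask.any():
                        continue
                    asc = epochs[mask].mean(axis=0)
                    asc_power[(taxonomy, taxon)][band][film] = block_power(
                        asc, config.block_len)
    return asf_power, asc_power, electrodes, counts


def _group_test(asc_power, ch: int,
                start: int, stop: int, taxonomy: str,
                electrode: str, band: str, center_ms: float,
                config: PipelineConfig):
    """KW + post hoc for one window; returns a result dict or None.

    Each taxon's replicates are its per-film window means (one value per
    film that has an ASC for the taxon).  Pooling the raw blocks instead
    would pseudo-replicate: the 6 blocks of a window are strongly
    autocorrelated, and treating them as independent inflates the false-
    positive rate far above alpha under random regroupings of the cuts.
    """
    groups, labels = [], []
    for taxon in sorted(t for (tx, t) in asc_power if tx == taxonomy):
        per_film = asc_power[(taxonomy, taxon)].get(band, {})
        values = [float(per_film[f][ch, start:stop].mean())
                  for f in sorted(per_film)]
        if len(values) < max(config.min_films_per_taxon, 2):
            continue
        groups.append(np.asarray(values))
        labels.append(taxon)
    if len(groups) < 2 or sum(len(g) for g in groups) < 5:
        return None
    h, p = kruskal_wallis(groups)
    posthoc = []
    if p < config.alpha:
        posthoc = tukey_kramer(groups, labels, alpha=config.alpha)
    return {"taxonomy": taxonomy, "electrode": electrode, "band": band,
            "center_ms": center_ms, "taxa": labels, "H": h, "p_kw": p,
            "posthoc": posthoc}


def run(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline and write all result tables."""
    t0 = time.monotonic()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- input stage
    try:
        if config.synthetic is not None:
            averages, cut_tables, n_subjects = _load_synthetic(config.synthetic)
            if config.write_recordings:
                from .synthetic_data import generate_study
                generate_study(config.synthetic, out_dir / "recordings")
        else:
            averages, cut_tables, n_subjects = _load_from_dir(
                Path(config.input_dir))
    except (OSError, ValueError, KeyError) as exc:
        raise StageError("input", str(config.input_dir or "synthetic"), exc)
    logger.info("input stage: %d films, %d subjects (%.1f s)",
                len(averages), n_subjects, time.monotonic() - t0)

    all_cuts = [c for cuts in cut_tables.values() for c in cuts]
    class_rows = classification_report(all_cuts)
    n_unclassified = sum(r["g1_label"] == "unclassified" for r in class_rows)
    write_results(class_rows, out_dir / "cut_classification.csv")

    # --- model signals + decomposition
    t1 = time.monotonic()
    asf_power, asc_power, electrodes, counts = analyze_films(
        averages, cut_tables, config)
    band_names = sorted(asf_power)
    films = sorted(averages)
    logger.info("decomposition stage: %d bands x %d films (%.1f s)",
                len(band_names), len(films), time.monotonic() - t1)

    # --- conjunction + ERD/ERS
    t2 = time.monotonic()
    rate = averages[films[0]].sampling_rate
    window_rows, group_rows = [], []
    n_tested = n_passing = 0
    from .tf_decomposition import BandPowerSeries
    for band in band_names:
        band_def = get_band(band)
        per_film = asf_power[band]
        n_blocks = per_film[films[0]].shape[1]
        windows = sliding_windows(n_blocks, 1000.0 * config.block_len / rate,
                                  width=config.window_width,
                                  step=config.window_step)
        for ch, electrode in enumerate(electrodes):
            series = {f: BandPowerSeries(
                band=band_def, block_len=config.block_len,
                sampling_rate=rate, values=per_film[f][ch],
                electrode=electrode, film_id=f, kind="ASF")
                for f in films}
            verdicts = asf_conjunction(
                series, width=config.window_width, step=config.window_step,
                rho_threshold=config.rho_threshold, alpha=config.alpha,
                electrode=electrode, band=band)
            n_pre = n_blocks // 2
            baselines = {f: float(np.mean(per_film[f][ch, :n_pre]))
                         for f in films}
            for win, verdict in zip(windows, verdicts):
                n_tested += 1
                erds = [erd_ers(baselines[f],
                                float(np.mean(per_film[f][ch,
                                              win.start_block:win.stop_block])))
                        for f in films if baselines[f] > 0]
                erd = float(np.mean(erds)) if erds else np.nan
                window_rows.append({
                    "electrode": electrode, "band": band,
                    "center_ms": win.center_label_ms,
                    "passed": verdict.passed,
                    "min_rho": verdict.min_rho, "max_p": verdict.max_p,
                    "erd_percent": erd,
                })
                if verdict.passed:
                    n_passing += 1
                    for taxonomy in config.taxonomies:
                        res = _group_test(
                            asc_power, ch, win.start_block, win.stop_block,
                            taxonomy, electrode, band, win.center_label_ms,
                            config)
                        if res is not None:
                            group_rows.append(res)
    logger.info("statistics stage: %d windows tested, %d passing (%.1f s)",
                n_tested, n_passing, time.monotonic() - t2)

    # --- reports
    windows_df = pd.DataFrame(window_rows)
    write_results(windows_df, out_dir / "window_results.csv")
    group_df = pd.DataFrame([{**r,
                              "taxa": ";".join(r["taxa"]),
                              "posthoc_significant": ";".join(
                                  f"{a}|{b}" for a, b, s in r["posthoc"] if s)}
                             for r in group_rows],
                            columns=["taxonomy", "electrode", "band",
                                     "center_ms", "taxa", "H", "p_kw",
                                     "posthoc_significant"])
    write_results(group_df, out_dir / "group_tests.csv")
    write_results(summarize_conjunction(windows_df),
                  out_dir / "conjunction_summary.csv")
    write_results(summarize_group_tests(group_df),
                  out_dir / "group_summary.csv")
    write_results(scale_group_crosstab(group_rows),
                  out_dir / "scale_group_crosstab.csv")

    report = RunReport(
        n_subjects=n_subjects, n_films=len(films),
        n_electrodes=len(electrodes), n_bands=len(band_names),
        n_cuts_total=counts["cuts_total"],
        n_cuts_epoched=counts["cuts_epoched"],
        n_cuts_skipped_edge=counts["cuts_skipped"],
        n_cuts_unclassified_g1=n_unclassified,
        n_windows_tested=n_tested, n_windows_passing=n_passing,
        n_group_tests=len(group_rows),
        n_group_tests_significant=sum(
            r["p_kw"] < config.alpha for r in group_rows),
        seed=config.seed, config_hash=_config_hash(config),
        outputs={p.name: str(p) for p in sorted(out_dir.glob("*.csv"))})
    report.validate()
    with open(out_dir / "report.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2, sort_keys=True)
    logger.info("run complete in %.1f s", time.monotonic() - t0)
    return report


# ---------------------------------------------------------------------------
# summaries

def summarize_conjunction(windows_df: pd.DataFrame) -> pd.DataFrame:
    """Passing-window counts per (band, center_ms), zero-filled.

    The tally of detected windows along the timeline — counting, for
    each frequency range, how many (electrode, window) cells passed the
    six-way conjunction at each latency.
    """
    if windows_df.empty:
        return pd.DataFrame(columns=["band", "center_ms", "n_passing"])
    table = (windows_df.groupby(["band", "center_ms"])["passed"]
             .sum().rename("n_passing").reset_index())
    table["n_passing"] = table["n_passing"].astype(int)
    return table


def summarize_group_tests(group_df: pd.DataFrame) -> pd.DataFrame:
    """Significant group-test counts per (taxonomy, band, center_ms)."""
    if group_df.empty:
        return pd.DataFrame(
            columns=["taxonomy", "band", "center_ms", "n_significant"])
    sig = group_df[group_df["p_kw"] < 0.05]
    if sig.empty:
        return pd.DataFrame(
            columns=["taxonomy", "band", "center_ms", "n_significant"])
    return (sig.groupby(["taxonomy", "band", "center_ms"])
            .size().rename("n_significant").reset_index())


def scale_group_crosstab(group_rows: "list[dict]") -> pd.DataFrame:
    """Post hoc differences regrouped by shot-scale variation and latency.

    Every significant post hoc pair of G2 categories is mapped to the
    (same/increased/reduced scale) groups of its two categories and
    counted per latency bin; pure-angle categories carry no scale
    information and are left out.
    """
    rows = []
    for res in group_rows:
        if res["taxonomy"] != "G2":
            continue
        for lo, hi in CROSSTAB_BINS_MS:
            if lo <= res["center_ms"] <= hi:
                tbin = f"{lo:g}-{hi:g} ms"
                break
        else:
            continue
        for a, b, significant in res["posthoc"]:
            if not significant:
                continue
            ga, gb = g2_scale_group(a), g2_scale_group(b)
            if ga is None or gb is None:
                continue
            ga, gb = sorted((ga, gb))
            rows.append({"time_bin": tbin, "group_a": ga, "group_b": gb,
                         "electrode": res["electrode"], "band": res["band"]})
    if not rows:
        return pd.DataFrame(columns=["time_bin", "group_a", "group_b",
                                     "n_differences", "electrodes"])
    df = pd.DataFrame(rows)
    agg = (df.groupby(["time_bin", "group_a", "group_b"])
           .agg(n_differences=("electrode", "size"),
                electrodes=("electrode",
                            lambda s: ";".join(sorted(set(s)))))
           .reset_index())
    return agg
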