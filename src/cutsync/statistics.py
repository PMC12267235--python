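"""Statistical stages: conjunction detection, taxon variance, ERD/ERS.

Stage 1 (common patterns).  For every electrode, frequency range and
sliding window, the 4 per-film ASF block-power profiles are compared
pairwise (6 pairs).  A window counts as a cut-locked neural response only
if *all six* pairs show a Spearman rank correlation above 0.5 *and* an
exact permutation p-value below 0.05 — a conjunction that controls false
positives without any further multiple-testing correction.

The permutation test is one-sided (alternative: positive correlation,
matching the requirement of significant *positive* correlation) and
enumerates all ``n!`` orderings of one member of the pair for n <= 8;
the identity permutation is included in the count so p >= 1/n!.

Stage 2 (taxon variance).  At windows that passed the conjunction, the
per-taxon ASC profiles are compared with a tie-corrected Kruskal-Wallis
rank ANOVA; each taxon's replicate set pools the window's blocks from
every film that has an ASC for it.  Significant windows get a
Tukey-Kramer post hoc on the rank-transformed values (coherent with the
nonparametric omnibus test; a parametric variant is a flag away).

ERD/ERS.  Every window is quantified as
``(baseline - test) / baseline * 100`` with the 1-s pre-cut block power
of the same model signal as the baseline: positive = desynchronization
(power drop), negative = synchronization (power rise).
"""

from __future__ import annotations

import functools
import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .tf_decomposition import (AnalysisWindow, BandPowerSeries,
                               sliding_windows, window_value_matrix)

__all__ = [
    "ComparisonResult", "ConjunctionVerdict", "GroupTestResult", "ERDResult",
    "spearman_rho", "exact_permutation_p", "asf_conjunction",
    "kruskal_wallis", "tukey_kramer", "erd_ers", "erd_for_window",
    "MAX_EXACT_N",
]

#: Largest sample size for which the permutation null is fully enumerated
#: (n! orderings); larger windows fall back to seeded Monte Carlo.
MAX_EXACT_N = 8

_RHO_TIE_EPS = 1e-12


@dataclass(frozen=True)
class ComparisonResult:
    """One film-pair comparison at one window."""

    film_pair: tuple[str, str]
    rho: float | None            # None = undefined (a constant profile)
    p: float | None

    @property
    def defined(self) -> bool:
        return self.rho is not None and self.p is not None


@dataclass
class ConjunctionVerdict:
    """All six pairwise comparisons of one (electrode, band, window)."""

    electrode: str
    band: str
    window: AnalysisWindow
    comparisons: list[ComparisonResult]
    rho_threshold: float = 0.5
    alpha: float = 0.05
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = bool(self.comparisons) and all(
            c.defined and c.rho > self.rho_threshold and c.p < self.alpha
            for c in self.comparisons)

    @property
    def center_ms(self) -> float:
        return self.window.center_label_ms

    @property
    def min_rho(self) -> float:
        return min((c.rho for c in self.comparisons if c.defined),
                   default=math.nan)

    @property
    def max_p(self) -> float:
        return max((c.p for c in self.comparisons if c.defined),
                   default=math.nan)


@dataclass
class GroupTestResult:
    """Kruskal-Wallis + post hoc outcome at one window."""

    electrode: str
    band: str
    center_ms: float
    taxonomy: str
    taxa: list[str]
    H: float
    p_kw: float
    posthoc: "list[tuple[str, str, bool]]" = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_kw < 0.05


@dataclass(frozen=True)
class ERDResult:
    """ERD/ERS quantification of one window against the pre-cut second."""

    electrode: str
    band: str
    center_ms: float
    baseline_power: float
    test_power: float
    erd_percent: float


# ---------------------------------------------------------------------------
# rank correlation and its exact permutation null

def _ranks(values: np.ndarray) -> np.ndarray:
    return sstats.rankdata(values, axis=-1)


def spearman_rho(x, y) -> float | None:
    """Spearman rank correlation (average ranks for ties).

    Returns None when either vector is constant — the correlation is
    undefined there, which is distinct from any numeric value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman_rho expects two equal-length vectors, n >= 3")
    rx, ry = _ranks(x), _ranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return None
    return float(np.dot(rx - rx.mean(), ry - ry.mean()) / (len(x) * sx * sy))


def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def exact_permutation_p(x, y, observed_rho: "float | None" = None,
                        *, n_monte_carlo: int = 10000,
                        rng: "np.random.Generator | None" = None
                        ) -> float | None:
    """One-sided exact permutation p-value for positive rank correlation.

    All ``n!`` orderings of ``y`` are enumerated for n <= 8 and
    ``p = #{rho_perm >= rho_obs} / n!`` (the identity ordering counts, so
    p is never 0 and p >= 1/n!).  For larger n a seeded Monte-Carlo
    fallback with ``n_monte_carlo`` draws (+ identity) is used.
    Returns None when the correlation is undefined (constant vector).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if observed_rho is None:
        observed_rho = spearman_rho(x, y)
    if observed_rho is None:
        return None
    rx, ry = _ranks(x), _ranks(y)
    zx = (rx - rx.mean()) / (rx.std() * len(rx))
    zy = (ry - ry.mean()) / ry.std()
    n = len(x)
    if n <= MAX_EXACT_N:
        perms = _perm_matrix(n)
        rho_perm = zy[perms] @ zx
        return float(np.mean(rho_perm >= observed_rho - _RHO_TIE_EPS))
    rng = rng or np.random.default_rng(0)
    count = 1                                    # identity permutation
    for _ in range(n_monte_carlo):
        rho_perm = float(np.dot(rng.permutation(zy), zx))
        if rho_perm >= observed_rho - _RHO_TIE_EPS:
            count += 1
    return count / (n_monte_carlo + 1)


def _pairwise_window_tests(a: np.ndarray, b: np.ndarray,
                           perms: np.ndarray):
    """Vectorized rho and exact-permutation p for stacked windows.

    ``a``, ``b``: (n_windows, width) block-power matrices of one film
    pair.  Returns ``(rho, p)`` arrays with NaN where a window profile is
    constant (undefined correlation).
    """
    ra, rb = _ranks(a), _ranks(b)
    sa = ra.std(axis=1)
    sb = rb.std(axis=1)
    ok = (sa > 0) & (sb > 0)
    n = a.shape[1]
    za = (ra - ra.mean(axis=1, keepdims=True)) / np.where(ok, sa, 1.0)[:, None] / n
    zb = (rb - rb.mean(axis=1, keepdims=True)) / np.where(ok, sb, 1.0)[:, None]
    rho = np.einsum("wk,wk->w", za, zb)
    # all-permutations null: (n_windows, n!, width) gather, then contract
    zb_perm = zb[:, perms]
    rho_perm = np.einsum("wpk,wk->wp", zb_perm, za)
    p = np.mean(rho_perm >= rho[:, None] - _RHO_TIE_EPS, axis=1)
    rho[~ok] = np.nan
    p[~ok] = np.nan
    return rho, p


def asf_conjunction(series_by_film: "dict[str, BandPowerSeries]",
                    *, width: int = 6, step: int = 1,
                    rho_threshold: float = 0.5, alpha: float = 0.05,
                    electrode: str = "", band: str = ""
                    ) -> "list[ConjunctionVerdict]":
    """Conjunction test over all sliding windows of one (electrode, band).

    ``series_by_film`` maps the four film ids to their ASF block-power
    series; every window is compared for all 6 film pairs and passes only
    if every pair shows rho > ``rho_threshold`` and p < ``alpha``.
    """
    films = sorted(series_by_film)
    if len(films) != 4:
        raise ValueError(f"conjunction expects 4 film series, got {len(films)}")
    ref = series_by_film[films[0]]
    n_blocks = ref.n_blocks
    for f in films[1:]:
        if series_by_film[f].n_blocks != n_blocks:
            raise ValueError("film series have differing block counts")
    windows = sliding_windows(n_blocks, ref.block_duration_ms,
                              width=width, step=step)
    mats = {f: window_value_matrix(series_by_film[f], windows) for f in films}
    perms = _perm_matrix(width)
    pair_stats = {}
    for fa, fb in itertools.combinations(films, 2):
        pair_stats[(fa, fb)] = _pairwise_window_tests(mats[fa], mats[fb], perms)
    verdicts = []
    for wi, win in enumerate(windows):
        comps = []
        for pair, (rho, p) in pair_stats.items():
            r, pv = rho[wi], p[wi]
            comps.append(ComparisonResult(
                film_pair=pair,
                rho=None if np.isnan(r) else float(r),
                p=None if np.isnan(pv) else float(pv)))
        verdicts.append(ConjunctionVerdict(
            electrode=electrode, band=band or ref.band.name, window=win,
            comparisons=comps, rho_threshold=rho_threshold, alpha=alpha))
    return verdicts


# ---------------------------------------------------------------------------
# taxon variance

def kruskal_wallis(groups: "list[np.ndarray]") -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (df = k - 1).

    All-identical data is a degenerate case with H = 0 and p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    if sum(len(g) for g in groups) < 5:
        raise ValueError("Kruskal-Wallis needs a total of at least 5 values")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sstats.kruskal(*groups)
    return float(h), float(p)


def tukey_kramer(groups: "list[np.ndarray]",
                 labels: "list[str] | None" = None,
                 *, alpha: float = 0.05, on_ranks: bool = True
                 ) -> "list[tuple[str, str, bool]]":
    """Tukey-Kramer pairwise comparisons (unequal group sizes allowed).

    With ``on_ranks`` (default) the studentized-range criterion is
    applied to the pooled average ranks of the values, keeping the post
    hoc coherent with the Kruskal-Wallis stage; ``on_ranks=False`` gives
    the parametric variant on the raw values.  Groups of fewer than 2
    values are excluded with a warning.  Returns (label_a, label_b,
    significant) for every retained pair.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    labels = list(labels) if labels is not None else [
        f"group{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels/groups length mismatch")
    keep = [i for i, g in enumerate(groups) if len(g) >= 2]
    dropped = [labels[i] for i in range(len(groups)) if i not in keep]
    if dropped:
        warnings.warn(f"tukey_kramer: dropping undersized groups {dropped}",
                      stacklevel=2)
    groups = [groups[i] for i in keep]
    labels = [labels[i] for i in keep]
    k = len(groups)
    if k < 2:
        return []
    if on_ranks:
        pooled = _ranks(np.concatenate(groups))
        sizes = np.cumsum([0] + [len(g) for g in groups])
        groups = [pooled[sizes[i]:sizes[i + 1]] for i in range(k)]
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    n_total = int(ns.sum())
    df = n_total - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    q_crit = _studentized_range_critical(alpha, k, df)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        diff = abs(means[i] - means[j])
        if msw <= 0:
            out.append((labels[i], labels[j], bool(diff > 0)))
            continue
        se = math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        out.append((labels[i], labels[j], bool(diff / se > q_crit)))
    return out


@functools.lru_cache(maxsize=256)
def _studentized_range_critical(alpha: float, k: int, df: int) -> float:
    """Upper alpha quantile of the studentized range (cached: the ppf is
    expensive and identical across the many windows sharing k and df)."""
    return float(sstats.studentized_range.ppf(1.0 - alpha, k, df))


# ---------------------------------------------------------------------------
# ERD/ERS

def erd_ers(baseline_power: float, test_power: float) -> float:
    """Percentage band-power change of a test window against baseline.

    ``(baseline - test) / baseline * 100``: positive values are
    desynchronization (ERD, power drop), negative values are
    synchronization (ERS, power rise).  Undefined for a non-positive
    baseline.
    """
    if baseline_power <= 0:
        raise ValueError(
            f"ERD/ERS undefined for baseline power {baseline_power}")
    return (baseline_power - test_power) / baseline_power * 100.0


def erd_for_window(series: BandPowerSeries, window: AnalysisWindow,
                   *, electrode: str = "", band: str = "") -> ERDResult:
    """ERD/ERS of one window with the pre-cut second as the baseline.

    The baseline is the mean block power over the first half of the
    series (the 32 pre-cut blocks of a 2-s epoch); the test value is the
    mean over the window's blocks.
    """
    n_pre = series.n_blocks // 2
    baseline = float(np.mean(series.values[:n_pre]))
    test = float(np.mean(series.values[window.start_block:window.stop_block]))
    return ERDResult(electrode=electrode, band=band or series.band.name,
                     center_ms=window.center_label_ms,
                     baseline_power=baseline, test_power=test,
                     erd_percent=erd_ers(baseline, test))
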