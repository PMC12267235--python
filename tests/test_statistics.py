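"""Rank statistics, permutation null, group tests, and ERD/ERS."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sstats

from cutsync.statistics import (asf_conjunction, erd_ers, exact_permutation_p,
                                kruskal_wallis, spearman_rho, tukey_kramer)
from cutsync.tf_decomposition import BandPowerSeries
from cutsync.bands import get_band


# --- Spearman -------------------------------------------------------------

def pearson_on_ranks(x, y):
    """Oracle: Pearson correlation of hand-assigned average ranks."""
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


def test_spearman_monotone_and_antitone():
    assert spearman_rho([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12]) == pytest.approx(1.0)
    assert spearman_rho(range(6), list(range(6))[::-1]) == pytest.approx(-1.0)


def test_spearman_rank_formula_case():
    x = [1, 2, 3, 4, 5, 6]
    y = [3, 1, 2, 5, 4, 6]
    assert spearman_rho(x, y) == pytest.approx(pearson_on_ranks(x, y))


def test_spearman_constant_is_undefined():
    assert spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]) is None


@settings(deadline=None, max_examples=50)
@given(hst.lists(hst.integers(0, 9), min_size=4, max_size=8),
       hst.lists(hst.integers(0, 9), min_size=4, max_size=8))
def test_spearman_matches_scipy(xs, ys):
    n = min(len(xs), len(ys))
    x, y = xs[:n], ys[:n]
    rho = spearman_rho(x, y)
    ref = sstats.spearmanr(x, y).statistic
    if rho is None:
        assert math.isnan(ref)
    else:
        assert rho == pytest.approx(ref, abs=1e-12)


# --- exact permutation test ----------------------------------------------

def brute_force_perm_p(x, y):
    """Oracle: enumerate every ordering of y and count rho >= observed."""
    obs = pearson_on_ranks(x, y)
    count = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if pearson_on_ranks(x, perm) >= obs - 1e-12:
            count += 1
    return count / total


def test_perfect_concordance_p_is_one_over_720():
    p = exact_permutation_p([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12])
    assert p == pytest.approx(1 / 720)


def test_constant_vector_p_is_undefined():
    assert exact_permutation_p([1, 2, 3, 4], [5, 5, 5, 5]) is None


@pytest.mark.parametrize("n", [4, 5, 6])
def test_permutation_p_equals_enumeration_oracle(n, rng):
    for _ in range(25):
        x = rng.integers(0, 6, size=n).astype(float)
        y = rng.integers(0, 6, size=n).astype(float)
        if spearman_rho(x, y) is None:
            continue
        assert exact_permutation_p(x, y) == pytest.approx(
            brute_force_perm_p(x, y), abs=1e-12)


def test_permutation_p_uniform_under_null(rng):
    """Under an independent shuffle of y, p is uniform on its support."""
    x = np.arange(6, dtype=float)
    n_rep = 2000
    ps = []
    for _ in range(n_rep):
        y = rng.permutation(6).astype(float)
        ps.append(exact_permutation_p(x, y))
    ps = np.asarray(ps)
    assert ps.min() >= 1 / 720
    # distinct rho values under distinct-rank inputs give a lattice of
    # attainable p values; uniformity => P(p <= t) ~ t
    for t in (0.05, 0.25, 0.5):
        assert np.mean(ps <= t) == pytest.approx(t, abs=0.04)


def test_monte_carlo_fallback_for_large_n(rng):
    x = np.arange(10, dtype=float)
    y = x + rng.normal(0, 0.1, size=10)
    p = exact_permutation_p(x, y, n_monte_carlo=2000,
                            rng=np.random.default_rng(5))
    assert 0 < p < 0.01


# --- Kruskal-Wallis --------------------------------------------------------

def kw_rank_sum_oracle(groups):
    """Hand rank-sum formula 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1)."""
    pooled = np.concatenate(groups)
    ranks = sstats.rankdata(pooled)
    n_total = len(pooled)
    out, i = 0.0, 0
    for g in groups:
        r = ranks[i:i + len(g)].sum()
        out += r ** 2 / len(g)
        i += len(g)
    return 12.0 / (n_total * (n_total + 1)) * out - 3 * (n_total + 1)


def test_kruskal_wallis_fixture_h():
    h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert h == pytest.approx(7.2)
    assert h == pytest.approx(kw_rank_sum_oracle(
        [np.array([1, 2, 3.]), np.array([4, 5, 6.]), np.array([7, 8, 9.])]))
    assert p == pytest.approx(sstats.chi2.sf(7.2, df=2))


def test_kruskal_wallis_identical_groups_degenerate():
    h, p = kruskal_wallis([[2, 2, 2], [2, 2, 2]])
    assert h == 0.0 and p == 1.0


def test_kruskal_wallis_p_uniform_under_label_permutation(rng):
    """Permuting group labels under the null gives a ~uniform p."""
    values = rng.standard_normal(18)
    ps = []
    for _ in range(400):
        v = rng.permutation(values)
        _, p = kruskal_wallis([v[:6], v[6:12], v[12:]])
        ps.append(p)
    # the chi-square approximation is calibrated in the rejection region;
    # mid-scale it deviates at this N, so only the tail is checked
    ps = np.asarray(ps)
    assert np.mean(ps < 0.05) == pytest.approx(0.05, abs=0.035)
    assert np.mean(ps < 0.25) == pytest.approx(0.25, abs=0.1)


def test_kruskal_wallis_input_validation():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1], [2, 3]])


# --- Tukey-Kramer -----------------------------------------------------------

def test_tukey_kramer_flags_only_the_far_pair(rng):
    near = rng.normal(0, 1, 12)
    far = rng.normal(8, 1, 10)
    middle = rng.normal(4, 4, 11)
    res = dict(((a, b), s) for a, b, s in tukey_kramer(
        [near, far, middle], ["near", "far", "middle"]))
    assert res[("near", "far")]
    assert not res[("near", "middle")] or not res[("far", "middle")]


def test_tukey_kramer_identical_groups_not_flagged():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    assert all(not s for _, _, s in tukey_kramer([g, g.copy(), g.copy()]))


def test_tukey_kramer_matches_statsmodels_on_ranks(rng):
    """Cross-check against the reference Tukey HSD implementation applied
    to the same rank-transformed data."""
    statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
    groups = [rng.normal(0, 1, 8), rng.normal(1.5, 1, 6), rng.normal(4, 1, 9)]
    labels = ["a", "b", "c"]
    ours = dict(((x, y), s) for x, y, s in tukey_kramer(groups, labels))
    pooled = sstats.rankdata(np.concatenate(groups))
    codes = np.repeat(labels, [len(g) for g in groups])
    ref = statsmodels.pairwise_tukeyhsd(pooled, codes, alpha=0.05)
    for (ga, gb), reject in zip(itertools.combinations(labels, 2),
                                ref.reject):
        assert ours[(ga, gb)] == bool(reject)


def test_tukey_kramer_family_wise_error_rate(rng):
    """Three same-distribution groups: ~5% of families flagged."""
    hits = 0
    n_rep = 400
    for _ in range(n_rep):
        groups = [rng.standard_normal(8) for _ in range(3)]
        if any(s for _, _, s in tukey_kramer(groups)):
            hits += 1
    assert hits / n_rep == pytest.approx(0.05, abs=0.035)


def test_tukey_kramer_drops_undersized_groups():
    with pytest.warns(UserWarning, match="undersized"):
        res = tukey_kramer([np.array([1.0]), np.array([1, 2, 3.0]),
                            np.array([4, 5, 6.0])], ["tiny", "a", "b"])
    assert {frozenset((a, b)) for a, b, _ in res} == {frozenset(("a", "b"))}


# --- ERD/ERS ----------------------------------------------------------------

def test_erd_identities():
    assert erd_ers(100.0, 50.0) == pytest.approx(50.0)
    assert erd_ers(7.0, 7.0) == 0.0
    assert erd_ers(50.0, 100.0) == pytest.approx(-100.0)


@settings(deadline=None, max_examples=60)
@given(hst.floats(0.01, 1e6), hst.floats(0.0, 1e6), hst.floats(1e-3, 1e3))
def test_erd_scale_invariance(baseline, test, k):
    assert erd_ers(k * baseline, k * test) == pytest.approx(
        erd_ers(baseline, test), rel=1e-9, abs=1e-9)


def test_erd_undefined_for_nonpositive_baseline():
    with pytest.raises(ValueError):
        erd_ers(0.0, 10.0)
    with pytest.raises(ValueError):
        erd_ers(-5.0, 10.0)


# --- conjunction ------------------------------------------------------------

def _series(values):
    return BandPowerSeries(band=get_band("theta"), block_len=8,
                           sampling_rate=256.0,
                           values=np.asarray(values, dtype=float))


def test_conjunction_identical_series_pass_everywhere(rng):
    base = rng.random(64) + 0.5
    series = {f: _series(base) for f in "ABCD"}
    verdicts = asf_conjunction(series)
    assert len(verdicts) == 59
    assert all(v.passed for v in verdicts)
    assert all(len(v.comparisons) == 6 for v in verdicts)
    assert all(c.rho == pytest.approx(1.0) and c.p == pytest.approx(1 / 720)
               for v in verdicts for c in v.comparisons)


def test_conjunction_on_independent_noise_is_rare(rng):
    """The six-way conjunction passes far less often than a single test."""
    n_pass = n_tot = 0
    for _ in range(8):
        series = {f: _series(rng.random(64)) for f in "ABCD"}
        verdicts = asf_conjunction(series)
        n_tot += len(verdicts)
        n_pass += sum(v.passed for v in verdicts)
    assert n_pass / n_tot < 0.01


def test_conjunction_monotone_in_thresholds(rng):
    series = {f: _series(np.convolve(rng.random(70), np.ones(7), "valid")
                         + 0.1) for f in "ABCD"}
    strict = asf_conjunction(series, rho_threshold=0.8, alpha=0.01)
    loose = asf_conjunction(series, rho_threshold=0.5, alpha=0.05)
    n_strict = sum(v.passed for v in strict)
    n_loose = sum(v.passed for v in loose)
    assert n_strict <= n_loose
    # passing under the strict rule implies passing under the loose one
    for s, l in zip(strict, loose):
        assert not s.passed or l.passed


def test_conjunction_needs_four_films(rng):
    with pytest.raises(ValueError):
        asf_conjunction({f: _series(rng.random(64)) for f in "ABC"})


def test_conjunction_six_pairs_from_four_films(rng):
    series = {f: _series(rng.random(64)) for f in "ABCD"}
    v = asf_conjunction(series)[0]
    assert len({frozenset(c.film_pair) for c in v.comparisons}) == 6
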