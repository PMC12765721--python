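import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from plaquemetry.core import ValidationError
from plaquemetry.stats import (
    StatConfig,
    contribution_breakpoint,
    crossing_point,
    fit_breakpoint,
    friedman,
    passing_bablok,
    roc_analysis,
    roc_auc,
    sample_size_correlation,
    shapiro_wilk,
    spearman,
    wilcoxon_pairwise_bonferroni,
    wilcoxon_signed_rank,
)
from plaquemetry.synthetic import make_breakpoint_records

# ---------------------------------------------------------------- oracles


def oracle_spearman(x, y):
    """Pearson correlation of midranks."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def oracle_wilcoxon_p(d):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


def oracle_friedman_perm_p(blocks):
    """Permutation p-value with an independently coded statistic."""
    blocks = np.asarray(blocks, float)
    n, k = blocks.shape

    def stat(mat):
        ranks = np.array([sps.rankdata(row) for row in mat])
        rj = ranks.sum(axis=0)
        s = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)
        ties = sum(float(np.sum(c**3 - c)) for _, c in
                   (np.unique(row, return_counts=True) for row in mat))
        cf = 1 - ties / (n * k * (k * k - 1))
        return s / cf if cf > 0 else 0.0

    obs = stat(blocks)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for choice in itertools.product(perms, repeat=n):
        mat = np.array([blocks[i, list(p)] for i, p in enumerate(choice)])
        if stat(mat) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def oracle_passing_bablok_slope(x, y):
    """All-pairs median slope with the K shift, by direct enumeration."""
    slopes = []
    k = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            s = np.inf * np.sign(dy) if dx == 0 else dy / dx
            if s == -1:
                continue
            slopes.append(s)
            if s < -1:
                k += 1
    slopes.sort()
    m = len(slopes)
    if m % 2 == 1:
        return slopes[(m + 1) // 2 + k - 1]
    return 0.5 * (slopes[m // 2 + k - 1] + slopes[m // 2 + k])


def oracle_auc(scores, labels):
    """Concordant-pair counting with half credit for ties."""
    pos = scores[labels]
    neg = scores[~labels]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            conc += 1.0 if p > q else (0.5 if p == q else 0.0)
            total += 1
    return conc / total


# ------------------------------------------------------------- elementary


def test_shapiro_wilk_calibration():
    """Type-I rate near the nominal 5%; near-certain rejection of exponential."""
    rng = np.random.default_rng(0)
    normal_ok = sum(shapiro_wilk(rng.normal(size=100))[1] > 0.05 for _ in range(200))
    rng = np.random.default_rng(0)
    expo_rej = sum(shapiro_wilk(rng.exponential(size=100))[1] < 0.05 for _ in range(200))
    assert normal_ok >= 180  # ~95% expected, binomial slack
    assert expo_rej >= 195


def test_shapiro_wilk_degenerate_cases():
    with pytest.raises(ValidationError):
        shapiro_wilk(np.array([1.0, 2.0]))
    w, p = shapiro_wilk(np.full(10, 3.0))  # constant: flagged, not crashed
    assert math.isnan(p)


def test_spearman_monotone_extremes():
    x = np.arange(10.0)
    assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
    assert spearman(x, -(x**3))[0] == pytest.approx(-1.0)


def test_spearman_matches_midrank_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        x = rng.integers(0, 4, size=6).astype(float)  # ties likely
        y = rng.integers(0, 4, size=6).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(oracle_spearman(x, y), abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.integers(-1000, 1000), min_size=6, max_size=30, unique=True))
def test_spearman_invariant_under_monotone_transform(xs):
    x = np.array(xs, dtype=float)
    rng = np.random.default_rng(0)
    y = rng.permutation(len(x)).astype(float)
    r1, _ = spearman(x, y)
    r2, _ = spearman(3 * x - 7, y)  # strictly monotone transform of x
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_friedman_identical_columns():
    chi2, p = friedman(np.tile(np.arange(5.0)[:, None], (1, 3)))
    assert chi2 == 0.0
    assert p == 1.0


def test_friedman_separated_columns():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(30, 1))
    blocks = np.hstack([base, base + 10, base + 20])
    chi2, p = friedman(blocks)
    assert p < 0.001


def test_friedman_matches_permutation_oracle():
    rng = np.random.default_rng(7)
    for _ in range(5):
        blocks = rng.integers(0, 5, size=(5, 3)).astype(float)
        _, p = friedman(blocks)
        assert p == pytest.approx(oracle_friedman_perm_p(blocks), abs=0.005)


def test_friedman_incomplete_blocks_rejected():
    b = np.ones((4, 3))
    b[0, 0] = np.nan
    with pytest.raises(ValidationError):
        friedman(b)


def test_wilcoxon_identical_pairs():
    x = np.arange(10.0)
    res = wilcoxon_signed_rank(x, x)
    assert res["p"] == 1.0
    assert res["degenerate"]


def test_wilcoxon_matches_enumeration_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        d = rng.integers(-5, 6, size=8).astype(float)
        if (d == 0).all():
            continue
        res = wilcoxon_signed_rank(d, np.zeros(8))
        assert res["p"] == pytest.approx(oracle_wilcoxon_p(d), abs=1e-12)


def test_wilcoxon_matches_scipy_exact_when_no_ties():
    rng = np.random.default_rng(8)
    x = rng.normal(size=15)
    y = rng.normal(size=15)
    res = wilcoxon_signed_rank(x, y)
    ref = sps.wilcoxon(x, y, method="exact")
    assert res["p"] == pytest.approx(ref.pvalue, abs=1e-10)


def test_bonferroni_family_size():
    rng = np.random.default_rng(0)
    measures = {m: rng.normal(size=12) for m in ("a", "b", "c", "d")}
    out = wilcoxon_pairwise_bonferroni(measures)
    assert len(out) == 6  # 4 measures -> 6 pairwise tests
    for res in out.values():
        assert res["m"] == 6
        assert res["p_adjusted"] == pytest.approx(min(1.0, 6 * res["p"]))


# --------------------------------------------------------- Passing-Bablok


def test_passing_bablok_identity_line():
    x = np.arange(10.0)
    r = passing_bablok(x, x, use_zscores=False)
    assert r.slope == pytest.approx(1.0)
    assert r.intercept == pytest.approx(0.0, abs=1e-12)
    assert not r.proportional_bias
    assert not r.constant_bias


def test_passing_bablok_affine_line():
    x = np.arange(12.0)
    r = passing_bablok(x, 2 * x + 1, use_zscores=False)
    assert r.slope == pytest.approx(2.0)
    assert r.intercept == pytest.approx(1.0)


def test_passing_bablok_matches_enumeration_oracle():
    rng = np.random.default_rng(11)
    for _ in range(20):
        x = rng.normal(size=12)
        y = 1.3 * x + rng.normal(scale=0.5, size=12)
        r = passing_bablok(x, y, use_zscores=False)
        assert r.slope == pytest.approx(oracle_passing_bablok_slope(x, y), abs=1e-12)


def test_passing_bablok_scale_equivariant():
    rng = np.random.default_rng(13)
    x = rng.normal(size=20)
    y = 0.8 * x + rng.normal(scale=0.3, size=20)
    r1 = passing_bablok(x, y, use_zscores=False)
    r2 = passing_bablok(5 * x, 5 * y, use_zscores=False)
    assert r1.slope == pytest.approx(r2.slope, abs=1e-12)
    # z-scoring makes the fit invariant to affine rescaling of either variable
    r3 = passing_bablok(x, y, use_zscores=True)
    r4 = passing_bablok(3 * x - 7, 0.5 * y + 2, use_zscores=True)
    assert r3.slope == pytest.approx(r4.slope, abs=1e-12)


def test_passing_bablok_small_n_rejected():
    with pytest.raises(ValidationError):
        passing_bablok(np.arange(5.0), np.arange(5.0))


# -------------------------------------------------------------------- ROC


def test_auc_perfect_separation():
    scores = np.r_[np.zeros(10), np.ones(10)]
    labels = np.r_[np.zeros(10, bool), np.ones(10, bool)]
    assert roc_auc(scores, labels)[2] == 1.0


def test_auc_random_scores_near_half():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=2000)
    labels = rng.random(2000) < 0.5
    _, _, auc = roc_auc(scores, labels)
    assert 0.47 <= auc <= 0.53


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(2)
    for _ in range(20):
        scores = rng.integers(0, 5, size=8).astype(float)
        labels = rng.random(8) < 0.5
        if labels.all() or not labels.any():
            continue
        _, _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(oracle_auc(scores, labels), abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=30)
    labels = rng.random(30) < 0.5
    if labels.all() or not labels.any():
        return
    a1 = roc_auc(scores, labels)[2]
    a2 = roc_auc(np.exp(scores), labels)[2]
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_roc_analysis_skips_empty_class(caplog):
    vpi = np.arange(20.0)
    coverage = np.full(20, 5.0)  # never reaches 10/25/50
    with caplog.at_level("WARNING"):
        out = roc_analysis(vpi, coverage, StatConfig())
    assert out == []


# ------------------------------------------------------------ sample size


@pytest.mark.parametrize("r,expected", [(0.66, 15), (0.5, 29)])
def test_sample_size_formula(r, expected):
    assert sample_size_correlation(r, 0.05, 0.2) == expected


def test_sample_size_limit_and_domain():
    assert sample_size_correlation(0.9999) == 3
    with pytest.raises(ValidationError):
        sample_size_correlation(1.2)
    with pytest.raises(ValidationError):
        sample_size_correlation(-0.1)


# ------------------------------------------------------------- breakpoint


def test_breakpoint_recovery_clean():
    rec = make_breakpoint_records(n=200, seed=0, noise_sd=0.01)
    m = fit_breakpoint(rec.plani_tot, rec.vpi)
    assert m.has_breakpoint
    assert abs(m.breakpoint - 32.5) <= 2.0
    assert m.slope_above / m.slope_below == pytest.approx(2.0, abs=0.1)


def test_single_line_flagged():
    """Pure (noiseless) linear data returns the single-line model flagged."""
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 100, 100)
    m = fit_breakpoint(x, 0.02 * x + 1.0)
    assert not m.has_breakpoint
    assert m.slope_below == pytest.approx(0.02)


def test_breakpoint_bootstrap_covers_truth():
    import pandas as pd

    rec = make_breakpoint_records(n=150, seed=3, noise_sd=0.2)
    df = pd.DataFrame({"plani_tot": rec.plani_tot, "vpi": rec.vpi, "subject_id": "S"})
    m = contribution_breakpoint(df, bootstrap=50, seed=0)
    assert m.breakpoint_ci is not None
    lo, hi = m.breakpoint_ci
    assert lo <= 32.5 <= hi


def test_crossing_point_of_component_fits():
    tot = np.linspace(5, 95, 50)
    dark = 0.8 * tot - 16.0  # crosses light at tot = 40
    light = 0.2 * tot + 8.0
    assert crossing_point(tot, dark, light) == pytest.approx(40.0)
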