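"""Method-comparison statistics for clinical, planimetric and volumetric indices.

Implements the comparison plan used to relate the TMQHPlI, the
planimetric measures (PLANItot, PLANIdark, PLANIlight, PLANIvolmap) and
the volumetric measures (VPI, AVPI) on per-surface records:

* Shapiro-Wilk normality screening (scipy-backed),
* tie-corrected Friedman test across the four planimetric measures with
  Wilcoxon signed-rank post-hoc tests under Bonferroni correction,
* Spearman rank correlations,
* Passing-Bablok method-comparison regression on z-scored variables,
* ROC analysis of the VPI against dichotomized planimetric coverage,
* the Fisher-z sample-size formula for a correlation study, and
* a two-segment (breakpoint) model of volume vs. coverage separating the
  lateral-spread and vertical-thickening growth regimes.

Surfaces are treated as independent, non-nested observations; an optional
subject-level bootstrap is available for the breakpoint CI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError

log = logging.getLogger(__name__)


@dataclass
class StatConfig:
    alpha: float = 0.05
    beta: float = 0.2
    bonferroni_m: int | None = None  # default: number of pairwise tests performed
    roc_dichotomizations: tuple[float, ...] = (10.0, 25.0, 50.0)  # % coverage
    percentile_split: bool = False  # alternative ROC dichotomization semantics
    pb_use_zscores: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValidationError("alpha and beta must lie in (0, 1)")
        if self.bonferroni_m is not None and self.bonferroni_m < 1:
            raise ValidationError("bonferroni_m must be >= 1")


# -- elementary tests ------------------------------------------------------


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p. Constant input returns (1, nan) flagged by warning."""
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValidationError("missing values not allowed in Shapiro-Wilk input")
    if len(x) < 3:
        raise ValidationError("Shapiro-Wilk needs n >= 3")
    if len(x) > 5000:
        raise ValidationError("Shapiro-Wilk p-value unreliable for n > 5000")
    if np.ptp(x) == 0:
        log.warning("Shapiro-Wilk on constant data: normality undefined")
        return 1.0, float("nan")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with two-sided p.

    Pairs with a missing value in either variable are dropped
    (pairwise-complete).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 5:
        raise ValidationError("Spearman needs at least 5 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("Spearman undefined: zero rank variance")
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _friedman_statistic(ranks: np.ndarray, c: float, n: int, k: int) -> float:
    rj = ranks.sum(axis=0)
    stat = (12.0 / (n * k * (k + 1))) * float(np.sum(rj**2)) - 3.0 * n * (k + 1)
    return stat / c


def friedman(blocks: np.ndarray, exact_max_perms: int = 100_000) -> tuple[float, float]:
    """Tie-corrected Friedman test on an (n blocks x k measures) matrix.

    Ranks within each block use midranks; the statistic is divided by the
    tie-correction factor C = 1 - sum(t^3 - t)/(n k (k^2-1)). For small
    problems (k!^n <= ``exact_max_perms``) the p-value is exact, from full
    enumeration of the within-block permutation null; otherwise it is the
    chi-square tail with k-1 df. All-tied data (C = 0) gives chi2 = 0,
    p = 1.
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2 or blocks.shape[1] < 3:
        raise ValidationError("Friedman needs an n x k matrix with k >= 3")
    if np.isnan(blocks).any():
        raise ValidationError("Friedman requires complete blocks (no imputation)")
    n, k = blocks.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, blocks)
    tie_sum = 0.0
    for row in blocks:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    c = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if c <= 0:
        return 0.0, 1.0
    stat = _friedman_statistic(ranks, c, n, k)

    if math.factorial(k) ** n <= exact_max_perms:
        from itertools import permutations, product

        perms = list(permutations(range(k)))
        block_variants = [np.array([row[list(p)] for p in perms]) for row in ranks]
        count = 0
        total = 0
        for choice in product(range(len(perms)), repeat=n):
            r = np.array([block_variants[i][ci] for i, ci in enumerate(choice)])
            if _friedman_statistic(r, c, n, k) >= stat - 1e-12:
                count += 1
            total += 1
        return float(stat), count / total

    return float(stat), float(sps.chi2.sf(stat, k - 1))


# -- Wilcoxon signed-rank --------------------------------------------------


def _signed_rank_exact_p(r2: np.ndarray, w2: float) -> float:
    """Exact two-sided p for the signed-rank sum, via the shift algorithm.

    ``r2`` are doubled midranks (integers even with ties), ``w2`` the
    doubled observed positive-rank sum. Enumerates the null distribution
    of the sum over all 2^n sign assignments by polynomial convolution.
    """
    r2 = np.asarray(np.rint(r2), dtype=np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2i = int(np.rint(w2))
    p_le = dist[: w2i + 1].sum()
    p_ge = dist[w2i:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray, exact_max_n: int = 25) -> dict:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped. For n <= ``exact_max_n`` non-zero pairs
    the exact null distribution is used (shift algorithm on doubled
    midranks, valid with ties); above, the normal approximation with tie
    correction and continuity correction. All differences zero returns
    p = 1 flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return {"statistic": 0.0, "p": 1.0, "n": 0, "degenerate": True, "method": "degenerate"}
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _signed_rank_exact_p(2 * ranks, 2 * w_plus)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            return {"statistic": w_plus, "p": 1.0, "n": n, "degenerate": True, "method": "approx"}
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "approx"
    return {"statistic": w_plus, "p": min(1.0, p), "n": n, "degenerate": False, "method": method}


def wilcoxon_pairwise_bonferroni(
    measures: dict[str, np.ndarray], pairs: list[tuple[str, str]] | None = None, m: int | None = None
) -> dict[tuple[str, str], dict]:
    """Pairwise signed-rank tests with Bonferroni-adjusted p-values.

    ``m`` defaults to the number of pairwise comparisons actually
    performed (post-hoc family), not a global count.
    """
    names = list(measures)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = m or len(pairs)
    out = {}
    for a, b in pairs:
        res = wilcoxon_signed_rank(measures[a], measures[b])
        res["p_adjusted"] = min(1.0, m * res["p"])
        res["m"] = m
        out[(a, b)] = res
    return out


# -- Passing-Bablok --------------------------------------------------------


@dataclass
class PassingBablokResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int
    proportional_bias: bool = field(init=False)
    constant_bias: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (self.slope_ci[0] <= self.slope <= self.slope_ci[1] + 1e-12):
            raise ValidationError("slope outside its own CI")
        self.proportional_bias = not (self.slope_ci[0] <= 1.0 <= self.slope_ci[1])
        self.constant_bias = not (self.intercept_ci[0] <= 0.0 <= self.intercept_ci[1])


def passing_bablok(
    x: np.ndarray, y: np.ndarray, use_zscores: bool = True, alpha: float = 0.05
) -> PassingBablokResult:
    """Passing-Bablok method-comparison regression.

    The slope is the shifted median of all pairwise slopes
    S_ij = (y_j - y_i)/(x_j - x_i), i < j, excluding undefined (0/0) and
    exactly -1 slopes; the shift K counts slopes below -1 so the estimator
    is invariant to swapping the methods. The CI uses the binomial
    rank-quantile method; the intercept is median(y - b x) with its CI from
    the slope CI bounds. With ``use_zscores`` both variables are first
    standardized to mean 0 / SD 1, making the comparison scale-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 10:
        raise ValidationError("Passing-Bablok needs n >= 10 complete pairs")
    if np.ptp(x) == 0:
        raise ValidationError("all x values equal")
    if use_zscores:
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)

    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = dy / dx
    # undefined slopes: 0/0 (identical points); x-ties with dy != 0 give +-inf,
    # which sort to the extremes and behave as in the original procedure
    s = s[~((dx == 0) & (dy == 0))]
    s = s[s != -1.0]
    s = np.sort(s[~np.isnan(s)])
    n_slopes = len(s)
    if n_slopes < 10:
        raise ValidationError("fewer than 10 finite pairwise slopes")

    k_shift = int(np.sum(s < -1.0))
    b = _shifted_median(s, k_shift)

    z = sps.norm.ppf(1 - alpha / 2)
    w = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((n_slopes - w) / 2.0))
    m2 = n_slopes - m1 + 1
    lo_idx = np.clip(m1 + k_shift - 1, 0, n_slopes - 1)  # 1-based -> 0-based
    hi_idx = np.clip(m2 + k_shift - 1, 0, n_slopes - 1)
    b_lo, b_hi = float(s[lo_idx]), float(s[hi_idx])

    a = float(np.median(y - b * x))
    a_lo = float(np.median(y - b_hi * x))
    a_hi = float(np.median(y - b_lo * x))
    return PassingBablokResult(
        slope=float(b),
        intercept=a,
        slope_ci=(b_lo, b_hi),
        intercept_ci=(min(a_lo, a_hi), max(a_lo, a_hi)),
        n=n,
    )


def _shifted_median(sorted_slopes: np.ndarray, k_shift: int) -> float:
    n = len(sorted_slopes)
    if n % 2 == 1:
        idx = (n + 1) // 2 + k_shift - 1
        return float(sorted_slopes[np.clip(idx, 0, n - 1)])
    i1 = np.clip(n // 2 + k_shift - 1, 0, n - 1)
    i2 = np.clip(n // 2 + k_shift, 0, n - 1)
    return float(0.5 * (sorted_slopes[i1] + sorted_slopes[i2]))


# -- ROC -------------------------------------------------------------------


@dataclass
class ROCResult:
    auc: float
    threshold: float  # the coverage dichotomization (%)
    n_positive: int
    n_negative: int
    fpr: np.ndarray
    tpr: np.ndarray


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC curve and AUC via the rank (Mann-Whitney) identity.

    Ties in scores are handled by midranks (equivalent to counting tied
    score pairs as half-concordant).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("ROC needs both classes non-empty")
    ranks = sps.rankdata(scores)
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(~sorted_labels)[distinct]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    return fpr, tpr, float(auc)


def roc_analysis(
    vpi: np.ndarray, coverage: np.ndarray, config: StatConfig | None = None
) -> list[ROCResult]:
    """ROC of the VPI as test variable against dichotomized coverage.

    Coverage (%) is dichotomized at each configured threshold: the default
    semantics are absolute coverage thresholds (plaque covering >= 10, 25,
    50% of the surface); ``percentile_split`` instead splits at the
    empirical coverage percentiles. Dichotomizations leaving one class
    empty are skipped with a warning.
    """
    config = config or StatConfig()
    vpi = np.asarray(vpi, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    ok = np.isfinite(vpi) & np.isfinite(coverage)
    vpi, coverage = vpi[ok], coverage[ok]
    out: list[ROCResult] = []
    for t in config.roc_dichotomizations:
        cut = float(np.percentile(coverage, t)) if config.percentile_split else float(t)
        labels = coverage >= cut
        if labels.all() or not labels.any():
            log.warning("dichotomization at %s%% leaves one class empty; skipped", t)
            continue
        fpr, tpr, auc = roc_auc(vpi, labels)
        out.append(
            ROCResult(
                auc=auc, threshold=float(t),
                n_positive=int(labels.sum()), n_negative=int((~labels).sum()),
                fpr=fpr, tpr=tpr,
            )
        )
    return out


# -- sample size -----------------------------------------------------------


def sample_size_correlation(r: float, alpha: float = 0.05, beta: float = 0.2) -> int:
    """Subjects needed to detect correlation ``r`` (Fisher-z formula).

    n = ((z_{1-alpha/2} + z_{1-beta}) / atanh(r))^2 + 3, rounded to the
    nearest integer.
    """
    if not (0 < r < 1):
        raise ValidationError("r must lie strictly between 0 and 1")
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ValidationError("alpha and beta must lie in (0, 1)")
    za = sps.norm.ppf(1 - alpha / 2)
    zb = sps.norm.ppf(1 - beta)
    n = ((za + zb) / math.atanh(r)) ** 2 + 3
    return int(round(n))


# -- growth-regime breakpoint ---------------------------------------------


@dataclass
class BreakpointModel:
    """Two-segment continuous piecewise-linear fit of volume vs. coverage."""

    breakpoint: float | None  # % coverage; None if no breakpoint improves the fit
    slope_below: float
    slope_above: float
    intercept: float
    rss: float
    single_line_rss: float
    slope_dark: float | None = None
    slope_light: float | None = None
    slope_ratio: float | None = None
    breakpoint_ci: tuple[float, float] | None = None

    @property
    def has_breakpoint(self) -> bool:
        return self.breakpoint is not None


def _two_segment_fit(x: np.ndarray, y: np.ndarray, c: float) -> tuple[np.ndarray, float]:
    design = np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((design @ coef - y) ** 2))
    return coef, rss


def fit_breakpoint(
    x: np.ndarray,
    y: np.ndarray,
    n_candidates: int = 41,
    min_improvement: float = 0.01,
) -> BreakpointModel:
    """Continuous two-segment least squares with grid search over breakpoints.

    Candidate breakpoints are data quantiles (10th to 90th percentile);
    if no candidate reduces the residual sum of squares by more than
    ``min_improvement`` relative to a single line, a single-line model is
    returned flagged (breakpoint None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 20:
        raise ValidationError("breakpoint fit needs at least 20 records")
    design1 = np.column_stack([np.ones_like(x), x])
    coef1, *_ = np.linalg.lstsq(design1, y, rcond=None)
    rss1 = float(np.sum((design1 @ coef1 - y) ** 2))
    if rss1 <= 1e-12 * max(1.0, float(np.sum(y**2))):
        # an exact line: no breakpoint can improve on it
        return BreakpointModel(
            breakpoint=None, slope_below=float(coef1[1]), slope_above=float(coef1[1]),
            intercept=float(coef1[0]), rss=rss1, single_line_rss=rss1,
        )

    candidates = np.quantile(x, np.linspace(0.10, 0.90, n_candidates))
    best_c, best_coef, best_rss = None, None, np.inf
    for c in np.unique(candidates):
        if np.sum(x < c) < 3 or np.sum(x > c) < 3:
            continue
        coef, rss = _two_segment_fit(x, y, float(c))
        if rss < best_rss:
            best_c, best_coef, best_rss = float(c), coef, rss
    if best_c is None or best_rss > (1.0 - min_improvement) * rss1:
        return BreakpointModel(
            breakpoint=None,
            slope_below=float(coef1[1]),
            slope_above=float(coef1[1]),
            intercept=float(coef1[0]),
            rss=rss1,
            single_line_rss=rss1,
        )
    assert best_coef is not None
    return BreakpointModel(
        breakpoint=best_c,
        slope_below=float(best_coef[1]),
        slope_above=float(best_coef[1] + best_coef[2]),
        intercept=float(best_coef[0]),
        rss=best_rss,
        single_line_rss=rss1,
    )


def contribution_breakpoint(
    records: pd.DataFrame,
    x_col: str = "plani_tot",
    y_col: str = "vpi",
    bootstrap: int = 0,
    seed: int = 0,
    subject_col: str = "subject_id",
    subject_bootstrap: bool = False,
) -> BreakpointModel:
    """Breakpoint model of VPI vs. total planimetric coverage.

    Also fits the separate linear models VPI ~ PLANIdark and
    VPI ~ PLANIlight and reports their slope ratio (dark/light) — the
    volume gained per unit of mature vs. newly-formed coverage. Optional
    bootstrap (surface-level by default, subject-level with
    ``subject_bootstrap``) attaches a percentile CI to the breakpoint.
    """
    df = records[np.isfinite(records[x_col]) & np.isfinite(records[y_col])]
    df = df[df[x_col] > 0]
    model = fit_breakpoint(df[x_col].to_numpy(), df[y_col].to_numpy())

    def _slope(col: str) -> float | None:
        sub = df[np.isfinite(df[col])]
        if len(sub) < 3 or np.ptp(sub[col].to_numpy()) == 0:
            return None
        coef = np.polyfit(sub[col].to_numpy(), sub[y_col].to_numpy(), 1)
        return float(coef[0])

    model.slope_dark = _slope("plani_dark") if "plani_dark" in df else None
    model.slope_light = _slope("plani_light") if "plani_light" in df else None
    if model.slope_dark is not None and model.slope_light not in (None, 0.0):
        model.slope_ratio = model.slope_dark / model.slope_light  # type: ignore[operator]

    if bootstrap > 0 and model.has_breakpoint:
        rng = np.random.default_rng(seed)
        bps = []
        subjects = df[subject_col].unique() if subject_bootstrap and subject_col in df else None
        for _ in range(bootstrap):
            if subjects is not None:
                chosen = rng.choice(subjects, size=len(subjects), replace=True)
                sample = pd.concat([df[df[subject_col] == s] for s in chosen])
            else:
                sample = df.sample(n=len(df), replace=True, random_state=rng.integers(2**31))
            try:
                m = fit_breakpoint(sample[x_col].to_numpy(), sample[y_col].to_numpy())
            except ValidationError:
                continue
            if m.has_breakpoint:
                bps.append(m.breakpoint)
        if len(bps) >= 10:
            model.breakpoint_ci = (float(np.percentile(bps, 2.5)), float(np.percentile(bps, 97.5)))
    return model


def crossing_point(plani_tot: np.ndarray, plani_dark: np.ndarray, plani_light: np.ndarray) -> float | None:
    """Coverage at which the PLANIdark and PLANIlight linear fits intersect.

    Alternative reading of the growth-regime threshold: fit each
    component's coverage against total coverage with a line and intersect
    the two fits.
    """
    plani_tot = np.asarray(plani_tot, dtype=float)
    d_coef = np.polyfit(plani_tot, np.asarray(plani_dark, dtype=float), 1)
    l_coef = np.polyfit(plani_tot, np.asarray(plani_light, dtype=float), 1)
    denom = d_coef[0] - l_coef[0]
    if abs(denom) < 1e-12:
        return None
    return float((l_coef[1] - d_coef[1]) / denom)


# -- full report -----------------------------------------------------------

PLANIMETRIC_MEASURES = ("plani_tot", "plani_dark", "plani_light", "plani_volmap")
ALL_MEASURES = PLANIMETRIC_MEASURES + ("vpi", "avpi", "tmqhpli_tdp_mean", "tmqhpli_ddp_mean")


def full_report(records: pd.DataFrame, config: StatConfig | None = None, seed: int = 0) -> dict:
    """Run the complete comparison plan on a per-surface record table.

    Returns a JSON-serializable dict: normality screen, Friedman +
    Bonferroni-corrected pairwise Wilcoxon over the four planimetric
    measures, Spearman and Passing-Bablok (z-scored) matrices over all
    measure pairs, ROC of VPI vs dichotomized coverage, and the
    growth-regime breakpoint model.
    """
    config = config or StatConfig()
    measures = [m for m in ALL_MEASURES if m in records.columns]
    report: dict = {"n_surfaces": int(len(records)), "measures": measures}

    report["shapiro_wilk"] = {}
    for m in measures:
        x = records[m].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if len(x) >= 3:
            w, p = shapiro_wilk(x)
            report["shapiro_wilk"][m] = {"W": w, "p": p}

    plani = [m for m in PLANIMETRIC_MEASURES if m in records.columns]
    if len(plani) >= 3:
        block = records[plani].to_numpy(dtype=float)
        block = block[np.isfinite(block).all(axis=1)]
        if len(block) >= 3:
            chi2, p = friedman(block)
            report["friedman"] = {"chi2": chi2, "p": p, "k": len(plani), "n": int(len(block))}
            cols = {m: block[:, i] for i, m in enumerate(plani)}
            pw = wilcoxon_pairwise_bonferroni(cols, m=config.bonferroni_m)
            report["wilcoxon_pairwise"] = {
                f"{a}|{b}": {k: v for k, v in res.items()} for (a, b), res in pw.items()
            }

    report["spearman"] = {}
    report["passing_bablok"] = {}
    for i, a in enumerate(measures):
        for b in measures[i + 1 :]:
            xa = records[a].to_numpy(dtype=float)
            xb = records[b].to_numpy(dtype=float)
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() >= 5 and np.ptp(xa[ok]) > 0 and np.ptp(xb[ok]) > 0:
                rho, p = spearman(xa[ok], xb[ok])
                report["spearman"][f"{a}|{b}"] = {"rho": rho, "p": p, "n": int(ok.sum())}
            if ok.sum() >= 10 and np.ptp(xa[ok]) > 0:
                try:
                    pb = passing_bablok(xa[ok], xb[ok], use_zscores=config.pb_use_zscores, alpha=config.alpha)
                except ValidationError:
                    continue
                report["passing_bablok"][f"{a}|{b}"] = {
                    "slope": pb.slope,
                    "intercept": pb.intercept,
                    "slope_ci": list(pb.slope_ci),
                    "intercept_ci": list(pb.intercept_ci),
                    "proportional_bias": pb.proportional_bias,
                    "constant_bias": pb.constant_bias,
                    "n": pb.n,
                }

    if "vpi" in records.columns and "plani_tot" in records.columns:
        rocs = roc_analysis(
            records["vpi"].to_numpy(dtype=float), records["plani_tot"].to_numpy(dtype=float), config
        )
        report["roc"] = [
            {"threshold_pct": r.threshold, "auc": r.auc, "n_positive": r.n_positive, "n_negative": r.n_negative}
            for r in rocs
        ]
        finite = records[np.isfinite(records["plani_tot"]) & np.isfinite(records["vpi"])]
        if len(finite[finite["plani_tot"] > 0]) >= 20:
            bp = contribution_breakpoint(records, seed=seed)
            report["breakpoint"] = {
                "breakpoint_pct": bp.breakpoint,
                "slope_below": bp.slope_below,
                "slope_above": bp.slope_above,
                "slope_dark": bp.slope_dark,
                "slope_light": bp.slope_light,
                "slope_ratio": bp.slope_ratio,
            }
    return report
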