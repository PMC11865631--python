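"""Inter-observer agreement and factorial statistics.

Implements, directly from their defining formulas, the statistics used
to assess two-observer reproducibility of ordinal wave-quality scores
and continuous stiffness measurements, and the non-parametric factorial
analysis of a repeated-measures design:

* Cohen's kappa (unweighted) with the conventional qualitative bands
  (poor / slight / fair / moderate / substantial / almost perfect);
* two-way mixed-model ICC, single-rater consistency form ICC(3,1)
  (absolute agreement available behind a flag), banded with the
  Koo & Li cut-points;
* Bland-Altman bias, SD of differences, limits of agreement
  LoA = 1.96 * SD, upper/lower bounds bias +/- LoA, and a t-based CI
  for the bias;
* coefficient of variation of paired measurements (per-pair sample SD
  over pair mean, averaged, as a percentage);
* Friedman's rank test with mid-rank tie correction;
* pairwise Wilcoxon signed-rank tests (exact null distribution for
  n <= 12 after zero removal, normal approximation with continuity and
  tie corrections otherwise) with Bonferroni adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm, rankdata, t as t_dist

__all__ = [
    "AgreementReport",
    "FactorialResult",
    "cohens_kappa",
    "kappa_band",
    "icc_two_way_mixed",
    "icc_band",
    "bland_altman",
    "cv_percent",
    "friedman_test",
    "wilcoxon_signed_rank",
    "pairwise_wilcoxon_bonferroni",
    "agreement_report",
]

_KAPPA_BANDS = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)

_ICC_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))


def kappa_band(kappa: float) -> str:
    """Qualitative agreement label for a kappa value."""
    if kappa <= 0:
        return "poor"
    for upper, label in _KAPPA_BANDS[1:]:
        if kappa <= upper + 1e-12:
            return label
    return "almost perfect"


def icc_band(icc: float) -> str:
    """Koo & Li qualitative reliability label for an ICC value."""
    for upper, label in _ICC_BANDS:
        if icc < upper:
            return label
    return "excellent"


def cohens_kappa(
    ratings_a, ratings_b, categories=None
) -> tuple[float, str]:
    """Unweighted Cohen's kappa between two raters, with its band label.

    kappa = (p_o - p_e) / (1 - p_e), where p_o is the observed
    proportion of agreement and p_e the chance agreement from the
    raters' marginal category frequencies.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be 1D vectors of equal length")
    if a.size == 0:
        raise ValueError("empty ratings")
    if categories is None:
        categories = np.unique(np.concatenate([a, b]))
    categories = list(categories)
    p_o = float(np.mean(a == b))
    n = a.size
    p_e = sum(
        (np.sum(a == c) / n) * (np.sum(b == c) / n) for c in categories
    )
    if p_e >= 1.0 - 1e-12:
        raise ValueError("chance agreement p_e = 1: kappa undefined "
                         "(all ratings in a single category)")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return float(kappa), kappa_band(kappa)


def icc_two_way_mixed(matrix, absolute_agreement: bool = False) -> float:
    """Two-way mixed-model, single-rater ICC of a subjects x raters table.

    Default is the consistency form ICC(3,1) =
    (MS_rows - MS_err) / (MS_rows + (k - 1) MS_err) from the two-way
    ANOVA decomposition (subjects x raters, no replication).  With
    *absolute_agreement* the rater variance enters the denominator
    (ICC(A,1) for fixed raters).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2D (subjects x raters)")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not supported")
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero total variance: ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if absolute_agreement:
        denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    else:
        denom = ms_rows + (k - 1) * ms_err
    if denom == 0:
        raise ValueError("degenerate ANOVA decomposition: ICC undefined")
    return float((ms_rows - ms_err) / denom)


@dataclass
class BlandAltman:
    bias: float
    sd_diff: float
    loa: float
    ub: float
    lb: float
    bias_ci: tuple[float, float]


def bland_altman(pairs) -> BlandAltman:
    """Bland-Altman agreement of paired measurements.

    Differences d_i = a_i - b_i; bias = mean(d); LoA = 1.96 * sample SD;
    ub/lb = bias +/- LoA; the bias CI uses the t distribution with
    n - 1 degrees of freedom.
    """
    p = np.asarray(pairs, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
        raise ValueError("need >= 2 (a, b) pairs")
    d = p[:, 0] - p[:, 1]
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = 1.96 * sd
    half = t_dist.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa=loa,
        ub=bias + loa,
        lb=bias - loa,
        bias_ci=(bias - half, bias + half),
    )


def cv_percent(pairs, pooled: bool = False) -> float:
    """Coefficient of variation of paired measurements, in percent.

    Default: per pair, CV_i = sample SD(a_i, b_i) / mean(a_i, b_i)
    (= |a_i - b_i| / (sqrt(2) mean)), averaged over pairs and scaled to
    percent.  With *pooled*, the SD of all differences over the grand
    mean is used instead.
    """
    p = np.asarray(pairs, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 1:
        raise ValueError("need >= 1 (a, b) pair")
    means = p.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("pair means must be positive for a CV")
    if pooled:
        d = p[:, 0] - p[:, 1]
        return float(100.0 * d.std(ddof=1) / means.mean())
    sds = np.abs(p[:, 0] - p[:, 1]) / math.sqrt(2.0)
    return float(100.0 * np.mean(sds / means))


@dataclass
class FactorialResult:
    """Friedman test plus Bonferroni-adjusted pairwise comparisons."""

    friedman_chi2: float
    df: int
    p: float
    pairwise: dict[tuple, float]


def friedman_test(matrix) -> tuple[float, int, float]:
    """Friedman rank test of a complete subjects x conditions block design.

    Within-subject mid-ranks with the standard tie correction; the
    statistic is referred to the chi-squared distribution with k - 1
    degrees of freedom.  Identical columns give chi2 = 0, p = 1.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2D (subjects x conditions)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(x)):
        raise ValueError("incomplete blocks are not supported")
    ranks = np.vstack([rankdata(row) for row in x])
    col_sums = ranks.sum(axis=0)
    stat = (12.0 / (n * k * (k + 1))) * float(
        ((col_sums - n * (k + 1) / 2.0) ** 2).sum()
    )
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:
        # every block fully tied: no information, no effect
        return 0.0, k - 1, 1.0
    stat /= correction
    df = k - 1
    return float(stat), df, float(chi2.sf(stat, df))


def wilcoxon_signed_rank(a, b, exact_max_n: int = 12) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded (Wilcoxon's original treatment);
    ties among |d| receive mid-ranks.  For n <= *exact_max_n* remaining
    pairs the null distribution is enumerated over all 2^n sign
    assignments of the observed ranks; otherwise the normal
    approximation with continuity and tie corrections is used.  All
    differences zero returns p = 1.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w_small = min(w_pos, total - w_pos)
    if n <= exact_max_n:
        count = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = float(np.dot(signs, ranks))
            if w <= w_small + 1e-9 or w >= total - w_small - 1e-9:
                count += 1
        return min(1.0, count / 2.0**n)
    mean = total / 2.0
    tie_term = 0.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_small - mean + 0.5) / math.sqrt(var)
    return float(min(1.0, 2.0 * norm.cdf(z)))


def pairwise_wilcoxon_bonferroni(
    matrix, condition_labels=None, pairs=None
) -> dict[tuple, float]:
    """Bonferroni-adjusted pairwise Wilcoxon tests between conditions.

    *matrix* is subjects x conditions; *pairs* is an iterable of column
    index pairs (default: all pairs).  Adjusted p = min(1, m * p_raw)
    with m the number of comparisons.
    """
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    if condition_labels is None:
        condition_labels = list(range(k))
    if pairs is None:
        pairs = list(itertools.combinations(range(k), 2))
    else:
        pairs = list(pairs)
    m = len(pairs)
    out: dict[tuple, float] = {}
    for i, j in pairs:
        p_raw = wilcoxon_signed_rank(x[:, i], x[:, j])
        out[(condition_labels[i], condition_labels[j])] = min(1.0, m * p_raw)
    return out


@dataclass
class AgreementReport:
    """Two-observer agreement summary for one study cell."""

    kappa: float | None
    kappa_band: str
    icc: float | None
    icc_band: str
    bias: float
    sd_diff: float
    loa: float
    ub: float
    lb: float
    cv_percent: float


def agreement_report(
    scores_a,
    scores_b,
    values_a,
    values_b,
    score_categories=(1, 2, 3, 4, 5),
) -> AgreementReport:
    """Assemble the per-cell agreement panel: kappa on ordinal scores,
    ICC / Bland-Altman / CV on continuous measurements.

    Degenerate kappa or ICC (no variance to agree on) is reported as
    ``None`` with band ``"undefined"`` rather than failing the cell.
    """
    try:
        k, k_band = cohens_kappa(scores_a, scores_b, categories=score_categories)
    except ValueError:
        k, k_band = None, "undefined"
    pairs = np.column_stack([values_a, values_b])
    try:
        icc = icc_two_way_mixed(pairs)
        i_band = icc_band(icc)
    except ValueError:
        icc, i_band = None, "undefined"
    try:
        ba = bland_altman(pairs)
    except ValueError:
        nan = float("nan")
        ba = BlandAltman(nan, nan, nan, nan, nan, (nan, nan))
    try:
        cv = cv_percent(pairs)
    except ValueError:
        cv = float("nan")
    return AgreementReport(
        kappa=k,
        kappa_band=k_band,
        icc=icc,
        icc_band=i_band,
        bias=ba.bias,
        sd_diff=ba.sd_diff,
        loa=ba.loa,
        ub=ba.ub,
        lb=ba.lb,
        cv_percent=cv,
    )
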