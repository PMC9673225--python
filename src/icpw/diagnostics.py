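"""Diagnostic-accuracy and group-comparison statistics.

AUROC is computed as tie-aware Mann-Whitney concordance; its variance and the
paired comparison of two AUROCs use the DeLong placement-value method.
Operating-point sensitivity/specificity carry Wilson 95% intervals.  Cohort
rows are compared with Pearson chi-square or Fisher's exact test (categorical,
dispatched on expected counts) and one-way ANOVA + Tukey or Kruskal-Wallis +
Dunn-Bonferroni (continuous, dispatched on a Shapiro-Wilk normality screen).
Sample size for a target AUROC against a null value uses the Hanley-McNeil
exponential-approximation variance.

The positivity convention is strict everywhere: a score counts as positive
only when it exceeds the cutoff.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidParameterError


# --------------------------------------------------------------------------
# ROC / AUROC
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    method: str = "delong"
    se: float = float("nan")
    degenerate: bool = False  # zero DeLong variance at auc in {0, 1}

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.auc <= self.ci_high <= 1):
            raise InvalidParameterError("CI must satisfy 0 <= low <= auc <= high <= 1")
        if self.n_pos < 1 or self.n_neg < 1:
            raise InvalidParameterError("both classes must be present")


@dataclass(frozen=True)
class ThresholdPerformance:
    cutoff: float
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    tp: int
    fp: int
    tn: int
    fn: int


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise InvalidParameterError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise InvalidParameterError("both classes must be present")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Tie-aware AUC and DeLong placement values via midranks (O(n log n))."""
    m, n = len(pos), len(neg)
    both = np.concatenate([pos, neg])
    r_all = stats.rankdata(both)  # midranks
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n  # P(pos_i beats a random neg), tie-aware
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # P(pos beats neg_j)
    auc = float((r_all[:m].sum() - m * (m + 1) / 2) / (m * n))
    return auc, v10, v01


def empirical_auc(scores, labels) -> RocResult:
    """Mann-Whitney concordance AUROC (ties count 1/2); point estimate only."""
    pos, neg = _split(scores, labels)
    auc, _, _ = _placements(pos, neg)
    return RocResult(
        auc=auc, ci_low=auc, ci_high=auc, n_pos=len(pos), n_neg=len(neg), se=0.0
    )


def delong_ci(scores, labels, level: float = 0.95) -> RocResult:
    """AUROC with a DeLong normal-approximation CI, clipped to [0, 1]."""
    pos, neg = _split(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise InvalidParameterError("DeLong CI requires >= 2 in each class")
    auc, v10, v01 = _placements(pos, neg)
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    se = math.sqrt(max(var, 0.0))
    degenerate = se == 0.0 and auc in (0.0, 1.0)
    z = stats.norm.ppf(0.5 + level / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return RocResult(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        n_pos=len(pos),
        n_neg=len(neg),
        se=se,
        degenerate=degenerate,
    )


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test that two classifiers share the same AUROC.

    Scores must be paired on identical subjects.  Returns (z, two-sided p).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise InvalidParameterError("paired scores must have identical lengths")
    pos_a, neg_a = _split(scores_a, labels)
    pos_b, neg_b = _split(scores_b, labels)
    auc_a, v10_a, v01_a = _placements(pos_a, neg_a)
    auc_b, v10_b, v01_b = _placements(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def confusion_at_cutoff(
    scores, labels, cutoff: float, strict: bool = True, level: float = 0.95
) -> ThresholdPerformance:
    """Sensitivity/specificity (with Wilson CIs) at a cutoff; positive iff score > cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _split(scores, labels)  # validates both classes present
    pred = scores > cutoff if strict else scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    def _wilson(k: int, n: int) -> tuple[float, float]:
        lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
        return max(0.0, float(lo)), min(1.0, float(hi))

    sens_ci = _wilson(tp, tp + fn)
    spec_ci = _wilson(tn, tn + fp)
    return ThresholdPerformance(
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        sens_ci=sens_ci,
        spec_ci=spec_ci,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def youden_optimal(scores, labels) -> tuple[float, float]:
    """Cutoff maximizing Youden's J = sens + spec - 1, over midpoints of
    adjacent sorted unique scores; ties resolved to the lowest cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _split(scores, labels)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0]), 0.0
    candidates = (uniq[:-1] + uniq[1:]) / 2
    best_c, best_j = candidates[0], -np.inf
    for c in candidates:
        perf = confusion_at_cutoff(scores, labels, c)
        j = perf.sensitivity + perf.specificity - 1
        if j > best_j + 1e-12:
            best_c, best_j = c, j
    return float(best_c), float(best_j)


# --------------------------------------------------------------------------
# correlation and group comparisons
# --------------------------------------------------------------------------


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidParameterError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidParameterError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    pvalue: float
    test_used: str
    posthoc: tuple = ()  # ((i, j, p), ...) pairwise, when >= 3 groups


def group_compare_categorical(table, force: str | None = None) -> GroupComparison:
    """Chi-square (no continuity correction) or Fisher's exact on an RxC table.

    Dispatch: Pearson chi-square when every expected count is >= 5, otherwise
    Fisher's exact (enumeration for small tables).  ``force`` overrides the
    dispatch with "chi2" or "fisher".
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or np.any(t != np.round(t)):
        raise InvalidParameterError("table must be a 2-D nonnegative integer array")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InvalidParameterError("table has a zero margin")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    use_chi2 = force == "chi2" or (force is None and np.all(expected >= 5))
    if force not in (None, "chi2", "fisher"):
        raise InvalidParameterError("force must be None, 'chi2' or 'fisher'")
    if use_chi2:
        chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
        return GroupComparison(float(chi2), float(p), "chi-square")
    ti = t.astype(int)
    if ti.shape == (2, 2):
        _, p = stats.fisher_exact(ti)
        return GroupComparison(float("nan"), float(p), "fisher")
    if _enumeration_size_bound(ti) <= 200_000:
        return GroupComparison(float("nan"), _fisher_exact_rxc(ti), "fisher")
    return GroupComparison(
        float("nan"), _fisher_montecarlo_rxc(ti), "fisher-montecarlo"
    )


def _enumeration_size_bound(table: np.ndarray) -> float:
    """Upper bound on the number of tables the exhaustive search may visit."""
    cols = table.shape[1]
    bound = 1.0
    for r in table.sum(axis=1)[:-1]:  # last row is determined by the margins
        bound *= math.comb(int(r) + cols - 1, cols - 1)
    return bound


def _fisher_montecarlo_rxc(
    table: np.ndarray, n_samples: int = 20_000, seed: int = 0
) -> float:
    """Monte-Carlo Fisher p for larger RxC tables.

    Samples tables from the margin-conditional null (Patefield algorithm) and
    estimates the probability of a table no more probable than the observed
    one; (k+1)/(B+1) correction keeps the estimate valid and never zero.
    Deterministically seeded: the same table always yields the same p.
    """
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)

    from scipy.special import gammaln

    # only the cell-dependent part of the hypergeometric log-probability is
    # needed: the margin terms are constant across tables with fixed margins
    lp_obs = -float(gammaln(table + 1).sum())
    rng = np.random.default_rng(seed)
    dist = stats.random_table(row_sums, col_sums)
    draws = dist.rvs(n_samples, random_state=rng)
    lps = -gammaln(draws + 1).sum(axis=(1, 2))
    k = int(np.sum(lps <= lp_obs + 1e-9))
    return (k + 1) / (n_samples + 1)


def _fisher_exact_rxc(table: np.ndarray, tol: float = 1e-9) -> float:
    """Exhaustive Fisher's exact p for a small RxC table with fixed margins.

    Enumerates all tables with the observed margins; the p-value sums the
    probabilities of tables no more probable than the observed one.  Feasible
    for the small contingency tables a cohort summary produces.
    """
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)

    def log_prob(t: np.ndarray) -> float:
        # multivariate hypergeometric log-probability given fixed margins
        n = t.sum()
        lp = (
            sum(math.lgamma(r + 1) for r in row_sums)
            + sum(math.lgamma(c + 1) for c in col_sums)
            - math.lgamma(n + 1)
            - sum(math.lgamma(x + 1) for x in t.flat)
        )
        return lp

    lp_obs = log_prob(table)
    p_total = 0.0

    rows, cols = table.shape

    def recurse(r: int, remaining_cols: np.ndarray, current: list[np.ndarray]):
        nonlocal p_total
        if r == rows - 1:
            last = remaining_cols
            if np.any(last < 0):
                return
            t = np.vstack(current + [last])
            if log_prob(t) <= lp_obs + tol:
                p_total += math.exp(log_prob(t))
            return
        # enumerate row r with sum row_sums[r], bounded by remaining columns
        def fill(c: int, left: int, row: list[int]):
            if c == cols - 1:
                if left <= remaining_cols[c]:
                    recurse(
                        r + 1,
                        remaining_cols - np.array(row + [left]),
                        current + [np.array(row + [left])],
                    )
                return
            for v in range(min(left, int(remaining_cols[c])) + 1):
                fill(c + 1, left - v, row + [v])

        fill(0, int(row_sums[r]), [])

    recurse(0, col_sums.copy(), [])
    return min(p_total, 1.0)


def group_compare_continuous(
    samples_by_group: dict | list,
    family: str = "auto",
    normality_alpha: float = 0.05,
) -> GroupComparison:
    """Omnibus comparison of >= 2 groups with post hoc pairwise tests.

    ``family="auto"`` runs one-way ANOVA (post hoc Tukey HSD) when every group
    passes a Shapiro-Wilk screen at ``normality_alpha``, otherwise
    Kruskal-Wallis (post hoc Dunn with Bonferroni).  ``family`` can force
    "anova" or "kruskal".
    """
    if isinstance(samples_by_group, dict):
        groups = [np.asarray(v, dtype=float) for v in samples_by_group.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in samples_by_group]
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise InvalidParameterError("every group must have n >= 2")

    if family == "auto":
        normal = True
        for g in groups:
            if np.std(g) == 0 or len(g) < 3:
                normal = False
                break
            if stats.shapiro(g).pvalue <= normality_alpha:
                normal = False
                break
        family = "anova" if normal else "kruskal"
    if family not in ("anova", "kruskal"):
        raise InvalidParameterError("family must be 'auto', 'anova' or 'kruskal'")

    k = len(groups)
    pairs = list(itertools.combinations(range(k), 2))
    if family == "anova":
        stat, p = stats.f_oneway(*groups)
        posthoc = ()
        if k > 2:
            res = stats.tukey_hsd(*groups)
            posthoc = tuple((i, j, float(res.pvalue[i, j])) for i, j in pairs)
        return GroupComparison(float(stat), float(p), "anova", posthoc)

    with np.errstate(invalid="ignore"):
        try:
            stat, p = stats.kruskal(*groups)
        except ValueError:
            stat, p = np.nan, np.nan
    if not (np.isfinite(stat) and np.isfinite(p)):
        # every pooled value identical: pure ties carry no evidence at all
        return GroupComparison(0.0, 1.0, "kruskal-wallis",
                               tuple((i, j, 1.0) for i, j in pairs) if k > 2 else ())
    posthoc = ()
    if k > 2:
        posthoc = tuple(_dunn_bonferroni(groups))
    return GroupComparison(float(stat), float(p), "kruskal-wallis", posthoc)


def _dunn_bonferroni(groups: list[np.ndarray]):
    """Dunn's rank-based pairwise z tests with Bonferroni correction."""
    k = len(groups)
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    m = k * (k - 1) // 2
    for i, j in itertools.combinations(range(k), 2):
        var = base_var * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
        if var <= 0:
            yield (i, j, 1.0)
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
        p = min(1.0, 2 * stats.norm.sf(abs(z)) * m)
        yield (i, j, float(p))


# --------------------------------------------------------------------------
# AUC sample size (Hanley-McNeil)
# --------------------------------------------------------------------------


def hanley_mcneil_var(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil exponential-approximation variance of an empirical AUROC."""
    if not 0 < auc < 1:
        raise InvalidParameterError("auc must lie in (0, 1)")
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def auc_sample_size(
    auc_alt: float,
    auc_null: float,
    power: float = 0.8,
    alpha: float = 0.05,
    neg_pos_ratio: float = 1.0,
) -> tuple[int, int, int]:
    """Smallest total n so a two-sided alpha-level AUC test attains the power.

    The test rejects H0: AUC = ``auc_null`` when |A - auc_null| exceeds
    z_{1-alpha/2} times the Hanley-McNeil SE under the null; power is
    evaluated with the alternative-hypothesis SE.  Returns
    (total_n, n_pos, n_neg) with n_neg = ceil(ratio * n_pos).
    """
    if not 0.5 <= auc_null < auc_alt < 1:
        raise InvalidParameterError("need 0.5 <= auc_null < auc_alt < 1")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise InvalidParameterError("power and alpha must lie in (0, 1)")
    if neg_pos_ratio < 1:
        raise InvalidParameterError("neg_pos_ratio must be >= 1")
    z_alpha = stats.norm.ppf(1 - alpha / 2)
    delta = auc_alt - auc_null
    for n_pos in range(2, 1_000_000):
        n_neg = max(2, math.ceil(neg_pos_ratio * n_pos))
        se0 = math.sqrt(hanley_mcneil_var(auc_null, n_pos, n_neg))
        se1 = math.sqrt(hanley_mcneil_var(auc_alt, n_pos, n_neg))
        achieved = stats.norm.cdf((delta - z_alpha * se0) / se1)
        if achieved >= power:
            return n_pos + n_neg, n_pos, n_neg
    raise InvalidParameterError("no feasible sample size below 10^6")


def simulate_auc_test_power(
    auc_alt: float,
    auc_null: float,
    n_pos: int,
    n_neg: int,
    alpha: float = 0.05,
    n_rep: int = 20_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo power of the Hanley-McNeil-null AUC test under a binormal
    alternative with equal unit SDs (validation utility for auc_sample_size)."""
    rng = np.random.default_rng(seed)
    delta_mu = math.sqrt(2) * stats.norm.ppf(auc_alt)
    z_alpha = stats.norm.ppf(1 - alpha / 2)
    se0 = math.sqrt(hanley_mcneil_var(auc_null, n_pos, n_neg))
    rejections = 0
    for _ in range(n_rep):
        pos = rng.standard_normal(n_pos) + delta_mu
        neg = rng.standard_normal(n_neg)
        auc, _, _ = _placements(pos, neg)
        if abs(auc - auc_null) > z_alpha * se0:
            rejections += 1
    return rejections / n_rep
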