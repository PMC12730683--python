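"""Paired statistical comparison battery for classifier accuracies.

Given per-subject metric values for two models (same subjects, same order),
the battery computes the paired Student t statistic t = d_bar / (s_d /
sqrt(n)), the Wilcoxon signed-rank test (W reported as the smaller
signed-rank sum; exact two-sided p by full enumeration of the 2^n sign
assignments for n <= 15, normal approximation with tie correction beyond),
the Friedman rank test across k models on the same subjects, the Nemenyi
post hoc pairwise comparison via the studentized-range distribution, the
paired effect sizes (Cohen's d on the difference scale and the Wilcoxon
r = Z / sqrt(n)), and the Bonferroni family-wise correction
alpha_adj = alpha / m with adjusted p_i = min(1, m p_i).

Zero differences in the Wilcoxon test are dropped (Wilcoxon's original
rule) and the drop count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats as _st

__all__ = [
    "PairedSample",
    "ComparisonReport",
    "paired_t",
    "wilcoxon_signed_rank",
    "friedman",
    "nemenyi_posthoc",
    "effect_sizes",
    "bonferroni_adjust",
    "compare_models",
]

_EXACT_LIMIT = 15


@dataclass
class PairedSample:
    """Metric values of two models over the same subjects, same order."""

    subjects: tuple[str, ...]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if not (len(self.subjects) == len(self.a) == len(self.b)):
            raise ValueError("subjects, a and b must have equal lengths")
        if len(self.a) < 2:
            raise ValueError("paired comparison needs at least 2 subjects")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("paired sample contains missing/non-finite values")

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


def paired_t(sample: PairedSample) -> tuple[float, float]:
    """Paired Student t: t = d_bar / (s_d / sqrt(n)), two-sided p, n-1 df."""
    d = sample.differences
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * _st.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks of |d| and the sign vector, zero differences removed."""
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero: Wilcoxon undefined")
    ranks = _st.rankdata(np.abs(d))
    return ranks, np.sign(d)


def wilcoxon_signed_rank(
    sample: PairedSample, mode: str = "auto"
) -> tuple[float, float, int]:
    """Wilcoxon signed-rank test.

    Returns (W, p, n_zeros_dropped) with W the smaller of the positive and
    negative rank sums. ``mode``: 'exact' enumerates all 2^n sign patterns
    (ties handled naturally through average ranks), 'approx' uses the normal
    approximation with tie correction, 'auto' picks exact for n <= 15.
    """
    d = sample.differences
    n_zeros = int((d == 0).sum())
    ranks, signs = _signed_ranks(d)
    n = len(ranks)
    w_pos = float(ranks[signs > 0].sum())
    w_neg = float(ranks[signs < 0].sum())
    W = min(w_pos, w_neg)
    if mode == "auto":
        mode = "exact" if n <= _EXACT_LIMIT else "approx"
    if mode == "exact":
        # two-sided p: share of the 2^n equiprobable sign assignments whose
        # min rank sum is <= the observed one
        total = ranks.sum()
        count = 0
        for signs_iter in product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs_iter, ranks))
            if min(w, total - w) <= W + 1e-12:
                count += 1
        p = count / 2.0**n
    elif mode == "approx":
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (W - mean) / np.sqrt(var)
        p = 2 * _st.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return W, float(min(p, 1.0)), n_zeros


def friedman(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test over a complete (subjects x models) matrix.

    chi2_F = 12 n / (k (k+1)) * sum_j (R_bar_j - (k+1)/2)^2 with average
    ranks on ties; p from the chi-square distribution with k-1 df.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x models)")
    n, k = matrix.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 models")
    if not np.all(np.isfinite(matrix)):
        raise ValueError(
            "incomplete matrix: the Friedman test needs every model measured "
            "on every subject (align cohorts first)"
        )
    ranks = np.apply_along_axis(_st.rankdata, 1, matrix)
    mean_ranks = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * ((mean_ranks - (k + 1) / 2.0) ** 2).sum()
    p = float(_st.chi2.sf(chi2, df=k - 1))
    return float(chi2), p


def nemenyi_posthoc(matrix: np.ndarray, alpha: float = 0.05) -> dict:
    """Nemenyi pairwise comparison following a Friedman test.

    Pairwise p-values come from the studentized-range distribution on the
    mean-rank differences; the critical difference is
    CD = q_alpha sqrt(k (k+1) / (6 n)) with q_alpha the infinite-df
    studentized-range quantile divided by sqrt(2). Requires k >= 3 (with two
    models the pairwise Wilcoxon test applies instead).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n, k = matrix.shape
    if k < 3:
        raise ValueError(
            "Nemenyi needs >= 3 models; for two models use the pairwise "
            "Wilcoxon signed-rank test"
        )
    ranks = np.apply_along_axis(_st.rankdata, 1, matrix)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    q_crit = _st.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2.0)
    cd = q_crit * se
    pvals = np.ones((k, k))
    significant = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(mean_ranks[i] - mean_ranks[j])
            q = diff / se * np.sqrt(2.0)
            p = float(_st.studentized_range.sf(q, k, np.inf)) if diff > 0 else 1.0
            pvals[i, j] = pvals[j, i] = min(p, 1.0)
            significant[i, j] = significant[j, i] = diff > cd
    return {
        "mean_ranks": mean_ranks,
        "critical_difference": float(cd),
        "p_values": pvals,
        "significant": significant,
    }


def effect_sizes(sample: PairedSample, pooled: bool = False) -> tuple[float, float]:
    """Paired effect sizes (cohens_d, wilcoxon_r).

    Cohen's d defaults to the paired (difference-SD) form d = d_bar / s_d;
    ``pooled=True`` divides by the pooled SD of the two samples instead.
    r = Z / sqrt(n) with Z the Wilcoxon normal deviate, signed by the
    direction of the median difference.
    """
    d = sample.differences
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (zero-variance) differences: d undefined")
    if pooled:
        s_pool = np.sqrt((sample.a.var(ddof=1) + sample.b.var(ddof=1)) / 2.0)
        cohens_d = d.mean() / s_pool
    else:
        cohens_d = d.mean() / sd
    ranks, signs = _signed_ranks(d)
    n = len(ranks)
    w_pos = ranks[signs > 0].sum()
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = abs(w_pos - mean) / np.sqrt(var) if var > 0 else 0.0
    direction = np.sign(np.median(d[d != 0]))
    r = float(direction * z / np.sqrt(n))
    return float(cohens_d), r


def bonferroni_adjust(
    p_values, m: int | None = None, alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Bonferroni correction: adjusted p_i = min(1, m p_i), alpha_adj = alpha/m.

    ``m`` is the size of the hypothesis family and must cover all supplied
    p-values (m >= len(p_values)).
    """
    p_values = np.asarray(p_values, dtype=np.float64)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p_values)
    if m < 1 or m < len(p_values):
        raise ValueError(
            f"family size m={m} must be >= number of p-values ({len(p_values)})"
        )
    return np.minimum(1.0, m * p_values), alpha / m


@dataclass
class ComparisonReport:
    """Full paired battery for one model-A-vs-model-B comparison."""

    label: str
    n: int
    t_statistic: float
    t_p: float
    wilcoxon_w: float
    wilcoxon_p: float
    wilcoxon_zeros_dropped: int
    cohens_d: float
    wilcoxon_r: float
    alpha: float = 0.05
    family_size: int = 1
    t_p_adjusted: float = field(init=False)
    wilcoxon_p_adjusted: float = field(init=False)
    alpha_adjusted: float = field(init=False)

    def __post_init__(self) -> None:
        # family_size counts ALL planned tests in the family (t + Wilcoxon
        # across datasets), so both p's are scaled by the same m
        adj, alpha_adj = bonferroni_adjust(
            [self.t_p, self.wilcoxon_p], m=max(self.family_size, 2), alpha=self.alpha
        )
        self.t_p_adjusted = float(adj[0])
        self.wilcoxon_p_adjusted = float(adj[1])
        self.alpha_adjusted = alpha_adj

    def significant(self, adjusted: bool = False) -> dict[str, bool]:
        if adjusted:
            return {
                "t": self.t_p_adjusted < self.alpha,
                "wilcoxon": self.wilcoxon_p_adjusted < self.alpha,
            }
        return {"t": self.t_p < self.alpha, "wilcoxon": self.wilcoxon_p < self.alpha}

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "t": self.t_statistic,
            "t_p": self.t_p,
            "t_p_adjusted": self.t_p_adjusted,
            "wilcoxon_W": self.wilcoxon_w,
            "wilcoxon_p": self.wilcoxon_p,
            "wilcoxon_p_adjusted": self.wilcoxon_p_adjusted,
            "wilcoxon_zeros_dropped": self.wilcoxon_zeros_dropped,
            "cohens_d": self.cohens_d,
            "wilcoxon_r": self.wilcoxon_r,
            "alpha": self.alpha,
            "alpha_adjusted": self.alpha_adjusted,
            "significant": self.significant(),
            "significant_adjusted": self.significant(adjusted=True),
        }


def compare_models(
    sample: PairedSample,
    label: str = "A vs B",
    family_size: int = 4,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Run the full paired battery on one A-vs-B sample."""
    t, t_p = paired_t(sample)
    w, w_p, zeros = wilcoxon_signed_rank(sample)
    d, r = effect_sizes(sample)
    return ComparisonReport(
        label=label,
        n=len(sample.a),
        t_statistic=t,
        t_p=t_p,
        wilcoxon_w=w,
        wilcoxon_p=w_p,
        wilcoxon_zeros_dropped=zeros,
        cohens_d=d,
        wilcoxon_r=r,
        alpha=alpha,
        family_size=family_size,
    )
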