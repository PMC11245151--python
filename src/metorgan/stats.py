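"""Shared statistical primitives: 2x2 tests, Mann-Whitney, BH, star buckets.

These wrap scipy/statsmodels with the conventions used throughout the
pipeline: two-sided tests, Fisher's exact when any expected cell count is
below 5 (else Pearson chi-square without continuity correction), and the
Mann-Whitney U with an exact null for small groups and a tie-corrected
normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXPECTED_COUNT_CUTOFF = 5.0
EXACT_MW_MAX_GROUP = 8

# raw-p thresholds for the four significance star buckets
STAR_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class TwoByTwoResult:
    test_used: str  # "fisher" | "chi_square" | "untestable"
    p: float  # nan when untestable
    direction: str  # "enriched" | "depleted"


def expected_counts(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        return np.zeros_like(table)
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / n


def compare_2x2(k1: int, n1: int, k2: int, n2: int) -> TwoByTwoResult:
    """Two-sided test of rate k1/n1 (group of interest) vs k2/n2 (reference).

    Fisher's exact test when any expected cell count is < 5, else Pearson
    chi-square without continuity correction. A zero row or column margin
    makes the table untestable (p = nan). Direction ties break to
    "enriched".
    """
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must satisfy 0 <= k <= n")

    rate1 = k1 / n1 if n1 > 0 else np.nan
    rate2 = k2 / n2 if n2 > 0 else np.nan
    if np.isnan(rate1) or np.isnan(rate2):
        direction = "enriched"
    else:
        direction = "enriched" if rate1 >= rate2 else "depleted"

    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return TwoByTwoResult("untestable", float("nan"), direction)

    if (expected_counts(table) < EXPECTED_COUNT_CUTOFF).any():
        _, p = sps.fisher_exact(table.astype(int), alternative="two-sided")
        used = "fisher"
    else:
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        used = "chi_square"
    return TwoByTwoResult(used, float(min(p, 1.0)), direction)


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null when the smaller group has <= 8 observations and the pooled
    data has no ties; otherwise the tie-corrected normal approximation
    (no continuity correction). Degenerate inputs where every pooled value
    is identical return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if min(a.size, b.size) <= EXACT_MW_MAX_GROUP and not _has_ties(pooled):
        method = "exact"
    else:
        method = "asymptotic"
    _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    if np.isnan(p):
        return 1.0
    return float(min(p, 1.0))


def mann_whitney_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney p-values for matrices A, B (genes x samples).

    Applies the same exact/asymptotic rule per row as :func:`mann_whitney`.
    Rows whose pooled values are all identical get p = 1.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n_rows = A.shape[0]
    ps = np.empty(n_rows)
    small = min(A.shape[1], B.shape[1]) <= EXACT_MW_MAX_GROUP

    if not small:
        with np.errstate(invalid="ignore"):
            _, ps_vec = sps.mannwhitneyu(
                A, B, alternative="two-sided", method="asymptotic", use_continuity=False, axis=1
            )
        ps = np.asarray(ps_vec, dtype=float)
        constant = np.all(np.concatenate([A, B], axis=1) == A[:, :1], axis=1)
        ps[constant | np.isnan(ps)] = 1.0
        return np.minimum(ps, 1.0)

    for i in range(n_rows):
        ps[i] = mann_whitney(A[i], B[i])
    return ps


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are passed through."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() > 0:
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def star_bucket(p: float) -> str:
    """Significance stars from a raw p: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if np.isnan(p):
        return ""
    stars = 0
    for thr in STAR_THRESHOLDS:
        if p < thr:
            stars += 1
    return "*" * stars
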