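"""Statistical tests for condition comparisons.

Two families are provided, matching how depth/condition comparisons are
customarily analysed in this setting:

* Welch's unequal-variance t-test with optional Bonferroni correction, for
  pairwise FWHM comparisons against a reference condition;
* the Friedman rank test over a block design (e.g. 21 xy-planes as blocks,
  imaging conditions as treatments) with the Dwass–Steel–Critchlow–Fligner
  (DSCF) all-pairs post-hoc: each pair is compared with a two-sample rank
  statistic computed on that pair alone (average ranks for ties,
  tie-corrected variance), standardised and referred to the studentized
  range distribution with k groups and infinite degrees of freedom,
  p = P(Q >= sqrt(2) |W*|).

The Friedman statistic and the studentized-range tail probability are
implemented here directly (the tail by numerical integration, absolute
tolerance 1e-8) so they can be cross-checked against independent
references in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats as sps

from .errors import ValidationError


@dataclass(frozen=True)
class PairwiseTestResult:
    statistic: float
    p_value: float
    degrees_of_freedom: float | None = None
    adjusted_p: float | None = None
    method: str = ""
    pair: tuple[int, int] | None = None


class DegenerateSampleError(ValidationError):
    """Both samples constant and equal; the test statistic is undefined."""


def welch_t_test(x, y) -> PairwiseTestResult:
    """Two-sided Welch's t-test (unequal variances, Welch–Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            raise DegenerateSampleError("both samples constant and equal")
    res = sps.ttest_ind(x, y, equal_var=False)
    return PairwiseTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        degrees_of_freedom=float(res.df),
        method="welch",
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Multiply each p by m (default: the number of tests), cap at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return np.minimum(p * m, 1.0)


def friedman_test(design) -> PairwiseTestResult:
    """Tie-corrected Friedman chi-square over a blocks x treatments matrix.

    Rows are blocks, columns treatments; no missing cells.  An all-tied
    design returns statistic 0, p = 1.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("design must be a 2D matrix with >= 2 blocks and >= 2 treatments")
    n, k = X.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, X)
    Rj = ranks.sum(axis=0)
    # tie correction: sum over blocks of (t^3 - t) for each tie group
    tie_sum = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:
        return PairwiseTestResult(0.0, 1.0, degrees_of_freedom=float(k - 1), method="friedman")
    chi2 = (12.0 / (n * k * (k + 1)) * float(np.sum(Rj**2)) - 3.0 * n * (k + 1)) / correction
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, k - 1))
    return PairwiseTestResult(float(chi2), p, degrees_of_freedom=float(k - 1), method="friedman")


def studentized_range_sf(q: float, k: int) -> float:
    """P(Q >= q) for the studentized range of k standard normals
    (infinite degrees of freedom), by numerical integration."""
    if q <= 0:
        return 1.0
    phi, Phi = sps.norm.pdf, sps.norm.cdf

    def integrand(u):
        return phi(u) * (Phi(u) - Phi(u - q)) ** (k - 1)

    val, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=1e-10, epsrel=1e-10, limit=200)
    return float(min(max(1.0 - k * val, 0.0), 1.0))


def _pair_rank_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Standardised two-sample rank-sum statistic on the pair alone."""
    pooled = np.concatenate([a, b])
    r = sps.rankdata(pooled)
    n1, n2 = len(a), len(b)
    N = n1 + n2
    W = float(r[n1:].sum())
    expect = n2 * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_sum / (N * (N - 1)))
    if var <= 0:
        return 0.0
    return (W - expect) / math.sqrt(var)


def dscf_all_pairs(groups) -> list[PairwiseTestResult]:
    """DSCF all-pairs comparisons over k >= 2 independent samples.

    Returns one result per unordered pair (i < j); the statistic is the
    standardised pairwise rank-sum W*, and
    p = P(Q_{k,inf} >= sqrt(2) |W*|).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValidationError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValidationError("each group needs n >= 2")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            w = _pair_rank_statistic(groups[i], groups[j])
            q = math.sqrt(2.0) * abs(w)
            p = studentized_range_sf(q, k)
            out.append(PairwiseTestResult(float(w), p, method="dscf", pair=(i, j)))
    return out


def results_table(results: list[PairwiseTestResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "pair": r.pair,
                "method": r.method,
                "statistic": r.statistic,
                "df": r.degrees_of_freedom,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
            }
            for r in results
        ]
    )
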