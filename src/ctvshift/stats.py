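"""Nonparametric and agreement statistics used in the evaluation.

* Spearman rank correlation with a two-sided p-value: exact permutation
  enumeration for n <= 9, the usual t approximation above that.
* Steel-Dwass all-pairs comparison: pairwise rank-sum statistics referred
  to the studentized-range distribution (large-sample, tie-corrected);
  with exactly two small untied groups the exact rank-sum p is used.
* Two-sided F-test for equality of variances.
* Cohen's kappa on shifts discretized to fixed-width bins.
* Dice similarity coefficient of two contours via polygon clipping.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps

from .geometry import Contour


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and two-sided p.

    For n <= 9 the p-value enumerates all n! rank permutations exactly;
    larger samples use the t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _pearson(rx, ry)
    if n <= 9:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
    return float(rho), float(min(p, 1.0))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise ValueError("constant input has no defined rank correlation")
    return float(a @ b) / denom


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]                       # (n!, n)
    a = rx - rx.mean()
    b = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt(float(a @ a) * (b * b).sum(axis=1))
    rhos = (b @ a) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def steel_dwass(groups: list[np.ndarray], alpha: float = 0.05) -> np.ndarray:
    """All-pairs nonparametric comparison; returns a symmetric p-value matrix.

    Each pair (i, j) is ranked jointly on its own; the standardized rank
    sum (tie-corrected) is referred to the studentized-range distribution
    with k groups and infinite degrees of freedom, the usual large-sample
    form.  For exactly two small groups without ties the exact
    Wilcoxon-Mann-Whitney two-sided p is returned instead, since the
    procedure then reduces to the plain rank-sum test.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p = _pairwise_p(groups[i], groups[j], k)
            pmat[i, j] = pmat[j, i] = p
    return pmat


def _pairwise_p(a: np.ndarray, b: np.ndarray, k: int) -> float:
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    n = n1 + n2
    ranks = sps.rankdata(pooled)
    no_ties = np.unique(pooled).size == n
    if k == 2 and no_ties and n <= 40:
        return float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                      method="exact").pvalue)
    w = ranks[:n1].sum()
    expect = n1 * (n + 1) / 2.0
    # tie-corrected variance of the rank sum
    var = n1 * n2 / (n * (n - 1.0)) * float(((ranks - (n + 1) / 2.0) ** 2).sum())
    if var <= 0:
        return 1.0
    z = (w - expect) / math.sqrt(var)
    q = math.sqrt(2.0) * abs(z)
    return float(sps.studentized_range.sf(q, k, np.inf))


def f_test_variance(a, b) -> tuple[float, float]:
    """Two-sided F-test for equality of variances (sample variances, n-1)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ValueError("second sample has zero variance")
    F = float(va / vb)
    dist = sps.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return F, float(min(p, 1.0))


def cohens_kappa(shifts_a, shifts_b, bin_width_mm: float = 1.0) -> float:
    """Unweighted Cohen's kappa after rounding shifts to bin centers.

    Continuous shifts are discretized to the nearest multiple of
    ``bin_width_mm`` (1 mm bins centered on integers by default) and
    agreement is scored on the resulting categories.
    """
    a = np.asarray(shifts_a, dtype=float).ravel()
    b = np.asarray(shifts_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("rating lists must have equal length")
    if bin_width_mm <= 0:
        raise ValueError("bin width must be positive")
    ca = np.rint(a / bin_width_mm).astype(int)
    cb = np.rint(b / bin_width_mm).astype(int)
    cats = np.union1d(ca, cb)
    n = ca.size
    po = float(np.mean(ca == cb))
    pa = np.array([np.mean(ca == c) for c in cats])
    pb = np.array([np.mean(cb == c) for c in cats])
    pe = float(pa @ pb)
    if 1.0 - pe < 1e-12:
        return 1.0 if po >= 1.0 - 1e-12 else 0.0
    return (po - pe) / (1.0 - pe)


def dice_coefficient(poly_a: Contour, poly_b: Contour) -> float:
    """DSC = 2|A∩B| / (|A| + |B|) of two contours, in [0, 1]."""
    pa, pb = poly_a.polygon, poly_b.polygon
    inter = pa.intersection(pb).area
    return float(2.0 * inter / (pa.area + pb.area))
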