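"""Paired small-sample nonparametric inference.

At the study scale (n = 8 cultures) asymptotic p-values are unreliable, so
the paired Wilcoxon signed-rank test is computed by exact enumeration of all
2^n sign assignments whenever the number of nonzero differences is small
(<= 12 by default).  The two-sided p-value is the doubled smaller tail,
capped at 1 — the standard convention for discrete exact tests, stated here
so results reproduce bit-for-bit.  Benjamini-Hochberg step-up adjustment
controls the false discovery rate across the declared comparison family, and
a Friedman test with Kendall's W effect size measures the global difference
across treatment conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # <= 4096 sign vectors
_RANK_TOL = 1e-9


@dataclass
class PairedTestResult:
    """One paired Wilcoxon signed-rank comparison."""

    comparison: str
    n_total: int
    n_effective: int
    statistic_w: float  # sum of ranks of positive differences
    p_two_sided: float
    method: str  # 'exact_enumeration', 'normal_approximation' or 'degenerate'
    degenerate: bool = False
    p_adjusted: Optional[float] = None


@dataclass
class FriedmanResult:
    """Friedman rank test over blocks (cultures) × treatments (conditions)."""

    n_blocks: int
    k_treatments: int
    chi2: float
    df: int
    p_value: float
    kendalls_w: float
    n_dropped_blocks: int = 0


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W (sum of positive-difference ranks) and the midranks of |d|."""
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_two_sided_p(w: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by enumerating all 2^n sign assignments.

    Builds the full distribution of W* = sum of ranks receiving a positive
    sign; p = min(1, 2 * min(P(W* <= W), P(W* >= W))).  Midranks make W*
    non-integer under ties, hence the small comparison tolerance.
    """
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    p_le = np.mean(sums <= w + _RANK_TOL)
    p_ge = np.mean(sums >= w - _RANK_TOL)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_two_sided_p(w: float, ranks: np.ndarray) -> float:
    """Normal approximation with tie and continuity corrections."""
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    # Tie correction: subtract sum(t^3 - t)/48 over tie groups of |d|.
    _, counts = np.unique(np.round(ranks / _RANK_TOL) * _RANK_TOL, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    diff = w - mean
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var) if diff != 0 else 0.0
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_signed_rank_exact(
    x: Sequence[float],
    y: Sequence[float],
    comparison: str = "",
    exact_max_n: int = EXACT_MAX_N,
    drop_zeros: bool = True,
) -> PairedTestResult:
    """Paired Wilcoxon signed-rank test, exact at small n.

    Differences ``d = x - y``; zero differences are discarded (Wilcoxon's
    original convention; set ``drop_zeros=False`` for Pratt's method, which
    ranks zeros then drops their ranks); |d| is ranked with midranks for
    ties; W is the sum of ranks of positive differences.  With at most
    ``exact_max_n`` nonzero differences the two-sided p comes from full
    enumeration of all sign assignments, otherwise from a normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if len(x) == 0:
        raise ValueError("need at least one pair")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")

    d = x - y
    n_total = len(d)
    if drop_zeros:
        d_eff = d[d != 0]
        ranks_all = None
    else:  # Pratt: rank zeros with the rest, then drop their ranks
        ranks_all = sps.rankdata(np.abs(d))
        d_eff = d
    n_eff = int(np.count_nonzero(d))

    if n_eff == 0:
        return PairedTestResult(
            comparison, n_total, 0, 0.0, 1.0, "degenerate", degenerate=True
        )

    if drop_zeros:
        w, ranks = _signed_rank_statistic(d_eff)
    else:
        nz = d != 0
        ranks = ranks_all[nz]
        w = float(ranks[d[nz] > 0].sum())

    if n_eff <= exact_max_n:
        p = _exact_two_sided_p(w, ranks)
        method = "exact_enumeration"
    else:
        p = _approx_two_sided_p(w, ranks)
        method = "normal_approximation"
    return PairedTestResult(comparison, n_total, n_eff, w, p, method)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``p_adj_(i) = min_{j >= i} (m * p_(j) / j)``, capped at 1, where (i)
    indexes the ascending order statistics of the m raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def friedman_test(matrix: pd.DataFrame | np.ndarray) -> FriedmanResult:
    """Friedman rank test with tie correction and Kendall's W effect size.

    ``matrix`` is blocks (cultures) × treatments (conditions); blocks with
    any missing cell are dropped with a logged count.  Within-block midranks;
    chi-square statistic with the standard tie correction; p from the
    chi-square distribution with k-1 df; Kendall's coefficient of
    concordance W = chi2 / (n (k - 1)), the conventional effect size in
    [0, 1] (1 iff every block ranks the treatments identically).
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("matrix must be 2-D (blocks x treatments)")
    complete = np.isfinite(arr).all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropping %d incomplete blocks from Friedman test", n_dropped)
    arr = arr[complete]
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 complete blocks and 2 treatments")

    ranks = np.apply_along_axis(sps.rankdata, 1, arr)
    rank_sums = ranks.sum(axis=0)
    chi2_uncorr = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * n * (k + 1)

    # Tie correction over within-block tie groups.
    tie_sum = 0.0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:  # every block fully tied
        chi2 = 0.0
        p = 1.0
        w = 0.0
    else:
        chi2 = chi2_uncorr / correction
        p = float(sps.chi2.sf(chi2, k - 1))
        w = float(min(1.0, max(0.0, chi2 / (n * (k - 1)))))
    return FriedmanResult(n, k, chi2, k - 1, p, w, n_dropped)


def compare_conditions(
    matrix: pd.DataFrame,
    control: str,
    family: Optional[Sequence[str]] = None,
) -> list[PairedTestResult]:
    """Exact paired tests of each treatment condition against the control.

    ``matrix`` is culture × condition (duplicate-averaged readouts).  Each
    declared comparison uses the cultures observed in both columns
    (pairwise-complete); Benjamini-Hochberg adjustment is applied across the
    whole family (default: every non-control column).
    """
    if control not in matrix.columns:
        raise ValueError(f"control column {control!r} not in matrix")
    if family is None:
        family = [c for c in matrix.columns if c != control]
    if len(family) == 0:
        raise ValueError("comparison family is empty")
    missing = [c for c in family if c not in matrix.columns]
    if missing:
        raise ValueError(f"family conditions not in matrix: {missing}")

    results = []
    for cond in family:
        if cond == control:
            vals = matrix[control].dropna().to_numpy()
            x, y = vals, vals
        else:
            pair = matrix[[control, cond]].dropna()
            x, y = pair[control].to_numpy(), pair[cond].to_numpy()
        res = wilcoxon_signed_rank_exact(x, y, comparison=f"{cond}_vs_{control}")
        results.append(res)
    adjusted = bh_adjust([r.p_two_sided for r in results])
    for r, padj in zip(results, adjusted):
        r.p_adjusted = float(padj)
    return results


def shapiro_screen(values: Sequence[float]) -> tuple[float, float]:
    """Descriptive Shapiro-Wilk normality screen (statistic, p).

    Reported only to motivate the nonparametric tests; delegated to scipy.
    """
    res = sps.shapiro(np.asarray(values, dtype=float))
    return float(res.statistic), float(res.pvalue)


def paired_results_frame(results: Sequence[PairedTestResult]) -> pd.DataFrame:
    """Tidy table of paired-test results."""
    return pd.DataFrame(
        {
            "comparison": [r.comparison for r in results],
            "n_total": [r.n_total for r in results],
            "n_effective": [r.n_effective for r in results],
            "statistic_w": [r.statistic_w for r in results],
            "p_two_sided": [r.p_two_sided for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "method": [r.method for r in results],
        }
    )
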