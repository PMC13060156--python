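"""Within-strain rank concordance with Monte-Carlo uncertainty propagation.

Concordance between temperature-induced changes in two quantities (e.g. CI
strength and symbiont density) is summarized by Kendall's tau-b across the
shared temperature conditions.  Because each condition value is an
estimated marginal mean with a standard error, uncertainty is propagated by
Monte Carlo: every iteration redraws all condition values independently
from Normal(mean, SE^2), recomputes tau, and the iterations are pooled by
averaging on the Fisher z-transformed scale and back-transforming.  The
probability of direction (p_d) is the fraction of iterations whose tau
shares the sign of the pooled point estimate.

Plain Pearson correlation (with r^2 and a t-based p-value) is provided for
raw paired log2 measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "kendall_tau",
    "mc_concordance",
    "pearson_correlation",
]

_Z_CLIP = 1.0 - 1e-6  # |tau| clip before atanh; +/-1 occurs at n=2


@dataclass(frozen=True)
class ConcordanceResult:
    tau: float
    p_d: float
    n_conditions: int
    n_mc: int


def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall rank correlation (tau-b).

    Returns NaN (undefined) when either vector is entirely tied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    return float(stats.kendalltau(x, y).statistic)


def _tau_b_rows(x, y):
    """Vectorized tau-b for row-aligned samples; shapes (m, n) -> (m,)."""
    n = x.shape[1]
    i, j = np.triu_indices(n, k=1)
    sx = np.sign(x[:, i] - x[:, j])
    sy = np.sign(y[:, i] - y[:, j])
    nc_minus_nd = (sx * sy).sum(axis=1)
    n0 = i.size
    tied_x = (sx == 0).sum(axis=1)
    tied_y = (sy == 0).sum(axis=1)
    denom = np.sqrt((n0 - tied_x) * (n0 - tied_y))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, nc_minus_nd / denom, np.nan)


def mc_concordance(means_x, ses_x, means_y, ses_y, n_mc: int = 10000,
                   seed: int = 0) -> ConcordanceResult:
    """Monte-Carlo-propagated Kendall tau between two sets of EMMs.

    The point estimate is tanh(mean(atanh(tau_i))) over iterations (taus
    clipped just inside +/-1 to keep the transform finite); p_d counts
    iterations whose tau sign matches the point estimate's (zero-tau
    iterations match neither; a zero point estimate reports p_d = 0.5).
    """
    mx, sx = np.asarray(means_x, float), np.asarray(ses_x, float)
    my, sy = np.asarray(means_y, float), np.asarray(ses_y, float)
    if not (mx.shape == sx.shape == my.shape == sy.shape):
        raise ValueError("mean/SE vectors must share one length")
    if mx.size < 2:
        raise ValueError("need at least 2 conditions")
    if np.any(sx < 0) or np.any(sy < 0):
        raise ValueError("SEs must be >= 0")

    if np.all(sx == 0) and np.all(sy == 0):
        tau = kendall_tau(mx, my)
        p_d = 0.5 if (np.isnan(tau) or tau == 0.0) else 1.0
        return ConcordanceResult(tau=tau, p_d=p_d,
                                 n_conditions=mx.size, n_mc=0)

    rng = np.random.default_rng(seed)
    draws_x = rng.normal(mx, sx, size=(n_mc, mx.size))
    draws_y = rng.normal(my, sy, size=(n_mc, my.size))
    taus = _tau_b_rows(draws_x, draws_y)
    taus = taus[~np.isnan(taus)]
    if taus.size == 0:
        return ConcordanceResult(float("nan"), 0.5, mx.size, n_mc)
    point = float(np.tanh(np.mean(np.arctanh(np.clip(taus, -_Z_CLIP, _Z_CLIP)))))
    if point == 0.0:
        p_d = 0.5
    else:
        p_d = float(np.mean(np.sign(taus) == np.sign(point)))
        p_d = max(p_d, 0.5)
    return ConcordanceResult(tau=point, p_d=p_d,
                             n_conditions=mx.size, n_mc=n_mc)


def pearson_correlation(x, y):
    """Sample Pearson r with r^2 and the two-sided t-test p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan"), float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)
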