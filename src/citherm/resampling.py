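"""Permutation and bootstrap inference for development-time data.

Development times (days from egg transfer to first adult emergence, on an
every-other-day monitoring grid) often have zero within-group variance, so
inference is resampling-based throughout:

* pairwise permutation tests of a mean difference, with the two-sided
  p-value computed as the pure proportion of permuted |differences| at or
  above the observed one, floored at 1/(n_perm + 1) when no permutation
  reaches it;
* a Euclidean-distance PERMANOVA with sequential (type-I) sums of squares
  via Gower-centered inner products, permuting observations freely;
* percentile bootstrap confidence intervals for group means.

All operations are deterministic under a caller-supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PermResult",
    "PermanovaRow",
    "permutation_diff_test",
    "permanova_seq",
    "bootstrap_percentile_ci",
]


@dataclass(frozen=True)
class PermResult:
    observed_diff: float
    n_perm: int
    n_exceed: int
    p: float


@dataclass(frozen=True)
class PermanovaRow:
    term: str
    df: int
    ss: float
    r2: float
    pseudo_f: float
    p: float


def permutation_diff_test(group_a, group_b, n_perm: int = 10000,
                          seed: int = 0) -> PermResult:
    """Two-sided permutation test of mean(group_a) - mean(group_b).

    The p-value is the proportion of label reshuffles whose |mean
    difference| is >= the observed |difference|; when no permutation
    reaches it, p = 1/(n_perm + 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        # no variation: every permuted difference is 0 = |observed|
        return PermResult(observed, n_perm, n_perm, 1.0)
    rng = np.random.default_rng(seed)
    na, n_tot = a.size, pooled.size
    perms = rng.permuted(np.broadcast_to(pooled, (n_perm, n_tot)).copy(),
                         axis=1)
    diffs = perms[:, :na].mean(axis=1) - perms[:, na:].mean(axis=1)
    n_exceed = int(np.sum(np.abs(diffs) >= abs(observed) - 1e-12))
    p = max(n_exceed / n_perm, 1.0 / (n_perm + 1))
    return PermResult(observed, n_perm, n_exceed, float(p))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(values):
    """Gower-centered inner-product matrix of a Euclidean distance matrix."""
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=2)
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _term_basis(factor_table, term_order):
    """Orthonormal basis increments for sequential (type-I) projections.

    Returns (list of (term, basis matrix), model df).  Each basis spans the
    extra column space the term adds beyond the preceding terms plus the
    intercept.
    """
    n = len(factor_table)
    design = [np.ones((n, 1))]
    bases = []
    q_prev = np.linalg.qr(np.ones((n, 1)) / np.sqrt(n))[0]
    for term in term_order:
        cols = _dummy_columns(factor_table, term)
        q_full = _orth(np.hstack(design + [cols]))
        # new directions beyond previous span
        resid = q_full - q_prev @ (q_prev.T @ q_full)
        basis = _orth(resid)
        bases.append((term, basis))
        design.append(cols)
        q_prev = _orth(np.hstack([q_prev, basis]))
    return bases


def _orth(a, tol=1e-9):
    if a.size == 0:
        return np.zeros((a.shape[0], 0))
    u, s, _ = np.linalg.svd(a, full_matrices=False)
    rank = int(np.sum(s > tol * max(1.0, s[0] if s.size else 0.0)))
    return u[:, :rank]


def _dummy_columns(table, term):
    """Full dummy coding for a term like "temperature" or "system:cytotype"."""
    parts = term.split(":")
    labels = table[parts[0]].astype(str)
    for p in parts[1:]:
        labels = labels + "\x1f" + table[p].astype(str)
    return pd.get_dummies(labels).to_numpy(dtype=float)


def permanova_seq(values, factor_table: pd.DataFrame, term_order,
                  n_perm: int = 9999, seed: int = 0):
    """Euclidean PERMANOVA with sequential (type-I) sums of squares.

    ``values`` is the (univariate or multivariate) response; ``term_order``
    lists main effects and interactions as column names of ``factor_table``
    joined by ':'.  Pseudo-F per term uses the full-model residual; p-values
    are (count of permuted F >= observed + 1)/(n_perm + 1) under free
    permutation of observations.
    """
    g = _gower_center(values)
    n = g.shape[0]
    if len(factor_table) != n:
        raise ValueError("factor_table length must match values")
    bases = _term_basis(factor_table.reset_index(drop=True), term_order)
    ss_total = float(np.trace(g))

    term_names = [t for t, _ in bases]
    dfs = np.array([b.shape[1] for _, b in bases])
    model_df = int(dfs.sum())
    df_resid = n - 1 - model_df
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    q_all = np.hstack([b for _, b in bases])          # n x model_df
    splits = np.cumsum(dfs)[:-1]

    def _term_ss(q):
        gq = g @ q
        per_col = np.einsum("ij,ij->j", q, gq)
        return np.array([s.sum() for s in np.split(per_col, splits)])

    ss_obs = _term_ss(q_all)
    ss_res = ss_total - ss_obs.sum()
    ms_res = ss_res / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = np.where(dfs > 0, (ss_obs / np.maximum(dfs, 1)) / ms_res, 0.0)
    f_obs = np.nan_to_num(f_obs, nan=0.0, posinf=np.inf)

    rng = np.random.default_rng(seed)
    count = np.zeros(len(bases))
    with np.errstate(divide="ignore", invalid="ignore"):
        for _ in range(n_perm):
            perm = rng.permutation(n)
            qp = q_all[_inverse_perm(perm)]
            ssp = _term_ss(qp)
            resp = ss_total - ssp.sum()
            fp = (ssp / np.maximum(dfs, 1)) / (resp / df_resid)
            count += fp >= f_obs - 1e-12
    p_vals = (count + 1.0) / (n_perm + 1.0)

    rows = []
    for i, term in enumerate(term_names):
        zero = ss_obs[i] <= 1e-12 or dfs[i] == 0
        rows.append(PermanovaRow(
            term=term, df=int(dfs[i]), ss=float(max(ss_obs[i], 0.0)),
            r2=float(ss_obs[i] / ss_total) if ss_total > 0 else 0.0,
            pseudo_f=float(f_obs[i]) if not zero else 0.0,
            p=1.0 if zero else float(p_vals[i]),
        ))
    rows.append(PermanovaRow(
        term="Residual", df=int(df_resid), ss=float(ss_res),
        r2=float(ss_res / ss_total) if ss_total > 0 else 1.0,
        pseudo_f=float("nan"), p=float("nan"),
    ))
    return rows


def _inverse_perm(perm):
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    return inv


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_percentile_ci(values, n_boot: int = 10000, level: float = 0.95,
                            seed: int = 0):
    """Percentile bootstrap interval for the mean of ``values``.

    Groups with zero variance get the degenerate interval (v, v) with a
    flag (third element of the returned tuple is True when degenerate).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(x) == 0.0:
        v = float(x[0])
        return v, v, True
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(low), float(high), False
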