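"""Factorial linear models on log2-transformed densities and transcripts.

Densities (Wolbachia per host, Wovirus per Wolbachia/host) and ddPCR
transcript abundances are analyzed on the log2 scale with ordinary least
squares: factor cell means, type-II ANOVA F tests, partial omega-squared
effect sizes, and pairwise estimated-marginal-mean contrasts whose
back-transform 2^Delta is reported as a risk ratio (RR) with t-based
confidence intervals and Benjamini-Hochberg FDR adjustment.

The OLS fitting and type-II decomposition are delegated to statsmodels;
this module adds the cell-mean bookkeeping, the effect sizes, and the RR
contrast machinery used throughout the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .hatch import ContrastResult, adjust_family

__all__ = [
    "OlsFit",
    "AnovaRow",
    "fit_factorial_ols",
    "typeII_anova_F",
    "partial_omega_sq",
    "emm_pairwise_rr",
]


@dataclass
class OlsFit:
    """A factorial OLS fit with explicit cell means.

    ``coef`` maps factor-level tuples (one entry per factor, in ``factors``
    order) to the cell mean of the response; the residual variance and df
    come from the saturated (full-interaction) model.
    """

    factors: list
    coef: dict
    cell_n: dict
    residual_var: float
    df_resid: int
    vcov: np.ndarray          # of the formula-model coefficients
    n_obs: int
    result: object            # statsmodels RegressionResults (saturated fit)


def fit_factorial_ols(table: pd.DataFrame, response: str,
                      factors) -> OlsFit:
    """Least-squares cell means for a fully crossed factor design.

    Every observed factor cell must be non-empty, and the model must leave
    at least one residual degree of freedom.
    """
    factors = list(factors)
    data = table.dropna(subset=[response]).copy()
    if not np.all(np.isfinite(data[response])):
        raise ValueError("response contains non-finite values")
    groups = data.groupby(factors, sort=True, observed=True)
    counts = groups.size()
    if counts.empty:
        raise ValueError("no observations")
    cell_n = {k if isinstance(k, tuple) else (k,): int(v)
              for k, v in counts.items()}
    means = {k if isinstance(k, tuple) else (k,): float(v)
             for k, v in groups[response].mean().items()}

    rhs = " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    df_resid = int(fit.df_resid)
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom; add replicates")
    return OlsFit(
        factors=factors, coef=means, cell_n=cell_n,
        residual_var=float(fit.mse_resid), df_resid=df_resid,
        vcov=np.asarray(fit.cov_params()), n_obs=int(fit.nobs), result=fit,
    )


@dataclass
class AnovaRow:
    term: str
    ss: float
    df: int
    F: float
    p: float
    omega_sq_p: float
    omega_sq_raw: float


def _term_blocks(data: pd.DataFrame, factors):
    """Full-dummy design blocks per factorial term (all orders)."""
    from itertools import combinations

    blocks = {}
    for order in range(1, len(factors) + 1):
        for combo in combinations(factors, order):
            labels = data[combo[0]].astype(str)
            for f in combo[1:]:
                labels = labels + "\x1f" + data[f].astype(str)
            blocks[":".join(combo)] = pd.get_dummies(labels).to_numpy(float)
    return blocks


def _rss_rank(columns, y):
    x = np.hstack(columns)
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def typeII_anova_F(fit: OlsFit):
    """Type-II sums of squares, F tests and partial omega-squared per term.

    Each term's SS is the residual-SS drop when adding it to the model that
    contains every term not containing it (type-II marginality), computed by
    explicit nested least-squares comparisons so that incomplete factorial
    designs (missing cells) are handled by rank rather than by aliased
    coefficients.  The error mean square comes from the full model.
    """
    data = fit.result.model.data.frame
    y = np.asarray(fit.result.model.endog, dtype=float)
    blocks = _term_blocks(data, fit.factors)
    ones = np.ones((len(y), 1))

    rss_full, rank_full = _rss_rank([ones] + list(blocks.values()), y)
    df_resid = len(y) - rank_full
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom")
    ms_error = rss_full / df_resid

    rows = []
    for term in blocks:
        parts = set(term.split(":"))
        others = [b for name, b in blocks.items()
                  if name != term and not parts < set(name.split(":"))]
        rss0, rank0 = _rss_rank([ones] + others, y)
        rss1, rank1 = _rss_rank([ones] + others + [blocks[term]], y)
        ss = max(rss0 - rss1, 0.0)
        df = rank1 - rank0
        if df < 1:
            warnings.warn(f"term {term} adds no estimable contrasts; skipped")
            continue
        F = (ss / df) / ms_error
        p = float(f_dist.sf(F, df, df_resid))
        raw = _omega_raw(ss, df, ms_error, fit.n_obs)
        rows.append(AnovaRow(term=term, ss=ss, df=df, F=float(F), p=p,
                             omega_sq_p=max(raw, 0.0), omega_sq_raw=raw))
    return rows


def _omega_raw(ss, df, ms_error, n_obs):
    denom = ss + (n_obs - df) * ms_error
    if denom <= 0:
        raise ValueError("ms_error must be positive with nonzero residual df")
    return (ss - df * ms_error) / denom


def partial_omega_sq(row: AnovaRow, ms_error: float, n_obs: int) -> float:
    """Partial omega-squared: (SS - df*MSE) / (SS + (N - df)*MSE), floored at 0.

    Negative raw values (effects below the noise floor) are reported as 0;
    the raw value is retained on the :class:`AnovaRow`.
    """
    if ms_error <= 0 and row.df > 0:
        raise ValueError("ms_error must be positive")
    return max(_omega_raw(row.ss, row.df, ms_error, n_obs), 0.0)


def emm_pairwise_rr(fit: OlsFit, within=None, across: str | None = None,
                    level: float = 0.95):
    """Pairwise fold-change (risk ratio) contrasts between factor levels.

    For each pair of ``across`` levels (within the fixed level ``within`` of
    the other factor, if given), the estimated-marginal-mean difference on
    the log2 scale is back-transformed as RR = 2^Delta, with t-based CI and
    p-value on residual df, and BH-FDR adjustment over the returned family.
    """
    across = across or fit.factors[-1]
    ai = fit.factors.index(across)
    cells = sorted(fit.coef)
    if within is not None:
        others = [f for f in fit.factors if f != across]
        oi = [fit.factors.index(f) for f in others]
        within = (within,) if not isinstance(within, tuple) else within
        cells = [c for c in cells
                 if tuple(c[i] for i in oi) == within]
    if not cells:
        raise ValueError(f"no cells for within={within!r}")
    levels = sorted({c[ai] for c in cells})
    by_level = {c[ai]: c for c in cells}
    unknown = [lv for lv in levels if lv not in by_level]
    if unknown:
        raise ValueError(f"unknown levels {unknown}")

    s = np.sqrt(fit.residual_var)
    tcrit = t_dist.ppf(0.5 + level / 2, fit.df_resid)
    out = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            ca, cb = by_level[levels[i]], by_level[levels[j]]
            diff = fit.coef[ca] - fit.coef[cb]
            se = s * np.sqrt(1.0 / fit.cell_n[ca] + 1.0 / fit.cell_n[cb])
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                p = 2.0 * t_dist.sf(abs(diff) / se, fit.df_resid)
            out.append(ContrastResult(
                label=f"{levels[i]} / {levels[j]}"
                      + (f" | {within}" if within is not None else ""),
                log_estimate=float(diff), ratio=float(2.0 ** diff),
                ci_low=float(2.0 ** (diff - tcrit * se)),
                ci_high=float(2.0 ** (diff + tcrit * se)),
                p_raw=float(p), p_adj=float(p), scale="log2",
            ))
    return adjust_family(out)
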