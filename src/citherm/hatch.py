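"""Zero-inflated binomial mixed model for egg-hatch counts.

The hatch analysis models, for each egg-lay replicate i in cell c(i)
(a strain x temperature x cross combination),

    y_i | not structural zero  ~  Binomial(n_i, logistic(eta_{c(i)} + u_i)),
    u_i ~ Normal(0, sigma^2)           (observation-level random effect),
    P(structural zero) = pi            (intercept-only zero inflation),

with a saturated cell-means fixed-effect parameterization: one logit per
cell, mathematically equivalent to the full factorial
strain * temperature * cross model but making estimated marginal means and
odds-ratio contrasts exact linear reads of the coefficient vector.

The per-record marginal likelihood integrates the observation-level effect
by Gauss-Hermite quadrature; the model is fitted by multi-start L-BFGS with
analytic gradients over (cell logits, log sigma, logit pi), and the
coefficient covariance is the inverse of the numerically differentiated
observed information at the optimum.

Downstream statistics: estimated marginal means per cell, odds-ratio
contrasts (CI strength OR_CI, rescue OR_R), ratios of odds ratios across
temperatures (OR_CI,T), type-II Wald chi-square tests with partial
eta-squared effect sizes, and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ZibFit",
    "CellMean",
    "ContrastResult",
    "ChiSqTest",
    "ModelSpecificationError",
    "filter_min_eggs",
    "zib_marginal_loglik",
    "fit_zib_glmm",
    "emm_cells",
    "odds_ratio_contrast",
    "ratio_of_odds_ratios",
    "typeII_wald_tests",
    "partial_eta_sq",
    "bh_fdr",
]

LOGIT_CAP = 8.0  # +/- cap on cell logits; keeps all-zero/all-perfect cells finite


class ModelSpecificationError(ValueError):
    """Raised when records reference cells the model cannot estimate."""


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class ZibFit:
    """Fitted zero-inflated binomial mixed model (cell-means form)."""

    cells: list                 # ordered (strain, temperature, cross) tuples
    cell_coef: dict             # cell -> logit-scale mean
    olre_sigma: float
    zi_prob: float
    vcov: np.ndarray            # over (cell logits..., log sigma[, logit pi])
    loglik: float
    n_obs: int
    converged: bool
    zero_inflated: bool
    capped_cells: list = field(default_factory=list)
    vcov_pseudo_inverse: bool = False

    @property
    def n_params(self):
        return len(self.cells) + 1 + (1 if self.zero_inflated else 0)

    def cell_index(self, cell):
        try:
            return self.cells.index(tuple(cell))
        except ValueError:
            raise ModelSpecificationError(f"unknown cell {cell!r}") from None


@dataclass(frozen=True)
class CellMean:
    cell: tuple
    estimate: float  # link (logit) scale
    se: float


@dataclass
class ContrastResult:
    label: str
    log_estimate: float
    ratio: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adj: float
    scale: str = "log-odds"


@dataclass(frozen=True)
class ChiSqTest:
    term: str
    chisq: float
    df: int
    p: float
    eta_sq_p: float | None = None


# ---------------------------------------------------------------------------
# Data handling
# ---------------------------------------------------------------------------

def filter_min_eggs(records, min_total: int = 10):
    """Drop replicates with fewer than ``min_total`` embryos (order kept)."""
    if isinstance(records, pd.DataFrame):
        return records.loc[records["eggs_total"] >= min_total].reset_index(drop=True)
    return [r for r in records if r.eggs_total >= min_total]


def _as_arrays(records):
    """Extract (y, n, cell tuple per record) from records or a DataFrame."""
    if isinstance(records, pd.DataFrame):
        y = records["eggs_hatched"].to_numpy(dtype=float)
        n = records["eggs_total"].to_numpy(dtype=float)
        cells = list(zip(records["strain"],
                         records["temperature_c"].astype(float),
                         records["cross_type"]))
    else:
        y = np.array([r.eggs_hatched for r in records], dtype=float)
        n = np.array([r.eggs_total for r in records], dtype=float)
        cells = [(r.strain, float(r.temperature), r.cross_type) for r in records]
    return y, n, cells


def _gh_nodes(quad_order):
    z, w = np.polynomial.hermite.hermgauss(quad_order)
    return z, w / np.sqrt(np.pi)


def _log_binom_pointmass(y, n, eta):
    logc = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return logc + y * eta - n * np.logaddexp(0.0, eta)


def _agq(y, n, eta, sigma, quad_order):
    """Adaptive Gauss-Hermite marginalization of the OLRE integral.

    For each record the quadrature is centered at the mode of the joint
    log-density h(u) = log Binom(y; n, logistic(eta+u)) + log N(u; 0, s^2)
    and scaled by its curvature, which reaches ~1e-10 relative accuracy at
    25 nodes.  Returns (log B, node deviates u, normalized node weights).
    """
    z, w = _gh_nodes(quad_order)
    logc = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    inv_var = 1.0 / sigma**2

    # Newton iterations for the per-record mode of h(u)
    u_hat = np.zeros_like(eta)
    for _ in range(50):
        p = expit(eta + u_hat)
        grad = y - n * p - u_hat * inv_var
        hess = -n * p * (1 - p) - inv_var
        step = grad / hess
        u_hat -= step
        if np.max(np.abs(step)) < 1e-12:
            break
    p = expit(eta + u_hat)
    s = 1.0 / np.sqrt(n * p * (1 - p) + inv_var)      # curvature scale

    u = u_hat[:, None] + np.sqrt(2.0) * s[:, None] * z[None, :]
    lin = eta[:, None] + u
    h = (logc[:, None] + y[:, None] * lin
         - n[:, None] * np.logaddexp(0.0, lin)
         - 0.5 * u**2 * inv_var
         - np.log(sigma) - 0.5 * np.log(2 * np.pi))
    # _gh_nodes returns w/sqrt(pi); the raw GH weights need the sqrt(pi) back
    log_terms = np.log(w)[None, :] + 0.5 * np.log(np.pi) + z[None, :]**2 + h
    log_b = logsumexp(log_terms, axis=1) + 0.5 * np.log(2.0) + np.log(s)
    post = np.exp(log_terms - logsumexp(log_terms, axis=1)[:, None])
    return log_b, u, post


def _log_binom_mix(y, n, eta, sigma, quad_order):
    """log of the OLRE-marginal binomial probability, per record."""
    if sigma == 0.0:
        return _log_binom_pointmass(y, n, eta)
    log_b, _, _ = _agq(y, n, eta, sigma, quad_order)
    return log_b


def zib_marginal_loglik(params, records, quad_order: int = 25) -> float:
    """Marginal log-likelihood of the zero-inflated binomial mixed model.

    ``params`` is a mapping with keys ``cell_logit`` (cell -> eta), ``sigma``
    (>= 0) and ``pi`` (in [0, 1]).
    """
    if quad_order < 5:
        raise ValueError("quad_order must be >= 5")
    y, n, rec_cells = _as_arrays(records)
    cell_logit = params["cell_logit"]
    try:
        eta = np.array([cell_logit[c] for c in rec_cells], dtype=float)
    except KeyError as exc:
        raise ModelSpecificationError(f"record in unknown cell {exc.args[0]!r}")
    sigma = float(params["sigma"])
    pi = float(params["pi"])
    log_b = _log_binom_mix(y, n, eta, sigma, quad_order)
    ll = _mixture_loglik(y, log_b, pi)
    total = float(ll.sum())
    if not np.isfinite(total):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(f"non-finite log-likelihood at record {bad}")
    return total


def _mixture_loglik(y, log_b, pi):
    if pi <= 0.0:
        return log_b
    with np.errstate(divide="ignore"):
        log_pi, log_1mpi = np.log(pi), np.log1p(-pi)
    ll = log_1mpi + log_b
    zero = y == 0
    if zero.any():
        ll = ll.copy()
        ll[zero] = np.logaddexp(log_pi, log_1mpi + log_b[zero])
    return ll


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _negloglik_and_grad(theta, y, n, idx, n_cells, quad_order, zero_inflated,
                        fixed_sigma=None):
    """Negative log-likelihood and analytic gradient.

    theta = (eta_1..eta_C[, log sigma][, logit pi]); the log-sigma entry is
    absent when ``fixed_sigma`` is given.
    """
    eta_cells = theta[:n_cells]
    pos = n_cells
    if fixed_sigma is None:
        sigma = np.exp(theta[pos])
        pos += 1
    else:
        sigma = float(fixed_sigma)
    pi = expit(theta[pos]) if zero_inflated else 0.0
    eta = eta_cells[idx]

    if sigma == 0.0:
        log_b = _log_binom_pointmass(y, n, eta)
        dB_deta = y - n * expit(eta)
        dB_dlogsig = None
    else:
        log_b, u, post = _agq(y, n, eta, sigma, quad_order)
        lin = eta[:, None] + u
        resid = y[:, None] - n[:, None] * expit(lin)  # d log f / d eta at node
        dB_deta = (post * resid).sum(axis=1)          # (1/B) dB/deta
        # d log N(u;0,s^2) / d log s = u^2/s^2 - 1, holding the nodes fixed
        dB_dlogsig = (post * (u**2 / sigma**2 - 1.0)).sum(axis=1)

    zero = y == 0
    if zero_inflated and pi > 0.0:
        b = np.exp(log_b)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            denom = np.where(zero, pi + (1 - pi) * b, (1 - pi) * b)
            ll = np.where(zero, np.log(denom), np.log1p(-pi) + log_b)
            # weight of the binomial branch in the mixture, per record
            w_bin = np.where(zero, (1 - pi) * b / denom, 1.0)
            dl_dpi = np.where(zero, (1 - b) / denom, -1.0 / (1 - pi))
        dl_dzpi = dl_dpi * pi * (1 - pi)        # wrt logit pi
    else:
        ll = log_b
        w_bin = np.ones_like(log_b)
        dl_dzpi = None

    g_eta_rec = w_bin * dB_deta
    g_eta = np.zeros(n_cells)
    np.add.at(g_eta, idx, g_eta_rec)
    g = np.concatenate([
        g_eta,
        [float((w_bin * dB_dlogsig).sum())] if dB_dlogsig is not None else [],
        [float(dl_dzpi.sum())] if dl_dzpi is not None else [],
    ])
    return -float(ll.sum()), -g


def _empirical_start(y, n, idx, n_cells):
    eta0 = np.zeros(n_cells)
    for c in range(n_cells):
        mask = idx == c
        p = (y[mask].sum() + 0.5) / (n[mask].sum() + 1.0)
        eta0[c] = np.clip(np.log(p / (1 - p)), -LOGIT_CAP, LOGIT_CAP)
    return eta0


def fit_zib_glmm(records, design=None, quad_order: int = 25,
                 zero_inflated: bool = True,
                 fixed_sigma: float | None = None) -> ZibFit:
    """Maximum-likelihood fit of the zero-inflated binomial mixed model.

    Uses three deterministic starting points and keeps the best optimum.
    If the zero-inflated likelihood cannot be maximized (or the data contain
    no zero-hatch replicates, leaving pi unidentifiable), the model is refit
    without zero inflation and ``zero_inflated`` is False on the result.
    ``fixed_sigma`` fixes the observation-level SD instead of estimating it
    (0 gives the plain (zero-inflated) binomial nested model).
    """
    y, n, rec_cells = _as_arrays(records)
    if design is not None:
        expected = set(design.cells)
        empty = sorted(expected - set(rec_cells))
        if empty:
            raise ModelSpecificationError(f"cells with zero records: {empty}")
    cells = sorted(set(rec_cells))
    cell_pos = {c: i for i, c in enumerate(cells)}
    idx = np.array([cell_pos[c] for c in rec_cells])
    n_cells = len(cells)

    if zero_inflated and not (y == 0).any():
        # no zero counts: the zero-inflation mass is unidentifiable
        return fit_zib_glmm(records, design, quad_order,
                            zero_inflated=False, fixed_sigma=fixed_sigma)

    eta0 = _empirical_start(y, n, idx, n_cells)
    est_sigma = fixed_sigma is None

    def _start(eta, log_sig, zpi):
        extra = ([log_sig] if est_sigma else []) \
            + ([zpi] if zero_inflated else [])
        return np.concatenate([eta, extra])

    starts = [
        _start(eta0, np.log(0.5), _safe_logit(0.05)),
        _start(eta0, np.log(1.5), _safe_logit(0.15)),
        _start(np.zeros(n_cells), np.log(0.8), _safe_logit(0.05)),
    ]
    bounds = ([(-LOGIT_CAP, LOGIT_CAP)] * n_cells
              + ([(-10.0, 3.0)] if est_sigma else [])
              + ([(-12.0, 12.0)] if zero_inflated else []))

    best = None
    for x0 in starts:
        res = minimize(
            _negloglik_and_grad, x0, jac=True,
            args=(y, n, idx, n_cells, quad_order, zero_inflated, fixed_sigma),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res

    if zero_inflated and not best.success:
        return fit_zib_glmm(records, design, quad_order,
                            zero_inflated=False, fixed_sigma=fixed_sigma)

    theta = best.x
    vcov, pseudo = _observed_info_vcov(
        theta, y, n, idx, n_cells, quad_order, zero_inflated, fixed_sigma)
    capped = [cells[i] for i in range(n_cells)
              if abs(theta[i]) >= LOGIT_CAP - 1e-6]
    sigma = float(np.exp(theta[n_cells])) if est_sigma else float(fixed_sigma)
    pi_pos = n_cells + (1 if est_sigma else 0)
    return ZibFit(
        cells=cells,
        cell_coef={c: float(theta[i]) for i, c in enumerate(cells)},
        olre_sigma=sigma,
        zi_prob=float(expit(theta[pi_pos])) if zero_inflated else 0.0,
        vcov=vcov,
        loglik=-float(best.fun),
        n_obs=len(y),
        converged=bool(best.success),
        zero_inflated=zero_inflated,
        capped_cells=capped,
        vcov_pseudo_inverse=pseudo,
    )


def _safe_logit(p):
    return float(np.log(p / (1 - p)))


def _observed_info_vcov(theta, y, n, idx, n_cells, quad_order, zero_inflated,
                        fixed_sigma=None):
    """Invert the numerically differentiated observed information."""
    p = len(theta)
    hess = np.empty((p, p))
    step = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step[j]
        tm[j] -= step[j]
        _, gp = _negloglik_and_grad(tp, y, n, idx, n_cells, quad_order,
                                    zero_inflated, fixed_sigma)
        _, gm = _negloglik_and_grad(tm, y, n, idx, n_cells, quad_order,
                                    zero_inflated, fixed_sigma)
        hess[:, j] = (gp - gm) / (2 * step[j])
    hess = 0.5 * (hess + hess.T)
    try:
        vcov = np.linalg.inv(hess)
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
            raise np.linalg.LinAlgError
        return vcov, False
    except np.linalg.LinAlgError:
        warnings.warn("singular observed information; using pseudo-inverse")
        return np.linalg.pinv(hess), True


# ---------------------------------------------------------------------------
# Marginal means and contrasts
# ---------------------------------------------------------------------------

def emm_cells(fit: ZibFit):
    """Estimated marginal mean (logit scale) and Wald SE for every cell."""
    out = []
    for i, c in enumerate(fit.cells):
        out.append(CellMean(cell=c, estimate=fit.cell_coef[c],
                            se=float(np.sqrt(max(fit.vcov[i, i], 0.0)))))
    return out


def _linear_contrast(fit, weights, label, scale="log-odds", level=0.95):
    est = float(weights @ np.array([fit.cell_coef[c] for c in fit.cells]))
    var = float(weights @ fit.vcov[: len(fit.cells), : len(fit.cells)] @ weights)
    se = np.sqrt(max(var, 0.0))
    zcrit = norm.ppf(0.5 + level / 2)
    if se == 0.0:
        p = 1.0 if est == 0.0 else 0.0
    else:
        p = 2.0 * norm.sf(abs(est) / se)
    return ContrastResult(
        label=label, log_estimate=est, ratio=float(np.exp(est)),
        ci_low=float(np.exp(est - zcrit * se)),
        ci_high=float(np.exp(est + zcrit * se)),
        p_raw=float(p), p_adj=float(p), scale=scale,
    )


def odds_ratio_contrast(fit: ZibFit, cell_a, cell_b,
                        label: str | None = None) -> ContrastResult:
    """Odds ratio of hatching in ``cell_a`` relative to ``cell_b``.

    With cell-a the CI cross and cell-b the compatible control this is the
    CI-strength odds ratio OR_CI (1 = no CI, < 1 = CI); with a rescue cross
    it is the rescue odds ratio OR_R.
    """
    ia, ib = fit.cell_index(cell_a), fit.cell_index(cell_b)
    w = np.zeros(len(fit.cells))
    w[ia] += 1.0
    w[ib] -= 1.0
    return _linear_contrast(fit, w, label or f"{cell_a} / {cell_b}")


def ratio_of_odds_ratios(fit: ZibFit, pair_cool, pair_warm,
                         label: str | None = None) -> ContrastResult:
    """OR_CI,T: odds ratio of odds ratios between two temperatures.

    Each pair is (numerator cell, denominator cell) — typically the CI and
    compatible cells at one temperature.  Values > 1 mean stronger CI at the
    warm temperature, < 1 stronger CI at the cool temperature.
    """
    w = np.zeros(len(fit.cells))
    (a1, b1), (a2, b2) = pair_cool, pair_warm
    w[fit.cell_index(a1)] += 1.0
    w[fit.cell_index(b1)] -= 1.0
    w[fit.cell_index(a2)] -= 1.0
    w[fit.cell_index(b2)] += 1.0
    return _linear_contrast(fit, w, label or "OR_CI,T")


# ---------------------------------------------------------------------------
# Type-II Wald tests
# ---------------------------------------------------------------------------

def _sum_code(levels):
    """Sum-to-zero contrast columns for one factor (levels x (L-1))."""
    L = len(levels)
    mat = np.zeros((L, L - 1))
    mat[: L - 1, :] = np.eye(L - 1)
    mat[L - 1, :] = -1.0
    return mat


def _term_columns(cells, factors):
    """Design columns per model term over the cell list.

    ``factors`` maps factor name -> position extractor over a cell tuple.
    Returns an ordered dict term name -> (n_cells x k) array, for all main
    effects and interactions up to the full order.
    """
    from itertools import combinations

    names = list(factors)
    level_maps = {}
    codes = {}
    for f in names:
        levels = sorted({factors[f](c) for c in cells})
        level_maps[f] = {lv: i for i, lv in enumerate(levels)}
        contrast = _sum_code(levels)
        rows = np.array([level_maps[f][factors[f](c)] for c in cells])
        codes[f] = contrast[rows]          # n_cells x (L_f - 1)

    terms = {}
    for order in range(1, len(names) + 1):
        for combo in combinations(names, order):
            cols = codes[combo[0]]
            for f in combo[1:]:
                cols = np.einsum("ni,nj->nij", cols, codes[f]).reshape(
                    len(cells), -1)
            terms[":".join(combo)] = cols
    return terms


def typeII_wald_tests(fit: ZibFit, factors=None, weights=None):
    """Type-II Wald chi-square test for every factorial term.

    Each term is tested adjusted for all terms that do not contain it
    (type-II marginality), via contrasts on the cell means: the term's
    design columns are residualized against the conditioning terms in the
    weighted cell inner product, giving a hypothesis matrix L with
    chi^2 = (L mu)' (L V L')^-1 (L mu).

    ``factors`` maps factor name -> extractor over the cell tuple; default
    is strain/temperature/cross from 3-tuples.  ``weights`` are per-cell
    information weights (default: equal).
    """
    if factors is None:
        factors = {
            "strain": lambda c: c[0],
            "temperature": lambda c: c[1],
            "cross": lambda c: c[2],
        }
    cells = fit.cells
    C = len(cells)
    mu = np.array([fit.cell_coef[c] for c in cells])
    V = fit.vcov[:C, :C]
    W = np.ones(C) if weights is None else np.asarray(weights, dtype=float)

    terms = _term_columns(cells, factors)
    results = []
    for term, X2 in terms.items():
        others = [X for name, X in terms.items()
                  if name != term and not _contains(name, term)]
        X1 = np.hstack([np.ones((C, 1))] + others)
        # residualize X2 against X1 under the weighted inner product
        WX1 = W[:, None] * X1
        beta = np.linalg.lstsq(X1.T @ WX1, X1.T @ (W[:, None] * X2),
                               rcond=None)[0]
        Z = X2 - X1 @ beta
        L = (W[:, None] * Z).T                      # hypothesis rows
        rank = np.linalg.matrix_rank(L, tol=1e-8)
        if rank < L.shape[0]:
            warnings.warn(f"rank-deficient contrasts for term {term}; "
                          f"df reduced to {rank}")
            # keep an independent row subset
            q, r, piv = _qr_pivot(L.T)
            L = L[piv[:rank]]
        stat_mat = L @ V @ L.T
        est = L @ mu
        try:
            chisq = float(est @ np.linalg.solve(stat_mat, est))
        except np.linalg.LinAlgError:
            chisq = float(est @ np.linalg.pinv(stat_mat) @ est)
        chisq = max(chisq, 0.0)
        df = int(rank)
        results.append(ChiSqTest(term=term, chisq=chisq, df=df,
                                 p=float(chi2.sf(chisq, df))))
    return results


def _contains(name_a, name_b):
    """True if term A contains term B (marginality)."""
    return set(name_b.split(":")) < set(name_a.split(":"))


def _qr_pivot(a):
    from scipy.linalg import qr
    q, r, piv = qr(a, pivoting=True)
    return q, r, piv


# ---------------------------------------------------------------------------
# Effect sizes and multiplicity
# ---------------------------------------------------------------------------

def partial_eta_sq(chisq: float, n: int) -> float:
    """Partial eta-squared from a Wald chi-square: chi^2 / (chi^2 + n)."""
    if chisq < 0:
        raise ValueError("chisq must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return chisq / (chisq + n)


def bh_fdr(p_values) -> list:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def adjust_family(contrasts) -> list:
    """Fill ``p_adj`` across one declared FDR family of contrasts."""
    adj = bh_fdr([c.p_raw for c in contrasts])
    for c, a in zip(contrasts, adj):
        c.p_adj = float(a)
    return contrasts
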