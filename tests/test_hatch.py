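"""Hatch model: quadrature oracle, GLM agreement, contrasts, FDR."""

import math

import numpy as np
import pytest
from scipy import stats

from citherm import hatch
from citherm import simulate as sim
from tests.conftest import recovery_design


def _records(design, logits, sigma=0.0, pi=0.0, seed=0, eggs=30.0):
    params = sim.SimParams(seed=seed, olre_sigma=sigma, zi_prob=pi,
                           egg_count_mean=eggs, egg_count_dispersion=10.0)
    params.cell_logit_mean = dict(logits)
    return sim.simulate_crosses(design, params)


class TestFilterMinEggs:
    def test_boundary_inclusive_at_ten(self):
        recs = [sim.CrossRecord("A", 23, "ci", n, 0, f"r{n}")
                for n in (3, 10, 25)]
        kept = hatch.filter_min_eggs(recs)
        assert [r.eggs_total for r in kept] == [10, 25]

    def test_empty_input(self):
        assert hatch.filter_min_eggs([]) == []

    def test_matches_brute_force_recount(self):
        design = sim.build_design({"strains": ["A"], "temperatures": [23],
                                   "cross_types": ["ci"],
                                   "replicates_per_cell": 1000})
        params = sim.SimParams(seed=3, egg_count_mean=30.0,
                               egg_count_dispersion=2.0)
        params.cell_logit_mean = {c: 0.0 for c in design.cells}
        recs = sim.simulate_crosses(design, params)
        kept = hatch.filter_min_eggs(recs)
        assert len(kept) == sum(1 for r in recs if r.eggs_total >= 10)


class TestMarginalLoglik:
    def test_degenerate_mixture_equals_binomial(self):
        recs = [sim.CrossRecord("A", 23, "ci", 20, y, f"r{y}")
                for y in (0, 7, 20)]
        params = {"cell_logit": {("A", 23.0, "ci"): 0.3},
                  "sigma": 0.0, "pi": 0.0}
        ll = hatch.zib_marginal_loglik(params, recs)
        oracle = sum(stats.binom.logpmf(y, 20, 1 / (1 + math.exp(-0.3)))
                     for y in (0, 7, 20))
        assert ll == pytest.approx(oracle, abs=1e-9)

    def test_pure_zero_inflation_all_zero_records(self):
        recs = [sim.CrossRecord("A", 23, "ci", 20, 0, f"r{i}")
                for i in range(5)]
        params = {"cell_logit": {("A", 23.0, "ci"): 0.0},
                  "sigma": 0.5, "pi": 1.0}
        assert hatch.zib_marginal_loglik(params, recs) == pytest.approx(0.0,
                                                                        abs=1e-12)

    def test_quadrature_matches_trapezoid_oracle(self):
        """Gauss-Hermite vs a dense trapezoid integral on one record."""
        y, n, eta, sigma = 7, 20, 0.3, 0.8
        recs = [sim.CrossRecord("A", 23, "ci", n, y, "r")]
        params = {"cell_logit": {("A", 23.0, "ci"): eta},
                  "sigma": sigma, "pi": 0.0}
        ll = hatch.zib_marginal_loglik(params, recs, quad_order=25)
        u = np.linspace(-8 * sigma, 8 * sigma, 10001)
        integrand = (stats.binom.pmf(y, n, 1 / (1 + np.exp(-(eta + u))))
                     * stats.norm.pdf(u, 0, sigma))
        oracle = math.log(np.trapezoid(integrand, u))
        assert abs(ll - oracle) < 1e-6

    def test_unknown_cell_errors(self):
        recs = [sim.CrossRecord("A", 23, "ci", 20, 5, "r")]
        with pytest.raises(hatch.ModelSpecificationError):
            hatch.zib_marginal_loglik(
                {"cell_logit": {("B", 23.0, "ci"): 0.0},
                 "sigma": 0.1, "pi": 0.0}, recs)


class TestFitZibGlmm:
    def test_nested_agreement_with_plain_logistic(self, small_design):
        """With sigma=0, pi=0 truth, contrasts match a binomial GLM."""
        import statsmodels.api as smapi

        logits = {c: (1.2 if c[2] == "compatible" else -0.8)
                  for c in small_design.cells}
        recs = _records(small_design, logits, seed=21, eggs=40.0)
        fit = hatch.fit_zib_glmm(recs)
        assert fit.olre_sigma < 0.05  # boundary

        y, n, cells = hatch._as_arrays(recs)
        cell_list = fit.cells
        x = np.zeros((len(y), len(cell_list)))
        for i, c in enumerate(cells):
            x[i, cell_list.index(c)] = 1.0
        glm = smapi.GLM(np.column_stack([y, n - y]), x,
                        family=smapi.families.Binomial()).fit()
        for i, c in enumerate(cell_list):
            assert fit.cell_coef[c] == pytest.approx(glm.params[i], abs=1e-3)

    def test_sigma_pi_point_recovery(self):
        design, logits = recovery_design()
        recs = _records(design, logits, sigma=0.6, pi=0.05, seed=4, eggs=24.0)
        fit = hatch.fit_zib_glmm(hatch.filter_min_eggs(recs))
        assert fit.converged and fit.zero_inflated
        assert abs(fit.olre_sigma - 0.6) < 0.25
        assert abs(fit.zi_prob - 0.05) < 0.05

    def test_no_zero_records_falls_back_to_plain_model(self, small_design):
        logits = {c: 3.5 for c in small_design.cells}  # ~97% hatch
        recs = _records(small_design, logits, seed=8, eggs=40.0)
        assert not any(r.eggs_hatched == 0 for r in recs)
        fit = hatch.fit_zib_glmm(recs)
        assert fit.zero_inflated is False
        assert fit.zi_prob == 0.0

    def test_empty_design_cell_errors(self, small_design):
        logits = {c: 0.0 for c in small_design.cells}
        recs = _records(small_design, logits, seed=1)
        recs = [r for r in recs if not (r.strain == "A"
                                        and r.cross_type == "ci")]
        with pytest.raises(hatch.ModelSpecificationError):
            hatch.fit_zib_glmm(recs, design=small_design)

    def test_vcov_symmetric(self, small_design):
        logits = {c: 0.5 for c in small_design.cells}
        fit = hatch.fit_zib_glmm(_records(small_design, logits, sigma=0.4,
                                          pi=0.05, seed=2))
        assert np.max(np.abs(fit.vcov - fit.vcov.T)) < 1e-8


@pytest.fixture(scope="module")
def fitted():
    design, logits = recovery_design()
    recs = _records(design, logits, sigma=0.5, pi=0.04, seed=6, eggs=30.0)
    return hatch.fit_zib_glmm(hatch.filter_min_eggs(recs))


class TestEmmAndContrasts:

    def test_emm_equals_cell_coefficient(self, fitted):
        for m in hatch.emm_cells(fitted):
            assert m.estimate == fitted.cell_coef[m.cell]
            assert m.se >= 0

    def test_emm_matches_empirical_logit_without_noise(self, small_design):
        """The nested plain-binomial model's EMMs are pooled empirical logits."""
        logits = {c: 0.6 for c in small_design.cells}
        recs = _records(small_design, logits, seed=13, eggs=40.0)
        fit = hatch.fit_zib_glmm(recs, fixed_sigma=0.0)
        assert fit.olre_sigma == 0.0
        y, n, cells = hatch._as_arrays(recs)
        for m in hatch.emm_cells(fit):
            mask = [c == m.cell for c in cells]
            p = y[mask].sum() / n[mask].sum()
            assert m.estimate == pytest.approx(math.log(p / (1 - p)),
                                               abs=1e-6)

    def test_replication_shrinks_se(self):
        design = sim.build_design({
            "strains": ["A"], "temperatures": [18.0, 23.0],
            "cross_types": ["ci"], "replicates_per_cell": 20,
        })
        logits = {c: 0.0 for c in design.cells}
        recs = _records(design, logits, sigma=0.3, pi=0.02, seed=3)
        dense = [r for r in recs if r.temperature == 18.0]
        sparse = [r for r in recs if r.temperature == 23.0][:2]
        fit = hatch.fit_zib_glmm(dense + sparse)
        ses = {m.cell[1]: m.se for m in hatch.emm_cells(fit)}
        assert ses[18.0] < ses[23.0]

    def test_identity_contrast(self, fitted):
        cell = fitted.cells[0]
        res = hatch.odds_ratio_contrast(fitted, cell, cell)
        assert res.ratio == pytest.approx(1.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_odds_arithmetic_converges(self):
        design = sim.build_design({
            "strains": ["A"], "temperatures": [23.0],
            "cross_types": ["compatible", "ci"], "replicates_per_cell": 400,
        })
        logits = {("A", 23.0, "ci"): math.log(0.2 / 0.8),
                  ("A", 23.0, "compatible"): math.log(0.8 / 0.2)}
        recs = _records(design, logits, seed=10, eggs=50.0)
        fit = hatch.fit_zib_glmm(recs)
        res = hatch.odds_ratio_contrast(fit, ("A", 23.0, "ci"),
                                        ("A", 23.0, "compatible"))
        assert res.ratio == pytest.approx(1 / 16, rel=0.10)

    def test_log_scale_transitivity_exact(self, fitted):
        a, b, c = fitted.cells[:3]
        ab = hatch.odds_ratio_contrast(fitted, a, b).log_estimate
        bc = hatch.odds_ratio_contrast(fitted, b, c).log_estimate
        ac = hatch.odds_ratio_contrast(fitted, a, c).log_estimate
        assert ac == pytest.approx(ab + bc, abs=1e-12)

    def test_equal_or_at_both_temperatures_gives_unit_ratio(self, fitted):
        # engineer a fit with identical OR at two temperatures
        fit = hatch.ZibFit(
            cells=[("A", 18.0, "ci"), ("A", 18.0, "compatible"),
                   ("A", 23.0, "ci"), ("A", 23.0, "compatible")],
            cell_coef={("A", 18.0, "ci"): -2.0, ("A", 18.0, "compatible"): 1.0,
                       ("A", 23.0, "ci"): -2.5, ("A", 23.0, "compatible"): 0.5},
            olre_sigma=0.1, zi_prob=0.0, vcov=np.eye(5) * 0.01,
            loglik=0.0, n_obs=1, converged=True, zero_inflated=False)
        res = hatch.ratio_of_odds_ratios(
            fit, (("A", 18.0, "ci"), ("A", 18.0, "compatible")),
            (("A", 23.0, "ci"), ("A", 23.0, "compatible")))
        assert res.ratio == pytest.approx(1.0)

    def test_unknown_cell_errors(self, fitted):
        with pytest.raises(hatch.ModelSpecificationError):
            hatch.odds_ratio_contrast(fitted, ("nope", 0.0, "ci"),
                                      fitted.cells[0])


class TestTypeIIWald:
    def test_additive_truth_zeroes_interaction(self):
        """Hand-built additive cell means give ~zero interaction chi-square."""
        cells = [("A", 18.0, "x"), ("A", 23.0, "x"),
                 ("B", 18.0, "x"), ("B", 23.0, "x")]
        coef = {("A", 18.0, "x"): 0.0, ("A", 23.0, "x"): 1.0,
                ("B", 18.0, "x"): 0.5, ("B", 23.0, "x"): 1.5}
        fit = hatch.ZibFit(cells=cells, cell_coef=coef, olre_sigma=0.1,
                           zi_prob=0.0, vcov=np.eye(5) * 0.04, loglik=0.0,
                           n_obs=40, converged=True, zero_inflated=False)
        tests = hatch.typeII_wald_tests(fit, factors={
            "strain": lambda c: c[0], "temperature": lambda c: c[1]})
        by_term = {t.term: t for t in tests}
        assert by_term["strain:temperature"].chisq == pytest.approx(0.0,
                                                                    abs=1e-10)
        assert by_term["strain:temperature"].p == pytest.approx(1.0)
        assert by_term["temperature"].chisq > 1.0

    def test_balanced_equals_direct_orthogonal_wald(self, small_design):
        """Under balance, type-II equals the direct sum-contrast Wald test."""
        logits = {c: (0.8 if c[2] == "compatible" else -0.5)
                  + (0.3 if c[0] == "A" else 0.0) for c in small_design.cells}
        recs = _records(small_design, logits, sigma=0.3, pi=0.03, seed=17)
        fit = hatch.fit_zib_glmm(recs)
        tests = {t.term: t for t in hatch.typeII_wald_tests(fit)}

        # independent construction: orthonormal sum contrasts per factor
        cells = fit.cells
        mu = np.array([fit.cell_coef[c] for c in cells])
        V = fit.vcov[:len(cells), :len(cells)]

        def contrast(extract):
            levels = sorted({extract(c) for c in cells})
            row = np.array([1.0 if extract(c) == levels[0] else -1.0
                            for c in cells])
            return row / len(cells) * 2  # mean difference contrast

        for name, ex in (("strain", lambda c: c[0]),
                         ("temperature", lambda c: c[1]),
                         ("cross", lambda c: c[2])):
            L = contrast(ex)[None, :]
            chisq = float((L @ mu) @ np.linalg.solve(L @ V @ L.T, L @ mu))
            assert tests[name].chisq == pytest.approx(chisq, abs=1e-6)

    def test_cross_effect_dominates(self):
        design, _ = recovery_design()
        logits = {c: (1.5 if c[2] == "compatible" else
                      (-1.5 if c[2] == "ci" else 1.2))
                  for c in design.cells}
        recs = _records(design, logits, sigma=0.3, pi=0.02, seed=30,
                        eggs=30.0)
        fit = hatch.fit_zib_glmm(recs)
        tests = hatch.typeII_wald_tests(fit)
        top = max(tests, key=lambda t: t.chisq)
        assert top.term == "cross"


class TestEffectSizesAndFdr:
    def test_partial_eta_trivial_and_errors(self):
        assert hatch.partial_eta_sq(0.0, 100) == 0.0
        with pytest.raises(ValueError):
            hatch.partial_eta_sq(-1.0, 100)
        with pytest.raises(ValueError):
            hatch.partial_eta_sq(1.0, 0)

    def test_bh_closed_form(self):
        assert hatch.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])
        assert hatch.bh_fdr([0.2]) == [0.2]

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        adj = np.array(hatch.bh_fdr(p))
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_bh_order_equivariance(self):
        rng = np.random.default_rng(2)
        p = rng.random(20)
        perm = rng.permutation(20)
        adj = np.array(hatch.bh_fdr(p))
        adj_perm = np.array(hatch.bh_fdr(p[perm]))
        assert adj_perm == pytest.approx(adj[perm])

    def test_bh_rejects_invalid(self):
        with pytest.raises(ValueError):
            hatch.bh_fdr([0.5, 1.2])

    def test_fdr_control_under_global_null(self):
        """P(any BH rejection at alpha=.05 | 100 uniform nulls) <= ~alpha."""
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            adj = hatch.bh_fdr(rng.random(100))
            hits += any(a <= 0.05 for a in adj)
        # binomial slack: 0.05 +/- 3*sqrt(.05*.95/1000)
        assert hits / n_rep <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_rep)
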