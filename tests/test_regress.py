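"""Stepwise refinement: OLS contracts, selection policy, refined index.

The stepwise path is cross-checked against an independent brute-force
re-implementation of the entry/removal rules built on raw numpy least
squares (see ``brute_force_stepwise``), kept deliberately separate from
the statsmodels-based production path.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epivuln.indexing import unitize
from epivuln.regress import (
    RegressionError,
    adjusted_r2,
    ols,
    refined_index,
    stepwise_select,
    t_statistic,
    univariate_relate,
)
from epivuln.screening import screen
from epivuln.indexing import compute_all_indices


# ---------------------------------------------------------------------------
# independent oracle: numpy-only p-values and literal entry/removal rules
# ---------------------------------------------------------------------------

def _numpy_pvalues(y, X):
    """OLS two-sided p-values via the normal equations (intercept first)."""
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    dof = n - k - 1
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    t = coef / se
    return 2.0 * stats.t.sf(np.abs(t), dof)


def brute_force_stepwise(y, candidates: pd.DataFrame, alpha_enter=0.05, alpha_remove=0.10):
    """Literal application of the bidirectional rules, coded independently."""
    y = np.asarray(y, dtype=float)
    names = list(candidates.columns)
    data = {c: candidates[c].to_numpy(dtype=float) for c in names}
    included: list[str] = []
    seen = {frozenset()}
    while True:
        changed = False
        entry_p = {}
        for c in names:
            if c in included:
                continue
            X = np.column_stack([data[m] for m in included + [c]])
            entry_p[c] = _numpy_pvalues(y, X)[-1]
        if entry_p:
            best = min(entry_p, key=lambda c: (entry_p[c], names.index(c)))
            if entry_p[best] < alpha_enter:
                included.append(best)
                changed = True
        while included:
            X = np.column_stack([data[m] for m in included])
            pvals = _numpy_pvalues(y, X)[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] >= alpha_remove:
                del included[worst]
                changed = True
            else:
                break
        if not changed:
            return included
        state = frozenset(included)
        if state in seen:
            return included
        seen.add(state)


# ---------------------------------------------------------------------------
# reporting contracts
# ---------------------------------------------------------------------------

class TestReportingContracts:
    def test_t_is_coefficient_over_se(self):
        assert t_statistic(2.31, 0.64) == pytest.approx(3.61, abs=0.005)

    def test_adjusted_r2_formula(self):
        assert adjusted_r2(0.880**2, n=298, k=11) == pytest.approx(0.766, abs=5e-4)

    def test_adjusted_r2_needs_enough_observations(self):
        with pytest.raises(RegressionError):
            adjusted_r2(0.5, n=5, k=4)


class TestOls:
    def test_exact_line_recovered(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        fit = ols(pd.Series(2.0 * np.arange(10.0)), x)
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_simple_regression_matches_closed_form(self, rng):
        x = rng.normal(size=80)
        y = 1.5 * x + rng.normal(size=80)
        fit = ols(pd.Series(y), pd.DataFrame({"x": x}))
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fit.params["x"] == pytest.approx(slope)
        assert fit.adj_r2 == pytest.approx(adjusted_r2(fit.r2, 80, 1))
        # t = b/se holds for every reported term
        np.testing.assert_allclose(fit.tvalues, fit.params / fit.bse)

    def test_rank_deficiency_names_collinear_columns(self, rng):
        x1 = rng.normal(size=30)
        X = pd.DataFrame({"x1": x1, "x2": 2.0 * x1})
        with pytest.raises(RegressionError, match="collinear"):
            ols(pd.Series(rng.normal(size=30)), X)

    def test_too_few_observations_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 3)), columns=list("abc"))
        with pytest.raises(RegressionError):
            ols(pd.Series(rng.normal(size=3)), X)


class TestStepwiseSelect:
    def test_single_true_predictor_selected(self, rng):
        n = 50
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = pd.Series(3.0 * x1 + rng.normal(0, 0.5, n))
        result = stepwise_select(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert result.selected == ["x1"]
        assert result.fit.pvalues["x1"] < 0.05

    def test_null_y_rarely_selects(self):
        """Pure-noise dependent, 5 candidates: empty selection should occur
        in >= 70% of 100 replicates (per-candidate entry is anti-conservative
        but rarely admits more than one)."""
        empty = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            y = pd.Series(r.normal(size=200))
            X = pd.DataFrame(r.normal(size=(200, 5)), columns=list("abcde"))
            if stepwise_select(y, X).intercept_only:
                empty += 1
        assert empty >= 70

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        n, k = 40, r.integers(2, 5)
        X = pd.DataFrame(r.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
        coefs = r.choice([0.0, 0.0, 0.6, 1.2], size=k)
        y = pd.Series(X.to_numpy() @ coefs + r.normal(size=n))
        result = stepwise_select(y, X)
        assert result.selected == brute_force_stepwise(y, X)

    def test_deterministic_path(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = pd.Series(X["a"] * 2 + rng.normal(size=60))
        first = stepwise_select(y, X)
        second = stepwise_select(y, X)
        assert first.selected == second.selected
        assert first.trace == second.trace

    def test_constant_candidate_rejected(self, rng):
        y = pd.Series(rng.normal(size=100))
        with pytest.raises(RegressionError):
            stepwise_select(y, pd.DataFrame({"a": np.ones(100)}))

    def test_intercept_only_flagged_when_nothing_enters(self, rng):
        y = pd.Series(rng.normal(size=100))
        x = rng.normal(size=100)
        yc = y - y.mean()
        x = x - float(np.dot(x, yc) / np.dot(yc, yc)) * yc  # sample-uncorrelated
        result = stepwise_select(y, pd.DataFrame({"a": x}))
        assert result.intercept_only
        assert result.selected == [] and result.fit is None

    def test_selected_terms_significant_in_final_fit(self, rng):
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=list("abcdef"))
        y = pd.Series(X["a"] + 0.8 * X["b"] + rng.normal(size=n))
        result = stepwise_select(y, X)
        pvals = result.fit.pvalues.drop("const")
        assert (pvals < result.alpha_remove).all()


class TestRefinedIndex:
    def test_full_selection_reproduces_wo(self, packaged_registry, rng):
        codes = packaged_registry.codes
        table = pd.DataFrame(rng.uniform(0, 50, size=(40, len(codes))), columns=codes)
        screened, _ = screen(table, packaged_registry)
        indices = compute_all_indices(screened, packaged_registry)
        wo_pop = refined_index(screened, list(screened.columns), packaged_registry)
        np.testing.assert_allclose(wo_pop, indices["WO"], atol=1e-12)

    def test_single_stimulant_selection_is_its_unitized_column(
        self, toy_table, toy_registry
    ):
        wo_pop = refined_index(toy_table, ["A"], toy_registry)
        np.testing.assert_allclose(wo_pop, unitize(toy_table["A"], "stimulant"))

    def test_empty_selection_rejected(self, toy_table, toy_registry):
        with pytest.raises(RegressionError):
            refined_index(toy_table, [], toy_registry)


class TestUnivariateRelate:
    def test_identity_relation(self, rng):
        v = pd.Series(rng.uniform(size=50), name="WO_pop")
        fit = univariate_relate(v, v)
        assert fit.attr_on_index[1] == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_independent_attribute_has_tiny_r2(self, rng):
        attr = pd.Series(rng.normal(size=300))
        refined = pd.Series(rng.uniform(size=300))
        assert univariate_relate(attr, refined).r2 < 0.05

    def test_r2_equals_squared_pearson(self, rng):
        attr = pd.Series(rng.normal(size=40))
        refined = pd.Series(0.3 * attr + rng.normal(size=40))
        fit = univariate_relate(attr, refined)
        r = np.corrcoef(attr, refined)[0, 1]
        assert fit.r2 == pytest.approx(r**2)
        # both directions share r2; slopes are reciprocal-linked via r2
        b_fwd = fit.attr_on_index[1]
        b_rev = fit.index_on_attr[1]
        assert b_fwd * b_rev == pytest.approx(fit.r2)

    def test_constant_input_rejected(self):
        with pytest.raises(RegressionError):
            univariate_relate(pd.Series([1.0, 1.0, 1.0]), pd.Series([1.0, 2.0, 3.0]))
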