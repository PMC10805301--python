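"""Concordance ordinalisation, Spearman, proportional-odds fit, ORs, C."""

import math

import numpy as np
import pytest
from scipy import stats

from edac.agreement import JudgementPair
from edac.association import (
    ConcordanceLevel,
    ConcordanceTable,
    concordance_table,
    fit_cumulative_logit,
    intercept_only_cumulative_logits,
    ordinal_cindex,
    ordinalize,
    reported_or,
    spearman_ordinal,
)
from edac.core import EDACClass

AV, PO, NO = (
    EDACClass.AVOIDABLE,
    EDACClass.POTENTIALLY_AVOIDABLE,
    EDACClass.NOT_AVOIDABLE,
)


@pytest.mark.parametrize(
    "a, b, level",
    [
        (True, True, ConcordanceLevel.BOTH_SUBACUTE),
        (False, False, ConcordanceLevel.BOTH_ED),
        (True, False, ConcordanceLevel.DISCORDANT),
        (False, True, ConcordanceLevel.DISCORDANT),
    ],
)
def test_ordinalize(a, b, level):
    assert ordinalize(JudgementPair("v", AV, a, b)) is level


class TestConcordanceTable:
    def test_fixture_rows(self, fixture_table):
        assert fixture_table.row(AV).tolist() == [1, 1, 52]
        assert fixture_table.row(NO).tolist() == [33, 7, 13]
        assert fixture_table.row_margins.tolist() == [53, 53, 54]
        assert fixture_table.total == 160
        assert fixture_table.n_agreements == 139

    def test_single_pair_unit_cell(self):
        t = concordance_table([JudgementPair("v", PO, True, True)])
        assert t.total == 1
        assert t.counts[int(PO), int(ConcordanceLevel.BOTH_SUBACUTE)] == 1

    def test_round_trips_through_pairs(self, fixture_table):
        again = concordance_table(fixture_table.to_pairs())
        assert (again.counts == fixture_table.counts).all()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            concordance_table([])


def expand(table):
    x, y = [], []
    for r in range(3):
        for c in range(3):
            x += [r] * table.counts[r, c]
            y += [c] * table.counts[r, c]
    return x, y


class TestSpearman:
    def test_fixture_value(self, fixture_table):
        assert round(spearman_ordinal(fixture_table), 2) == 0.64

    def test_perfect_monotone_diagonal(self):
        t = ConcordanceTable(np.diag([5, 7, 9]))
        assert spearman_ordinal(t) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_scipy_on_random_tables(self, seed):
        """Enumeration oracle: tie-corrected Spearman from counts equals
        scipy's spearmanr on the explicitly expanded observations."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 12, size=(3, 3))
        counts[0, 0] += 1
        counts[1, 1] += 1  # keep both margins non-degenerate
        counts[2, 2] += 1
        t = ConcordanceTable(counts)
        rho_scipy = stats.spearmanr(*expand(t)).statistic
        assert spearman_ordinal(t) == pytest.approx(rho_scipy, abs=1e-12)

    def test_two_level_toy_table_against_enumeration(self):
        t = ConcordanceTable(np.array([[3, 0, 1], [0, 0, 0], [1, 0, 3]]))
        rho_scipy = stats.spearmanr(*expand(t)).statistic
        assert spearman_ordinal(t) == pytest.approx(rho_scipy, abs=1e-12)

    def test_degenerate_margin_signals(self):
        t = ConcordanceTable(np.array([[0, 5, 0], [0, 3, 0], [0, 2, 0]]))
        with pytest.raises(ArithmeticError):
            spearman_ordinal(t)


class TestCumulativeLogit:
    def test_matches_statsmodels_on_fixture(self, fixture_table):
        """Independent oracle: statsmodels OrderedModel on the expanded data."""
        sm = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
        import pandas as pd

        fit = fit_cumulative_logit(fixture_table)
        x, y = expand(fixture_table)
        df = pd.DataFrame({"cls": x, "y": y})
        ex = pd.get_dummies(df.cls.astype("category"), drop_first=True).astype(float)
        res = sm.OrderedModel(df.y, ex, distr="logit").fit(method="bfgs", disp=0)
        assert fit.beta["potentially_avoidable"] == pytest.approx(res.params.iloc[0], abs=1e-4)
        assert fit.beta["avoidable"] == pytest.approx(res.params.iloc[1], abs=1e-4)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-5)

    def test_identical_rows_give_zero_beta_and_marginal_thresholds(self):
        counts = np.array([[10, 5, 15], [10, 5, 15], [10, 5, 15]])
        t = ConcordanceTable(counts)
        fit = fit_cumulative_logit(t)
        assert fit.beta["avoidable"] == pytest.approx(0.0, abs=1e-6)
        assert fit.beta["potentially_avoidable"] == pytest.approx(0.0, abs=1e-6)
        th = intercept_only_cumulative_logits(t)
        assert fit.thresholds[0] == pytest.approx(th[0], abs=1e-6)
        assert fit.thresholds[1] == pytest.approx(th[1], abs=1e-6)

    def test_loglik_dominates_intercept_only(self, fixture_table):
        """Likelihood-ratio sanity: the full fit can never be worse than the
        intercept-only model."""
        fit = fit_cumulative_logit(fixture_table)
        th1, th2 = intercept_only_cumulative_logits(fixture_table)
        marg = fixture_table.col_margins.astype(float)
        n = marg.sum()
        cum = marg.cumsum() / n
        p = np.array([cum[0], cum[1] - cum[0], 1 - cum[1]])
        ll0 = float((marg * np.log(p)).sum())
        assert fit.loglik >= ll0 - 1e-9

    def test_thresholds_ordered_and_ors_exponentiate_beta(self, fixture_table):
        fit = fit_cumulative_logit(fixture_table)
        assert fit.thresholds[0] < fit.thresholds[1]
        for cls in ("potentially_avoidable", "avoidable"):
            assert fit.or_point[cls] == pytest.approx(math.exp(fit.beta[cls]))
        assert fit.or_point["not_avoidable"] == 1.0

    def test_empty_class_row_rejected(self):
        counts = np.array([[5, 5, 5], [0, 0, 0], [5, 5, 5]])
        with pytest.raises(ValueError, match="non-empty"):
            fit_cumulative_logit(ConcordanceTable(counts))

    def test_separation_flagged(self):
        counts = np.array([[20, 3, 2], [3, 5, 10], [0, 0, 25]])
        with pytest.warns(RuntimeWarning, match="extreme"):
            fit = fit_cumulative_logit(ConcordanceTable(counts))
        assert fit.separation_warning


class TestReportedOR:
    def test_fixture_avoidable(self, fixture_table):
        orv, (lo, hi) = reported_or(fixture_table, AV)
        assert round(orv, 1) == 80.0
        assert round(lo, 1) == 17.1
        assert round(hi, 1) == 374.9

    def test_fixture_potentially_avoidable(self, fixture_table):
        orv, (lo, hi) = reported_or(fixture_table, PO)
        assert round(orv, 1) == 7.1
        assert round(lo, 1) == 3.0
        assert round(hi, 1) == 16.8

    def test_referent_is_one(self, fixture_table):
        assert reported_or(fixture_table, NO)[0] == 1.0

    def test_matches_saturated_logistic_fit(self, fixture_table):
        """Oracle equivalence: the cross-product ratio equals exp(coef) of a
        binary logistic regression on the dichotomised outcome."""
        import pandas as pd
        import statsmodels.api as smapi

        rows = []
        for cls in (AV, NO):
            row = fixture_table.row(cls)
            rows.append((1 if cls is AV else 0, 1, row[2]))
            rows.append((1 if cls is AV else 0, 0, row[0] + row[1]))
        df = pd.DataFrame(rows, columns=["x", "y", "w"])
        res = smapi.GLM(
            df.y,
            smapi.add_constant(df.x.astype(float)),
            family=smapi.families.Binomial(),
            freq_weights=df.w,
        ).fit()
        assert reported_or(fixture_table, AV)[0] == pytest.approx(
            math.exp(res.params["x"]), rel=1e-6
        )

    def test_zero_cell_error_and_continuity(self):
        counts = np.array([[10, 0, 0], [2, 2, 2], [0, 0, 10]])
        t = ConcordanceTable(counts)
        with pytest.raises(ZeroDivisionError, match="continuity"):
            reported_or(t, AV)
        orv, _ = reported_or(t, AV, continuity=True)
        assert orv > 0


class TestCIndex:
    def test_fixture_value(self, fixture_table):
        assert round(ordinal_cindex(fixture_table), 2) == 0.84

    def test_perfect_separation(self):
        t = ConcordanceTable(np.diag([5, 5, 5]))
        assert ordinal_cindex(t) == 1.0

    def test_all_tied_scores_give_half(self, fixture_table):
        scores = {c: 0.0 for c in EDACClass}
        assert ordinal_cindex(fixture_table, scores) == 0.5

    def test_antisymmetric_under_score_reversal(self, fixture_table):
        c = ordinal_cindex(fixture_table)
        rev = {k: -float(int(k)) for k in EDACClass}
        assert ordinal_cindex(fixture_table, rev) == pytest.approx(1 - c)

    def test_bounded(self, fixture_table):
        assert 0.0 <= ordinal_cindex(fixture_table) <= 1.0

    def test_no_informative_pairs_signals(self):
        t = ConcordanceTable(np.array([[0, 5, 0], [0, 3, 0], [0, 2, 0]]))
        with pytest.raises(ArithmeticError):
            ordinal_cindex(t)
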