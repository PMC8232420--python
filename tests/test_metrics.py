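import numpy as np
import pytest
from hypothesis import given, strategies as st

from dilitree.metrics import (
    ConfusionMatrix,
    amw_contingency,
    atc_stratified,
    confusion,
    eq_metrics,
    roc_auc,
    round_half_away,
    yearly_amw_trend,
)
from dilitree.reference import AMW_SCREEN_COUNTS, expand_counts

cms = st.tuples(
    st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
).filter(lambda t: sum(t) > 0).map(lambda t: ConfusionMatrix(*t))


class TestConfusion:
    def test_all_positive(self):
        cm = confusion([1] * 5, [1] * 5)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (5, 0, 0, 0)

    def test_crossed(self):
        cm = confusion([1, 0], [0, 1])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (0, 0, 1, 1)

    def test_matches_direct_tally(self, rng):
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        cm = confusion(y, p)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for yi, pi in zip(y, p):
            key = ("t" if yi == pi else "f") + ("p" if pi == 1 else "n")
            tally[key] += 1
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"]
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1], [1, 0])


class TestEqMetrics:
    def test_published_confusion_matrix(self):
        r = eq_metrics(ConfusionMatrix(tp=384, tn=130, fp=90, fn=48)).rounded(2)
        assert r["sensitivity"] == 0.89
        assert r["specificity"] == 0.59
        assert r["balanced_accuracy"] == 0.74
        assert r["mcc"] == 0.51
        # exact-arithmetic accuracy is 514/652 = 0.788..., i.e. 0.79 at 2 dp
        assert r["accuracy"] == 0.79

    def test_perfect_classifier(self):
        r = eq_metrics(ConfusionMatrix(tp=10, tn=10, fp=0, fn=0))
        assert r.accuracy == r.sensitivity == r.specificity == 1.0
        assert r.mcc == 1.0

    def test_symmetric(self):
        r = eq_metrics(ConfusionMatrix(25, 25, 25, 25))
        assert r.accuracy == 0.5
        assert r.mcc == 0.0

    def test_undefined_not_zero(self):
        r = eq_metrics(ConfusionMatrix(tp=5, tn=0, fp=0, fn=1))
        assert r.specificity is None
        assert "specificity" in r.undefined
        assert r.balanced_accuracy is None

    @given(cms)
    def test_ba_identity(self, cm):
        r = eq_metrics(cm)
        if r.sensitivity is not None and r.specificity is not None:
            assert r.balanced_accuracy == (r.sensitivity + r.specificity) / 2

    @given(cms)
    def test_mcc_antisymmetric_under_prediction_flip(self, cm):
        r = eq_metrics(cm)
        flipped = eq_metrics(ConfusionMatrix(tp=cm.fn, tn=cm.fp, fp=cm.tn, fn=cm.tp))
        if r.mcc is not None and flipped.mcc is not None:
            assert flipped.mcc == pytest.approx(-r.mcc, abs=1e-12)

    @given(cms)
    def test_ranges(self, cm):
        r = eq_metrics(cm)
        for name in ("accuracy", "sensitivity", "specificity", "balanced_accuracy"):
            v = getattr(r, name)
            if v is not None:
                assert 0.0 <= v <= 1.0
        if r.mcc is not None:
            assert -1.0 <= r.mcc <= 1.0


class TestRounding:
    @pytest.mark.parametrize(
        "x,nd,expected",
        [(0.785, 2, 0.79), (0.784999, 2, 0.78), (-0.785, 2, -0.79), (63.888, 0, 64.0),
         (81.17, 1, 81.2)],
    )
    def test_half_away(self, x, nd, expected):
        assert round_half_away(x, nd) == expected


class TestRoc:
    def test_perfect_ranking(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0

    def test_three_quarters(self):
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == 0.75

    def test_concordance_equivalence(self, rng):
        scores = rng.normal(size=200)
        y = rng.integers(0, 2, size=200)
        pos = scores[y == 1]
        neg = scores[y == 0]
        conc = np.mean([
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        ])
        assert roc_auc(scores, y).auc == pytest.approx(conc, abs=1e-12)

    def test_negation_symmetry(self, rng):
        scores = rng.normal(size=100)
        y = rng.integers(0, 2, size=100)
        assert roc_auc(scores, y).auc == pytest.approx(
            1.0 - roc_auc(-scores, y).auc, abs=1e-12
        )

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestContingency:
    def test_published_counts(self):
        amw, classes = expand_counts(AMW_SCREEN_COUNTS)
        report = amw_contingency(amw, classes)
        assert report.row("DILI").ge == 276
        assert report.row("Total").ge == 340
        assert report.percent_within_column("DILI", "ge") == 81.2
        assert report.percent_within_column("no-DILI", "ge") == 18.8
        assert report.percent_within_column("Most", "ge") == 35.3
        assert report.percent_within_column("DILI", "lt") == 50.0

    def test_dili_row_is_most_plus_less(self):
        amw, classes = expand_counts(AMW_SCREEN_COUNTS)
        report = amw_contingency(amw, classes)
        assert report.row("DILI").ge == report.row("Most").ge + report.row("Less").ge
        assert report.row("DILI").lt == report.row("Most").lt + report.row("Less").lt

    def test_all_below_threshold(self):
        report = amw_contingency([5.0, 6.0, 7.0], ["Most", "Less", "No"])
        assert report.row("Total").ge == 0

    def test_hand_tally(self):
        report = amw_contingency(
            [8.0, 9.0, 7.0, 7.2, 8.5, 6.9],
            ["Most", "Less", "No", "Most", "No", "Less"],
        )
        assert report.row("DILI").ge == 2
        assert report.row("no-DILI").ge == 1
        assert report.row("Total").lt == 3

    def test_boundary_counts_ge(self):
        report = amw_contingency([7.4], ["Most"])
        assert report.row("Most").ge == 1

    def test_percentage_roundtrip(self, rng):
        amw = rng.uniform(5, 10, 300)
        classes = rng.choice(["Most", "Less", "No"], 300)
        report = amw_contingency(amw, classes)
        total = report.row("Total")
        for label in ("Most", "Less", "DILI", "no-DILI"):
            for col, col_total in (("ge", total.ge), ("lt", total.lt)):
                if col_total == 0:
                    continue
                pct = report.percent_within_column(label, col)
                count = getattr(report.row(label), col)
                assert abs(pct * col_total / 100.0 - count) <= col_total * 0.0005 + 1e-9


class TestAtcStratified:
    def test_hand_tally(self):
        # 9 DILI (8 correct = AMW>=7.4), 12 no-DILI (10 correct = below)
        amw = [8.0] * 8 + [7.0] + [7.0] * 10 + [8.0] * 2
        labels = [1] * 9 + [0] * 12
        codes = [["N"]] * 21
        report = atc_stratified(amw, labels, codes)
        row = report.rows[0]
        assert row.code == "N"
        assert row.metrics.accuracy == pytest.approx(18 / 21)
        assert (row.n_dili, row.n_nodili) == (9, 12)

    def test_multi_code_counts_per_code(self):
        report = atc_stratified([8.0], [1], [["A", "B"]])
        assert {r.code for r in report.rows} == {"A", "B"}
        assert report.total.n_dili == 2  # pooled per (drug, code)

    def test_only_dili_specificity_undefined(self):
        report = atc_stratified([8.0, 7.0], [1, 1], [["J"], ["J"]])
        assert report.rows[0].metrics.specificity is None
        assert "specificity" in report.rows[0].metrics.undefined

    def test_empty_category_omitted_and_no_codes_tallied(self):
        report = atc_stratified([8.0, 7.0], [1, 0], [["A"], []])
        assert [r.code for r in report.rows] == ["A"]
        assert report.n_without_codes == 1

    def test_unknown_code_goes_to_other(self):
        with pytest.warns(UserWarning, match="unknown ATC"):
            report = atc_stratified([8.0], [1], [["Z"]])
        assert report.rows[-1].code == "other"

    def test_pooled_counts_reproduce_total(self, rng):
        n = 120
        amw = rng.uniform(5, 10, n)
        labels = rng.integers(0, 2, n)
        codes = [
            list(rng.choice(list("ABCN"), size=rng.integers(0, 3), replace=False))
            for _ in range(n)
        ]
        try:
            report = atc_stratified(amw, labels, codes)
        except ValueError:
            return
        pooled = report.rows[0].cm
        for r in report.rows[1:]:
            pooled = pooled + r.cm
        assert pooled == report.total.cm


class TestTrend:
    def test_single_year(self):
        report = yearly_amw_trend([2015, 2015, 2015], [7, 8, 9])
        row = report.per_year.iloc[0]
        assert row["mean"] == 8.0 and row["median"] == 8.0

    def test_constant_values_no_outliers(self):
        report = yearly_amw_trend([2011] * 10, [7.4] * 10)
        row = report.per_year.iloc[0]
        assert row["iqr"] == 0.0 and row["n_outliers"] == 0
        assert report.fraction_ge_threshold == 1.0

    def test_moments_match_direct(self, rng):
        values = rng.normal(7.5, 1.0, 100)
        report = yearly_amw_trend([2019] * 100, values)
        row = report.per_year.iloc[0]
        assert row["mean"] == pytest.approx(values.mean(), rel=1e-12)
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        assert row["q1"] == pytest.approx(q1)
        assert row["median"] == pytest.approx(med)
        assert row["q3"] == pytest.approx(q3)
        assert row["lower_fence"] == pytest.approx(q1 - 1.5 * (q3 - q1))

    def test_noninteger_year_rejected(self):
        with pytest.raises(ValueError):
            yearly_amw_trend([2015.5], [7.0])
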