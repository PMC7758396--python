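"""Confusion metrics, unclipped Wald intervals, ROC/AUC, gene t-tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dscore as d
from conftest import cohort_from_counts


@pytest.mark.parametrize(
    "k, n, expected",
    [
        (51, 52, (98.08, 94.34, 101.81)),  # >100% upper bound is intentional
        (49, 96, (51.04, 41.04, 61.04)),
        (52, 52, (100.0, 100.0, 100.0)),
        (3, 55, (5.45, -0.55, 11.46)),  # unclipped lower bound below 0
    ],
)
def test_wald_interval(k, n, expected):
    point, lower, upper = d.wald_interval(k, n)
    assert (round(point, 2), round(lower, 2), round(upper, 2)) == expected


def test_wald_interval_errors():
    with pytest.raises(ValueError):
        d.wald_interval(1, 0)
    with pytest.raises(ValueError):
        d.wald_interval(5, 3)


def test_confusion_from_contingency_layout():
    # higher-risk row (124 called positive, 25 negative), lower-risk row (11, 42)
    calls, truth = cohort_from_counts(tp=124, fn=25, fp=11, tn=42)
    cm = d.confusion(calls, truth, "higher_risk")
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (124, 25, 11, 42)
    assert cm.n == 202


def test_confusion_degenerate_cases():
    calls, truth = cohort_from_counts(tp=10, fn=0, fp=0, tn=10)
    cm = d.confusion(calls, truth, "higher_risk")
    assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 10, 0, 0)

    all_pos = d.confusion(
        ["higher_risk"] * 20, ["higher_risk"] * 10 + ["lower_risk"] * 10,
        "higher_risk",
    )
    assert all_pos.fn == all_pos.tn == 0

    with pytest.raises(ValueError, match="sensitivity undefined"):
        d.confusion(["lower_risk"] * 5, ["lower_risk"] * 5, "higher_risk")


def test_confusion_drops_unknown_labels():
    calls = ["higher_risk", "lower_risk", "higher_risk"]
    truth = ["higher_risk", "lower_risk", "unknown"]
    cm = d.confusion(calls, truth, "higher_risk")
    assert cm.n == 2


def test_complementarity_of_sensitivity_and_specificity():
    calls, truth = cohort_from_counts(tp=30, fn=12, fp=7, tn=21)
    a = d.confusion(calls, truth, "higher_risk")
    b = d.confusion(calls, truth, "lower_risk")
    assert a.sensitivity == b.specificity
    assert a.ppv == b.npv


@given(
    tp=st.integers(1, 400), fn=st.integers(0, 400),
    fp=st.integers(0, 400), tn=st.integers(1, 400),
)
def test_ppv_recoverable_via_bayes_rule(tp, fn, fp, tn):
    cm = d.ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)
    sens = cm.sensitivity[0] / 100
    spec = cm.specificity[0] / 100
    prev = (tp + fn) / cm.n
    bayes = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
    assert cm.ppv[0] / 100 == pytest.approx(bayes, abs=1e-12)


def test_performance_table_formatting():
    summaries = {
        "14-Gene Panel": d.ConfusionSummary(tp=124, fn=25, fp=11, tn=42),
        "8-Gene Panel": d.ConfusionSummary(tp=231, fn=4, fp=52, tn=3),
    }
    table = d.performance_table(summaries)
    assert table.loc["Sensitivity (95% CI)", "14-Gene Panel"] == "83.22 (89.22–77.22)%"
    assert table.loc["NPV (95% CI)", "8-Gene Panel"].startswith("42.86")
    single = d.performance_table({"panel": summaries["14-Gene Panel"]})
    assert list(single.columns) == ["panel"]
    with pytest.raises(ValueError):
        d.performance_table({})


@pytest.mark.parametrize(
    "scores, truth, expected_auc",
    [
        ([3, 2, 1, 0], ["p", "p", "n", "n"], 1.0),
        ([1, 1, 1, 1], ["p", "p", "n", "n"], 0.5),
        ([3, 2, 1, 2], ["p", "p", "n", "n"], 0.875),
    ],
)
def test_roc_auc_examples(scores, truth, expected_auc):
    res = d.roc(scores, truth, "p")
    assert res.auc == pytest.approx(expected_auc)


def test_roc_curve_shape():
    res = d.roc([3, 2, 1, 2], ["p", "p", "n", "n"], "p")
    pts = res.points
    assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
    assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()
    with pytest.raises(ValueError):
        d.roc([1, 2], ["p", "p"], "p")


@given(
    data=st.lists(
        st.tuples(st.integers(0, 5), st.booleans()), min_size=2, max_size=20
    ).filter(lambda v: len({b for _, b in v}) == 2)
)
def test_trapezoid_auc_equals_pairwise_concordance(data):
    """Trapezoidal area == Mann-Whitney concordance with half-credit ties."""
    scores = [s for s, _ in data]
    truth = ["p" if b else "n" for _, b in data]
    res = d.roc(scores, truth, "p")
    pos = [s for s, b in data if b]
    neg = [s for s, b in data if not b]
    conc = sum(
        1.0 if sp > sn else 0.5 if sp == sn else 0.0 for sp in pos for sn in neg
    )
    assert res.auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)


def test_auc_interval_hanley_mcneil():
    # independent evaluation of the closed-form SE at auc=0.875, n=2/2
    auc, n_pos, n_neg = 0.875, 2, 2
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se = np.sqrt(
        (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
         + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    )
    lo, hi = d.auc_interval(auc, n_pos, n_neg)
    assert lo == pytest.approx(auc - 1.96 * se)
    assert hi == 1.0  # clipped

    lo, hi = d.auc_interval(0.5, 10_000, 10_000)
    assert lo == pytest.approx(1.0 - hi, abs=1e-12)
    assert hi - lo < 0.05

    assert d.auc_interval(1.0, 50, 50) == (1.0, 1.0)


def _profiles(a_vals, b_vals, gene="CST3"):
    df = pd.DataFrame({gene: list(a_vals) + list(b_vals)})
    df["label"] = ["higher_risk"] * len(a_vals) + ["lower_risk"] * len(b_vals)
    return df


def test_gene_ttest_identical_groups():
    res = d.gene_ttest(
        _profiles([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]),
        "CST3", ("higher_risk", "lower_risk"),
    )
    assert res.difference == 0.0
    assert res.p_value == pytest.approx(1.0)
    assert not res.significant


def test_gene_ttest_degenerate_groups_raise():
    with pytest.raises(ValueError, match="zero variance"):
        d.gene_ttest(
            _profiles([0.0, 0.0], [1.0, 1.0]),
            "CST3", ("higher_risk", "lower_risk"),
        )
    with pytest.raises(ValueError, match="fewer than 2"):
        d.gene_ttest(
            _profiles([1.0], [1.0, 2.0]), "CST3", ("higher_risk", "lower_risk")
        )


def test_gene_ttest_welch_vs_pooled():
    prof = _profiles([1.0, 2.0, 3.0, 4.0], [10.0, 30.0])
    welch = d.gene_ttest(prof, "CST3", ("higher_risk", "lower_risk"))
    pooled = d.gene_ttest(
        prof, "CST3", ("higher_risk", "lower_risk"), equal_var=True
    )
    assert welch.difference == pooled.difference
    assert welch.p_value != pooled.p_value


def test_gene_ttest_table_order(small_cohort):
    table = d.gene_ttest_table(
        small_cohort, list(d.PANEL14), ("higher_risk", "lower_risk")
    )
    assert list(table.index) == list(d.PANEL14)
    assert {"mean_a", "mean_b", "difference", "t_statistic", "p_value"} <= set(
        table.columns
    )
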