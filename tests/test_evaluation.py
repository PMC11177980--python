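"""Metrics, aggregation and the cross-validated protocol."""

import numpy as np
import pandas as pd
import pytest

from acsselect import (
    aggregate_report,
    auroc,
    confusion_metrics,
    run_ablation,
    run_cv_protocol,
)
from acsselect.evaluation import CVPlan, ablation_summary, assert_no_leakage
from acsselect.exceptions import AcsSelectError, ValidationError


def brute_force_auroc(y, s):
    """Independent oracle: enumerate all positive-negative pairs, ties 1/2."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_confusion_metrics_hand_values():
    y = [1] * 10 + [0] * 10
    p = [1] * 9 + [0] + [0] * 8 + [1] * 2  # TP=9 FN=1 TN=8 FP=2
    m = confusion_metrics(y, p)
    assert m.sensitivity == pytest.approx(0.9)
    assert m.specificity == pytest.approx(0.8)
    assert m.ppv == pytest.approx(9 / 11)
    assert m.npv == pytest.approx(8 / 9)
    assert m.accuracy == pytest.approx(0.85)
    assert m.prevalence == pytest.approx(0.5)


def test_confusion_metrics_edge_cases():
    y = [1, 0, 1, 0]
    perfect = confusion_metrics(y, y)
    assert (perfect.sensitivity, perfect.specificity, perfect.ppv,
            perfect.npv, perfect.accuracy) == (1, 1, 1, 1, 1)
    all_neg = confusion_metrics(y, [0, 0, 0, 0])
    assert np.isnan(all_neg.ppv)
    assert all_neg.npv == pytest.approx(1 - all_neg.prevalence)
    with pytest.raises(ValidationError):
        confusion_metrics([1, 0], [1])


def test_auroc_known_values(rng):
    assert auroc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
    # brute-force oracle: positives {0.9, 0.4} vs negatives {0.6, 0.2}
    # -> 3 wins of 4 pairs
    assert auroc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == pytest.approx(0.75)
    y = (rng.random(5000) < 0.5).astype(int)
    assert auroc(y, rng.random(5000)) == pytest.approx(0.5, abs=0.03)
    assert np.isnan(auroc([1, 1], [0.2, 0.3]))


def test_auroc_matches_brute_force(rng):
    """Rank-based AUROC vs pairwise enumeration on random small instances."""
    for _ in range(300):
        n = rng.integers(4, 31)
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if y.min() == y.max():
            continue
        s = rng.integers(0, 6, size=n).astype(float)  # coarse -> many ties
        assert auroc(y, s) == pytest.approx(brute_force_auroc(y, s), abs=1e-12)


def test_aggregate_hand_values():
    rows = pd.DataFrame({"auroc": [0.8, 0.9]})
    agg = aggregate_report(rows)
    assert agg.loc["auroc", "mean"] == pytest.approx(0.85)
    assert agg.loc["auroc", "two_sigma"] == pytest.approx(0.1)
    const = pd.DataFrame({"auroc": [0.9] * 5})
    assert aggregate_report(const).loc["auroc", "two_sigma"] == 0.0
    sd = aggregate_report(rows, dispersion="sd")
    assert sd.loc["auroc", "two_sigma"] == pytest.approx(0.1 * np.sqrt(2))


def test_aggregate_excludes_missing_with_warning():
    rows = pd.DataFrame({"ppv": [0.5, np.nan, 0.7]})
    with pytest.warns(UserWarning, match="ppv"):
        agg = aggregate_report(rows)
    assert agg.loc["ppv", "mean"] == pytest.approx(0.6)
    with pytest.raises(ValidationError):
        aggregate_report(rows.iloc[:1])


def test_aggregate_order_invariant(rng):
    vals = rng.random(5)
    a = aggregate_report(pd.DataFrame({"auroc": vals}))
    b = aggregate_report(pd.DataFrame({"auroc": vals[::-1]}))
    pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def protocol_reports(small_pair, tiny_ensemble_config):
    internal, external = small_pair
    return run_cv_protocol(
        internal, external, task="acs", subset="full",
        ensemble_config=tiny_ensemble_config, coverage_target=0.8,
        plan=CVPlan(seed=5),
    )


def test_protocol_shapes_and_prevalence(protocol_reports, small_pair):
    rep_int, rep_ext = protocol_reports
    _, external = small_pair
    assert sorted(rep_int.rows["fold"].unique()) == [0, 1, 2, 3, 4]
    non_sel = rep_ext.select(False)
    assert (non_sel["coverage"] == 1.0).all()
    # non-selective external prevalence is the cohort's exact positive rate
    assert non_sel["prevalence"].unique() == pytest.approx(external.acs.mean())
    sel = rep_ext.select(True)
    assert ((sel["coverage"] > 0) & (sel["coverage"] <= 1)).all()


def test_protocol_deterministic(small_pair, tiny_ensemble_config, protocol_reports):
    internal, external = small_pair
    again_int, _ = run_cv_protocol(
        internal, external, task="acs", subset="full",
        ensemble_config=tiny_ensemble_config, coverage_target=0.8,
        plan=CVPlan(seed=5),
    )
    pd.testing.assert_frame_equal(again_int.rows, protocol_reports[0].rows)


def test_protocol_full_coverage_matches_nonselective(small_pair, tiny_ensemble_config):
    internal, external = small_pair
    rep_int, rep_ext = run_cv_protocol(
        internal, external, ensemble_config=tiny_ensemble_config,
        coverage_target=1.0, plan=CVPlan(seed=5),
    )
    for rep in (rep_int, rep_ext):
        sel = rep.select(True).drop(columns="selective").reset_index(drop=True)
        non = rep.select(False).drop(columns="selective").reset_index(drop=True)
        pd.testing.assert_frame_equal(sel, non)


def test_protocol_nste_task_relabels(small_pair, tiny_ensemble_config):
    internal, external = small_pair
    rep_int, rep_ext = run_cv_protocol(
        internal, external, task="nste_acs",
        ensemble_config=tiny_ensemble_config, plan=CVPlan(seed=5),
    )
    assert rep_ext.task == "nste_acs"
    expected_prev = external.nste_acs.mean()
    assert rep_ext.select(False)["prevalence"].unique() == pytest.approx(expected_prev)
    assert expected_prev < external.acs.mean()  # STEMI cases count as negative


def test_leakage_guard_passes_and_detects_tampering(protocol_reports, small_pair):
    rep_int, _ = protocol_reports
    audit = rep_int.details["audit"]
    n = len(small_pair[0])
    assert_no_leakage(audit, n)  # passes on a real run
    tampered = {
        "folds": [dict(f) for f in audit["folds"]],
        "external_used_for_fitting": False,
    }
    tampered["folds"][0] = dict(
        tampered["folds"][0],
        fit_idx=tampered["folds"][0]["fit_idx"] + tampered["folds"][0]["test_idx"][:1],
    )
    with pytest.raises(AcsSelectError, match="leakage"):
        assert_no_leakage(tampered, n)
    with pytest.raises(AcsSelectError, match="external"):
        assert_no_leakage(dict(audit, external_used_for_fitting=True), n)


def test_ablation_subsets_and_summary(small_pair, tiny_ensemble_config):
    internal, external = small_pair
    reports = run_ablation(
        internal, external, ensemble_config=tiny_ensemble_config,
        plan=CVPlan(seed=5),
    )
    assert list(reports) == [
        "baseline", "baseline_symptoms", "baseline_symptoms_history"
    ]
    table = ablation_summary(reports)
    assert list(table.columns) == list(reports)
    assert table.loc["auroc"].notna().all()
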