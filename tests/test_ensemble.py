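"""Boosted-tree ensemble: weighting, fitting, grid search, decisions."""

import numpy as np
import pandas as pd
import pytest

from acsselect import (
    EnsembleConfig,
    auroc,
    compute_class_weights,
    fit_ensemble,
    grid_search_fit,
    impute_constant,
    mean_probability,
    predict_label,
    predict_members,
    select_covariates,
    uncertainty_table,
)
from acsselect.ensemble import DEFAULT_GRID, load_ensemble, save_ensemble
from acsselect.exceptions import (
    ConfigurationError,
    DegenerateLabelsError,
    SchemaError,
)
from acsselect.synthetic import generate_cohort, internal_config


def _xy(cohort, subset="full", task="acs"):
    X = select_covariates(cohort, subset).to_numpy()
    return X, cohort.task_labels(task)


def test_class_weights_inverse_frequency():
    w = compute_class_weights([1] * 20 + [0] * 80)
    assert w[1] / w[0] == pytest.approx(4.0)
    assert (w[0] + w[1]) / 2 == pytest.approx(1.0)
    balanced = compute_class_weights([0, 1] * 10)
    assert balanced == {0: pytest.approx(1.0), 1: pytest.approx(1.0)}
    with pytest.raises(DegenerateLabelsError):
        compute_class_weights([1, 1, 1])


def test_default_grid_mirrors_search_space():
    cfg = EnsembleConfig()
    assert cfg.grid == DEFAULT_GRID
    assert cfg.iterations == 1000 and cfg.n_members == 10
    n_points = (len(DEFAULT_GRID["learning_rate"])
                * len(DEFAULT_GRID["depth"]) * len(DEFAULT_GRID["subsample"]))
    assert n_points == 36


def test_config_validation():
    with pytest.raises(ConfigurationError):
        EnsembleConfig(learning_rate=0.0)
    with pytest.raises(ConfigurationError):
        EnsembleConfig(subsample=1.5)
    with pytest.raises(ConfigurationError):
        EnsembleConfig(grid={"max_leaves": [4]})


def test_fit_is_deterministic_and_member_count(small_pair, tiny_ensemble_config):
    internal, _ = small_pair
    X, y = _xy(internal)
    a = fit_ensemble(X, y, tiny_ensemble_config)
    b = fit_ensemble(X, y, tiny_ensemble_config)
    assert a.n_members == tiny_ensemble_config.n_members
    np.testing.assert_array_equal(predict_members(a, X), predict_members(b, X))


def test_member_rows_are_distributions(small_pair, tiny_ensemble_config):
    internal, external = small_pair
    X, y = _xy(internal)
    ens = fit_ensemble(X, y, tiny_ensemble_config)
    preds = predict_members(ens, _xy(external)[0])
    assert preds.shape == (3, len(external), 2)
    np.testing.assert_allclose(preds.sum(axis=2), 1.0, atol=1e-6)
    assert preds.min() >= 0.0 and preds.max() <= 1.0


def test_permuting_rows_permutes_predictions(small_pair, tiny_ensemble_config, rng):
    internal, external = small_pair
    ens = fit_ensemble(*_xy(internal), tiny_ensemble_config)
    X = _xy(external)[0]
    order = rng.permutation(len(X))
    np.testing.assert_array_equal(
        predict_members(ens, X[order]), predict_members(ens, X)[:, order, :]
    )


def test_feature_mismatch_rejected(small_pair, tiny_ensemble_config):
    internal, _ = small_pair
    Xdf = select_covariates(internal, "full")
    ens = fit_ensemble(Xdf, internal.acs, tiny_ensemble_config)
    with pytest.raises(SchemaError):
        predict_members(ens, Xdf.iloc[:, :-1])


def test_single_member_has_zero_model_uncertainty(small_pair, tiny_ensemble_config):
    internal, external = small_pair
    cfg = tiny_ensemble_config.with_(n_members=1)
    ens = fit_ensemble(*_xy(internal), cfg)
    table = uncertainty_table(predict_members(ens, _xy(external)[0]))
    assert (table["model_u"] == 0.0).all()
    np.testing.assert_allclose(table["total_u"], table["data_u"], atol=1e-12)


def test_no_signal_cohort_gives_chance_auroc(tiny_ensemble_config):
    null_coef = {k: 0.0 for k in internal_config().effect_coefficients}
    train = impute_constant(generate_cohort(
        internal_config(n=800, seed=31, effect_coefficients=null_coef)))
    test = impute_constant(generate_cohort(
        internal_config(n=800, seed=32, effect_coefficients=null_coef)))
    ens = fit_ensemble(*_xy(train), tiny_ensemble_config)
    a = auroc(test.acs, mean_probability(ens, _xy(test)[0]))
    assert abs(a - 0.5) < 0.06


def test_signal_monotonicity(tiny_ensemble_config):
    """Test AUROC is non-decreasing in the planted effect size."""
    base = internal_config().effect_coefficients
    aurocs = []
    for i, scale in enumerate((0.0, 0.4, 1.0)):
        coef = {k: v * scale for k, v in base.items()}
        train = impute_constant(generate_cohort(
            internal_config(n=700, seed=41 + i, effect_coefficients=coef)))
        test = impute_constant(generate_cohort(
            internal_config(n=700, seed=51 + i, effect_coefficients=coef)))
        ens = fit_ensemble(*_xy(train), tiny_ensemble_config)
        aurocs.append(auroc(test.acs, mean_probability(ens, _xy(test)[0])))
    assert aurocs[0] < aurocs[1] < aurocs[2]


def test_grid_single_point_equals_plain_fit(small_pair, tiny_ensemble_config):
    internal, external = small_pair
    X, y = _xy(internal)
    cfg = tiny_ensemble_config.with_(
        grid={"learning_rate": [0.2], "depth": [3], "subsample": [0.75]}
    )
    searched = grid_search_fit(X[:300], y[:300], cfg, validation=(X[300:], y[300:]))
    plain = fit_ensemble(X[:300], y[:300], tiny_ensemble_config)
    Xe = _xy(external)[0]
    np.testing.assert_array_equal(
        predict_members(searched, Xe), predict_members(plain, Xe)
    )
    assert len(searched.search_trace) == 1


def test_grid_trace_covers_all_candidates(small_pair, tiny_ensemble_config):
    internal, _ = small_pair
    X, y = _xy(internal)
    cfg = tiny_ensemble_config.with_(
        grid={"learning_rate": [0.1, 0.3], "depth": [2, 3], "subsample": [0.75]}
    )
    ens = grid_search_fit(X[:300], y[:300], cfg, validation=(X[300:], y[300:]))
    assert len(ens.search_trace) == 4
    assert ens.selected_point in [
        {"learning_rate": lr, "depth": d, "subsample": 0.75}
        for lr in (0.1, 0.3) for d in (2, 3)
    ]


def test_grid_ties_break_toward_simpler_models(tiny_ensemble_config, rng):
    # one perfectly separating feature: every candidate scores AUROC 1.0
    n = 200
    y = (rng.random(n) < 0.4).astype(int)
    X = np.column_stack([y * 2.0 - 1.0, rng.random(n)])
    cfg = tiny_ensemble_config.with_(
        grid={"learning_rate": [0.1, 1.0], "depth": [1, 3], "subsample": [0.75]}
    )
    ens = grid_search_fit(X[:150], y[:150], cfg, validation=(X[150:], y[150:]))
    assert ens.selected_point["depth"] == 1
    assert ens.selected_point["learning_rate"] == 0.1


def test_predict_label_threshold_semantics():
    probs = np.array([[0.5, 0.5], [0.9, 0.1], [0.2, 0.8]])
    np.testing.assert_array_equal(predict_label(probs, 0.5), [1, 0, 1])
    np.testing.assert_array_equal(predict_label(np.array([[1.0, 0.0]] * 3)), [0, 0, 0])
    with pytest.raises(ConfigurationError):
        predict_label(probs, threshold=1.0)


def test_threshold_monotonicity(small_pair, tiny_ensemble_config):
    from acsselect import confusion_metrics

    internal, external = small_pair
    ens = fit_ensemble(*_xy(internal), tiny_ensemble_config)
    p1 = mean_probability(ens, _xy(external)[0])
    probs = np.column_stack([1 - p1, p1])
    y = external.acs
    lo = confusion_metrics(y, predict_label(probs, 0.3))
    hi = confusion_metrics(y, predict_label(probs, 0.5))
    assert lo.sensitivity >= hi.sensitivity
    assert lo.specificity <= hi.specificity


def test_bundle_round_trip(tmp_path, small_pair, tiny_ensemble_config):
    internal, external = small_pair
    ens = fit_ensemble(*_xy(internal), tiny_ensemble_config)
    save_ensemble(ens, tmp_path / "bundle")
    back = load_ensemble(tmp_path / "bundle")
    Xe = _xy(external)[0]
    np.testing.assert_allclose(
        predict_members(back, Xe), predict_members(ens, Xe), atol=1e-7
    )
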