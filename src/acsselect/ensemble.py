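"""Ensemble of gradient-boosted tree classifiers.

The ensemble's M members are exchangeable probabilistic classifiers whose
predictions serve as Monte-Carlo samples for the posterior-predictive
uncertainty decomposition: each member is a boosted-tree model (xgboost,
histogram method) trained with identical hyperparameters but an independent
seed and Bernoulli row subsampling, so members differ only through training
stochasticity.  Class imbalance is handled by weighting samples inversely
to their class frequency, with the weights estimated from whatever data the
member is fitted on.  Hyperparameters are chosen by exhaustive grid search
scored on held-out validation AUROC.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .exceptions import ConfigurationError, DegenerateLabelsError, SchemaError

#: full hyperparameter search space: 3 learning rates x 4 depths x 3
#: subsample rates = 36 candidates, each trained for 1000 rounds.
DEFAULT_GRID: dict[str, list] = {
    "learning_rate": [0.01, 0.1, 1.0],
    "depth": [1, 3, 6, 10],
    "subsample": [0.25, 0.5, 0.75],
}

#: reduced search space for desk-scale experiments (see docs/methods.md).
REDUCED_GRID: dict[str, list] = {
    "learning_rate": [0.1, 1.0],
    "depth": [3],
    "subsample": [0.75],
}

DEFAULT_BASE_SEED = 1_419_528
_GRID_KEYS = ("learning_rate", "depth", "subsample")


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters for one ensemble fit (and optionally a search grid)."""

    learning_rate: float = 0.1
    depth: int = 6
    subsample: float = 0.75
    iterations: int = 1000
    n_members: int = 10
    base_seed: int = DEFAULT_BASE_SEED
    class_weight_mode: str = "inverse_frequency"
    grid: dict[str, list] | None = field(default_factory=lambda: dict(DEFAULT_GRID))

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.depth < 1 or self.iterations < 1 or self.n_members < 1:
            raise ConfigurationError("depth, iterations and n_members must be >= 1")
        if not (0.0 < self.subsample <= 1.0):
            raise ConfigurationError("subsample must lie in (0, 1]")
        if self.class_weight_mode not in ("inverse_frequency", "none"):
            raise ConfigurationError(
                f"unknown class_weight_mode {self.class_weight_mode!r}"
            )
        if self.grid is not None:
            unknown = set(self.grid) - set(_GRID_KEYS)
            if unknown:
                raise ConfigurationError(f"unknown grid keys {sorted(unknown)}")

    def with_(self, **kw) -> "EnsembleConfig":
        return replace(self, **kw)

    @classmethod
    def reduced(cls, **kw) -> "EnsembleConfig":
        """Desk-scale profile: 60 boosting rounds, 2-point grid."""
        kw.setdefault("iterations", 60)
        kw.setdefault("depth", 3)
        kw.setdefault("grid", dict(REDUCED_GRID))
        return cls(**kw)


@dataclass
class FittedEnsemble:
    members: list
    config: EnsembleConfig
    feature_names: list[str]
    selected_point: dict | None = None
    search_trace: list[dict] | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)


def compute_class_weights(labels) -> dict[int, float]:
    """Per-class weights inversely proportional to class frequency.

    Normalised so the two weights average to 1; with 20% positives the
    weight ratio w1/w0 is 4.
    """
    y = np.asarray(labels, dtype=int)
    if y.size == 0 or y.min() == y.max():
        raise DegenerateLabelsError("class weights need both classes present")
    f1 = y.mean()
    inv = {0: 1.0 / (1.0 - f1), 1: 1.0 / f1}
    norm = (inv[0] + inv[1]) / 2.0
    return {c: w / norm for c, w in inv.items()}


def _coerce_features(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise SchemaError(f"expected an n x p feature matrix, got shape {X.shape}")
    return X, [f"f{j}" for j in range(X.shape[1])]


def _member(config: EnsembleConfig, m: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=config.iterations,
        learning_rate=config.learning_rate,
        max_depth=config.depth,
        subsample=config.subsample,
        tree_method="hist",
        n_jobs=1,
        random_state=int((config.base_seed + m) % (2**31)),
        objective="binary:logistic",
        eval_metric="logloss",
        verbosity=0,
    )


def fit_ensemble(features, labels, config: EnsembleConfig) -> FittedEnsemble:
    """Train M members; deterministic given ``config.base_seed``."""
    X, names = _coerce_features(features)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] < 20:
        raise ConfigurationError("need at least 20 training cases")
    if X.shape[0] != y.size:
        raise SchemaError("features and labels differ in length")
    if y.min() == y.max():
        raise DegenerateLabelsError("training labels contain a single class")
    sample_weight = None
    if config.class_weight_mode == "inverse_frequency":
        w = compute_class_weights(y)
        sample_weight = np.where(y == 1, w[1], w[0])
    members = []
    for m in range(config.n_members):
        clf = _member(config, m)
        clf.fit(X, y, sample_weight=sample_weight)
        members.append(clf)
    return FittedEnsemble(members, config, names)


def predict_members(ensemble: FittedEnsemble, features) -> np.ndarray:
    """Full M x n x 2 class-probability tensor (class order: not-ACS, ACS).

    The per-member tensor, not just its mean, is returned so the
    uncertainty module can decompose total into data + model components.
    """
    X, names = _coerce_features(features)
    if isinstance(features, pd.DataFrame) and names != ensemble.feature_names:
        raise SchemaError("feature columns do not match the fitted ensemble")
    if X.shape[1] != len(ensemble.feature_names):
        raise SchemaError(
            f"expected {len(ensemble.feature_names)} feature columns, got {X.shape[1]}"
        )
    return np.stack([_member_proba(clf, X) for clf in ensemble.members])


def _member_proba(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)
    p1 = clf.inplace_predict(X)  # raw Booster from a loaded bundle
    return np.column_stack([1.0 - p1, p1])


def mean_probability(ensemble: FittedEnsemble, features) -> np.ndarray:
    """Ensemble-mean P(positive) per case."""
    return predict_members(ensemble, features).mean(axis=0)[:, 1]


def predict_label(mean_probs, threshold: float = 0.5) -> np.ndarray:
    """Hard decision: 1 iff P(positive) >= threshold (boundary counts in)."""
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError(f"threshold must lie in (0, 1), got {threshold}")
    p = np.asarray(mean_probs, dtype=float)
    if p.ndim != 2 or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ConfigurationError("mean_probs rows must be distributions over 2 classes")
    return (p[:, 1] >= threshold).astype(int)


def grid_search_fit(
    features, labels, config: EnsembleConfig, validation,
    search_members: int = 1,
) -> FittedEnsemble:
    """Exhaustive grid search scored by validation AUROC, then refit.

    Candidates are scored with ``search_members`` members (default 1 — the
    search compares hyperparameters, not ensemble size) on the held-out
    validation split; ties break toward smaller depth, then smaller
    learning rate.  The winning point is refitted at the configured full
    ensemble size, and the complete search trace is attached to the result.
    """
    from .evaluation import auroc

    X_val, y_val = validation
    y_val = np.asarray(y_val, dtype=int)
    if y_val.min() == y_val.max():
        raise DegenerateLabelsError("validation labels contain a single class")
    grid = config.grid if config.grid is not None else dict(DEFAULT_GRID)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigurationError("hyperparameter grid is empty")
    axes = {k: list(grid.get(k, [getattr(config, k)])) for k in _GRID_KEYS}
    candidates = sorted(
        (dict(zip(_GRID_KEYS, vals)) for vals in product(*(axes[k] for k in _GRID_KEYS))),
        key=lambda c: (c["depth"], c["learning_rate"], c["subsample"]),
    )
    trace, best, best_score = [], None, -np.inf
    for cand in candidates:
        cand_cfg = config.with_(**cand, n_members=search_members, grid=None)
        ens = fit_ensemble(features, labels, cand_cfg)
        score = auroc(y_val, mean_probability(ens, X_val))
        trace.append({**cand, "val_auroc": score})
        if np.isfinite(score) and score > best_score:
            best, best_score = cand, score
    if best is None:
        raise ConfigurationError("grid search produced no finite validation AUROC")
    final = fit_ensemble(features, labels, config.with_(**best, grid=None))
    final.selected_point = dict(best)
    final.search_trace = trace
    return final


# ---------------------------------------------------------------------------
# on-disk bundle

BUNDLE_VERSION = 1


def save_ensemble(ensemble: FittedEnsemble, directory: str | Path) -> None:
    """Serialise config + members + feature names to a versioned bundle."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "bundle_version": BUNDLE_VERSION,
        "config": asdict(ensemble.config),
        "feature_names": ensemble.feature_names,
        "n_members": ensemble.n_members,
        "selected_point": ensemble.selected_point,
    }
    (d / "ensemble.json").write_text(json.dumps(meta, indent=2))
    for m, clf in enumerate(ensemble.members):
        booster = clf.get_booster() if hasattr(clf, "get_booster") else clf
        booster.save_model(d / f"member_{m:03d}.json")


def load_ensemble(directory: str | Path) -> FittedEnsemble:
    d = Path(directory)
    meta = json.loads((d / "ensemble.json").read_text())
    if meta["bundle_version"] != BUNDLE_VERSION:
        raise ConfigurationError(
            f"unsupported bundle version {meta['bundle_version']}"
        )
    import xgboost as xgb

    config = EnsembleConfig(**meta["config"])
    members = []
    for m in range(meta["n_members"]):
        booster = xgb.Booster()
        booster.load_model(d / f"member_{m:03d}.json")
        members.append(booster)
    return FittedEnsemble(members, config, meta["feature_names"],
                          selected_point=meta.get("selected_point"))
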