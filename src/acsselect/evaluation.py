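"""Metrics and the cross-validated evaluation protocol.

The protocol mirrors a temporally split development/deployment design:
5-fold stratified cross-validation over the internal cohort, where each
fold's training portion is further split 90/10 into a fitting set ``D`` and
a validation set ``D_val``.  ``D`` fits the boosted-tree ensemble (with
hyperparameter grid search scored on ``D_val``), ``D_val`` also sets the
selective-classification cutoff, the fold's held-out internal slice gives
internal-cohort performance, and the entire external cohort — never touched
during fitting — gives external performance.  Each metric is reported as
the mean over the 5 folds with a dispersion of twice the standard error
(``sd/sqrt(5)``; twice the SD is available via ``dispersion="sd"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cohort import Cohort, select_covariates
from .exceptions import AcsSelectError, DegenerateLabelsError, ValidationError

METRIC_COLUMNS = (
    "prevalence", "coverage", "sensitivity", "specificity",
    "ppv", "npv", "auroc", "accuracy",
)

ABLATION_SUBSETS = ("baseline", "baseline_symptoms", "baseline_symptoms_history")


class ConfusionMetrics(NamedTuple):
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    prevalence: float


def confusion_metrics(y_true, y_pred) -> ConfusionMetrics:
    """Threshold-based classification ratios; zero denominators give NaN."""
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if y.shape != p.shape:
        raise ValidationError("y_true and y_pred differ in length")
    if y.size == 0:
        raise ValidationError("cannot compute metrics on an empty set")
    tp = int(((y == 1) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return ConfusionMetrics(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        accuracy=(tp + tn) / y.size,
        prevalence=y.mean(),
    )


def auroc(y_true, scores) -> float:
    """Probability a random positive outranks a random negative (ties 1/2).

    Returns NaN (missing) when only one class is present.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("labels and scores differ in length")
    if y.size == 0 or y.min() == y.max():
        return float("nan")
    return float(roc_auc_score(y, s))


def aggregate_report(per_fold: pd.DataFrame, dispersion: str = "se") -> pd.DataFrame:
    """Mean and 2x dispersion per metric over fold rows.

    ``dispersion="se"`` (default) reports twice the standard error of the
    fold values, ``"sd"`` twice their standard deviation.  Folds where a
    metric is undefined (NaN) are excluded from that metric's aggregate
    with a warning.
    """
    if len(per_fold) < 2:
        raise ValidationError("need at least 2 fold rows to aggregate")
    if dispersion not in ("se", "sd"):
        raise ValidationError(f"dispersion must be 'se' or 'sd', got {dispersion!r}")
    out = {}
    for metric in METRIC_COLUMNS:
        if metric not in per_fold.columns:
            continue
        vals = per_fold[metric].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if not ok.all():
            warnings.warn(
                f"metric {metric!r}: {int((~ok).sum())} undefined fold value(s) "
                "excluded from aggregation",
                stacklevel=2,
            )
        vals = vals[ok]
        if vals.size == 0:
            out[metric] = (float("nan"), float("nan"))
            continue
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        spread = sd / np.sqrt(vals.size) if dispersion == "se" else sd
        out[metric] = (float(vals.mean()), 2.0 * spread)
    return pd.DataFrame(out, index=["mean", "two_sigma"]).T


@dataclass
class MetricsReport:
    """Per-fold metric rows plus aggregation, for one cohort and task."""

    rows: pd.DataFrame
    task: str
    cohort: str
    subset: str
    details: dict = field(default_factory=dict)

    def select(self, selective: bool) -> pd.DataFrame:
        return self.rows[self.rows["selective"] == selective]

    def aggregate(self, selective: bool, dispersion: str = "se") -> pd.DataFrame:
        return aggregate_report(self.select(selective), dispersion=dispersion)

    def summary_text(self) -> str:
        """Human-readable mu +/- 2 sigma table, metrics as percentages."""
        lines = [f"task={self.task} cohort={self.cohort} covariates={self.subset}"]
        header = "method      " + "".join(f"{m:>14}" for m in METRIC_COLUMNS)
        lines.append(header)
        for selective, name in ((True, "GBDT+SC"), (False, "GBDT")):
            agg = self.aggregate(selective)
            cells = []
            for m in METRIC_COLUMNS:
                mean, ts = agg.loc[m, "mean"], agg.loc[m, "two_sigma"]
                cells.append(f"{100 * mean:5.0f}±{100 * ts:<4.0f}".rjust(14))
            lines.append(f"{name:<12}" + "".join(cells))
        return "\n".join(lines)


@dataclass(frozen=True)
class CVPlan:
    """Fold layout: 5 stratified folds, 10% of each training portion held
    out for validation (hyperparameter search + cutoff estimation)."""

    n_folds: int = 5
    val_fraction: float = 0.10
    seed: int = 0


def _evaluate_split(y, mean_p1, uncert, cutoff, threshold: float) -> list[dict]:
    """Non-selective and selective metric rows for one evaluation set."""
    from .ensemble import predict_label
    from .selective import apply_filter, coverage

    probs = np.column_stack([1.0 - mean_p1, mean_p1])
    pred = predict_label(probs, threshold)
    rows = []
    cm = confusion_metrics(y, pred)
    rows.append(
        {"selective": False, "coverage": 1.0, "auroc": auroc(y, mean_p1),
         **cm._asdict()}
    )
    mask = apply_filter(uncert, cutoff).astype(bool)
    if mask.any():
        cmf = confusion_metrics(y[mask], pred[mask])
        rows.append(
            {"selective": True, "coverage": coverage(mask.astype(int)),
             "auroc": auroc(y[mask], mean_p1[mask]), **cmf._asdict()}
        )
    else:
        rows.append(
            {"selective": True, "coverage": 0.0,
             **{m: float("nan") for m in METRIC_COLUMNS if m != "coverage"}}
        )
    return rows


def assert_no_leakage(audit: dict, n_internal: int) -> None:
    """Structural guard: folds partition the internal cohort; the fitting
    and validation indices never intersect the fold's test indices; the
    external cohort is identified only by its tag and is never fitted on."""
    seen_test: set[int] = set()
    for fold in audit["folds"]:
        fit, val, test = (set(fold[k]) for k in ("fit_idx", "val_idx", "test_idx"))
        if (fit | val) & test:
            raise AcsSelectError(f"leakage: fold {fold['fold']} trains on its test slice")
        if fit & val:
            raise AcsSelectError(f"leakage: fold {fold['fold']} validation overlaps fitting")
        seen_test |= test
    if seen_test != set(range(n_internal)):
        raise AcsSelectError("folds do not partition the internal cohort")
    if audit.get("external_used_for_fitting", False):
        raise AcsSelectError("external cohort influenced fitting")


def run_cv_protocol(
    internal: Cohort,
    external: Cohort,
    task: str = "acs",
    subset: str = "full",
    ensemble_config=None,
    coverage_target: float = 0.8,
    plan: CVPlan | None = None,
    threshold: float = 0.5,
    search_members: int = 1,
) -> tuple[MetricsReport, MetricsReport]:
    """Full protocol; returns (internal report, external report).

    Both cohorts must be imputed.  Every stage is deterministic given the
    plan seed and the ensemble config's base seed.
    """
    from .ensemble import EnsembleConfig, fit_ensemble, grid_search_fit, predict_members
    from .selective import SelectiveCutoff, estimate_cutoff
    from .uncertainty import uncertainty_table

    if ensemble_config is None:
        ensemble_config = EnsembleConfig()
    plan = plan or CVPlan()
    y_all = internal.task_labels(task)
    y_ext = external.task_labels(task)
    X_all = select_covariates(internal, subset).to_numpy()
    X_ext = select_covariates(external, subset).to_numpy()
    if y_all.min() == y_all.max():
        raise DegenerateLabelsError(f"task {task!r} has a single class internally")

    skf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=plan.seed)
    rows_int, rows_ext = [], []
    audit: dict = {"folds": [], "external_used_for_fitting": False}
    fold_details = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X_all, y_all)):
        fit_idx, val_idx = train_test_split(
            train_idx,
            test_size=plan.val_fraction,
            stratify=y_all[train_idx],
            random_state=(plan.seed * 100 + fold) % (2**31),
        )
        audit["folds"].append(
            {"fold": fold, "fit_idx": fit_idx.tolist(),
             "val_idx": val_idx.tolist(), "test_idx": test_idx.tolist()}
        )
        member_cfg = ensemble_config
        if member_cfg.base_seed is not None:
            member_cfg = member_cfg.with_(base_seed=member_cfg.base_seed + 1000 * fold)
        if member_cfg.grid:
            ens = grid_search_fit(
                X_all[fit_idx], y_all[fit_idx], member_cfg,
                validation=(X_all[val_idx], y_all[val_idx]),
                search_members=search_members,
            )
        else:
            ens = fit_ensemble(X_all[fit_idx], y_all[fit_idx], member_cfg)
        u_val = uncertainty_table(predict_members(ens, X_all[val_idx]))["total_u"]
        cutoff = estimate_cutoff(u_val.to_numpy(), coverage_target)
        if coverage_target >= 1.0:
            # ln 2 bounds binary total uncertainty, so nothing is filtered
            cutoff = SelectiveCutoff(float(np.log(2.0)), 1.0, cutoff.source_size)
        fold_details.append(
            {"fold": fold, "cutoff": cutoff.cutoff,
             "hyperparameters": getattr(ens, "selected_point", None),
             "search_trace": getattr(ens, "search_trace", None)}
        )
        for X_eval, y_eval, sink in ((X_all[test_idx], y_all[test_idx], rows_int),
                                     (X_ext, y_ext, rows_ext)):
            preds = predict_members(ens, X_eval)
            mean_p1 = preds.mean(axis=0)[:, 1]
            uncert = uncertainty_table(preds)["total_u"].to_numpy()
            for row in _evaluate_split(y_eval, mean_p1, uncert, cutoff, threshold):
                sink.append({"fold": fold, **row})

    assert_no_leakage(audit, len(internal))
    details = {"audit": audit, "folds": fold_details,
               "coverage_target": coverage_target, "threshold": threshold}
    rep_int = MetricsReport(pd.DataFrame(rows_int), task, internal.tag, subset, details)
    rep_ext = MetricsReport(pd.DataFrame(rows_ext), task, external.tag, subset, details)
    return rep_int, rep_ext


def run_ablation(
    internal: Cohort,
    external: Cohort,
    ensemble_config=None,
    task: str = "acs",
    subsets: tuple[str, ...] = ABLATION_SUBSETS,
    **kwargs,
) -> dict[str, tuple[MetricsReport, MetricsReport]]:
    """Run the protocol over nested covariate subsets (ablation study)."""
    return {
        s: run_cv_protocol(internal, external, task=task, subset=s,
                           ensemble_config=ensemble_config, **kwargs)
        for s in subsets
    }


def ablation_summary(
    reports: dict[str, tuple[MetricsReport, MetricsReport]],
    cohort_index: int = 1,
    selective: bool = False,
) -> pd.DataFrame:
    """Metric x subset table of fold means (external cohort by default)."""
    cols = {}
    for s, pair in reports.items():
        agg = pair[cohort_index].aggregate(selective)
        cols[s] = agg["mean"]
    return pd.DataFrame(cols)
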