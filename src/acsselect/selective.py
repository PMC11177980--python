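"""Selective classification: abstain on the most-uncertain cases.

The abstention rule is fixed, not learned: a total-uncertainty cutoff is
estimated on a validation split as the empirical quantile at the coverage
target (0.8 by default — "predict on the 80% least-uncertain cases"), and
at test time every case whose total uncertainty strictly exceeds the cutoff
is filtered out.  Filtering only subsets the test set; predictions on
retained cases are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .evaluation import auroc


@dataclass(frozen=True)
class SelectiveCutoff:
    """An uncertainty cutoff with its provenance."""

    cutoff: float
    coverage_target: float
    source_size: int


def estimate_cutoff(
    val_uncertainties, coverage_target: float = 0.8
) -> SelectiveCutoff:
    """Empirical quantile of validation uncertainties at the coverage target.

    Uses the inverse-ECDF (lower) convention: the cutoff is the smallest
    observed value ``v`` such that the fraction of validation uncertainties
    ``<= v`` is at least ``coverage_target``.  On the validation set itself
    the retained fraction is therefore the smallest achievable fraction
    >= the target.
    """
    u = np.asarray(val_uncertainties, dtype=float)
    if u.size == 0:
        raise ValidationError("cannot estimate a cutoff from an empty set")
    if not (0.0 < coverage_target <= 1.0):
        raise ConfigurationError(
            f"coverage_target must lie in (0, 1], got {coverage_target}"
        )
    cutoff = float(np.quantile(u, coverage_target, method="inverted_cdf"))
    return SelectiveCutoff(cutoff, coverage_target, int(u.size))


def apply_filter(test_uncertainties, cutoff: SelectiveCutoff) -> np.ndarray:
    """Retain mask: 1 where uncertainty <= cutoff (strict excess abstains)."""
    u = np.asarray(test_uncertainties, dtype=float)
    return (u <= cutoff.cutoff).astype(int)


def coverage(mask) -> float:
    """Fraction of cases retained by a filter mask."""
    m = np.asarray(mask, dtype=float)
    if m.size == 0:
        raise ValidationError("coverage of an empty mask is undefined")
    return float(m.mean())


def risk_coverage_sweep(
    test_uncertainties, labels, scores, exclusion_fractions
) -> pd.DataFrame:
    """AUROC of the retained subpopulation as abstention grows.

    For each exclusion fraction ``f``, the ``floor(f*n)`` most-uncertain
    cases are dropped (ties broken by original case order, for determinism)
    and the AUROC of ``scores`` against ``labels`` on the remainder is
    recorded.  A remainder with a single outcome class yields NaN for that
    point rather than an error.

    Returns a DataFrame with columns ``exclusion_fraction``, ``auroc``,
    ``n_retained``.
    """
    u = np.asarray(test_uncertainties, dtype=float)
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if not (u.shape == y.shape == s.shape):
        raise ValidationError("uncertainties, labels and scores must align")
    fracs = sorted(float(f) for f in exclusion_fractions)
    if any(not (0.0 <= f < 1.0) for f in fracs):
        raise ConfigurationError("exclusion fractions must lie in [0, 1)")
    # stable sort of -u: most uncertain first, ties in original case order
    drop_order = np.argsort(-u, kind="stable")
    rows = []
    for f in fracs:
        k = int(np.floor(f * u.size))
        keep = np.ones(u.size, dtype=bool)
        keep[drop_order[:k]] = False
        rows.append(
            {
                "exclusion_fraction": f,
                "auroc": auroc(y[keep], s[keep]),
                "n_retained": int(keep.sum()),
            }
        )
    return pd.DataFrame(rows)
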