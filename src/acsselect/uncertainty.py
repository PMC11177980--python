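"""Predictive-uncertainty decomposition for an ensemble classifier.

For one case, let ``p_m`` be member *m*'s predicted class distribution.
The ensemble mean ``p_bar = mean_m(p_m)`` is the Monte-Carlo estimate of the
posterior predictive distribution, and

* **total uncertainty**  = H(p_bar), the entropy of the posterior
  predictive distribution;
* **data (aleatoric) uncertainty** = mean_m H(p_m), the expected
  per-member entropy — irreducible outcome randomness;
* **model (epistemic) uncertainty** = total − data, the mutual information
  between the prediction and the model parameters — high for inputs unlike
  the training data, and identically zero for a single-member "ensemble".

Entropies are in nats (natural log; the selective-classification cutoff is
quantile-based, so the base cancels there) with the convention 0·ln 0 = 0.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import AcsSelectError, ValidationError

ROW_SUM_TOL = 1e-6
DECOMPOSITION_TOL = 1e-9


class UncertaintyTriple(NamedTuple):
    total: float
    data: float
    model: float


def _validate_rows(member_probs: np.ndarray) -> np.ndarray:
    p = np.asarray(member_probs, dtype=float)
    if p.ndim != 2:
        raise ValidationError(f"expected an M x K array, got shape {p.shape}")
    if np.any(p < -ROW_SUM_TOL) or np.any(p > 1 + ROW_SUM_TOL):
        raise ValidationError("probabilities must lie in [0, 1]")
    sums = p.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
        m = int(np.argmax(np.abs(sums - 1.0)))
        raise ValidationError(f"member row {m} sums to {sums[m]!r}, not 1")
    return p


def entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy in nats along the last axis, with 0·ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0.0, -p * np.log(p), 0.0)
    return terms.sum(axis=-1)


def total_uncertainty(member_probs: np.ndarray) -> float:
    """Entropy of the member-mean distribution (posterior predictive)."""
    p = _validate_rows(member_probs)
    return float(entropy(p.mean(axis=0)))


def data_uncertainty(member_probs: np.ndarray) -> float:
    """Mean of the per-member entropies."""
    p = _validate_rows(member_probs)
    return float(entropy(p).mean())


def model_uncertainty(member_probs: np.ndarray) -> float:
    """Total minus data uncertainty (mutual information).

    By Jensen's inequality this is nonnegative up to floating point; values
    below ``-1e-9`` indicate a bug upstream and raise.
    """
    mi = total_uncertainty(member_probs) - data_uncertainty(member_probs)
    if mi < -DECOMPOSITION_TOL:
        raise AcsSelectError(
            f"uncertainty decomposition violated: model uncertainty {mi} < 0"
        )
    return max(mi, 0.0)


def case_uncertainty(member_probs: np.ndarray) -> UncertaintyTriple:
    """All three uncertainties for one case's M x K member predictions."""
    total = total_uncertainty(member_probs)
    data = data_uncertainty(member_probs)
    mi = total - data
    if mi < -DECOMPOSITION_TOL:
        raise AcsSelectError(
            f"uncertainty decomposition violated: model uncertainty {mi} < 0"
        )
    return UncertaintyTriple(total, data, max(mi, 0.0))


def uncertainty_table(member_preds: np.ndarray) -> pd.DataFrame:
    """Vectorised decomposition of an M x n x K prediction tensor.

    Returns a DataFrame with columns ``total_u``, ``data_u``, ``model_u``
    (one row per case, in case order) suitable for appending to a
    prediction table.
    """
    p = np.asarray(member_preds, dtype=float)
    if p.ndim != 3:
        raise ValidationError(f"expected an M x n x K tensor, got shape {p.shape}")
    sums = p.sum(axis=2)
    if np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
        m, i = np.unravel_index(int(np.argmax(np.abs(sums - 1.0))), sums.shape)
        raise ValidationError(
            f"member {m}, case {i}: probabilities sum to {sums[m, i]!r}, not 1"
        )
    total = entropy(p.mean(axis=0))
    data = entropy(p).mean(axis=0)
    model = total - data
    if np.any(model < -DECOMPOSITION_TOL):
        raise AcsSelectError("uncertainty decomposition violated beyond tolerance")
    return pd.DataFrame(
        {"total_u": total, "data_u": data, "model_u": np.maximum(model, 0.0)}
    )
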