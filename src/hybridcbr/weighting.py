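"""Attribute and case weights derived from a fitted logistic model.

Two weight families drive the hybrid K-NN:

* **attribute weights** — the Wald statistic (beta / se)^2 of each attribute,
  normalized to sum to one over the full attribute set; attributes excluded
  from the model (stepwise selection or degenerate columns) get weight 0;
* **case weights** — the reliability of each solved case, phi(|r|) with r its
  Pearson residual and phi the standard-normal density: cases matching the
  model archetype (r near 0) weigh most, outliers decay smoothly towards 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .logistic import FittedLogisticModel

__all__ = ["WeightSet", "attribute_weights", "case_weights", "uniform_weights"]

PHI_AT_ZERO = 1.0 / np.sqrt(2.0 * np.pi)  # upper bound of any raw case weight


@dataclass(frozen=True)
class WeightSet:
    """Normalized attribute weights plus raw per-case reliability weights.

    Raw case weights are kept unnormalized here; they are renormalized over
    the K selected neighbors at fusion time.
    """

    attribute_weights: dict[str, float]
    case_weights_raw: dict[str, float]
    source_model_id: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        w = np.array(list(self.attribute_weights.values()), dtype=float)
        if w.size:
            if (w < 0).any():
                raise ValueError("attribute weights must be non-negative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"attribute weights must sum to 1, got {w.sum()}")
        cw = np.array(list(self.case_weights_raw.values()), dtype=float)
        if cw.size and ((cw <= 0).any() or (cw > PHI_AT_ZERO + 1e-12).any()):
            raise ValueError(
                "raw case weights must lie in (0, 1/sqrt(2*pi)]"
            )

    def attribute_vector(self, attribute_names: Sequence[str]) -> np.ndarray:
        return np.array(
            [self.attribute_weights[a] for a in attribute_names], dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        """Attribute-weight table (attribute, weight, percent)."""
        items = list(self.attribute_weights.items())
        df = pd.DataFrame(items, columns=["attribute", "weight"])
        df["percent"] = 100.0 * df["weight"]
        return df


def attribute_weights(
    model: FittedLogisticModel,
    all_attributes: Sequence[str],
    squared: bool = True,
) -> dict[str, float]:
    """Normalized Wald-statistic weights over ``all_attributes``.

    W_a = (beta_a / se_a)^2 for attributes in the model, 0 for the rest;
    w_a = W_a / sum(W).  ``squared=False`` switches to the unsquared |z|
    variant for sensitivity analysis.  If every Wald statistic is zero the
    weights fall back to uniform (with a warning).
    """
    if not model.converged:
        raise ValueError("model did not converge; weights undefined")
    missing = set(model.included_attributes) - set(all_attributes)
    if missing:
        raise ValueError(f"model attributes absent from the set: {sorted(missing)}")
    stats = {}
    for a in all_attributes:
        if a in model.included_attributes:
            se = model.standard_errors[a]
            if se == 0:
                raise ValueError(f"zero standard error for {a!r}")
            z = model.coefficients[a] / se
            stats[a] = z * z if squared else abs(z)
        else:
            stats[a] = 0.0
    total = sum(stats.values())
    if total == 0.0:
        warnings.warn(
            "all Wald statistics are zero; falling back to uniform weights",
            stacklevel=2,
        )
        return uniform_weights(all_attributes)
    return {a: s / total for a, s in stats.items()}


def uniform_weights(attributes: Sequence[str]) -> dict[str, float]:
    """Uniform attribute weights 1/m over the given attributes."""
    m = len(attributes)
    if m == 0:
        raise ValueError("empty attribute set")
    return {a: 1.0 / m for a in attributes}


def case_weights(
    residuals: Sequence[float], case_ids: Sequence[str]
) -> dict[str, float]:
    """Raw reliability weights omega = phi(|r|), phi the N(0,1) density.

    Strictly positive, maximal (1/sqrt(2*pi)) at r = 0, strictly decreasing
    in |r|.
    """
    r = np.asarray(residuals, dtype=float)
    if len(case_ids) != r.size:
        raise ValueError("one residual per case id required")
    if not np.isfinite(r).all():
        raise ValueError("residuals must be finite")
    omega = norm.pdf(np.abs(r))
    return {str(c): float(w) for c, w in zip(case_ids, omega)}
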