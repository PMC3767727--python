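"""Model / Results surface tying the pipeline together.

``HybridCBR`` is built from a labeled case base and a variant choice; its
``fit()`` performs the whole learning phase — three-way split, logistic
maximum-likelihood fit (optionally backward-AIC selected), attribute and
case weighting, K tuning on the setting set — and returns a
``HybridCBRResults`` carrying the estimates, the tuned K, evaluation helpers
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .casebase import CaseBase, SplitSpec, split_case_base
from .evaluation import EvaluationReport, auc, bootstrap_auc
from .knn import KnnConfig, predict as knn_predict, tune_k
from .knn import _attribute_weight_vector, _case_weight_vector
from .logistic import (
    FittedLogisticModel,
    fit_logistic,
    pearson_residuals,
    predict_prob,
    stepwise_select,
)
from .weighting import WeightSet, attribute_weights, case_weights

__all__ = ["HybridCBR", "HybridCBRResults"]


class HybridCBR:
    """Hybrid case-based-reasoning classifier over binary attributes.

    Parameters
    ----------
    cohort
        Labeled, complete case base.
    variant
        One of ``lr``, ``cbr``, ``cbr_wa``, ``cbr_wp``, ``cbr_wa_wp``
        (default: the doubly weighted hybrid).
    stepwise
        Whether to run backward stepwise AIC selection on the logistic model
        before weighting (the "selected attributes" sub-scenario).
    k
        Neighborhood size, or ``"auto"`` to tune on the setting split.
    k_max
        Upper bound of the K scan when tuning.
    fractions, seed
        Train / setting / evaluation split specification.
    """

    def __init__(
        self,
        cohort: CaseBase,
        variant: str = "cbr_wa_wp",
        stepwise: bool = False,
        k: int | str = "auto",
        k_max: int = 51,
        fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
        seed: int = 0,
        wald_squared: bool = True,
        ridge_fallback: bool = False,
    ) -> None:
        if not cohort.is_labeled:
            raise ValueError("cohort must be labeled")
        if not cohort.is_complete:
            raise ValueError(
                "cohort must be complete; run filter_complete_cases first"
            )
        self.cohort = cohort
        self.config = KnnConfig(variant=variant, k=k, k_max=k_max)
        self.stepwise = stepwise
        self.split_spec = SplitSpec(fractions=fractions, seed=seed)
        self.wald_squared = wald_squared
        self.ridge_fallback = ridge_fallback

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str = "label",
        id_column: str | None = "case_id",
        **kwargs,
    ) -> "HybridCBR":
        cb = CaseBase.from_dataframe(df, label_column=label_column, id_column=id_column)
        return cls(cb, **kwargs)

    def fit(self) -> "HybridCBRResults":
        train, setting, eval_set = split_case_base(self.cohort, self.split_spec)
        if self.stepwise:
            lr = stepwise_select(train, ridge=self.ridge_fallback)
        else:
            lr = fit_logistic(train, ridge=self.ridge_fallback)
        aw = attribute_weights(
            lr, self.cohort.attribute_names, squared=self.wald_squared
        )
        cw = case_weights(pearson_residuals(lr, train), train.case_ids)
        wset = WeightSet(
            attribute_weights=aw,
            case_weights_raw=cw,
            source_model_id="stepwise" if self.stepwise else "full",
        )
        active = lr.included_attributes if self.stepwise else None

        k_used: int | None = None
        setting_auc = None
        auc_per_k = None
        if self.config.variant != "lr":
            use_wald = self.config.variant in ("cbr_wa", "cbr_wa_wp")
            use_cw = self.config.variant in ("cbr_wp", "cbr_wa_wp")
            w = _attribute_weight_vector(train, wset, use_wald, active)
            cwv = _case_weight_vector(train, wset, use_cw)
            if self.config.k == "auto":
                k_used, auc_per_k = tune_k(
                    train, setting, w, cwv, k_max=self.config.k_max
                )
                setting_auc = float(auc_per_k[k_used - 1])
            else:
                k_used = int(self.config.k)

        return HybridCBRResults(
            model=self,
            logistic_model=lr,
            weight_set=wset,
            train=train,
            setting=setting,
            eval_set=eval_set,
            k_used=k_used,
            setting_auc=setting_auc,
            auc_per_k=auc_per_k,
            active_attributes=active,
        )


@dataclass
class HybridCBRResults:
    """Learned state of a :class:`HybridCBR` plus prediction / evaluation."""

    model: HybridCBR
    logistic_model: FittedLogisticModel
    weight_set: WeightSet
    train: CaseBase
    setting: CaseBase
    eval_set: CaseBase
    k_used: int | None
    setting_auc: float | None
    auc_per_k: np.ndarray | None
    active_attributes: tuple[str, ...] | None
    _eval_scores: np.ndarray | None = field(default=None, repr=False)

    @property
    def variant(self) -> str:
        return self.model.config.variant

    def predict(self, queries: CaseBase | pd.DataFrame) -> np.ndarray:
        """Soft scores in [0,1] for query cases."""
        if isinstance(queries, pd.DataFrame):
            queries = CaseBase.from_dataframe(queries, label_column=None)
        cfg = self.model.config
        if cfg.variant != "lr":
            cfg = KnnConfig(variant=cfg.variant, k=self.k_used, k_max=cfg.k_max)
        results = knn_predict(
            cfg,
            self.logistic_model,
            self.weight_set,
            self.train,
            queries.without_labels(),
            active_attributes=self.active_attributes,
        )
        return np.array([r.score for r in results])

    def predict_detailed(self, queries: CaseBase):
        """Per-query :class:`~hybridcbr.knn.PredictionResult` objects."""
        cfg = self.model.config
        if cfg.variant != "lr":
            cfg = KnnConfig(variant=cfg.variant, k=self.k_used, k_max=cfg.k_max)
        return knn_predict(
            cfg,
            self.logistic_model,
            self.weight_set,
            self.train,
            queries.without_labels(),
            active_attributes=self.active_attributes,
        )

    def eval_scores(self) -> np.ndarray:
        if self._eval_scores is None:
            self._eval_scores = self.predict(self.eval_set)
        return self._eval_scores

    def evaluate(self, B: int = 500, seed: int = 0) -> EvaluationReport:
        """Bootstrap AUC of the held-out evaluation split."""
        return bootstrap_auc(self.eval_scores(), self.eval_set.labels, B=B, seed=seed)

    def eval_auc(self) -> float:
        return auc(self.eval_scores(), self.eval_set.labels)

    def summary(self) -> str:
        """Text summary: split sizes, logistic estimates, weights, tuned K."""
        lr = self.logistic_model
        lines = [
            "Hybrid CBR results",
            "==================",
            f"variant:            {self.variant}",
            f"stepwise selection: {self.model.stepwise}",
            f"split sizes:        train={self.train.n_cases}, "
            f"setting={self.setting.n_cases}, eval={self.eval_set.n_cases}",
            f"logistic model:     {len(lr.included_attributes)} attributes, "
            f"AIC={lr.aic:.2f}, converged={lr.converged}",
        ]
        if self.k_used is not None:
            lines.append(
                f"tuned K:            {self.k_used}"
                + (
                    f"  (setting AUC={self.setting_auc:.3f})"
                    if self.setting_auc is not None
                    else ""
                )
            )
        lines.append("")
        lines.append(f"{'attribute':<30}{'coef':>9}{'se':>8}{'weight %':>10}")
        lines.append("-" * 57)
        for a in self.model.cohort.attribute_names:
            w = 100.0 * self.weight_set.attribute_weights[a]
            if a in lr.included_attributes:
                lines.append(
                    f"{a:<30}{lr.coefficients[a]:>9.3f}"
                    f"{lr.standard_errors[a]:>8.3f}{w:>10.1f}"
                )
            else:
                lines.append(f"{a:<30}{'-':>9}{'-':>8}{w:>10.1f}")
        return "\n".join(lines)
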