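"""AUC, bootstrap AUC with percentile intervals, and the full protocol grid.

The protocol mirrors the study design around the hybrid classifier: split a
labeled cohort into train / setting / evaluation thirds; learn the logistic
model (with and without backward-AIC attribute selection) on the training
set; derive Wald attribute weights and Pearson-residual case weights; tune K
per variant on the setting set; score the evaluation set with the five
algorithm variants; and bootstrap the evaluation AUC (B resamples,
percentile 95% interval).  The whole grid is repeated with a block of
pure-noise attributes appended (before splitting, same split seed) to probe
robustness to irrelevant attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .casebase import CaseBase, SplitSpec, split_case_base
from .knn import KnnConfig, VARIANTS, predict, tune_k, _attribute_weight_vector, _case_weight_vector
from .logistic import (
    FittedLogisticModel,
    fit_logistic,
    pearson_residuals,
    predict_prob,
    stepwise_select,
)
from .synthetic import SyntheticSpec, add_random_attributes, generate_case_base
from .weighting import WeightSet, attribute_weights, case_weights

__all__ = [
    "EvaluationReport",
    "ProtocolConfig",
    "CellResult",
    "ProtocolResult",
    "auc",
    "bootstrap_auc",
    "run_protocol",
]

SCENARIOS = ("clean", "noise")
SELECTIONS = ("all", "selected")


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney form with midrank ties.

    Equals P(score+ > score-) + 0.5 P(tie) over positive/negative pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # midranks
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class EvaluationReport:
    """Point AUC plus the bootstrap Monte-Carlo AUC estimator and its
    percentile 95% interval."""

    auc_point: float
    auc_bootstrap_mean: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int
    n_eval: int
    n_redraws: int = 0

    def __post_init__(self) -> None:
        for v in (self.auc_point, self.auc_bootstrap_mean, self.ci_low, self.ci_high):
            if not 0.0 <= v <= 1.0:
                raise ValueError("AUC quantities must lie in [0,1]")
        if not self.ci_low <= self.auc_bootstrap_mean <= self.ci_high:
            raise ValueError("bootstrap mean must lie inside the interval")
        if self.n_bootstrap < 1:
            raise ValueError("need at least one bootstrap replicate")


def bootstrap_auc(scores, labels, B: int = 500, seed: int = 0) -> EvaluationReport:
    """Bootstrap the AUC of (scores, labels).

    Draws B with-replacement resamples of the original evaluation size,
    computes the AUC of each, and reports the point AUC (unresampled data),
    the mean of the replicate AUCs, and their empirical 2.5 / 97.5
    percentiles.  A resample missing one of the classes is redrawn (counted;
    aborts after 10*B redraws).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    point = auc(scores, labels)
    n = scores.size
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.min() != lab.max():
                break
            redraws += 1
            if redraws > 10 * B:
                raise RuntimeError("too many single-class bootstrap resamples")
        reps[b] = auc(scores[idx], lab)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return EvaluationReport(
        auc_point=point,
        auc_bootstrap_mean=float(reps.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_bootstrap=B,
        seed=seed,
        n_eval=n,
        n_redraws=redraws,
    )


# ---------------------------------------------------------------------------
# Protocol grid


@dataclass(frozen=True)
class ProtocolConfig:
    """Knobs of the full evaluation protocol."""

    fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    split_seed: int = 0
    n_noise_attributes: int = 50
    noise_prevalence: float = 0.5
    noise_seed: int = 1
    k_max: int = 51
    n_bootstrap: int = 500
    bootstrap_seed: int = 0
    wald_squared: bool = True
    ridge_fallback: bool = False


@dataclass(frozen=True)
class CellResult:
    """One (scenario, selection, variant) cell of the protocol grid."""

    scenario: str
    selection: str
    variant: str
    report: EvaluationReport | None
    k_used: int | None = None
    setting_auc: float | None = None
    error: str | None = None


@dataclass(frozen=True)
class ProtocolResult:
    """Full grid plus per-(scenario, selection) weight tables and manifest."""

    cells: dict[tuple[str, str, str], CellResult]
    weight_sets: dict[tuple[str, str], WeightSet]
    models: dict[tuple[str, str], FittedLogisticModel]
    manifest: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sc, sel, var), cell in sorted(self.cells.items()):
            r = cell.report
            rows.append(
                {
                    "scenario": sc,
                    "selection": sel,
                    "variant": var,
                    "auc_point": None if r is None else r.auc_point,
                    "auc_bootstrap_mean": None if r is None else r.auc_bootstrap_mean,
                    "ci_low": None if r is None else r.ci_low,
                    "ci_high": None if r is None else r.ci_high,
                    "k": cell.k_used,
                    "error": cell.error,
                }
            )
        return pd.DataFrame(rows)


def _cell_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence((base, index)).generate_state(1)[0] % (2**31))


def run_protocol(
    cohort: CaseBase | SyntheticSpec, config: ProtocolConfig = ProtocolConfig()
) -> ProtocolResult:
    """Run the five algorithms over the 2 x 2 scenario grid.

    Scenarios: ``clean`` (the cohort as given) and ``noise`` (the cohort with
    ``n_noise_attributes`` pure-noise columns appended before splitting, same
    split seed, so the two scenarios are paired on the same case rows).
    Sub-scenarios: logistic model fitted on ``all`` attributes or on the
    backward-AIC ``selected`` subset.  Failed cells are recorded, not fatal.
    """
    if isinstance(cohort, SyntheticSpec):
        cohort = generate_case_base(cohort)
    if not cohort.is_labeled or not cohort.is_complete:
        raise ValueError("protocol requires a labeled, complete cohort")

    cells: dict[tuple[str, str, str], CellResult] = {}
    weight_sets: dict[tuple[str, str], WeightSet] = {}
    models: dict[tuple[str, str], FittedLogisticModel] = {}

    cell_index = 0
    for scenario in SCENARIOS:
        if scenario == "noise":
            if config.n_noise_attributes == 0:
                continue
            base = add_random_attributes(
                cohort,
                config.n_noise_attributes,
                prevalence=config.noise_prevalence,
                seed=config.noise_seed,
            )
        else:
            base = cohort
        train, setting, eval_set = split_case_base(
            base, SplitSpec(config.fractions, config.split_seed)
        )
        for selection in SELECTIONS:
            try:
                if selection == "all":
                    model = fit_logistic(train, ridge=config.ridge_fallback)
                else:
                    model = stepwise_select(train, ridge=config.ridge_fallback)
                aw = attribute_weights(
                    model, base.attribute_names, squared=config.wald_squared
                )
                cw = case_weights(pearson_residuals(model, train), train.case_ids)
                wset = WeightSet(
                    attribute_weights=aw,
                    case_weights_raw=cw,
                    source_model_id=f"{scenario}/{selection}",
                )
            except Exception as e:  # noqa: BLE001 - cell-level isolation
                for variant in VARIANTS:
                    cells[(scenario, selection, variant)] = CellResult(
                        scenario, selection, variant, None, error=str(e)
                    )
                    cell_index += 1
                continue
            models[(scenario, selection)] = model
            weight_sets[(scenario, selection)] = wset
            active = model.included_attributes if selection == "selected" else None

            for variant in VARIANTS:
                seed_b = _cell_seed(config.bootstrap_seed, cell_index)
                cell_index += 1
                try:
                    if variant == "lr":
                        scores = predict_prob(model, eval_set)
                        k_used, setting_auc = None, None
                    else:
                        use_wald = variant in ("cbr_wa", "cbr_wa_wp")
                        use_cw = variant in ("cbr_wp", "cbr_wa_wp")
                        w = _attribute_weight_vector(train, wset, use_wald, active)
                        cwv = _case_weight_vector(train, wset, use_cw)
                        k_used, auc_per_k = tune_k(
                            train, setting, w, cwv, k_max=config.k_max
                        )
                        setting_auc = float(auc_per_k[k_used - 1])
                        results = predict(
                            KnnConfig(variant=variant, k=k_used, k_max=config.k_max),
                            model,
                            wset,
                            train,
                            eval_set.without_labels(),
                            active_attributes=active,
                        )
                        scores = np.array([r.score for r in results])
                    report = bootstrap_auc(
                        scores, eval_set.labels, B=config.n_bootstrap, seed=seed_b
                    )
                    cells[(scenario, selection, variant)] = CellResult(
                        scenario, selection, variant, report,
                        k_used=k_used, setting_auc=setting_auc,
                    )
                except Exception as e:  # noqa: BLE001
                    warnings.warn(
                        f"protocol cell ({scenario},{selection},{variant}) "
                        f"failed: {e}",
                        stacklevel=2,
                    )
                    cells[(scenario, selection, variant)] = CellResult(
                        scenario, selection, variant, None, error=str(e)
                    )

    manifest = {
        "n_cases": cohort.n_cases,
        "n_attributes": cohort.n_attributes,
        "config": {
            "fractions": list(config.fractions),
            "split_seed": config.split_seed,
            "n_noise_attributes": config.n_noise_attributes,
            "noise_prevalence": config.noise_prevalence,
            "noise_seed": config.noise_seed,
            "k_max": config.k_max,
            "n_bootstrap": config.n_bootstrap,
            "bootstrap_seed": config.bootstrap_seed,
            "wald_squared": config.wald_squared,
        },
        "cohort_metadata": dict(cohort.metadata),
    }
    return ProtocolResult(
        cells=cells, weight_sets=weight_sets, models=models, manifest=manifest
    )
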