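"""Maximum-likelihood logistic regression on a labeled case base.

Fitting is delegated to statsmodels (Newton scoring); this module adds the
case-base plumbing, degenerate-column handling, quasi-separation detection
with an optional ridge fallback, backward stepwise selection by Akaike's
information criterion, and Pearson residuals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .casebase import CaseBase

__all__ = [
    "FittedLogisticModel",
    "SeparationError",
    "fit_logistic",
    "stepwise_select",
    "predict_prob",
    "pearson_residuals",
]

PROB_CLAMP = 1e-12
SEPARATION_COEF_BOUND = 15.0


class SeparationError(RuntimeError):
    """Quasi-complete separation: the MLE diverges.

    Either remove the offending attribute or refit with ``ridge=True`` for a
    weakly penalized estimate.
    """


@dataclass(frozen=True)
class FittedLogisticModel:
    """Fitted logistic model: log odds(y=1) = intercept + sum(beta_a x_a).

    ``included_attributes`` is the subset of the case base's attributes that
    actually entered the model (after any stepwise selection and after
    dropping degenerate columns); excluded attributes simply have no
    coefficient.
    """

    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    included_attributes: tuple[str, ...]
    fitted_probabilities: np.ndarray
    log_likelihood: float
    aic: float
    converged: bool
    n_train: int
    intercept_se: float = float("nan")
    dropped_attributes: tuple[str, ...] = ()
    ridge: bool = False
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for a in self.included_attributes:
            se = self.standard_errors.get(a)
            if se is None or not np.isfinite(se) or se <= 0:
                raise ValueError(f"attribute {a!r} lacks a finite positive SE")
        p = np.asarray(self.fitted_probabilities, dtype=float)
        if p.size and (p.min() <= 0.0 or p.max() >= 1.0):
            raise ValueError("fitted probabilities must lie strictly in (0,1)")
        object.__setattr__(self, "fitted_probabilities", p)
        expected_aic = -2.0 * self.log_likelihood + 2.0 * (
            1 + len(self.included_attributes)
        )
        if abs(expected_aic - self.aic) > 1e-6:
            raise ValueError("aic inconsistent with log-likelihood")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "included_attributes": list(self.included_attributes),
            "dropped_attributes": list(self.dropped_attributes),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "converged": self.converged,
            "n_train": self.n_train,
            "ridge": self.ridge,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedLogisticModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            intercept_se=d.get("intercept_se", float("nan")),
            coefficients=d["coefficients"],
            standard_errors=d["standard_errors"],
            included_attributes=tuple(d["included_attributes"]),
            dropped_attributes=tuple(d.get("dropped_attributes", ())),
            fitted_probabilities=np.empty(0),
            log_likelihood=d["log_likelihood"],
            aic=d["aic"],
            converged=d["converged"],
            n_train=d["n_train"],
            ridge=d.get("ridge", False),
        )


def _design_matrix(
    cb: CaseBase, attributes: tuple[str, ...]
) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Column-screened design matrix with a leading constant.

    Constant columns and columns linearly dependent on earlier ones are
    dropped (with a warning) rather than breaking the information matrix.
    """
    name_to_col = {a: j for j, a in enumerate(cb.attribute_names)}
    X_cols, kept, dropped = [], [], []
    basis = np.ones((cb.n_cases, 1))
    for a in attributes:
        col = cb.values[:, name_to_col[a]]
        if col.min() == col.max():
            dropped.append(a)
            continue
        cand = np.column_stack([basis, col])
        if np.linalg.matrix_rank(cand) == basis.shape[1]:
            dropped.append(a)
            continue
        basis = cand
        X_cols.append(col)
        kept.append(a)
    if dropped:
        warnings.warn(
            f"dropped degenerate attribute columns before fitting: {dropped}",
            stacklevel=3,
        )
    X = np.column_stack([np.ones(cb.n_cases)] + X_cols) if X_cols else np.ones(
        (cb.n_cases, 1)
    )
    return X, tuple(kept), tuple(dropped)


def _ridge_fit(X: np.ndarray, y: np.ndarray, lam: float = 1e-4, maxiter: int = 200):
    """Newton fit with a small L2 penalty on slopes (never the intercept).

    Step-halving keeps the penalized log-likelihood monotone, so the solver
    is safe on quasi-separated designs where the unpenalized MLE diverges.
    """
    n, p = X.shape
    pen = np.full(p, lam)
    pen[0] = 0.0

    def pllf(b):
        mu = np.clip(expit(X @ b), PROB_CLAMP, 1 - PROB_CLAMP)
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        return ll - 0.5 * float(pen @ (b * b)), mu

    beta = np.zeros(p)
    obj, mu = pllf(beta)
    for _ in range(maxiter):
        grad = X.T @ (y - mu) - pen * beta
        if np.max(np.abs(grad)) < 1e-8:
            break
        W = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X.T * W) @ X + np.diag(pen)
        step = np.linalg.solve(H, grad)
        scale = 1.0
        for _ in range(12):
            cand = beta + scale * step
            obj_new, mu_new = pllf(cand)
            if obj_new >= obj - 1e-12:
                break
            scale /= 2.0
        beta, obj, mu = cand, obj_new, mu_new
    mu = np.clip(expit(X @ beta), PROB_CLAMP, 1 - PROB_CLAMP)
    llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    cov = np.linalg.inv((X.T * (mu * (1 - mu))) @ X + np.diag(pen))
    return beta, np.sqrt(np.diag(cov)), llf


def fit_logistic(
    train: CaseBase,
    attributes: tuple[str, ...] | list[str] | None = None,
    ridge: bool = False,
) -> FittedLogisticModel:
    """ML logistic fit of the label on the given attributes (default: all).

    Newton scoring with standard errors from the inverse observed
    information.  Raises :class:`SeparationError` when the fit fails to
    converge with a diverging coefficient (|beta| > 15) unless ``ridge=True``,
    which applies a small L2 penalty (lambda = 1e-4) to the slopes.
    """
    if not train.is_labeled:
        raise ValueError("training case base must be labeled")
    if not train.is_complete:
        raise ValueError("training case base must be complete")
    y = train.labels.astype(float)
    if y.min() == y.max():
        raise ValueError("labels contain a single class; cannot fit")
    if attributes is None:
        attributes = train.attribute_names
    attributes = tuple(attributes)
    unknown = set(attributes) - set(train.attribute_names)
    if unknown:
        raise ValueError(f"unknown attributes: {sorted(unknown)}")

    X, kept, dropped = _design_matrix(train, attributes)

    if ridge:
        beta, se, llf = _ridge_fit(X, y)
        converged = True
    else:
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(
                    method="newton", maxiter=100, tol=1e-10, disp=0,
                    warn_convergence=False,
                )
        except (np.linalg.LinAlgError, PerfectSeparationError) as e:
            raise SeparationError(
                "quasi-complete separation detected (singular information); "
                "refit with ridge=True or remove the offending attribute"
            ) from e
        beta = np.asarray(res.params, dtype=float)
        converged = bool(res.mle_retvals.get("converged", False))
        if not converged and np.max(np.abs(beta)) > SEPARATION_COEF_BOUND:
            raise SeparationError(
                "quasi-complete separation detected (diverging coefficient); "
                "refit with ridge=True or remove the offending attribute"
            )
        se = np.asarray(res.bse, dtype=float)
        llf = float(res.llf)

    probs = np.clip(expit(X @ beta), PROB_CLAMP, 1 - PROB_CLAMP)
    k_params = 1 + len(kept)
    return FittedLogisticModel(
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        coefficients={a: float(b) for a, b in zip(kept, beta[1:])},
        standard_errors={a: float(s) for a, s in zip(kept, se[1:])},
        included_attributes=kept,
        dropped_attributes=dropped,
        fitted_probabilities=probs,
        log_likelihood=llf,
        aic=-2.0 * llf + 2.0 * k_params,
        converged=converged,
        n_train=train.n_cases,
        ridge=ridge,
    )


def _newton_llf(X: np.ndarray, y: np.ndarray, maxiter: int = 100):
    """Plain Newton MLE returning (beta, llf, converged).

    Step-halving safeguard; used only to scan candidate models during
    stepwise selection, where only the log-likelihood (hence AIC) matters.
    """
    beta = np.zeros(X.shape[1])
    eta = X @ beta
    mu = expit(eta)
    llf = float(np.sum(y * np.log(np.clip(mu, PROB_CLAMP, None))
                       + (1 - y) * np.log(np.clip(1 - mu, PROB_CLAMP, None))))
    converged = False
    for _ in range(maxiter):
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < 1e-8:
            converged = True
            break
        W = np.clip(mu * (1 - mu), 1e-10, None)
        try:
            step = np.linalg.solve((X.T * W) @ X, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(10):
            new_beta = beta + scale * step
            mu_new = np.clip(expit(X @ new_beta), PROB_CLAMP, 1 - PROB_CLAMP)
            llf_new = float(
                np.sum(y * np.log(mu_new) + (1 - y) * np.log(1 - mu_new))
            )
            if llf_new >= llf - 1e-12:
                break
            scale /= 2.0
        beta, mu, llf = new_beta, mu_new, llf_new
    return beta, llf, converged


def stepwise_select(
    train: CaseBase,
    attributes: tuple[str, ...] | list[str] | None = None,
    ridge: bool = False,
) -> FittedLogisticModel:
    """Backward stepwise selection by AIC.

    Starts from the full model and repeatedly removes the single attribute
    whose removal lowers AIC the most, stopping when no removal lowers AIC.
    There is no forward re-entry.  If the full model fails by separation,
    selection starts from the largest fittable subset (offending columns
    greedily dropped, with a warning).

    Candidate models are scanned with an internal Newton solver (only their
    AIC is needed); the surviving model is refitted through
    :func:`fit_logistic`.
    """
    if attributes is None:
        attributes = train.attribute_names
    attributes = tuple(attributes)
    if not train.is_labeled or not train.is_complete:
        raise ValueError("training case base must be labeled and complete")
    y = train.labels.astype(float)
    if len(attributes) == 0:
        return fit_logistic(train, ())

    X_full, kept, _ = _design_matrix(train, attributes)
    current = list(kept)
    col_of = {a: j + 1 for j, a in enumerate(kept)}  # +1: constant first

    def scan(attrs: list[str]) -> float:
        """AIC of the model on ``attrs`` (inf when separation-degenerate)."""
        X = X_full[:, [0] + [col_of[a] for a in attrs]]
        beta, llf, conv = _newton_llf(X, y)
        if not conv and np.max(np.abs(beta)) > SEPARATION_COEF_BOUND:
            return float("inf")
        return -2.0 * llf + 2.0 * (1 + len(attrs))

    aic = scan(current)
    if not np.isfinite(aic):
        # largest fittable subset: greedily drop the worst-diverging column
        while current and not np.isfinite(aic):
            diag = fit_logistic(train, tuple(current), ridge=True)
            worst = max(
                diag.included_attributes, key=lambda a: abs(diag.coefficients[a])
            )
            current.remove(worst)
            warnings.warn(
                f"stepwise_select: dropped {worst!r} to escape separation",
                stacklevel=2,
            )
            aic = scan(current)

    improved = True
    while improved and current:
        improved = False
        best_aic, best_attr = aic, None
        for a in current:
            cand_aic = scan([x for x in current if x != a])
            if cand_aic < best_aic - 1e-10:
                best_aic, best_attr = cand_aic, a
        if best_attr is not None:
            current.remove(best_attr)
            aic = best_aic
            improved = True
    return fit_logistic(train, tuple(current), ridge=ridge)


def predict_prob(model: FittedLogisticModel, cb: CaseBase) -> np.ndarray:
    """Per-case probability expit(intercept + sum(coef * value)).

    Attributes absent from the model are ignored; a model attribute missing
    from the case base is an error.
    """
    if not cb.is_complete:
        raise ValueError("case base must be complete")
    missing = set(model.included_attributes) - set(cb.attribute_names)
    if missing:
        raise ValueError(f"case base lacks model attributes: {sorted(missing)}")
    eta = np.full(cb.n_cases, model.intercept)
    name_to_col = {a: j for j, a in enumerate(cb.attribute_names)}
    for a in model.included_attributes:
        eta += model.coefficients[a] * cb.values[:, name_to_col[a]]
    return np.clip(expit(eta), PROB_CLAMP, 1 - PROB_CLAMP)


def pearson_residuals(model: FittedLogisticModel, train: CaseBase) -> np.ndarray:
    """r = (y - pi) / sqrt(pi (1 - pi)) per training case.

    Fitted probabilities are clamped to [1e-12, 1 - 1e-12] (with a warning)
    should they touch the boundary numerically.
    """
    if not train.is_labeled:
        raise ValueError("training case base must be labeled")
    pi = predict_prob(model, train)
    if np.any(pi <= PROB_CLAMP) or np.any(pi >= 1 - PROB_CLAMP):
        warnings.warn("fitted probabilities clamped away from 0/1", stacklevel=2)
        pi = np.clip(pi, PROB_CLAMP, 1 - PROB_CLAMP)
    y = train.labels.astype(float)
    return (y - pi) / np.sqrt(pi * (1 - pi))
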