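"""The CBR core: weighted similarity, soft K-NN selection/fusion, K tuning.

Similarity between two binary cases is one minus a weighted Hamming
distance: d(p, q) = sum_a w_a * XOR(p_a, q_a), with attribute weights w
summing to one, so both distance and similarity live in [0, 1].

A query's soft score is a convex combination of its K most similar labeled
cases' labels; fusion weights are either uniform or the cases' reliability
weights (standard-normal density of their Pearson residuals), renormalized
over the selected neighbors.

Five algorithm variants are dispatched by :func:`predict`:

========== =====================================================
``lr``        standalone logistic regression (no neighbors)
``cbr``       standalone K-NN (uniform attributes, uniform fusion)
``cbr_wa``    K-NN with Wald-weighted attributes
``cbr_wp``    K-NN with reliability-weighted fusion
``cbr_wa_wp`` both weightings (the hybrid of interest)
========== =====================================================

All floating-point reductions along the attribute axis use numpy's pairwise
summation on contiguous slices, so scores are bit-reproducible and can be
compared exactly against a naive per-pair reimplementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .casebase import CaseBase
from .logistic import FittedLogisticModel, predict_prob
from .weighting import WeightSet, uniform_weights

__all__ = [
    "VARIANTS",
    "KnnConfig",
    "PredictionResult",
    "similarity",
    "similarity_matrix",
    "select_neighbors",
    "fuse",
    "tune_k",
    "predict",
]

VARIANTS = ("lr", "cbr", "cbr_wa", "cbr_wp", "cbr_wa_wp")
Variant = Literal["lr", "cbr", "cbr_wa", "cbr_wp", "cbr_wa_wp"]


@dataclass(frozen=True)
class KnnConfig:
    """Variant choice plus K policy.

    ``k`` may be an integer or ``"auto"``; ``"auto"`` means the caller (the
    model layer) tunes K on a setting set via :func:`tune_k` before
    prediction.  Ties at the K-th neighbor are broken deterministically by
    ascending case index.
    """

    variant: Variant = "cbr_wa_wp"
    k: int | str = "auto"
    k_max: int = 51

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if isinstance(self.k, str):
            if self.k != "auto":
                raise ValueError("k must be a positive integer or 'auto'")
        elif self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")


@dataclass(frozen=True)
class PredictionResult:
    """Soft prediction for one query case."""

    case_id: str
    score: float
    k_used: int
    neighbor_ids: tuple[str, ...] = ()
    neighbor_similarities: tuple[float, ...] = ()
    fusion_weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0,1]")
        fw = np.asarray(self.fusion_weights, dtype=float)
        if fw.size:
            if (fw < 0).any() or abs(fw.sum() - 1.0) > 1e-9:
                raise ValueError("fusion weights must be non-negative, sum 1")
            if not (
                len(self.neighbor_ids)
                == len(self.neighbor_similarities)
                == fw.size
                == self.k_used
            ):
                raise ValueError("neighbor lists must all have length k_used")


# ---------------------------------------------------------------------------
# Similarity


def similarity(p: np.ndarray, q: np.ndarray, w: np.ndarray) -> float:
    """1 - sum_a w_a XOR(p_a, q_a) for two complete binary vectors."""
    p = np.ascontiguousarray(p, dtype=float)
    q = np.ascontiguousarray(q, dtype=float)
    w = np.ascontiguousarray(w, dtype=float)
    if p.shape != q.shape or p.shape != w.shape:
        raise ValueError("p, q and w must have identical length")
    d = float(np.where(p != q, w, 0.0).sum())
    return 1.0 - d


def similarity_matrix(
    queries: np.ndarray, labeled: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """(n_queries, n_labeled) similarity matrix.

    Computed in query chunks to bound memory; the reduction runs over the
    contiguous attribute axis so each entry equals the scalar
    :func:`similarity` bit-for-bit.
    """
    Q = np.ascontiguousarray(queries, dtype=float)
    L = np.ascontiguousarray(labeled, dtype=float)
    w = np.ascontiguousarray(w, dtype=float)
    nq, m = Q.shape
    nl = L.shape[0]
    if L.shape[1] != m or w.shape != (m,):
        raise ValueError("attribute dimensions do not match")
    out = np.empty((nq, nl))
    chunk = max(1, int(2e7 // max(1, nl * m)))
    for start in range(0, nq, chunk):
        stop = min(start + chunk, nq)
        xor = Q[start:stop, None, :] != L[None, :, :]
        out[start:stop] = 1.0 - np.where(xor, w, 0.0).sum(axis=2)
    return out


def _neighbor_order(sims: np.ndarray) -> np.ndarray:
    """Indices by similarity descending, ties by ascending case index."""
    return np.argsort(-sims, kind="stable")


def select_neighbors(
    query: np.ndarray, labeled: CaseBase, w: np.ndarray, k: int
) -> np.ndarray:
    """Indices (into ``labeled``) of the K most similar cases to ``query``."""
    if not labeled.is_complete:
        raise ValueError("labeled case base must be complete")
    if not 1 <= k <= labeled.n_cases:
        raise ValueError("k must satisfy 1 <= k <= n_labeled")
    sims = similarity_matrix(np.atleast_2d(query), labeled.values, w)[0]
    return _neighbor_order(sims)[:k]


# ---------------------------------------------------------------------------
# Fusion


def fuse(labels: np.ndarray, raw_weights: np.ndarray | None = None) -> float:
    """Convex fusion of neighbor labels.

    ``raw_weights`` are renormalized to sum to one over the neighbor set;
    ``None`` means uniform 1/K.  Returns sum(weight * label) in [0, 1].
    """
    labels = np.ascontiguousarray(labels, dtype=float)
    if labels.size == 0:
        raise ValueError("need at least one neighbor")
    if raw_weights is None:
        raw_weights = np.ones(labels.size)
    raw = np.ascontiguousarray(raw_weights, dtype=float)
    if raw.shape != labels.shape:
        raise ValueError("one weight per neighbor required")
    total = raw.sum()
    if total <= 0.0:  # unreachable for phi(|r|) weights; guarded anyway
        raw = np.ones(labels.size)
        total = raw.sum()
    fw = raw / total
    # clamp: sum(fw) can overshoot 1 by one ulp when all labels are 1
    return min(1.0, max(0.0, float(np.sum(fw * labels))))


def _fusion_weights(raw: np.ndarray) -> np.ndarray:
    total = raw.sum()
    if total <= 0.0:
        raw = np.ones(raw.size)
        total = raw.sum()
    return raw / total


# ---------------------------------------------------------------------------
# K tuning and prediction


def _case_weight_vector(
    labeled: CaseBase, weights: WeightSet | None, use_case_weights: bool
) -> np.ndarray | None:
    if not use_case_weights:
        return None
    if weights is None:
        raise ValueError("this variant requires a WeightSet with case weights")
    try:
        return np.array(
            [weights.case_weights_raw[c] for c in labeled.case_ids], dtype=float
        )
    except KeyError as e:
        raise ValueError(f"missing case weight for labeled case {e}") from e


def _attribute_weight_vector(
    labeled: CaseBase,
    weights: WeightSet | None,
    use_wald: bool,
    active_attributes: Sequence[str] | None,
) -> np.ndarray:
    if use_wald:
        if weights is None:
            raise ValueError("this variant requires a WeightSet")
        return weights.attribute_vector(labeled.attribute_names)
    active = (
        tuple(active_attributes)
        if active_attributes is not None
        else labeled.attribute_names
    )
    u = uniform_weights(active)
    return np.array([u.get(a, 0.0) for a in labeled.attribute_names], dtype=float)


def tune_k(
    labeled_train: CaseBase,
    setting: CaseBase,
    w: np.ndarray,
    case_weights_vec: np.ndarray | None,
    k_max: int = 51,
) -> tuple[int, np.ndarray]:
    """Smallest K in 1..k_max maximizing AUC of soft K-NN on the setting set.

    Returns ``(k, auc_per_k)`` with ``auc_per_k[i]`` the setting-set AUC at
    K = i + 1.  Each K's scores are exactly the scores :func:`predict` would
    produce at that K.
    """
    from .evaluation import auc  # local import to avoid a cycle

    if not setting.is_labeled:
        raise ValueError("setting set must be labeled")
    if len(np.unique(setting.labels)) < 2:
        raise ValueError("setting set has a single outcome class; AUC undefined")
    k_max = min(k_max, labeled_train.n_cases)
    sims = similarity_matrix(setting.values, labeled_train.values, w)
    train_labels = labeled_train.labels.astype(float)
    n_set = setting.n_cases
    scores = np.empty((k_max, n_set))
    for i in range(n_set):
        order = _neighbor_order(sims[i])
        lbl_sorted = train_labels[order]
        raw_sorted = (
            np.ones(labeled_train.n_cases)
            if case_weights_vec is None
            else case_weights_vec[order]
        )
        for k in range(1, k_max + 1):
            scores[k - 1, i] = fuse(lbl_sorted[:k], raw_sorted[:k])
    aucs = np.array([auc(scores[k - 1], setting.labels) for k in range(1, k_max + 1)])
    best_k = int(np.argmax(aucs)) + 1  # argmax returns the first (smallest) max
    return best_k, aucs


def predict(
    config: KnnConfig,
    model: FittedLogisticModel | None,
    weights: WeightSet | None,
    labeled: CaseBase | None,
    queries: CaseBase,
    active_attributes: Sequence[str] | None = None,
) -> list[PredictionResult]:
    """Score every query case with the configured algorithm variant.

    ``active_attributes`` restricts the uniform attribute weighting of the
    ``cbr`` / ``cbr_wp`` variants (used for the selected-attributes
    sub-scenario); Wald-weighted variants carry that restriction inside the
    WeightSet (excluded attributes have weight 0).
    """
    if not queries.is_complete:
        raise ValueError("queries must be complete (no missing values)")

    if config.variant == "lr":
        if model is None:
            raise ValueError("lr variant requires a fitted logistic model")
        probs = predict_prob(model, queries)
        return [
            PredictionResult(case_id=c, score=float(p), k_used=0)
            for c, p in zip(queries.case_ids, probs)
        ]

    if labeled is None or not labeled.is_labeled or not labeled.is_complete:
        raise ValueError("CBR variants require a complete labeled case base")
    if labeled.attribute_names != queries.attribute_names:
        raise ValueError("queries and labeled base must share attributes")
    if not isinstance(config.k, int):
        raise ValueError(
            "k='auto' must be resolved (tune_k) before calling predict"
        )
    k = config.k
    if k > labeled.n_cases:
        raise ValueError("k exceeds the number of labeled cases")

    use_wald = config.variant in ("cbr_wa", "cbr_wa_wp")
    use_case_w = config.variant in ("cbr_wp", "cbr_wa_wp")
    w = _attribute_weight_vector(labeled, weights, use_wald, active_attributes)
    cw = _case_weight_vector(labeled, weights, use_case_w)

    sims = similarity_matrix(queries.values, labeled.values, w)
    train_labels = labeled.labels.astype(float)
    results = []
    for i, cid in enumerate(queries.case_ids):
        order = _neighbor_order(sims[i])[:k]
        raw = np.ones(k) if cw is None else cw[order]
        fw = _fusion_weights(raw)
        score = min(1.0, max(0.0, float(np.sum(fw * train_labels[order]))))
        results.append(
            PredictionResult(
                case_id=cid,
                score=score,
                k_used=k,
                neighbor_ids=tuple(labeled.case_ids[j] for j in order),
                neighbor_similarities=tuple(float(s) for s in sims[i][order]),
                fusion_weights=tuple(float(x) for x in fw),
            )
        )
    return results
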