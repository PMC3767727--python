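"""Independent brute-force reimplementation of the five algorithm variants.

Deliberately naive: explicit Python loops over queries and labeled cases,
full sorts via ``sorted`` with an explicit tie-breaking key, no vectorized
shortcuts and no imports from the package's K-NN machinery.  Used as the
oracle that the production implementation must match exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def naive_lr_scores(intercept, coefficients, included, queries_values, attr_names):
    """Logistic scores by explicit per-case accumulation."""
    col = {a: j for j, a in enumerate(attr_names)}
    out = []
    for row in queries_values:
        eta = intercept
        for a in included:
            eta = eta + coefficients[a] * row[col[a]]
        p = float(expit(np.float64(eta)))
        out.append(min(max(p, 1e-12), 1.0 - 1e-12))
    return np.array(out)


def naive_knn_scores(
    queries_values,
    labeled_values,
    labeled_labels,
    labeled_ids,
    attr_weight_map,
    attr_names,
    k,
    case_weight_map=None,
):
    """Soft K-NN scores by exhaustive pairwise distances and full sorting."""
    w = np.array([attr_weight_map[a] for a in attr_names], dtype=float)
    n_labeled = len(labeled_values)
    labels = np.asarray(labeled_labels, dtype=float)
    scores = []
    for q in queries_values:
        sims = []
        for j in range(n_labeled):
            d = np.where(np.asarray(q) != np.asarray(labeled_values[j]), w, 0.0).sum()
            sims.append(1.0 - d)
        order = sorted(range(n_labeled), key=lambda j: (-sims[j], j))[:k]
        if case_weight_map is None:
            raw = np.ones(k)
        else:
            raw = np.array([case_weight_map[labeled_ids[j]] for j in order])
        fw = raw / raw.sum()
        scores.append(min(1.0, max(0.0, float(np.sum(fw * labels[order])))))
    return np.array(scores)


def naive_variant_scores(variant, model, weight_set, labeled, queries, k,
                         active_attributes=None):
    """Dispatch mirroring the production ``predict`` contract."""
    if variant == "lr":
        return naive_lr_scores(
            model.intercept,
            model.coefficients,
            model.included_attributes,
            queries.values,
            queries.attribute_names,
        )
    names = labeled.attribute_names
    if variant in ("cbr_wa", "cbr_wa_wp"):
        aw = weight_set.attribute_weights
    else:
        active = tuple(active_attributes) if active_attributes else names
        aw = {a: (1.0 / len(active) if a in active else 0.0) for a in names}
    cw = (
        weight_set.case_weights_raw
        if variant in ("cbr_wp", "cbr_wa_wp")
        else None
    )
    return naive_knn_scores(
        queries.values, labeled.values, labeled.labels, labeled.case_ids,
        aw, names, k, case_weight_map=cw,
    )
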