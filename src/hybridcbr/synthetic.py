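"""Seeded generator of labeled binary cohorts.

Emulates the structure of a renal-transplant waiting-list registry cohort:
roughly a thousand complete cases described by 19 binary attributes of
heterogeneous prevalence, a binary registration outcome of ~23% prevalence
driven by a logistic model with one dominant attribute (an age indicator),
and an optional block of pure-noise binary attributes that are independent
of the outcome.

Attribute values are mutually independent Bernoulli draws; the label is
Bernoulli(expit(intercept + sum(beta_a * x_a))).  The intercept can be given
directly or calibrated so the marginal outcome prevalence hits a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .casebase import CaseBase

__all__ = [
    "AttributeSpec",
    "SyntheticSpec",
    "rein_like_spec",
    "calibrate_intercept",
    "generate_case_base",
    "add_random_attributes",
]


@dataclass(frozen=True)
class AttributeSpec:
    """One informative attribute: name, marginal prevalence, true log-odds
    coefficient in the label model."""

    name: str
    prevalence: float
    coefficient: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence of {self.name} must be in (0,1)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for a synthetic labeled cohort.

    Exactly one of ``intercept`` / ``target_prevalence`` must be supplied;
    with ``target_prevalence`` the intercept is solved by
    :func:`calibrate_intercept` at generation time.
    """

    n_cases: int
    informative_attributes: tuple[AttributeSpec, ...]
    intercept: float | None = None
    target_prevalence: float | None = None
    n_noise_attributes: int = 0
    noise_prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "informative_attributes", tuple(self.informative_attributes)
        )
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if (self.intercept is None) == (self.target_prevalence is None):
            raise ValueError(
                "exactly one of intercept / target_prevalence must be given"
            )
        if self.target_prevalence is not None and not (
            0.0 < self.target_prevalence < 1.0
        ):
            raise ValueError("target_prevalence must be in (0,1)")
        if self.n_noise_attributes < 0:
            raise ValueError("n_noise_attributes must be >= 0")
        if not 0.0 < self.noise_prevalence < 1.0:
            raise ValueError("noise_prevalence must be in (0,1)")
        names = [a.name for a in self.informative_attributes]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")


# Default informative block: one dominant factor (an age indicator), a
# handful of moderate clinical/care factors, and the rest null — mimicking a
# Wald-weight profile with a single dominant attribute.  Coefficients are
# configuration, not constants of the method.
_REIN_ATTRIBUTES: tuple[AttributeSpec, ...] = (
    AttributeSpec("age_lt_60", 0.45, 2.00),
    AttributeSpec("hypertension", 0.45, -0.55),
    AttributeSpec("ischemic_heart_disease", 0.25, -0.60),
    AttributeSpec("malignancy_history", 0.20, -0.60),
    AttributeSpec("private_facility", 0.50, 0.50),
    AttributeSpec("transplant_center_followup", 0.40, 0.45),
    AttributeSpec("employed", 0.35, 0.45),
    AttributeSpec("disability", 0.15, -0.50),
    AttributeSpec("sex_male", 0.61, 0.0),
    AttributeSpec("diabetes", 0.35, 0.0),
    AttributeSpec("chronic_respiratory_failure", 0.12, 0.0),
    AttributeSpec("chronic_heart_failure", 0.18, 0.0),
    AttributeSpec("conduction_disorder", 0.15, 0.0),
    AttributeSpec("positive_serology", 0.05, 0.0),
    AttributeSpec("liver_cirrhosis", 0.04, 0.0),
    AttributeSpec("hemoglobin_ge_11", 0.55, 0.0),
    AttributeSpec("hemodialysis_first", 0.80, 0.0),
    AttributeSpec("urgent_first_dialysis", 0.30, 0.0),
    AttributeSpec("urgent_first_catheterization", 0.25, 0.0),
)


def rein_like_spec(
    n_cases: int = 1137,
    n_noise_attributes: int = 0,
    noise_prevalence: float = 0.5,
    seed: int = 0,
    target_prevalence: float = 0.23,
) -> SyntheticSpec:
    """Preset emulating the registry cohort: n=1137 complete cases, 19 binary
    attributes, ~23% outcome prevalence, one dominant predictor."""
    return SyntheticSpec(
        n_cases=n_cases,
        informative_attributes=_REIN_ATTRIBUTES,
        target_prevalence=target_prevalence,
        n_noise_attributes=n_noise_attributes,
        noise_prevalence=noise_prevalence,
        seed=seed,
    )


def _linear_predictor_distribution(
    attrs: tuple[AttributeSpec, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of sum(beta_a X_a) over independent Bernoullis.

    Only attributes with nonzero coefficients matter; the support is built by
    successive convolution, merging numerically identical atoms.
    """
    values = np.array([0.0])
    probs = np.array([1.0])
    for a in attrs:
        if a.coefficient == 0.0:
            continue
        v = np.concatenate([values, values + a.coefficient])
        p = np.concatenate([probs * (1 - a.prevalence), probs * a.prevalence])
        # merge identical support points to keep the support compact
        key = np.round(v, 12)
        uniq, inverse = np.unique(key, return_inverse=True)
        values = uniq
        probs = np.bincount(inverse, weights=p)
    return values, probs


def calibrate_intercept(
    spec: SyntheticSpec, tol: float = 1e-3, mc_draws: int = 200_000
) -> float:
    """Intercept c with E[expit(c + sum(beta_a X_a))] = target_prevalence.

    Uses the exact linear-predictor distribution when at most 20 attributes
    carry a nonzero coefficient (the support is then small), otherwise a
    Monte-Carlo approximation of that distribution with ``mc_draws`` draws.
    """
    if spec.target_prevalence is None:
        raise ValueError("spec must carry a target_prevalence")
    target = spec.target_prevalence
    nonzero = [a for a in spec.informative_attributes if a.coefficient != 0.0]
    if len(nonzero) <= 20:
        values, probs = _linear_predictor_distribution(spec.informative_attributes)
    else:
        rng = np.random.default_rng(spec.seed)
        draws = np.zeros(mc_draws)
        for a in nonzero:
            draws += a.coefficient * (rng.random(mc_draws) < a.prevalence)
        values, probs = draws, np.full(mc_draws, 1.0 / mc_draws)

    def prevalence_gap(c: float) -> float:
        return float(np.dot(probs, expit(c + values)) - target)

    lo, hi = -40.0, 40.0
    if prevalence_gap(lo) > 0 or prevalence_gap(hi) < 0:
        raise ValueError("target prevalence unreachable")
    c = brentq(prevalence_gap, lo, hi, xtol=1e-10)
    if abs(prevalence_gap(c)) > tol:
        raise ValueError("intercept calibration did not reach tolerance")
    return float(c)


def generate_case_base(spec: SyntheticSpec) -> CaseBase:
    """Draw a complete, labeled case base from the spec (deterministic in
    the seed).  Noise attributes, when requested, are appended after the
    informative block and are independent of the label."""
    intercept = (
        spec.intercept
        if spec.intercept is not None
        else calibrate_intercept(spec)
    )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases
    attrs = spec.informative_attributes
    X = np.empty((n, len(attrs)))
    for j, a in enumerate(attrs):
        X[:, j] = (rng.random(n) < a.prevalence).astype(float)
    beta = np.array([a.coefficient for a in attrs])
    p = expit(intercept + X @ beta)
    labels = (rng.random(n) < p).astype(np.int64)

    cb = CaseBase(
        case_ids=tuple(str(i) for i in range(n)),
        attribute_names=tuple(a.name for a in attrs),
        values=X,
        labels=labels,
        metadata={
            "generator": "hybridcbr.synthetic",
            "intercept": float(intercept),
            "seed": spec.seed,
            "true_coefficients": {a.name: a.coefficient for a in attrs},
        },
    )
    if spec.n_noise_attributes:
        cb = add_random_attributes(
            cb,
            spec.n_noise_attributes,
            prevalence=spec.noise_prevalence,
            seed=spec.seed + 1,
        )
    return cb


def add_random_attributes(
    cb: CaseBase, m: int, prevalence: float = 0.5, seed: int = 0
) -> CaseBase:
    """Append ``m`` pure-noise Bernoulli(prevalence) attributes, named
    ``noise_001`` ... ``noise_m``, independent of labels and existing
    attributes.  Original columns are untouched."""
    if not cb.is_complete:
        raise ValueError("case base must be complete")
    if m == 0:
        return cb
    if m < 0:
        raise ValueError("m must be >= 0")
    width = max(3, len(str(m)))
    names = tuple(f"noise_{i + 1:0{width}d}" for i in range(m))
    clash = set(names) & set(cb.attribute_names)
    if clash:
        raise ValueError(f"attribute name collision: {sorted(clash)}")
    rng = np.random.default_rng(seed)
    noise = (rng.random((cb.n_cases, m)) < prevalence).astype(float)
    meta = dict(cb.metadata)
    meta["n_noise_attributes"] = m
    return CaseBase(
        case_ids=cb.case_ids,
        attribute_names=cb.attribute_names + names,
        values=np.hstack([cb.values, noise]),
        labels=cb.labels,
        metadata=meta,
    )
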