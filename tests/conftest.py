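import numpy as np
import pytest

from hybridcbr import CaseBase, generate_case_base, rein_like_spec


@pytest.fixture(scope="session")
def rein_cohort():
    """One REIN-like synthetic cohort (n=1137, 19 attributes, ~23% labels)."""
    return generate_case_base(rein_like_spec(seed=42))


@pytest.fixture
def tiny_labeled():
    """Six labeled cases over three attributes, no missing values."""
    values = np.array(
        [
            [0, 0, 0],
            [1, 0, 0],
            [0, 1, 0],
            [1, 1, 0],
            [0, 1, 1],
            [1, 1, 1],
        ],
        dtype=float,
    )
    return CaseBase(
        case_ids=tuple(f"c{i}" for i in range(6)),
        attribute_names=("a", "b", "c"),
        values=values,
        labels=np.array([0, 0, 0, 1, 1, 1]),
    )


def random_case_base(rng, n, m, labeled=True, prefix="r"):
    """Random complete binary case base with both classes present."""
    values = (rng.random((n, m)) < rng.uniform(0.2, 0.8, size=m)).astype(float)
    labels = None
    if labeled:
        labels = (rng.random(n) < 0.4).astype(np.int64)
        labels[0], labels[1] = 0, 1  # guarantee both classes
    return CaseBase(
        case_ids=tuple(f"{prefix}{i}" for i in range(n)),
        attribute_names=tuple(f"x{j}" for j in range(m)),
        values=values,
        labels=labels,
    )
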