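"""Case-base data model and plumbing.

A *case base* is a rectangular table of cases (patients) by binary
attributes, optionally carrying a binary outcome label per case.  Missing
values are allowed on input but every downstream analysis is complete-case:
callers filter with :func:`filter_complete_cases` before modelling.

Values are stored as a float matrix with ``numpy.nan`` marking missing
entries; non-missing entries are exactly 0.0 or 1.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CaseBase",
    "SplitSpec",
    "CaseBaseFormatError",
    "read_case_base",
    "write_case_base",
    "filter_complete_cases",
    "split_case_base",
    "homogeneity_check",
]

DEFAULT_MISSING_TOKENS = ("", "NA")


class CaseBaseFormatError(ValueError):
    """Raised when an input table violates the binary case-base format."""


@dataclass(frozen=True)
class CaseBase:
    """Cases x binary-attributes matrix with optional binary labels.

    Parameters
    ----------
    case_ids
        Unique case identifiers (strings).
    attribute_names
        Ordered, unique attribute names.
    values
        ``(n_cases, n_attributes)`` float array with entries in {0.0, 1.0,
        nan}; nan marks a missing value.
    labels
        Optional length ``n_cases`` integer array in {0, 1}.  Present for
        labeled (solved) sets, absent for query sets.
    """

    case_ids: tuple[str, ...]
    attribute_names: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray | None = None
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "case_ids", tuple(str(c) for c in self.case_ids))
        object.__setattr__(self, "attribute_names", tuple(self.attribute_names))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = values.shape
        if len(self.case_ids) != n:
            raise ValueError(f"{len(self.case_ids)} case ids for {n} rows")
        if len(self.attribute_names) != m:
            raise ValueError(f"{len(self.attribute_names)} names for {m} columns")
        if len(set(self.case_ids)) != n:
            raise ValueError("case_ids must be unique")
        if len(set(self.attribute_names)) != m:
            raise ValueError("attribute_names must be unique")
        observed = values[~np.isnan(values)]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            raise ValueError("non-missing values must be exactly 0 or 1")
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != (n,):
                raise ValueError("labels must have one entry per case")
            if not np.isin(labels, (0, 1)).all():
                raise ValueError("labels must be binary 0/1")
            object.__setattr__(self, "labels", labels.astype(np.int64))

    # -- basic introspection ------------------------------------------------

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    @property
    def is_complete(self) -> bool:
        """True when no value is missing."""
        return not np.isnan(self.values).any()

    def __len__(self) -> int:
        return self.n_cases

    # -- derived views ------------------------------------------------------

    def take(self, indices: Sequence[int]) -> "CaseBase":
        """Row subset (order follows ``indices``)."""
        idx = np.asarray(indices, dtype=int)
        return CaseBase(
            case_ids=tuple(self.case_ids[i] for i in idx),
            attribute_names=self.attribute_names,
            values=self.values[idx],
            labels=None if self.labels is None else self.labels[idx],
            metadata=dict(self.metadata),
        )

    def without_labels(self) -> "CaseBase":
        return replace(self, labels=None)

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        """Render as a DataFrame (missing -> NaN), label column last."""
        df = pd.DataFrame(self.values, columns=list(self.attribute_names))
        df.insert(0, "case_id", list(self.case_ids))
        if self.labels is not None:
            df[label_column] = self.labels
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str | None = "label",
        id_column: str | None = "case_id",
        metadata: dict | None = None,
    ) -> "CaseBase":
        """Build a CaseBase from a DataFrame of 0/1 (or NaN) cells."""
        df = df.copy()
        if id_column is not None and id_column in df.columns:
            ids = df.pop(id_column).astype(str).tolist()
        else:
            ids = [str(i) for i in range(len(df))]
        labels = None
        if label_column is not None and label_column in df.columns:
            labels = df.pop(label_column).to_numpy()
        return cls(
            case_ids=tuple(ids),
            attribute_names=tuple(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            labels=labels,
            metadata=metadata or {},
        )


@dataclass(frozen=True)
class SplitSpec:
    """Three-way split fractions (train, setting, evaluation) plus seed."""

    fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        if len(fr) != 3:
            raise ValueError("exactly three fractions required")
        if any(f <= 0 for f in fr):
            raise ValueError("every fraction must be > 0")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fr)}")


# ---------------------------------------------------------------------------
# IO


def _detect_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_case_base(
    path: str | Path,
    label_column: str | None = "label",
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    id_column: str | None = "case_id",
    delimiter: str | None = None,
) -> CaseBase:
    """Read a delimited text file (header row) into a :class:`CaseBase`.

    Every data cell must be ``0``, ``1`` or one of ``missing_tokens``.
    The delimiter is inferred from the extension (``.tsv`` -> tab,
    otherwise comma) unless given explicitly.
    """
    path = Path(path)
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if id_column is not None and id_column in df.columns:
        ids = df.pop(id_column).astype(str).tolist()
        if len(set(ids)) != len(ids):
            raise CaseBaseFormatError(f"duplicate case ids in {path}")
    else:
        ids = [str(i) for i in range(len(df))]

    labels = None
    if label_column is not None and label_column in df.columns:
        raw = df.pop(label_column)
        bad = ~raw.isin(("0", "1"))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CaseBaseFormatError(
                f"missing or non-binary label at row {row} of {path}"
            )
        labels = raw.astype(int).to_numpy()

    values = np.empty(df.shape, dtype=float)
    tokens = set(missing_tokens)
    for j, col in enumerate(df.columns):
        cells = df[col].str.strip()
        is_missing = cells.isin(tokens)
        ok = is_missing | cells.isin(("0", "1"))
        if not ok.all():
            row = int(np.flatnonzero(~ok.to_numpy())[0])
            raise CaseBaseFormatError(
                f"non-binary cell {cells.iloc[row]!r} at row {row}, "
                f"column {col!r} of {path}"
            )
        col_vals = np.where(is_missing.to_numpy(), np.nan, 0.0)
        col_vals[(cells == "1").to_numpy()] = 1.0
        values[:, j] = col_vals

    return CaseBase(
        case_ids=tuple(ids),
        attribute_names=tuple(df.columns.astype(str)),
        values=values,
        labels=labels,
        metadata={"source": str(path), "delimiter": sep},
    )


def write_case_base(
    cb: CaseBase,
    path: str | Path,
    label_column: str = "label",
    missing_token: str = "",
    delimiter: str | None = None,
) -> None:
    """Write a CaseBase as delimited text, mirroring :func:`read_case_base`."""
    path = Path(path)
    sep = delimiter or cb.metadata.get("delimiter") or _detect_delimiter(path)
    cells = np.full(cb.values.shape, missing_token, dtype=object)
    cells[cb.values == 0.0] = "0"
    cells[cb.values == 1.0] = "1"
    df = pd.DataFrame(cells, columns=list(cb.attribute_names))
    df.insert(0, "case_id", list(cb.case_ids))
    if cb.labels is not None:
        df[label_column] = cb.labels
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Complete-case filtering and splitting


def filter_complete_cases(cb: CaseBase) -> CaseBase:
    """Keep only cases with no missing attribute value (order preserved)."""
    keep = ~np.isnan(cb.values).any(axis=1)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("no complete cases remain after filtering")
    if n_removed:
        warnings.warn(
            f"filter_complete_cases: removed {n_removed} of {cb.n_cases} cases",
            stacklevel=2,
        )
    out = cb.take(np.flatnonzero(keep))
    out.metadata["n_removed_incomplete"] = n_removed
    return out


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer part sizes summing to n (largest-remainder apportionment)."""
    quotas = np.asarray(fractions, dtype=float) * n
    sizes = np.floor(quotas).astype(int)
    short = n - int(sizes.sum())
    # ties broken by lower index for determinism
    order = np.lexsort((np.arange(len(fractions)), -(quotas - sizes)))
    for i in order[:short]:
        sizes[i] += 1
    return sizes.tolist()


def split_case_base(
    cb: CaseBase, spec: SplitSpec, stratify: bool = False
) -> tuple[CaseBase, CaseBase, CaseBase]:
    """Random disjoint partition into (train, setting, evaluation).

    Sizes follow largest-remainder rounding of ``n * fractions`` so they
    always sum to ``n``.  Unstratified simple random sampling by default;
    ``stratify=True`` samples within each outcome class separately.
    """
    if not cb.is_labeled:
        raise ValueError("split_case_base requires a labeled case base")
    if not cb.is_complete:
        raise ValueError("split_case_base requires a complete case base")
    n = cb.n_cases
    if n < 3:
        raise ValueError("need at least 3 cases to form three parts")
    rng = np.random.default_rng(spec.seed)

    if stratify:
        perm_parts: list[list[int]] = [[], [], []]
        for cls in (0, 1):
            idx = np.flatnonzero(cb.labels == cls)
            perm = rng.permutation(idx)
            sizes = _largest_remainder_sizes(len(idx), spec.fractions)
            start = 0
            for part, size in enumerate(sizes):
                perm_parts[part].extend(perm[start : start + size].tolist())
                start += size
        parts_idx = [np.sort(np.asarray(p, dtype=int)) for p in perm_parts]
    else:
        perm = rng.permutation(n)
        sizes = _largest_remainder_sizes(n, spec.fractions)
        bounds = np.cumsum([0] + sizes)
        parts_idx = [
            np.sort(perm[bounds[i] : bounds[i + 1]]) for i in range(3)
        ]

    parts = tuple(cb.take(idx) for idx in parts_idx)
    for name, part in zip(("train", "setting", "evaluation"), parts):
        if part.n_cases < 2 or len(np.unique(part.labels)) < 2:
            warnings.warn(
                f"split_case_base: {name} part has <2 cases or a single "
                "outcome class; downstream fitting may fail",
                stacklevel=2,
            )
    return parts


# ---------------------------------------------------------------------------
# Split-homogeneity check


def homogeneity_check(
    parts: Sequence[CaseBase], include_label: bool = True
) -> pd.DataFrame:
    """Pearson chi-squared homogeneity test of each attribute across parts.

    For every attribute (and the outcome label when all parts carry one) the
    proportion of 1s is compared across the parts with a Pearson chi-squared
    test on the 2 x n_parts contingency table; df = n_parts - 1.

    Returns a DataFrame indexed by attribute name with columns ``statistic``,
    ``df``, ``pvalue`` and ``degenerate`` (True when the attribute is constant
    over all parts combined, in which case statistic 0 / p-value 1 is
    reported).
    """
    if len(parts) < 2:
        raise ValueError("need at least two parts")
    names = parts[0].attribute_names
    for p in parts[1:]:
        if p.attribute_names != names:
            raise ValueError("parts must share identical attribute_names")

    columns: list[tuple[str, list[np.ndarray]]] = [
        (a, [p.values[:, j] for p in parts]) for j, a in enumerate(names)
    ]
    if include_label and all(p.is_labeled for p in parts):
        columns.append(("label", [p.labels.astype(float) for p in parts]))

    rows = []
    df_h = len(parts) - 1
    for name, vecs in columns:
        ones = np.array([np.nansum(v) for v in vecs])
        totals = np.array([np.sum(~np.isnan(v)) for v in vecs])
        zeros = totals - ones
        table = np.vstack([ones, zeros])  # 2 x n_parts
        if table.sum(axis=1).min() == 0:  # constant attribute overall
            rows.append((name, 0.0, df_h, 1.0, True))
            continue
        stat, pval, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append((name, float(stat), df_h, float(pval), False))

    return pd.DataFrame(
        rows, columns=["attribute", "statistic", "df", "pvalue", "degenerate"]
    ).set_index("attribute")
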