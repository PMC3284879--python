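"""Count normalization, filtering, ratios and differential expression.

The normalization is quantile-quantile scaling to a reference dataset: for
each dataset, the miRNAs with raw counts > 5 in both that dataset and the
reference are selected, both selections are sorted, corresponding quantile
values are paired, and the dataset's scaling factor is the median of their
log2 differences.  The whole dataset is then rescaled by 2**(-factor) — a
single linear transformation per dataset, robust to the handful of extreme
counts that dominate small-RNA libraries.

Differential expression between two groups of datasets (e.g. tumour vs
normal tissue) uses a per-miRNA two-sided t-test (Welch by default) on
log2(normalized + 1), after requiring > 5 raw counts in a minimum number of
the analysed datasets; Benjamini-Hochberg adjusted p-values are reported
alongside the raw ones, and records sort by raw p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScalingFactors",
    "GroupDesign",
    "NormalizationError",
    "qq_normalize",
    "log2_ratio",
    "expression_filter",
    "de_test",
    "replicate_correlation",
]


class NormalizationError(ValueError):
    """A dataset shares too few qualifying miRNAs with the reference."""


@dataclass
class ScalingFactors:
    """Per-dataset log2-space offsets to the reference; the reference's own
    factor is 0 by construction."""

    factors: pd.Series
    reference: str

    def __getitem__(self, dataset: str) -> float:
        return float(self.factors[dataset])


@dataclass
class GroupDesign:
    """Dataset -> group label plus the explicit mask of analysed datasets.

    ``group_a`` is the ratio numerator (e.g. the tumour group), ``group_b``
    the denominator.  Datasets not in ``included`` are ignored by filtering
    and testing — exclusions are always explicit, never implicit.
    """

    groups: dict[str, str]
    group_a: str
    group_b: str
    included: list[str] | None = None

    def __post_init__(self) -> None:
        if self.included is None:
            self.included = list(self.groups)
        missing = [d for d in self.included if d not in self.groups]
        if missing:
            raise ValueError(f"included datasets without a group label: {missing}")
        for g in (self.group_a, self.group_b):
            if self.members(g) and len(self.members(g)) < 2:
                raise ValueError(f"group {g!r} needs >= 2 analysed datasets")

    def members(self, label: str) -> list[str]:
        return [d for d in self.included if self.groups[d] == label]

    @classmethod
    def from_csv(cls, handle, group_a: str, group_b: str) -> "GroupDesign":
        """CSV with header dataset,group[,included]; included defaults true."""
        close = isinstance(handle, str)
        fh = open(handle) if close else handle
        try:
            header = [h.strip().lower() for h in fh.readline().split(",")]
            groups: dict[str, str] = {}
            included: list[str] = []
            for line in fh:
                parts = [p.strip() for p in line.strip().split(",")]
                if not parts or not parts[0]:
                    continue
                groups[parts[0]] = parts[1]
                inc = True
                if len(header) > 2 and len(parts) > 2:
                    inc = parts[2].lower() in ("1", "true", "yes")
                if inc:
                    included.append(parts[0])
        finally:
            if close:
                fh.close()
        return cls(groups, group_a, group_b, included)


def _pair_quantiles(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pair two sorted samples by quantile rank; when sizes differ the larger
    sample is linearly interpolated at the smaller one's plotting positions."""
    a, b = np.sort(a), np.sort(b)
    if len(a) == len(b):
        return a, b
    small, large = (a, b) if len(a) < len(b) else (b, a)
    q = (np.arange(len(small)) + 0.5) / len(small)
    pos_large = (np.arange(len(large)) + 0.5) / len(large)
    interp = np.interp(q, pos_large, large)
    return (small, interp) if len(a) < len(b) else (interp, small)


def qq_normalize(
    matrix: pd.DataFrame, reference: str, min_count: float = 5
) -> tuple[pd.DataFrame, ScalingFactors]:
    """Quantile-quantile normalize every dataset (column) to the reference.

    For each dataset d, rows with count > ``min_count`` in BOTH d and the
    reference are selected; the two selections are sorted independently,
    corresponding quantile values are paired, and
    ``factor_d = median(log2 q_d - log2 q_ref)``.  Every value of d is then
    multiplied by ``2**(-factor_d)``.

    Returns the normalized matrix (floats) and the per-dataset factors.
    """
    if reference not in matrix.columns:
        raise NormalizationError(f"reference dataset {reference!r} not in matrix")
    ref = matrix[reference].to_numpy(dtype=float)
    factors = pd.Series(0.0, index=matrix.columns)
    for d in matrix.columns:
        col = matrix[d].to_numpy(dtype=float)
        mask = (col > min_count) & (ref > min_count)
        if mask.sum() < 2:
            raise NormalizationError(
                f"dataset {d!r} shares only {int(mask.sum())} rows with counts > "
                f"{min_count} with reference {reference!r}"
            )
        qd, qr = _pair_quantiles(np.log2(col[mask]), np.log2(ref[mask]))
        factors[d] = float(np.median(qd - qr))
    normalized = matrix.astype(float) * np.power(2.0, -factors.to_numpy())
    return normalized, ScalingFactors(factors=factors, reference=reference)


def log2_ratio(mean_a: float, mean_b: float, pseudocount: float = 1.0) -> float:
    """log2 of the ratio of two group means; zero means are replaced by the
    pseudocount so the ratio stays finite."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("group means must be nonnegative")
    a = mean_a if mean_a > 0 else pseudocount
    b = mean_b if mean_b > 0 else pseudocount
    return float(np.log2(a / b))


def expression_filter(
    matrix: pd.DataFrame,
    threshold: float,
    min_datasets: int,
    datasets: list[str] | None = None,
) -> list[str]:
    """Rows whose value strictly exceeds ``threshold`` in at least
    ``min_datasets`` of the selected columns."""
    sub = matrix if datasets is None else matrix[datasets]
    if min_datasets > sub.shape[1]:
        raise ValueError(
            f"min_datasets={min_datasets} exceeds the {sub.shape[1]} selected datasets"
        )
    keep = (sub > threshold).sum(axis=1) >= min_datasets
    return list(sub.index[keep])


def de_test(
    normalized: pd.DataFrame,
    design: GroupDesign,
    raw: pd.DataFrame | None = None,
    raw_threshold: float = 5,
    min_datasets: int = 20,
    alpha: float = 0.05,
    log: bool = True,
    pseudocount: float = 1.0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-miRNA two-group t-test with expression filtering.

    The filter requires > ``raw_threshold`` raw counts in >= ``min_datasets``
    of the analysed datasets (``raw`` defaults to the normalized matrix).
    The test is a two-sided t-test (Welch unless ``equal_var``) on
    log2(normalized + pseudocount) by default, or on linear normalized values
    with ``log=False``.  Zero variance in both groups with equal means gives
    t = 0, p = 1 by convention (flagged in the ``degenerate`` column).

    Returns a DataFrame sorted by raw p with columns name, mean_a, mean_b,
    log2_ratio, t, p_raw, p_bh, significant, degenerate.
    """
    a_cols = design.members(design.group_a)
    b_cols = design.members(design.group_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("both groups need >= 2 analysed datasets")

    filter_matrix = normalized if raw is None else raw
    keep = expression_filter(
        filter_matrix, raw_threshold, min_datasets, datasets=list(design.included)
    )
    sub = normalized.loc[keep]

    a = sub[a_cols].to_numpy(dtype=float)
    b = sub[b_cols].to_numpy(dtype=float)
    if log:
        ta, tb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    else:
        ta, tb = a, b
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a precision warning; they are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(ta, tb, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(p)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ratios = [log2_ratio(x, y, pseudocount) for x, y in zip(mean_a, mean_b)]
    p_bh = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    out = pd.DataFrame(
        {
            "name": sub.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_ratio": np.round(ratios, 2),
            "t": t,
            "p_raw": p,
            "p_bh": p_bh,
            "significant": p < alpha,
            "degenerate": degenerate,
        }
    )
    return out.sort_values("p_raw", kind="mergesort").reset_index(drop=True)


def replicate_correlation(
    col_a: pd.Series, col_b: pd.Series, min_count: float = 5
) -> float:
    """Pearson correlation between two datasets over miRNAs with counts >
    ``min_count`` in both — the technical-replicate concordance measure."""
    a = col_a.to_numpy(dtype=float)
    b = col_b.to_numpy(dtype=float)
    mask = (a > min_count) & (b > min_count)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} miRNAs exceed {min_count} counts in both "
            "datasets; need >= 3"
        )
    r, _ = sps.pearsonr(a[mask], b[mask])
    return float(r)
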