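"""Differential-expression filters and gene-list comparison.

Two filters reproduce the study designs this package targets: a one-way
ANOVA across dose groups at a fixed time point (dose-series design) and an
unpaired two-group t-test (control vs treated design). Both combine a raw
p-value cutoff with a max-pairwise fold-change threshold computed on
linear-scale group means. Gene lists from the two systems are then compared
with exact Venn partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, ExpressionError, StudyDesign

__all__ = [
    "GeneListResult",
    "one_way_anova",
    "max_pairwise_fold_change",
    "anova_dose_filter",
    "ttest_filter",
    "intersect_gene_lists",
    "venn_percentage",
    "concordance_correlation",
]


class DesignError(ValueError):
    """Raised when the sample design cannot support the requested contrast."""


@dataclass
class GeneListResult:
    """Per-gene test results plus the filter metadata that produced them.

    ``table`` columns: gene_id, p, q (Benjamini-Hochberg, informational only),
    max_fc (linear max-pairwise fold change), direction (up/down/none), passes.
    A gene passes iff p < alpha and max_fc >= fold; direction is ``none``
    exactly for non-passing genes.
    """

    table: pd.DataFrame
    test: str
    alpha: float
    fold: float
    contrast: str

    def __post_init__(self) -> None:
        t = self.table
        ok = (t["p"] < self.alpha) & (t["max_fc"] >= self.fold)
        if not (t["passes"] == ok).all():
            raise ValueError("passes flag inconsistent with alpha/fold thresholds")
        if ((t["direction"] == "none") != ~t["passes"]).any():
            raise ValueError("direction must be 'none' exactly for non-passing genes")

    @property
    def passing_genes(self) -> set[str]:
        return set(self.table.loc[self.table["passes"], "gene_id"])

    def directions(self) -> dict[str, str]:
        """gene_id -> up/down for passing genes."""
        t = self.table[self.table["passes"]]
        return dict(zip(t["gene_id"], t["direction"]))


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA.

    Returns ``(F, p)`` with the upper-tail p from the F distribution.
    Degenerate inputs with zero between- and within-group variance return
    ``(0.0, 1.0)`` (no evidence against the null) so constant genes flow
    through the filter rather than erroring.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DesignError("one_way_anova requires at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise DesignError("every ANOVA group needs at least 2 values")
    F, p = _anova_rows(
        [g[np.newaxis, :] for g in groups]
    )
    return float(F[0]), float(p[0])


def _anova_rows(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA over rows (genes); each group is genes x n_i."""
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    N = int(ns.sum())
    means = np.stack([g.mean(axis=1) for g in groups], axis=1)  # genes x k
    grand = sum(g.sum(axis=1) for g in groups) / N
    ss_between = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = sum(((g - mg[:, None]) ** 2).sum(axis=1) for g, mg in zip(groups, means.T))
    df_b, df_w = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(F, df_b, df_w)
    # degenerate conventions: no within-variance
    zero_w = ss_within <= 0
    zero_b = ss_between <= np.finfo(float).eps * np.maximum(ss_within, 1.0)
    F = np.where(zero_w & zero_b, 0.0, F)
    p = np.where(zero_w & zero_b, 1.0, p)
    F = np.where(zero_w & ~zero_b, np.inf, F)
    p = np.where(zero_w & ~zero_b, 0.0, p)
    return F, p


def max_pairwise_fold_change(group_means, scale: str = "linear") -> float:
    """Largest ratio of group means over any ordered pair (>= 1 by convention).

    ``scale='log2'`` inputs are exponentiated before taking the ratio.
    """
    means = np.asarray(group_means, dtype=float)
    if means.size < 2:
        raise DesignError("need at least 2 group means")
    if scale == "log2":
        means = np.exp2(means)
    elif scale != "linear":
        raise ValueError(f"scale must be linear or log2, got {scale!r}")
    if (means <= 0).any():
        raise ExpressionError("fold change undefined for non-positive linear means")
    return float(means.max() / means.min())


def _group_linear_means(vals: np.ndarray, idx_groups: list[np.ndarray]) -> np.ndarray:
    """Arithmetic group means on linear scale from log2 values; genes x k."""
    lin = np.exp2(vals)
    return np.stack([lin[:, idx].mean(axis=1) for idx in idx_groups], axis=1)


def _bh_q(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def anova_dose_filter(
    m: ExpressionMatrix,
    design: StudyDesign,
    time_h: float,
    alpha: float = 0.05,
    fold: float = 1.5,
) -> GeneListResult:
    """Dose-series filter: one-way ANOVA across dose groups at one time point.

    A gene passes when its ANOVA p < ``alpha`` and the max pairwise fold
    change between any two dose-group means (linear scale) is >= ``fold``.
    Direction is assigned from the top-dose mean relative to the control
    (dose 0) mean.
    """
    if m.scale != "log2":
        raise ExpressionError("anova_dose_filter expects a log2 matrix")
    rows = design.rows_for(m)
    rows = rows[rows["time_h"] == float(time_h)]
    if rows.empty:
        raise DesignError(f"no samples at time point {time_h}")
    doses = sorted(rows["dose"].unique())
    if len(doses) < 2:
        raise DesignError("dose-series ANOVA needs at least 2 dose groups")
    sample_pos = {s: i for i, s in enumerate(m.sample_ids)}
    idx_groups = []
    for d in doses:
        sids = rows.loc[rows["dose"] == d, "sample_id"]
        idx = np.array([sample_pos[s] for s in sids])
        if idx.size < 2:
            raise DesignError(f"dose group {d} has fewer than 2 samples")
        idx_groups.append(idx)
    vals = m.values.to_numpy(dtype=float)
    F, p = _anova_rows([vals[:, idx] for idx in idx_groups])
    means = _group_linear_means(vals, idx_groups)
    max_fc = means.max(axis=1) / means.min(axis=1)
    passes = (p < alpha) & (max_fc >= fold)
    up = means[:, -1] > means[:, 0]  # top dose vs control mean
    direction = np.where(passes, np.where(up, "up", "down"), "none")
    table = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "p": p,
            "q": _bh_q(p),
            "max_fc": max_fc,
            "direction": direction,
            "passes": passes,
        }
    )
    return GeneListResult(
        table,
        test="one_way_anova",
        alpha=alpha,
        fold=fold,
        contrast=f"dose series at {time_h} h ({len(doses)} doses); "
        "p strict <, fold inclusive >=",
    )


def ttest_filter(
    m: ExpressionMatrix,
    design: StudyDesign,
    alpha: float = 0.05,
    fold: float = 1.5,
    welch: bool = False,
) -> GeneListResult:
    """Two-group filter: unpaired (Student) t-test of control vs treated.

    Equal-variance by default; ``welch=True`` switches to the unequal-variance
    form. Direction is up when the treated mean exceeds the control mean.
    """
    if m.scale != "log2":
        raise ExpressionError("ttest_filter expects a log2 matrix")
    rows = design.rows_for(m)
    ctrl = rows.loc[rows["is_control"], "sample_id"]
    trt = rows.loc[~rows["is_control"], "sample_id"]
    if len(ctrl) < 2 or len(trt) < 2:
        raise DesignError("t-test needs >=2 control and >=2 treated samples")
    sample_pos = {s: i for i, s in enumerate(m.sample_ids)}
    ci = np.array([sample_pos[s] for s in ctrl])
    ti = np.array([sample_pos[s] for s in trt])
    vals = m.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(
            vals[:, ti], vals[:, ci], axis=1, equal_var=not welch
        )
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    means = _group_linear_means(vals, [ci, ti])
    max_fc = means.max(axis=1) / means.min(axis=1)
    passes = (p < alpha) & (max_fc >= fold)
    up = means[:, 1] > means[:, 0]
    direction = np.where(passes, np.where(up, "up", "down"), "none")
    table = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "p": p,
            "q": _bh_q(p),
            "max_fc": max_fc,
            "direction": direction,
            "passes": passes,
        }
    )
    return GeneListResult(
        table,
        test="welch_ttest" if welch else "student_ttest",
        alpha=alpha,
        fold=fold,
        contrast="treated vs control; p strict <, fold inclusive >=",
    )


@dataclass
class VennPartition:
    a_only: set[str]
    common: set[str]
    b_only: set[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.a_only), len(self.common), len(self.b_only)


def intersect_gene_lists(a, b) -> VennPartition:
    """Disjoint Venn partition of two gene sets."""
    a, b = set(a), set(b)
    return VennPartition(a_only=a - b, common=a & b, b_only=b - a)


def venn_percentage(common: int, reference: int) -> int:
    """Integer percentage of a reference list covered by the overlap.

    Rounds half away from zero, matching how overlap percentages are usually
    reported (e.g. 164 of 214 -> 77).
    """
    if reference <= 0:
        raise ValueError("reference count must be positive")
    if common > reference:
        raise ValueError("common count cannot exceed reference count")
    return int(np.floor(100.0 * common / reference + 0.5))


def concordance_correlation(x, y) -> float:
    """Pearson correlation between two log2-ratio vectors (e.g. array vs QPCR)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
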