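"""Condition averaging and two-way hierarchical clustering.

Samples are first expressed relative to their stratum's control mean,
replicates are averaged into one column per condition, and both axes are
clustered with centred Pearson dissimilarity (d = 1 - r) under average
linkage (UPGMA). The agglomeration is implemented directly so the merge
order is fully deterministic: ties are broken by the lexicographically
smallest pair of cluster labels, independent of input order or platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, ExpressionError, StudyDesign

__all__ = [
    "Dendrogram",
    "control_ratio_matrix",
    "average_replicates",
    "pearson_distance",
    "average_linkage_cluster",
    "two_way_cluster",
]


def control_ratio_matrix(m: ExpressionMatrix, design: StudyDesign) -> ExpressionMatrix:
    """Divide each value by the gene's mean over the matching stratum's controls.

    Strata are (system, time_h): each sample is normalized against the mean
    of the control samples measured in the same system at the same time.
    """
    rows = design.rows_for(m)
    vals = m.values.to_numpy(dtype=float)
    if m.scale == "log2":
        raise ExpressionError("control_ratio_matrix expects linear-scale values")
    out = np.empty_like(vals)
    sample_pos = {s: i for i, s in enumerate(m.sample_ids)}
    for (_sys, _t), grp in rows.groupby(["system", "time_h"], sort=False):
        ctrl_ids = grp.loc[grp["is_control"], "sample_id"]
        if ctrl_ids.empty:
            raise ExpressionError(
                f"stratum (system={_sys!r}, time={_t}) has no control samples"
            )
        ci = [sample_pos[s] for s in ctrl_ids]
        ctrl_mean = vals[:, ci].mean(axis=1)
        if (ctrl_mean <= 0).any():
            g = int(np.argmax(ctrl_mean <= 0))
            raise ExpressionError(
                f"non-positive control mean for gene {m.gene_ids[g]!r} "
                f"in stratum (system={_sys!r}, time={_t})"
            )
        gi = [sample_pos[s] for s in grp["sample_id"]]
        out[:, gi] = vals[:, gi] / ctrl_mean[:, None]
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        "ratio",
        m.flags,
    )


def condition_label(system, compound, dose, time_h) -> str:
    return f"{system}|{compound}|{dose:g}|{time_h:g}h"


def average_replicates(m: ExpressionMatrix, design: StudyDesign) -> ExpressionMatrix:
    """Average replicate samples into one column per (system, compound, dose, time)."""
    rows = design.rows_for(m)
    sample_pos = {s: i for i, s in enumerate(m.sample_ids)}
    vals = m.values.to_numpy(dtype=float)
    cols = {}
    for key, grp in rows.groupby(["system", "compound", "dose", "time_h"], sort=False):
        if grp.empty:
            raise ExpressionError(f"empty condition {key}")
        idx = [sample_pos[s] for s in grp["sample_id"]]
        cols[condition_label(*key)] = vals[:, idx].mean(axis=1)
    out = pd.DataFrame(cols, index=m.values.index)
    return ExpressionMatrix(out, m.scale)


def pearson_distance(a, b) -> float:
    """Centred Pearson dissimilarity d = 1 - r, in [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson distance undefined for zero-variance profile")
    r = np.corrcoef(a, b)[0, 1]
    return float(1.0 - r)


def pearson_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """All-pairs 1 - r over the columns of ``profiles``."""
    arr = profiles.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    if (sd == 0).any():
        j = int(np.argmax(sd == 0))
        raise ValueError(
            f"zero-variance profile {profiles.columns[j]!r}; Pearson undefined"
        )
    d = 1.0 - np.corrcoef(arr.T)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.columns, columns=profiles.columns)


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    ``merges`` is a list of (left, right, height, size) where left/right are
    either leaf labels or previous merge indices (as ``int``), in merge order.
    """

    labels: list[str]
    merges: list[tuple[object, object, float, int]]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h, _ in self.merges]

    def to_newick(self) -> str:
        """Newick string; branch lengths are parent height minus child height."""
        if not self.labels:
            raise ValueError("empty dendrogram")
        if len(self.labels) == 1:
            return f"'{self.labels[0]}':0;"

        def render(node):
            if isinstance(node, str):
                return f"'{node}'", 0.0
            left, right, h, _ = self.merges[node]
            ls, lh = render(left)
            rs, rh = render(right)
            return f"({ls}:{h - lh:.10g},{rs}:{h - rh:.10g})", h

        s, _ = render(len(self.merges) - 1)
        return s + ";"


def average_linkage_cluster(labels, dissimilarity) -> Dendrogram:
    """UPGMA agglomeration of a precomputed dissimilarity matrix.

    At each step the pair of clusters with the smallest mean pairwise
    dissimilarity is merged; the mean is over all original-leaf pairs
    spanning the two clusters. Equal dissimilarities are resolved by the
    lexicographically smallest (representative-label) pair.
    """
    labels = [str(l) for l in labels]
    d = np.asarray(dissimilarity, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("dissimilarity matrix shape does not match labels")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have zero diagonal")
    if len(set(labels)) != n:
        raise ValueError("duplicate labels")
    if n == 0:
        return Dendrogram([], [])

    # active clusters: id -> (node ref, size, representative label)
    clusters: dict[int, tuple[object, int, str]] = {
        i: (labels[i], 1, labels[i]) for i in range(n)
    }
    dist = {}
    ids = list(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    merges: list[tuple[object, object, float, int]] = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for i in clusters:
            for j in clusters:
                if i >= j:
                    continue
                dij = dist[(i, j)]
                ri, rj = clusters[i][2], clusters[j][2]
                tie = tuple(sorted((ri, rj)))
                if best is None or (dij, tie) < (best[0], best[1]):
                    best = (dij, tie, i, j)
        dij, _, i, j = best
        ni, si, ri = clusters[i]
        nj, sj, rj = clusters[j]
        merges.append((ni, nj, float(dij), si + sj))
        new = next_id
        next_id += 1
        del clusters[i], clusters[j]
        for k in clusters:
            a, b = (i, k) if i < k else (k, i)
            c, e = (j, k) if j < k else (k, j)
            dnew = (si * dist[(a, b)] + sj * dist[(c, e)]) / (si + sj)
            dist[(min(new, k), max(new, k))] = dnew
        clusters[new] = (len(merges) - 1, si + sj, min(ri, rj))
    return Dendrogram(labels, merges)


def two_way_cluster(
    m: ExpressionMatrix,
) -> tuple[Dendrogram, Dendrogram]:
    """Cluster conditions (columns) and genes (rows) independently.

    Returns ``(condition_tree, gene_tree)``. The two axes are clustered on
    the same matrix, so the condition tree does not depend on whether genes
    were clustered first.
    """
    cond_d = pearson_distance_matrix(m.values)
    cond_tree = average_linkage_cluster(list(cond_d.columns), cond_d.to_numpy())
    gene_d = pearson_distance_matrix(m.values.T)
    gene_tree = average_linkage_cluster(list(gene_d.columns), gene_d.to_numpy())
    return cond_tree, gene_tree
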