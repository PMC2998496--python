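"""Context Likelihood of Relatedness (CLR) network inference.

CLR scores every gene pair by how extreme its mutual information (MI) is
against the background MI distribution of each endpoint: for genes A and B,
``z_A`` and ``z_B`` standardize MI(A,B) within A's and B's MI values to all
other genes, and the composite score is sqrt(z_A^2 + z_B^2). MI itself is
estimated with B-spline soft binning: each sample receives fractional
membership across bins via B-spline basis functions, which lowers the
variance of the plug-in histogram estimator without increasing bin count.

Defaults follow common practice for expression compendia: 10 bins, spline
order 3, composite z cutoff 2.0, MI in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .expression import ExpressionMatrix

__all__ = [
    "CLRParameters",
    "MIMatrix",
    "CLRNetwork",
    "bspline_weights",
    "mutual_information",
    "mi_matrix",
    "clr_scores",
    "threshold_network",
    "infer_network",
    "collapse_probes",
    "write_edge_list",
    "read_edge_list",
    "write_sif",
    "write_graphml",
]


class DegenerateProfile(ValueError):
    """Raised when a constant profile admits no binning."""


@dataclass(frozen=True)
class CLRParameters:
    """Estimator and thresholding settings.

    ``spline_order`` is the B-spline order (order 1 = hard equal-width
    binning; order 3, the default, is the quadratic spline commonly used for
    this estimator). ``z_clamp`` clips negative background z-scores to zero
    before squaring so that pairs with mutually *low* MI cannot score high.
    """

    n_bins: int = 10
    spline_order: int = 3
    z_cutoff: float = 2.0
    log_base: float = 2.0
    z_clamp: bool = True

    def __post_init__(self) -> None:
        if not (self.n_bins >= self.spline_order >= 1):
            raise ValueError("need n_bins >= spline_order >= 1")
        if self.z_cutoff < 0:
            raise ValueError("z_cutoff must be >= 0")
        if self.log_base not in (2.0, np.e):
            raise ValueError("log_base must be 2 or e")


@dataclass
class MIMatrix:
    """Symmetric pairwise MI with self-MI on the diagonal."""

    gene_ids: list[str]
    values: np.ndarray
    params: CLRParameters

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("MI matrix shape does not match gene ids")


@dataclass
class CLRNetwork:
    """Undirected thresholded network with per-edge CLR provenance.

    ``edges`` columns: gene_a, gene_b (lexicographically ordered within each
    row), clr_score, z_a, z_b, mi.
    """

    gene_ids: list[str]
    edges: pd.DataFrame
    params: CLRParameters
    metadata: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        """Genes incident to at least one retained edge."""
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in zip(self.edges["gene_a"], self.edges["gene_b"])}


def _knots(n_bins: int, order: int) -> np.ndarray:
    """Uniform knot vector with order-fold repeated boundary knots."""
    k = order - 1  # polynomial degree
    interior_top = n_bins - k
    return np.concatenate(
        [np.zeros(k), np.arange(interior_top + 1, dtype=float), np.full(k, interior_top)]
    )


def bspline_weights(x, n_bins: int, spline_order: int) -> np.ndarray:
    """Per-sample fractional bin memberships (samples x n_bins).

    Values are linearly rescaled from [min, max] onto the spline domain;
    each row of the result is non-negative and sums to one (partition of
    unity). A constant vector has no usable range and raises
    :class:`DegenerateProfile`; callers treat its MI as zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(x).all():
        raise ValueError("non-finite value in profile")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateProfile("constant profile cannot be binned")
    k = spline_order - 1
    domain_top = n_bins - k
    z = (x - lo) / (hi - lo) * domain_top
    t = _knots(n_bins, spline_order)
    return BSpline.design_matrix(z, t, k).toarray()


def _entropy(p: np.ndarray, log_base: float) -> float:
    p = p[p > 0]
    if log_base == 2.0:
        return float(-(p * np.log2(p)).sum())
    return float(-(p * np.log(p)).sum())


def mutual_information(x, y, p: CLRParameters = CLRParameters()) -> float:
    """B-spline plug-in MI between two equal-length profiles.

    The joint bin distribution is the sample average of outer products of the
    two weight rows; marginals are its row/column sums (equivalently the mean
    weight vectors). Constant profiles yield MI = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("profiles must have equal length")
    try:
        wx = bspline_weights(x, p.n_bins, p.spline_order)
        wy = bspline_weights(y, p.n_bins, p.spline_order)
    except DegenerateProfile:
        return 0.0
    joint = wx.T @ wy / x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = _entropy(px, p.log_base) + _entropy(py, p.log_base) - _entropy(
        joint.ravel(), p.log_base
    )
    return max(float(mi), 0.0)


def mi_matrix(
    m: ExpressionMatrix, p: CLRParameters = CLRParameters(), chunk: int = 64
) -> MIMatrix:
    """All-pairs MI over the genes (rows) of an expression matrix.

    Pairs are computed once and mirrored; the diagonal holds self-MI
    (the binned entropy of the profile). Computation is blocked so the
    joint-distribution workspace stays modest for compendium-scale inputs.
    """
    genes = m.gene_ids
    G = len(genes)
    if G < 3:
        raise ValueError("mi_matrix needs at least 3 genes")
    vals = m.values.to_numpy(dtype=float)
    n = vals.shape[1]
    b = p.n_bins
    W = np.zeros((G, n, b))
    degenerate = np.zeros(G, dtype=bool)
    for g in range(G):
        try:
            W[g] = bspline_weights(vals[g], b, p.spline_order)
        except DegenerateProfile:
            degenerate[g] = True
    marg = W.mean(axis=1)  # G x b
    log = np.log2 if p.log_base == 2.0 else np.log
    with np.errstate(divide="ignore", invalid="ignore"):
        H1 = -np.nansum(np.where(marg > 0, marg * log(marg), 0.0), axis=1)
    out = np.zeros((G, G))
    for i0 in range(0, G, chunk):
        i1 = min(i0 + chunk, G)
        # joint[(i-i0), j, a, c] averaged over samples
        J = np.einsum("ina,jnc->ijac", W[i0:i1], W, optimize=True) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            Hj = -np.where(J > 0, J * log(J), 0.0).sum(axis=(2, 3))
        out[i0:i1] = H1[i0:i1, None] + H1[None, :] - Hj
    out = np.maximum(out, 0.0)
    out[degenerate, :] = 0.0
    out[:, degenerate] = 0.0
    out = (out + out.T) / 2.0  # symmetrize away float noise
    return MIMatrix(genes, out, p)


@dataclass
class CLRScores:
    """All-pairs composite CLR scores with endpoint z-scores."""

    gene_ids: list[str]
    scores: np.ndarray  # symmetric composite
    z: np.ndarray  # z[i, j] = clamped z of MI(i,j) within i's background
    mi: np.ndarray
    params: CLRParameters


def clr_scores(mi: MIMatrix) -> CLRScores:
    """Background-standardize the MI matrix and combine endpoint z-scores.

    For each gene the background is its MI to every *other* gene (diagonal
    excluded); mean and population-sd standardize each pair, negatives are
    clamped at zero (when ``z_clamp``), and the composite is the Euclidean
    combination of the two endpoint z-scores. A gene whose background has
    zero spread contributes z = 0.
    """
    G = len(mi.gene_ids)
    if G < 3:
        raise ValueError("CLR background undefined for fewer than 3 genes")
    vals = mi.values.copy()
    off = vals[~np.eye(G, dtype=bool)].reshape(G, G - 1)
    mean = off.mean(axis=1)
    sd = off.std(axis=1)  # population denominator
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals - mean[:, None]) / sd[:, None]
    z[sd == 0, :] = 0.0
    if mi.params.z_clamp:
        z = np.maximum(z, 0.0)
    scores = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(scores, 0.0)
    return CLRScores(mi.gene_ids, scores, z, mi.values, mi.params)


def threshold_network(s: CLRScores, p: CLRParameters | None = None) -> CLRNetwork:
    """Retain undirected edges whose composite score >= the cutoff (inclusive)."""
    p = p or s.params
    G = len(s.gene_ids)
    iu, ju = np.triu_indices(G, k=1)
    keep = s.scores[iu, ju] >= p.z_cutoff
    ii, jj = iu[keep], ju[keep]
    ids = np.asarray(s.gene_ids, dtype=object)
    a, b = ids[ii], ids[jj]
    swap = a > b
    a[swap], b[swap] = b[swap], a[swap]
    za = np.where(swap, s.z[jj, ii], s.z[ii, jj])
    zb = np.where(swap, s.z[ii, jj], s.z[jj, ii])
    edges = pd.DataFrame(
        {
            "gene_a": a,
            "gene_b": b,
            "clr_score": s.scores[ii, jj],
            "z_a": za,
            "z_b": zb,
            "mi": s.mi[ii, jj],
        }
    ).sort_values("clr_score", ascending=False, kind="mergesort", ignore_index=True)
    meta = {
        "n_bins": p.n_bins,
        "spline_order": p.spline_order,
        "z_cutoff": p.z_cutoff,
        "log_base": "2" if p.log_base == 2.0 else "e",
        "z_clamp": p.z_clamp,
    }
    return CLRNetwork(list(s.gene_ids), edges, p, meta)


def infer_network(
    m: ExpressionMatrix, p: CLRParameters = CLRParameters()
) -> CLRNetwork:
    """MI -> background z -> threshold, in one call."""
    return threshold_network(clr_scores(mi_matrix(m, p)), p)


def collapse_probes(m: ExpressionMatrix, probe_to_gene: dict) -> ExpressionMatrix:
    """Collapse probes mapping to one gene symbol, keeping the max-variance probe.

    Probes without a mapping are dropped. Row labels become gene symbols.
    """
    var = m.values.var(axis=1)
    best: dict[str, str] = {}
    for probe in m.gene_ids:
        sym = probe_to_gene.get(probe)
        if sym is None:
            continue
        if sym not in best or var[probe] > var[best[sym]]:
            best[sym] = probe
    probes = list(best.values())
    sub = m.values.loc[probes]
    sub.index = list(best.keys())
    return ExpressionMatrix(sub, m.scale)


# ---------------------------------------------------------------------------
# Edge-list / Cytoscape export


def write_edge_list(net: CLRNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_edge_list(path, params: CLRParameters = CLRParameters()) -> CLRNetwork:
    edges = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "clr_score"}
    if not required.issubset(edges.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")
    genes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    return CLRNetwork(genes, edges, params, {})


def write_sif(net: CLRNetwork, path) -> None:
    """Simple interaction format for Cytoscape: ``gene_a  clr  gene_b``."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in zip(net.edges["gene_a"], net.edges["gene_b"]):
            fh.write(f"{a}\tclr\t{b}\n")


def write_graphml(net: CLRNetwork, path) -> None:
    import networkx as nx

    g = nx.Graph()
    for _, row in net.edges.iterrows():
        g.add_edge(
            row["gene_a"],
            row["gene_b"],
            clr_score=float(row["clr_score"]),
            mi=float(row["mi"]),
        )
    nx.write_graphml(g, path)
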