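"""Expression-matrix containers, TSV I/O and microarray preprocessing.

The preprocessing chain mirrors a standard one-colour Agilent workflow:
floor raw intensities at 5.0, divide each array by its 50th percentile
(per-chip normalization), divide each probe by its across-sample median
(per-gene normalization), drop probes absent on more than half the arrays,
drop arrays whose mean Pearson correlation with the rest falls below 0.8,
and log2-transform for statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "StudyDesign",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_study_design",
    "write_study_design",
    "floor_intensities",
    "per_chip_normalize",
    "per_gene_normalize",
    "presence_filter",
    "sample_qc_filter",
    "log2_transform",
    "normalize_chain",
]

SCALES = ("intensity", "ratio", "log2")

#: accepted present/absent flag encodings
_FLAG_TRUE = {"P", "1"}
_FLAG_FALSE = {"A", "0"}

DESIGN_COLUMNS = [
    "sample_id",
    "system",
    "compound",
    "dose",
    "time_h",
    "replicate",
    "is_control",
]


class ExpressionError(ValueError):
    """Raised for malformed or out-of-contract expression inputs."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with a recorded measurement scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene/probe id with sample ids as columns.
    scale
        One of ``intensity`` (raw positive scanner units), ``ratio``
        (normalized, centred on 1) or ``log2``.
    flags
        Optional boolean present/absent matrix, same shape and labels.
    """

    values: pd.DataFrame
    scale: str = "intensity"
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if self.scale not in SCALES:
            raise ExpressionError(
                f"scale must be one of {SCALES}, got {self.scale!r}"
            )
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ExpressionError(f"duplicated gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ExpressionError(f"duplicated sample id: {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionError("expression values must be numeric")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ExpressionError(
                f"missing value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if self.flags is not None:
            f = self.flags
            if f.shape != v.shape or list(f.index) != list(v.index) or list(
                f.columns
            ) != list(v.columns):
                raise ExpressionError(
                    "flag matrix shape/labels do not match expression matrix"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        keep = [g for g in gene_ids if g in self.values.index]
        flags = self.flags.loc[keep] if self.flags is not None else None
        return ExpressionMatrix(self.values.loc[keep], self.scale, flags)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        keep = list(sample_ids)
        flags = self.flags[keep] if self.flags is not None else None
        return ExpressionMatrix(self.values[keep], self.scale, flags)


@dataclass
class StudyDesign:
    """Per-sample experimental factors (system, compound, dose, time, replicate)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ExpressionError(f"design table missing columns: {missing}")
        t = self.table.copy()
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ExpressionError(f"duplicated sample id in design: {dup!r}")
        t["dose"] = t["dose"].astype(float)
        t["time_h"] = t["time_h"].astype(float)
        t["is_control"] = t["is_control"].astype(bool)
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def check_matches(self, m: ExpressionMatrix) -> None:
        """Every sample in ``m`` must have exactly one design row."""
        missing = set(m.sample_ids) - set(self.sample_ids)
        if missing:
            raise ExpressionError(
                f"samples without a design row: {sorted(missing)}"
            )

    def subset(self, sample_ids) -> "StudyDesign":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return StudyDesign(keep.copy())

    def rows_for(self, m: ExpressionMatrix) -> pd.DataFrame:
        """Design rows reindexed to the matrix's sample order."""
        self.check_matches(m)
        t = self.table.set_index("sample_id")
        return t.loc[m.sample_ids].reset_index()


# ---------------------------------------------------------------------------
# I/O


def read_expression_matrix(path, flag_path=None) -> ExpressionMatrix:
    """Read a tab-delimited genes x samples matrix.

    First row holds sample ids (first cell is an arbitrary corner label,
    canonically ``gene_id``); first column holds gene ids; the body must be
    numeric. An optional flag file of identical layout carries present/absent
    calls encoded as P/A or 1/0.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    body = raw.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & raw.notna()
    if bad.any().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ExpressionError(
            f"non-numeric cell at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}: {raw.iat[g, s]!r}"
        )
    if raw.isna().any().any():
        g, s = np.argwhere(raw.isna().to_numpy())[0]
        raise ExpressionError(
            f"missing/ragged cell at gene {raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    flags = None
    if flag_path is not None:
        flags = _read_flags(flag_path)
    return ExpressionMatrix(body.astype(float), "intensity", flags)


def _read_flags(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    vals = raw.to_numpy()
    out = np.zeros(vals.shape, dtype=bool)
    for (i, j), v in np.ndenumerate(vals):
        v = str(v).strip()
        if v in _FLAG_TRUE:
            out[i, j] = True
        elif v in _FLAG_FALSE:
            out[i, j] = False
        else:
            raise ExpressionError(
                f"invalid flag {v!r} at gene {raw.index[i]!r}, "
                f"sample {raw.columns[j]!r} (expected P/A or 1/0)"
            )
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def write_expression_matrix(m: ExpressionMatrix, path, flag_path=None) -> None:
    """Write in the canonical TSV layout (``%.10g`` floats, ``gene_id`` corner)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(map(str, m.sample_ids)) + "\n")
        arr = m.values.to_numpy()
        for gid, row in zip(m.gene_ids, arr):
            fh.write(str(gid) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    if flag_path is not None and m.flags is not None:
        with open(flag_path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\t" + "\t".join(map(str, m.sample_ids)) + "\n")
            for gid, row in zip(m.gene_ids, m.flags.to_numpy()):
                fh.write(
                    str(gid) + "\t" + "\t".join("P" if v else "A" for v in row) + "\n"
                )


def read_study_design(path) -> StudyDesign:
    return StudyDesign(pd.read_csv(path, sep="\t"))


def write_study_design(d: StudyDesign, path) -> None:
    t = d.table.copy()
    t["is_control"] = t["is_control"].astype(int)
    t.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preprocessing operations


def floor_intensities(m: ExpressionMatrix, floor: float = 5.0) -> ExpressionMatrix:
    """Raise every raw intensity below ``floor`` (default 5.0) to the floor."""
    if m.scale != "intensity":
        raise ExpressionError(
            f"floor_intensities requires intensity scale, got {m.scale!r}"
        )
    return replace(m, values=m.values.clip(lower=floor))


def per_chip_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each array (column) by its 50th percentile; scale becomes ratio."""
    if m.scale != "intensity":
        raise ExpressionError(
            f"per_chip_normalize requires intensity scale, got {m.scale!r}"
        )
    med = m.values.median(axis=0)
    bad = med <= 0
    if bad.any():
        raise ExpressionError(
            f"non-positive chip median for sample {med.index[bad][0]!r}"
        )
    return ExpressionMatrix(m.values / med, "ratio", m.flags)


def per_gene_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each probe (row) by its across-sample median."""
    if m.scale != "ratio":
        raise ExpressionError(
            f"per_gene_normalize requires ratio scale, got {m.scale!r}"
        )
    med = m.values.median(axis=1)
    bad = med <= 0
    if bad.any():
        raise ExpressionError(
            f"non-positive gene median for gene {med.index[bad][0]!r}"
        )
    return ExpressionMatrix(m.values.div(med, axis=0), "ratio", m.flags)


def presence_filter(m: ExpressionMatrix, min_fraction: float = 0.5) -> ExpressionMatrix:
    """Keep probes flagged present on at least ``min_fraction`` of arrays (inclusive)."""
    if m.flags is None:
        raise ExpressionError("presence_filter requires an attached flag matrix")
    frac = m.flags.mean(axis=1)
    keep = frac >= min_fraction
    return ExpressionMatrix(
        m.values.loc[keep], m.scale, m.flags.loc[keep]
    )


def sample_qc_filter(
    m: ExpressionMatrix, min_mean_r: float = 0.8
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop arrays poorly correlated with the rest of the experiment.

    For each sample the mean Pearson correlation with every other sample is
    computed on log2 values; samples with mean r below ``min_mean_r`` are
    removed in a single pass (exclusion is not iterated, so the result does
    not depend on removal order).
    """
    if m.n_samples < 3:
        raise ExpressionError("sample_qc_filter requires at least 3 samples")
    vals = m.values.to_numpy(dtype=float)
    if m.scale != "log2":
        if (vals <= 0).any():
            raise ExpressionError(
                "sample_qc_filter needs positive values to take log2"
            )
        vals = np.log2(vals)
    sd = vals.std(axis=0)
    if (sd == 0).any():
        idx = int(np.argmax(sd == 0))
        raise ExpressionError(
            f"sample {m.sample_ids[idx]!r} has zero variance; correlation undefined"
        )
    corr = np.corrcoef(vals.T)
    n = corr.shape[0]
    mean_r = (corr.sum(axis=1) - 1.0) / (n - 1)
    keep_mask = mean_r >= min_mean_r
    excluded = [s for s, k in zip(m.sample_ids, keep_mask) if not k]
    kept = [s for s, k in zip(m.sample_ids, keep_mask) if k]
    return m.subset_samples(kept), excluded


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log base 2; requires strictly positive values."""
    if m.scale == "log2":
        raise ExpressionError("matrix is already on log2 scale")
    arr = m.values.to_numpy()
    if (arr <= 0).any():
        g, s = np.argwhere(arr <= 0)[0]
        raise ExpressionError(
            f"non-positive value at gene {m.gene_ids[g]!r}, "
            f"sample {m.sample_ids[s]!r}; cannot log2"
        )
    return ExpressionMatrix(np.log2(m.values), "log2", m.flags)


def normalize_chain(
    m: ExpressionMatrix,
    floor: float = 5.0,
    min_fraction: float = 0.5,
    min_mean_r: float = 0.8,
    qc: bool = True,
) -> tuple[ExpressionMatrix, dict]:
    """Full preprocessing chain: floor -> per-chip -> QC -> per-gene -> presence -> log2.

    Sample QC runs on per-chip-normalized values, before per-gene
    normalization: between-array Pearson correlation is dominated by the
    shared probe-intensity structure (bright probes bright everywhere),
    which is exactly what per-gene normalization removes — after it, even
    perfect arrays decorrelate and the mean-r criterion is meaningless.

    Returns the log2 matrix and a small report dict (genes before/after,
    excluded samples).
    """
    report: dict = {"n_genes_in": m.n_genes, "n_samples_in": m.n_samples}
    m = floor_intensities(m, floor)
    m = per_chip_normalize(m)
    excluded: list[str] = []
    if qc:
        m, excluded = sample_qc_filter(m, min_mean_r)
    report["excluded_samples"] = excluded
    report["n_samples_kept"] = m.n_samples
    m = per_gene_normalize(m)
    if m.flags is not None:
        m = presence_filter(m, min_fraction)
    report["n_genes_kept"] = m.n_genes
    m = log2_transform(m)
    return m, report
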