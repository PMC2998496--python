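"""End-to-end orchestration of the cross-system comparison workflow.

Fixed stage order: normalize both systems' study matrices and compendia ->
differential expression per system (dose-series ANOVA per time point in
system A, control/treated t-test in system B) -> common-gene Venn ->
condition clustering -> CLR network per system, inferred over the common
genes using the compendium samples -> conserved-subnetwork extraction and
TF connectivity tables -> optional gene-set enrichment -> manifest.

Every threshold lives in one config block and is echoed into the manifest,
which also records input checksums and per-stage counts so a run can be
audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (
    read_expression_matrix,
    read_study_design,
    normalize_chain,
    write_expression_matrix,
    ExpressionMatrix,
)
from .diffexpr import anova_dose_filter, ttest_filter, intersect_gene_lists, venn_percentage
from .clustering import control_ratio_matrix, average_replicates, two_way_cluster
from .clr import CLRParameters, infer_network, write_edge_list, write_sif
from .compare import intersect_networks, tf_degree_table, degree_ratio_flags
from .enrichment import read_gmt, hypergeometric_enrichment

__all__ = ["PipelineConfig", "RunManifest", "run_full_comparison"]


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one full comparison run.

    The DE matrices and the network compendia are distinct inputs on
    purpose: the gene list comes from the perturbation studies, while the
    networks are inferred from the (larger, more heterogeneous) compendium
    samples restricted to those genes.
    """

    vivo_matrix: str
    vivo_design: str
    vitro_matrix: str
    vitro_design: str
    vivo_compendium: str
    vitro_compendium: str
    tf_list: str
    vivo_flags: str | None = None
    vitro_flags: str | None = None
    gmt: str | None = None
    # thresholds (defaults follow the workflow's standard settings)
    floor: float = 5.0
    present_fraction: float = 0.5
    qc_min_r: float = 0.8
    alpha: float = 0.05
    fold: float = 1.5
    time_points: tuple = (24.0, 48.0)
    n_bins: int = 10
    spline_order: int = 3
    z_cutoff: float = 2.0
    min_tf_connections: int = 15
    degree_ratio: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise PipelineConfigError(f"bad pipeline config: {exc}") from None

    def validate(self) -> None:
        for name in (
            "vivo_matrix",
            "vivo_design",
            "vitro_matrix",
            "vitro_design",
            "vivo_compendium",
            "vitro_compendium",
            "tf_list",
        ):
            path = getattr(self, name)
            if path is None:
                raise PipelineConfigError(f"config entry {name!r} is required")
            if not Path(path).exists():
                raise PipelineConfigError(f"{name}: no such file {path!r}")


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict
    stage_counts: dict
    version: str = __version__

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)

    def check_monotone(self) -> None:
        """Filtering stages must not create genes out of thin air."""
        c = self.stage_counts
        for system in ("vivo", "vitro"):
            if c[f"de_{system}_passing"] > c[f"{system}_genes_normalized"]:
                raise ValueError(f"DE output exceeds input gene count ({system})")
        if c["common_genes"] > min(c["de_vivo_passing"], c["de_vitro_passing"]):
            raise ValueError("common gene count exceeds a source list")
        if c["conserved_edges"] > min(c["vivo_network_edges"], c["vitro_network_edges"]):
            raise ValueError("conserved edges exceed a source network")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_full_comparison(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the full workflow; writes all stage outputs under ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    checksums = {
        name: _sha256(getattr(config, name))
        for name in (
            "vivo_matrix",
            "vivo_design",
            "vitro_matrix",
            "vitro_design",
            "vivo_compendium",
            "vitro_compendium",
            "tf_list",
        )
    }

    # --- stage 1: normalization
    norm = {}
    designs = {}
    for system, mpath, fpath, dpath in (
        ("vivo", config.vivo_matrix, config.vivo_flags, config.vivo_design),
        ("vitro", config.vitro_matrix, config.vitro_flags, config.vitro_design),
    ):
        m = read_expression_matrix(mpath, fpath)
        d = read_study_design(dpath)
        d.check_matches(m)
        nm, report = normalize_chain(
            m, config.floor, config.present_fraction, config.qc_min_r
        )
        norm[system] = nm
        designs[system] = d.subset(nm.sample_ids)
        counts[f"{system}_genes_in"] = report["n_genes_in"]
        counts[f"{system}_genes_normalized"] = report["n_genes_kept"]
        counts[f"{system}_samples_excluded"] = len(report["excluded_samples"])
        write_expression_matrix(nm, out / f"{system}_normalized.tsv")

    # --- stage 2: differential expression
    de_vivo_tables = []
    vivo_pass: set[str] = set()
    for t in config.time_points:
        res = anova_dose_filter(
            norm["vivo"], designs["vivo"], t, config.alpha, config.fold
        )
        de_vivo_tables.append(res)
        vivo_pass |= res.passing_genes
    pd.concat(
        [r.table.assign(time_h=t) for r, t in zip(de_vivo_tables, config.time_points)]
    ).to_csv(out / "de_vivo.tsv", sep="\t", index=False)
    de_vitro = ttest_filter(norm["vitro"], designs["vitro"], config.alpha, config.fold)
    de_vitro.table.to_csv(out / "de_vitro.tsv", sep="\t", index=False)
    vitro_pass = de_vitro.passing_genes
    counts["de_vivo_passing"] = len(vivo_pass)
    counts["de_vitro_passing"] = len(vitro_pass)

    # --- stage 3: common genes (Venn)
    venn = intersect_gene_lists(vivo_pass, vitro_pass)
    common = sorted(venn.common)
    counts["common_genes"] = len(common)
    with open(out / "venn.tsv", "w", encoding="utf-8") as fh:
        fh.write("partition\tcount\tgenes\n")
        for name, block in (
            ("vivo_only", venn.a_only),
            ("common", venn.common),
            ("vitro_only", venn.b_only),
        ):
            fh.write(f"{name}\t{len(block)}\t{','.join(sorted(block))}\n")
    if not common:
        raise RuntimeError("stage common_genes: empty intersection; cannot continue")

    # --- stage 4: condition clustering on common genes (control-ratio, averaged)
    cluster_cols = []
    for system in ("vivo", "vitro"):
        linear = ExpressionMatrix(
            np.exp2(norm[system].values.loc[common]), "ratio"
        )
        ratio = control_ratio_matrix(linear, designs[system])
        avg = average_replicates(ratio, designs[system])
        cluster_cols.append(avg.values)
    combined = ExpressionMatrix(pd.concat(cluster_cols, axis=1), "ratio")
    cond_tree, gene_tree = two_way_cluster(combined)
    (out / "conditions.nwk").write_text(cond_tree.to_newick() + "\n", encoding="utf-8")
    (out / "genes.nwk").write_text(gene_tree.to_newick() + "\n", encoding="utf-8")
    counts["cluster_conditions"] = len(cond_tree.labels)

    # --- stage 5: CLR networks on common genes from the compendia
    params = CLRParameters(
        n_bins=config.n_bins,
        spline_order=config.spline_order,
        z_cutoff=config.z_cutoff,
    )
    nets = {}
    for system, path in (
        ("vivo", config.vivo_compendium),
        ("vitro", config.vitro_compendium),
    ):
        comp = read_expression_matrix(path)
        ncomp, _ = normalize_chain(comp, config.floor, qc=comp.n_samples >= 3)
        nets[system] = infer_network(ncomp.subset_genes(common), params)
        counts[f"{system}_compendium_samples"] = ncomp.n_samples
        counts[f"{system}_network_nodes"] = len(nets[system].nodes)
        counts[f"{system}_network_edges"] = nets[system].n_edges
        write_edge_list(nets[system], out / f"net_{system}.tsv")
        write_sif(nets[system], out / f"net_{system}.sif")

    # --- stage 6: conserved subnetworks + TF connectivity
    tf_ids = [
        line.strip()
        for line in Path(config.tf_list).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    dir_vivo: dict[str, str] = {}
    for r in de_vivo_tables:
        dir_vivo.update(r.directions())
    conserved = intersect_networks(
        nets["vivo"],
        nets["vitro"],
        tf_ids=tf_ids,
        directions_a=dir_vivo,
        directions_b=de_vitro.directions(),
    )
    counts["conserved_edges"] = conserved.n_edges
    counts["conserved_components"] = len(conserved.components)
    with open(out / "conserved_edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tcomponent\n")
        for ci, comp in enumerate(conserved.components, 1):
            for a, b in comp.edges:
                fh.write(f"{a}\t{b}\t{ci}\n")
    deg_tabs = {
        system: tf_degree_table(nets[system], tf_ids, config.min_tf_connections)
        for system in ("vivo", "vitro")
    }
    merged = deg_tabs["vivo"].merge(
        deg_tabs["vitro"], on="tf", suffixes=("_vivo", "_vitro")
    )
    ratio_flags = degree_ratio_flags(
        dict(zip(deg_tabs["vivo"]["tf"], deg_tabs["vivo"]["degree"])),
        dict(zip(deg_tabs["vitro"]["tf"], deg_tabs["vitro"]["degree"])),
        config.degree_ratio,
    )
    merged = merged.merge(ratio_flags[["tf", "biased_to"]], on="tf")
    merged.to_csv(out / "tf_degrees.tsv", sep="\t", index=False)

    # --- stage 7: enrichment of the common list (optional)
    if config.gmt is not None:
        collection = read_gmt(config.gmt)
        universe = set(norm["vivo"].gene_ids) & set(norm["vitro"].gene_ids)
        table = hypergeometric_enrichment(set(common), collection, universe, config.alpha)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        counts["enriched_sets"] = (
            int(table["significant"].sum()) if not table.empty else 0
        )

    manifest = RunManifest(
        config=asdict(config), input_checksums=checksums, stage_counts=counts
    )
    manifest.check_monotone()
    manifest.to_json(out / "manifest.json")
    return manifest
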