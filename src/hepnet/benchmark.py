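"""End-to-end recovery benchmarks on planted-network simulations.

Two standard experiments:

* :func:`ranking_recovery` — infer CLR scores over the full simulated gene
  panel from one system's compendium and score the ranking against the
  planted edges (average-precision AUPR, precision at the number of true
  edges).

* :func:`conserved_recovery` — run the complete two-system workflow
  (normalize, differential expression per system, common genes, CLR network
  per system on the common panel from each compendium, intersection) and
  score the conserved edge set against the planted shared-module edges.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clr import CLRParameters, clr_scores, mi_matrix, threshold_network
from .compare import intersect_networks
from .diffexpr import anova_dose_filter, ttest_filter
from .expression import normalize_chain
from .scoring import aupr, precision_at_k, edge_set_metrics
from .simulate import SimulationConfig, generate_truth_networks, simulate_expression

__all__ = ["ranking_recovery", "conserved_recovery"]


def ranking_recovery(
    cfg: SimulationConfig, params: CLRParameters = CLRParameters(), system: str = "a"
) -> dict:
    """CLR score ranking vs planted truth on one compendium; returns metrics."""
    truth_a, truth_b = generate_truth_networks(cfg)
    truth = truth_a if system == "a" else truth_b
    m, _ = simulate_expression(truth, cfg, design="compendium", system=system)
    norm, _ = normalize_chain(m)
    scores = clr_scores(mi_matrix(norm, params))
    true_edges = {e for e in truth.edge_set() if all(g in set(norm.gene_ids) for g in e)}
    n_pairs = norm.n_genes * (norm.n_genes - 1) / 2
    density = len(true_edges) / n_pairs
    area = aupr(scores, true_edges)
    return {
        "aupr": area,
        "baseline": density,
        "aupr_ratio": area / density,
        "precision_at_true": precision_at_k(scores, true_edges, len(true_edges)),
        "n_true": len(true_edges),
        "n_genes": norm.n_genes,
    }


def conserved_recovery(
    cfg: SimulationConfig, params: CLRParameters = CLRParameters()
) -> dict:
    """Full paired-system workflow scored against planted shared edges.

    System A contributes the dose-series study (ANOVA filter, union over
    time points); system B the control/treated study (t-test filter).
    Networks are inferred over the common differentially-expressed genes
    from each system's compendium, then intersected.
    """
    truth_a, truth_b = generate_truth_networks(cfg)
    de_sets = {}
    for system, truth, design in (
        ("a", truth_a, "dose_series"),
        ("b", truth_b, "control_treated"),
    ):
        m, d = simulate_expression(truth, cfg, design=design, system=system)
        norm, _ = normalize_chain(m)
        dsub = d.subset(norm.sample_ids)
        if design == "dose_series":
            passing: set[str] = set()
            for t in cfg.time_points:
                passing |= anova_dose_filter(norm, dsub, t).passing_genes
        else:
            passing = ttest_filter(norm, dsub).passing_genes
        de_sets[system] = passing
    panel = sorted(de_sets["a"] & de_sets["b"])
    nets = {}
    for system, truth in (("a", truth_a), ("b", truth_b)):
        m, _ = simulate_expression(truth, cfg, design="compendium", system=system)
        norm, _ = normalize_chain(m)
        nets[system] = threshold_network(
            clr_scores(mi_matrix(norm.subset_genes(panel), params)), params
        )
    conserved = intersect_networks(nets["a"], nets["b"])
    metrics = edge_set_metrics(conserved.edges, truth_a.shared_edge_set())
    metrics.update(
        {
            "n_de_a": len(de_sets["a"]),
            "n_de_b": len(de_sets["b"]),
            "n_common": len(panel),
            "edges_a": nets["a"].n_edges,
            "edges_b": nets["b"].n_edges,
        }
    )
    return metrics
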