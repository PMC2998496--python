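"""Benchmark metrics for inferred networks against a planted truth."""

from __future__ import annotations

import numpy as np

from .clr import CLRScores

__all__ = ["ranked_pairs", "aupr", "precision_at_k", "edge_set_metrics"]


def ranked_pairs(s: CLRScores) -> list[tuple[float, frozenset]]:
    """All unordered pairs sorted by descending score (deterministic ties)."""
    G = len(s.gene_ids)
    iu, ju = np.triu_indices(G, k=1)
    pairs = [
        (float(s.scores[i, j]), frozenset((s.gene_ids[i], s.gene_ids[j])))
        for i, j in zip(iu, ju)
    ]
    pairs.sort(key=lambda t: (-t[0], sorted(t[1])))
    return pairs


def aupr(s: CLRScores, true_edges: set[frozenset]) -> float:
    """Area under the precision-recall curve of the full score ranking.

    Step-wise summation: each true edge encountered at rank k contributes
    precision@k / n_true (average precision).
    """
    pairs = ranked_pairs(s)
    n_true = len(true_edges)
    if n_true == 0:
        raise ValueError("no true edges")
    tp = 0
    ap = 0.0
    for k, (_, e) in enumerate(pairs, start=1):
        if e in true_edges:
            tp += 1
            ap += tp / k
    return ap / n_true


def precision_at_k(s: CLRScores, true_edges: set[frozenset], k: int) -> float:
    pairs = ranked_pairs(s)[:k]
    hits = sum(1 for _, e in pairs if e in true_edges)
    return hits / k


def edge_set_metrics(
    predicted: set[frozenset], true_edges: set[frozenset]
) -> dict[str, float]:
    tp = len(predicted & true_edges)
    recall = tp / len(true_edges) if true_edges else float("nan")
    precision = tp / len(predicted) if predicted else float("nan")
    return {
        "tp": tp,
        "predicted": len(predicted),
        "true": len(true_edges),
        "recall": recall,
        "precision": precision,
    }
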