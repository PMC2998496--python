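"""Hypergeometric over-representation of a gene list against named gene sets.

A transparent replacement for proprietary knowledge-base enrichment tools:
gene sets come from standard GMT files, the test is the upper-tail
hypergeometric (equivalently one-sided Fisher exact on the 2x2 table), and
significance uses the raw p < alpha convention with Benjamini-Hochberg
q-values reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        sets = {
            n: s & universe for n, s in self.sets.items() if s & universe
        }
        return GeneSetCollection(sets, {n: self.descriptions.get(n, "") for n in sets})


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected name, description and >=1 gene"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.sets:
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.descriptions.get(name, '')}\t{genes}\n")


def hypergeometric_enrichment(
    gene_list,
    collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric P[X >= overlap] per gene set.

    The list and every set are intersected with the universe first. Returns
    one row per set: set, set_size, overlap, p, q, significant (raw p <
    alpha).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list) & universe
    if not gene_list:
        raise ValueError("empty gene list (after universe restriction)")
    M = len(universe)
    N = len(gene_list)
    rows = []
    for name, members in collection.sets.items():
        members = members & universe
        if not members:
            continue
        n = len(members)
        k = len(members & gene_list)
        # P[X >= k] for X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append(
            {
                "set": name,
                "description": collection.descriptions.get(name, ""),
                "set_size": n,
                "overlap": k,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = stats.false_discovery_control(table["p"], method="bh")
    table["significant"] = table["p"] < alpha
    return table.sort_values("p", kind="mergesort", ignore_index=True)
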