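"""Over-representation analysis of a gene list against GMT collections.

One-sided hypergeometric (Fisher upper-tail) test per gene set, with the
conservative EASE variant that recomputes the tail after removing one
overlapping gene (so a single-gene overlap is never significant).
P-values are BH-adjusted across the sets of the collection.

Symbols are matched case-insensitively (uppercased on entry).  The
background universe defaults to the union of all genes in the collection
and can be overridden with e.g. the full list of genes on the array --
the background choice materially affects p-values, so it is always
recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy.stats import hypergeom

from .pca import bh_adjust

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "enrich"]


@dataclass
class GeneSetCollection:
    """Named gene sets plus a background universe.

    Sets are restricted to the universe on construction; set names must be
    unique and all symbols are uppercased.
    """

    sets: Mapping[str, frozenset]
    universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        clean: dict = {}
        for name, genes in self.sets.items():
            if name in clean:
                raise ValueError(f"duplicate gene-set name {name!r}")
            clean[name] = frozenset(str(g).upper() for g in genes)
        universe = frozenset(str(g).upper() for g in self.universe)
        if not universe:
            universe = frozenset().union(*clean.values()) if clean else frozenset()
        self.sets = {name: genes & universe for name, genes in clean.items()}
        self.universe = universe


def read_gmt(path, universe: Optional[Iterable] = None) -> GeneSetCollection:
    """Read a GMT file: ``set_name<TAB>description<TAB>gene1<TAB>gene2...``"""
    sets: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs name, description, >=1 gene: {line[:60]!r}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}: duplicate gene-set name {name!r}")
        sets[name] = set(parts[2:])
    return GeneSetCollection(sets, frozenset(universe or ()))


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(genes)])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def enrich(
    query: Iterable,
    collection: GeneSetCollection,
    mode: str = "fisher",
) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of ``collection``.

    Returns one row per set with ``set_name``, ``overlap``, ``set_size``,
    ``query_size``, ``universe_size``, ``pvalue`` (one-sided upper tail)
    and ``fdr`` (BH across sets).  ``mode="ease"`` recomputes the tail
    with the overlap reduced by one (floored at 0, giving p = 1).
    Duplicate query symbols are dropped; query genes outside the universe
    are ignored (DAVID-style restriction to the background).
    """
    if mode not in ("fisher", "ease"):
        raise ValueError(f"unknown mode {mode!r}")
    if not collection.universe:
        raise ValueError("empty background universe")
    q = []
    seen: set = set()
    for gene in query:
        gene = str(gene).upper()
        if gene not in seen:
            seen.add(gene)
            q.append(gene)
    qset = set(q) & collection.universe
    if not qset:
        raise ValueError("query is empty after restriction to the universe")
    M, N = len(collection.universe), len(qset)
    rows = []
    for name, genes in collection.sets.items():
        K = len(genes)
        k = len(qset & genes)
        k_eff = k if mode == "fisher" else max(k - 1, 0)
        # P(X >= k_eff) for X ~ Hypergeom(M, K, N); sf(k_eff - 1)
        p = float(hypergeom.sf(k_eff - 1, M, K, N)) if k_eff > 0 else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": N,
                "universe_size": M,
                "pvalue": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    return out
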