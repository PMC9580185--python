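"""Hypergeometric over-representation analysis against GMT gene sets.

For a query of n genes drawn from a universe of M genes, the overlap k
with a set of K members is tested with the hypergeometric upper tail
P(X >= k); p-values are BH-adjusted across the collection. The background
(universe) policy is explicit: by default the union of all collection
members, intersected with an explicit universe when one is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .detest import bh_fdr

log = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "enrichment_test",
    "top_terms",
    "results_to_frame",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional explicit background universe."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("empty gene-set collection")
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")

    def effective_universe(self) -> frozenset[str]:
        union = frozenset().union(*(m for _, m in self.sets.values()))
        if self.universe is not None:
            return union & self.universe
        return union


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    description: str
    k: int  # overlap
    K: int  # set size (within the universe)
    n: int  # query size (within the universe)
    M: int  # universe size
    p: float
    q: float
    overlap_genes: tuple[str, ...]


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need name, description, members")
            name, desc, *members = parts
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, frozenset(m for m in members if m))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def enrichment_test(
    query, collection: GeneSetCollection, universe=None
) -> list[EnrichmentResult]:
    """Over-representation p/q per set, sorted by q then p then name.

    Query genes outside the universe are dropped (count logged), not an
    error; an empty intersection of query and universe is one.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query")
    bg = collection.effective_universe()
    if universe is not None:
        bg = bg & frozenset(universe)
    q_in = query & bg
    dropped = len(query) - len(q_in)
    if dropped:
        log.warning("dropped %d query genes outside the universe", dropped)
    if not q_in:
        raise ValueError("query is disjoint from the universe")

    M, n = len(bg), len(q_in)
    rows = []
    for name, (desc, members) in collection.sets.items():
        mem = members & bg
        k = len(mem & q_in)
        K = len(mem)
        p = float(hypergeom.sf(k - 1, M, K, n))  # upper tail P(X >= k)
        rows.append((name, desc, k, K, tuple(sorted(mem & q_in)), min(p, 1.0)))
    qvals = bh_fdr([r[5] for r in rows])
    results = [
        EnrichmentResult(name, desc, k, K, n, M, p, float(qv), genes)
        for (name, desc, k, K, genes, p), qv in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.set_name))
    return results


def top_terms(results: list[EnrichmentResult], k: int) -> list[EnrichmentResult]:
    """First ``k`` results; ties on (q, p) break alphabetically by set name."""
    if k <= 0:
        raise ValueError("k must be positive")
    return sorted(results, key=lambda r: (r.q, r.p, r.set_name))[:k]


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "description": r.description,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "M": r.M,
                "p": r.p,
                "q": r.q,
                "overlap_genes": ",".join(r.overlap_genes),
            }
            for r in results
        ]
    )
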