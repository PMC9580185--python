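"""Degree-based hub analysis of scored protein-interaction edge lists.

Edges below the combined-score cutoff (strictly > 0.15 by default, the
STRING low-confidence setting) are discarded before the graph is built;
hubs are nodes whose degree strictly exceeds the configured threshold
(default 30).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["ScoredEdgeList", "DegreeTable", "load_edges", "degree_analysis", "subnetwork"]


@dataclass
class ScoredEdgeList:
    """Undirected weighted edges, normalised: no self-loops, unordered
    pairs unique with the maximum score kept."""

    edges: list[tuple[str, str, float]]

    @classmethod
    def from_rows(cls, rows, score_min: float = 0.0) -> "ScoredEdgeList":
        scores = [s for _, _, s in rows]
        # STRING sometimes exports combined scores as integers 0-999
        if scores and max(scores) > 1.0:
            log.info("scores exceed 1; rescaling by 1/1000 (STRING integer export)")
            rows = [(a, b, s / 1000.0) for a, b, s in rows]
        best: dict[tuple[str, str], float] = {}
        self_loops = 0
        for a, b, s in rows:
            if s <= score_min:
                continue
            if a == b:
                self_loops += 1
                continue
            key = (a, b) if a <= b else (b, a)
            if s > best.get(key, -1.0):
                best[key] = s
        if self_loops:
            log.warning("dropped %d self-loops", self_loops)
        return cls([(a, b, s) for (a, b), s in sorted(best.items())])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_weighted_edges_from(self.edges, weight="combined_score")
        return g

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.edges, columns=["node1", "node2", "combined_score"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class DegreeTable:
    degrees: dict[str, int]
    n_nodes: int
    n_edges: int
    hubs: set[str]
    hub_min_degree: int = 30

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.degrees.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            [{"node": n, "degree": d, "hub": n in self.hubs} for n, d in rows]
        )


def load_edges(path, score_min: float = 0.15) -> ScoredEdgeList:
    """Read a 3-column TSV (node1, node2, combined_score), keep score > cutoff."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (node1, node2, combined_score)")
    scores = pd.to_numeric(df.iloc[:, 2], errors="coerce")
    bad = scores.isna()
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad][:5]]
        raise ValueError(f"{path}: non-numeric scores at line(s) {', '.join(lines)}")
    rows = list(
        zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str), scores.astype(float))
    )
    return ScoredEdgeList.from_rows(rows, score_min=score_min)


def degree_analysis(edges: ScoredEdgeList, hub_min_degree: int = 30) -> DegreeTable:
    """Node degrees on the simple undirected graph; hubs strictly above threshold."""
    g = edges.graph()
    if g.number_of_edges() == 0:
        log.warning("empty edge list")
    degrees = {n: int(d) for n, d in g.degree()}
    hubs = {n for n, d in degrees.items() if d > hub_min_degree}
    return DegreeTable(degrees, g.number_of_nodes(), g.number_of_edges(), hubs, hub_min_degree)


def subnetwork(edges: ScoredEdgeList, nodes) -> ScoredEdgeList:
    """Induced subgraph on ``nodes``; unknown nodes are ignored with a warning."""
    nodes = set(nodes)
    present = {n for e in edges.edges for n in e[:2]}
    missing = nodes - present
    if missing:
        log.warning("%d requested nodes absent from the graph", len(missing))
    keep = nodes & present
    return ScoredEdgeList([e for e in edges.edges if e[0] in keep and e[1] in keep])
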