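"""Hub-gene -> ion-channel bridge paths in an evidence-channel PPI graph.

Edges below the minimum combined score (default 400/1000) are discarded;
paths run from a hub to an eligible (up-regulated) ion channel through at
most two intermediates (4 nodes). Each path is scored by the geometric mean
of its edge combined scores on the 0-1 scale and graded "strong" if any
edge carries experimental or database channel evidence, else "moderate".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

STRONG = "strong"
MODERATE = "moderate"


@dataclass
class IonChannelUniverse:
    """Ion-channel gene universe with family labels (K+, Cl-, Glu, ...)."""

    families: pd.Series  # gene -> family label

    @property
    def genes(self) -> pd.Index:
        return self.families.index

    def family_of(self, gene: str) -> str:
        return str(self.families.get(gene, "?"))


@dataclass
class BridgePath:
    hub: str
    nodes: tuple[str, ...]  # ordered, hub..channel, 2-4 nodes
    channel: str
    edge_scores: tuple[float, ...]  # combined/1000 per edge, in (0, 1]
    path_score: float
    grade: str

    @property
    def intermediates(self) -> tuple[str, ...]:
        return self.nodes[1:-1]

    def path_string(self) -> str:
        return " -> ".join(self.nodes)


def filter_channels(
    universe: IonChannelUniverse,
    log2fc: pd.Series,
) -> list[str]:
    """Channels with log2FC strictly > 0; missing values are excluded."""
    eligible = []
    for gene in universe.genes:
        lfc = log2fc.get(gene)
        if lfc is None or pd.isna(lfc):
            logger.info("channel %s has no log2FC; excluded", gene)
            continue
        if lfc > 0:
            eligible.append(gene)
    return eligible


def path_score(edge_scores: tuple[float, ...] | list[float]) -> float:
    """Geometric mean of edge scores; all scores must lie in (0, 1]."""
    if not edge_scores:
        raise ValueError("path has no edges")
    if any(s <= 0 or s > 1 for s in edge_scores):
        raise ValueError("edge scores must lie in (0, 1]")
    return math.exp(sum(math.log(s) for s in edge_scores) / len(edge_scores))


def grade_evidence(
    nodes: tuple[str, ...],
    graph: nx.Graph,
    channel_floor: float = 0.0,
) -> str:
    """"strong" iff any path edge has experimental or database evidence."""
    for a, b in zip(nodes[:-1], nodes[1:]):
        data = graph.edges[a, b]
        if data.get("experimental", 0.0) > channel_floor:
            return STRONG
        if data.get("database", 0.0) > channel_floor:
            return STRONG
    return MODERATE


def find_bridge_paths(
    graph: nx.Graph,
    hubs: list[str],
    eligible_channels: list[str],
    min_score: float = 400.0,
    max_intermediates: int = 2,
    channel_floor: float = 0.0,
    all_paths: bool = False,
) -> list[BridgePath]:
    """Shortest qualifying path per (hub, channel) pair.

    The graph is first restricted to edges with combined_score >= min_score.
    Among equal-length shortest paths the highest path score wins, ties
    break on the lexicographically smallest node list. With ``all_paths``
    every shortest path is reported.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for a, b, d in graph.edges(data=True):
        if d.get("combined_score", 0.0) >= min_score:
            g.add_edge(a, b, **d)

    cutoff = max_intermediates + 1  # edges
    results: list[BridgePath] = []
    channel_set = [c for c in eligible_channels if c in g]
    for hub in hubs:
        if hub not in g:
            logger.info("hub %s not in PPI graph; skipped", hub)
            continue
        lengths = nx.single_source_shortest_path_length(g, hub, cutoff=cutoff)
        for channel in channel_set:
            if channel == hub or channel not in lengths:
                continue
            paths = nx.all_shortest_paths(g, hub, channel)
            scored = []
            for nodes in paths:
                edge_sc = tuple(
                    g.edges[a, b]["combined_score"] / 1000.0
                    for a, b in zip(nodes[:-1], nodes[1:])
                )
                scored.append(
                    BridgePath(
                        hub=hub,
                        nodes=tuple(nodes),
                        channel=channel,
                        edge_scores=edge_sc,
                        path_score=path_score(edge_sc),
                        grade=grade_evidence(tuple(nodes), g, channel_floor),
                    )
                )
            scored.sort(key=lambda bp: (-bp.path_score, bp.nodes))
            results.extend(scored if all_paths else scored[:1])
    return results


def bridge_table(
    paths: list[BridgePath],
    universe: IonChannelUniverse | None = None,
) -> pd.DataFrame:
    """Table-shaped output: hub, path string, channel, family, score, grade."""
    return pd.DataFrame(
        [
            {
                "hub": p.hub,
                "path": p.path_string(),
                "channel": p.channel,
                "family": universe.family_of(p.channel) if universe else "?",
                "score": round(p.path_score, 3),
                "grade": p.grade,
            }
            for p in paths
        ]
    )
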