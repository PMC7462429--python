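"""Signed weighted graph metrics on masked connectomes.

Strength splits a node's incident weights by sign (negative strength is a
magnitude, so total = positive + negative).  Fractional strength — the
ratio of summed positive to summed negative weight, analyzed downstream on
the natural-log scale — captures the balance between correlated and
anticorrelated links at the node or whole-component level; it is undefined
when a graph has no negative (or no positive) weight, and such subjects
propagate as missing values, never as zeros.

Betweenness centrality uses edge lengths 1/|w| on absolute weights (signed
shortest-path semantics are not well defined), normalized so that the
middle node of a 3-node path scores 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import Connectome

logger = logging.getLogger(__name__)


def _component_nodes(masked: Connectome) -> np.ndarray:
    if masked.component_nodes is not None:
        return np.asarray(masked.component_nodes, dtype=int)
    return np.arange(masked.n_nodes)


def node_strengths(masked: Connectome) -> pd.DataFrame:
    """Positive / negative (magnitude) / total strength per component node."""
    nodes = _component_nodes(masked)
    w = masked.weights[np.ix_(nodes, nodes)]
    pos = np.clip(w, 0, None).sum(axis=1)
    neg = np.clip(-w, 0, None).sum(axis=1)
    return pd.DataFrame({"node_id": nodes, "pos_strength": pos,
                         "neg_strength": neg, "total_strength": pos + neg})


def fractional_strength(masked: Connectome, level: str = "graph"):
    """Ratio of summed positive to summed negative weight.

    ``level="graph"`` returns a scalar (NaN when undefined, with a logged
    warning); ``level="node"`` returns a per-node Series with NaN at nodes
    lacking negative or positive incident weight.
    """
    s = node_strengths(masked)
    if level == "node":
        with np.errstate(divide="ignore", invalid="ignore"):
            fs = np.where((s.neg_strength > 0) & (s.pos_strength > 0),
                          s.pos_strength / s.neg_strength, np.nan)
        return pd.Series(fs, index=s.node_id.to_numpy(), name="fractional_strength")
    if level != "graph":
        raise ValueError("level must be 'node' or 'graph'")
    pos_sum = s.pos_strength.sum() / 2.0   # each edge counted at both endpoints
    neg_sum = s.neg_strength.sum() / 2.0
    if pos_sum <= 0 or neg_sum <= 0:
        logger.warning("fractional strength undefined (pos=%g, neg=%g) for %r",
                       pos_sum, neg_sum, masked.subject_id)
        return float("nan")
    return float(pos_sum / neg_sum)


def betweenness(masked: Connectome) -> pd.Series:
    """Weighted betweenness centrality over component nodes.

    Shortest paths on lengths 1/|w|; ties split fractionally; normalized
    by the number of ordered node pairs excluding the endpoint, so values
    lie in [0, 1].  Components with fewer than 3 nodes return all zeros.
    """
    nodes = _component_nodes(masked)
    if nodes.size < 3:
        return pd.Series(np.zeros(nodes.size), index=nodes, name="betweenness")
    g = nx.Graph()
    g.add_nodes_from(nodes.tolist())
    sub = masked.weights[np.ix_(nodes, nodes)]
    for a in range(nodes.size):
        for b in range(a + 1, nodes.size):
            w = sub[a, b]
            if w != 0:
                g.add_edge(int(nodes[a]), int(nodes[b]), length=1.0 / abs(w))
    bc = nx.betweenness_centrality(g, weight="length", normalized=True)
    return pd.Series([bc[int(v)] for v in nodes], index=nodes, name="betweenness")


@dataclass
class GraphMetrics:
    """Per-node and per-graph summaries of one masked connectome."""

    nodes: pd.DataFrame
    pos_sum: float
    neg_sum: float
    total_sum: float
    fractional_strength: float       # NaN when undefined
    log_fractional_strength: float   # natural log; NaN when undefined
    subject_id: str = ""
    component_index: int | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.fractional_strength)


def compute_metrics(masked: Connectome,
                    component_index: int | None = None) -> GraphMetrics:
    """All strength metrics plus betweenness for one masked connectome."""
    s = node_strengths(masked)
    s["fractional_strength"] = fractional_strength(masked, level="node").to_numpy()
    s["betweenness"] = betweenness(masked).to_numpy()
    pos_sum = float(s.pos_strength.sum() / 2.0)
    neg_sum = float(s.neg_strength.sum() / 2.0)
    fs = fractional_strength(masked, level="graph")
    return GraphMetrics(
        nodes=s, pos_sum=pos_sum, neg_sum=neg_sum,
        total_sum=pos_sum + neg_sum, fractional_strength=fs,
        log_fractional_strength=float(np.log(fs)) if np.isfinite(fs) and fs > 0
        else float("nan"),
        subject_id=masked.subject_id, component_index=component_index)


def group_metrics(masked_connectomes) -> pd.DataFrame:
    """Group-level characterization: per-subject metrics, then averaged.

    Returns the mean of each per-node metric across subjects (metrics of
    the average graph are deliberately *not* used).
    """
    frames = []
    for c in masked_connectomes:
        m = compute_metrics(c)
        frames.append(m.nodes.set_index("node_id"))
    return sum(frames) / len(frames) if frames else pd.DataFrame()
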