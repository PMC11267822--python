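"""TF activity scoring and co-regulation network modeling.

Activity of a gene set (a TF's regulon, or the union of several) in a
sample is the network Z-score: each member gene is standardized
across all samples (population convention, group-blind, so group
differences remain interpretable), and the per-sample activity is the
sum of member z-scores scaled by 1/sqrt(set size).  The scaling keeps
scores comparable across regulons of different sizes, and under
independence gives the score unit variance.

The network model of the top TFs maps analysis quantities to drawing
attributes: node size is the fraction of a TF's targets among the
DEGs (|regulon ∩ DEG| / |DEG|), node color the mean activity
difference of the TF's regulon between the groups, and an undirected
edge joins two TFs with weight |regulon_i ∩ regulon_j ∩ DEG| / |DEG|
— the proportion of DEGs the pair co-regulates.  Zero-weight edges
are omitted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .io import ExpressionMatrix, SampleAnnotation, TFTargetMap
from .stats import wilcoxon_ranksum

logger = logging.getLogger(__name__)


def activity_score(expr: ExpressionMatrix, gene_set: frozenset[str] | set[str]) -> pd.Series:
    """Per-sample network Z-score of a gene set.

    z[g, s] = (x[g, s] - mean_g) / sd_g with the population (n)
    denominator over all samples; activity_s = sum over usable member
    genes of z[g, s], divided by sqrt(number of usable genes).
    Zero-variance members and members absent from the matrix are
    dropped with a logged count.
    """
    present = [g for g in expr.data.index if g in gene_set]
    n_absent = len(gene_set) - len(present)
    if n_absent:
        logger.info("%d gene-set members absent from the expression matrix", n_absent)
    if not present:
        raise InputError("gene set has no members in the expression matrix")
    sub = expr.data.loc[present]
    x = sub.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    usable = sd > 0
    if not usable.any():
        raise InputError("all gene-set members have zero variance")
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance gene-set members", n_dropped)
    x = x[usable]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[usable][:, None]
    activity = z.sum(axis=0) / np.sqrt(usable.sum())
    return pd.Series(activity, index=expr.data.columns, name="activity")


def network_activity(
    expr: ExpressionMatrix, tf_map: TFTargetMap, top_tfs: list[str]
) -> pd.Series:
    """Activity of the union regulon of several TFs (each gene once)."""
    missing = [tf for tf in top_tfs if tf not in tf_map.regulons]
    if missing:
        raise InputError(f"TFs absent from the regulon map: {missing}")
    union: set[str] = set()
    for tf in top_tfs:
        union |= tf_map[tf]
    return activity_score(expr, union)


def activity_difference(
    activity: pd.Series, ann: SampleAnnotation
) -> tuple[float, float]:
    """Mean activity difference (A minus B) and Wilcoxon rank-sum p."""
    mask_a, mask_b = ann.mask_for(list(activity.index))
    a = activity.to_numpy()[mask_a]
    b = activity.to_numpy()[mask_b]
    _, p = wilcoxon_ranksum(a, b)
    return float(a.mean() - b.mean()), p


@dataclass
class NetworkModel:
    """Co-regulation network of the top TFs.

    ``node_size`` and ``edge_weight`` are fractions of the DEG set;
    ``node_color`` is each TF's regulon activity difference between
    the groups (A minus B).
    """

    nodes: list[str]
    node_size: dict[str, float]
    node_color: dict[str, float]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for tf in self.nodes:
            g.add_node(tf, size_value=self.node_size[tf], color_value=self.node_color[tf])
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        return g

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "NetworkModel":
        nodes = sorted(g.nodes)
        return cls(
            nodes=nodes,
            node_size={n: float(g.nodes[n]["size_value"]) for n in nodes},
            node_color={n: float(g.nodes[n]["color_value"]) for n in nodes},
            edges={
                tuple(sorted((u, v))): float(d["weight"])
                for u, v, d in g.edges(data=True)
            },
        )


def build_network_model(
    tf_map: TFTargetMap,
    top_tfs: list[str],
    deg_set: frozenset[str] | set[str],
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
) -> NetworkModel:
    """Construct the co-regulation network of the top TFs.

    Node size: proportion of each TF's targets among the DEGs.  Node
    color: mean regulon-activity difference between groups.  Edge
    weight between two TFs: proportion of DEGs they co-regulate; only
    strictly positive weights become edges.
    """
    deg_set = frozenset(deg_set)
    if not deg_set:
        raise InputError("empty DEG set")
    missing = [tf for tf in top_tfs if tf not in tf_map.regulons]
    if missing:
        raise InputError(f"TFs absent from the regulon map: {missing}")

    node_size, node_color = {}, {}
    for tf in top_tfs:
        node_size[tf] = len(tf_map[tf] & deg_set) / len(deg_set)
        diff, _ = activity_difference(activity_score(expr, tf_map[tf]), ann)
        node_color[tf] = diff

    edges: dict[tuple[str, str], float] = {}
    for i, u in enumerate(top_tfs):
        for v in top_tfs[i + 1:]:
            shared = tf_map[u] & tf_map[v] & deg_set
            if shared:
                edges[tuple(sorted((u, v)))] = len(shared) / len(deg_set)
    return NetworkModel(list(top_tfs), node_size, node_color, edges)


def export_network(model: NetworkModel, path: str | Path, fmt: str = "graphml") -> None:
    """Serialize the model to GraphML or JSON node-link.

    Both formats round-trip node size_value, color_value and edge
    weight losslessly (within float text representation).
    """
    g = model.to_graph()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "json":
        payload = nx.node_link_data(g, edges="links")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    else:
        raise ConfigError(f"unknown network format {fmt!r}")


def import_network(path: str | Path, fmt: str = "graphml") -> NetworkModel:
    if fmt == "graphml":
        g = nx.read_graphml(path)
    elif fmt == "json":
        with open(path) as fh:
            g = nx.node_link_graph(json.load(fh), edges="links")
    else:
        raise ConfigError(f"unknown network format {fmt!r}")
    return NetworkModel.from_graph(g)
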