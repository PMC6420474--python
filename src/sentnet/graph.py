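"""Weighted-graph centralities and hub classification on the core network.

Graphs keep only positive correlations as edge weights.  Degree
centrality (DC) is the summed positive weight of a node; betweenness
centrality (BC) counts, for every ordered source-target pair, the
fraction of minimum-cost paths through the node, with edge cost
w**(-alpha) (alpha = 1 by default: strong correlations are short).
Centrality hubs exceed mean + SD on both DC and BC; connector hubs are
the top 15% of participation indices over the full selected-region set,
the remaining centrality hubs being provincial.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ConnectivityMatrix, Partition
from .config import AnalysisConfig
from .data import DataError


def positive_graph(mat: ConnectivityMatrix) -> nx.Graph:
    """Undirected graph over the regions; edges = strictly positive r."""
    pear = mat.to_pearson()
    g = nx.Graph()
    g.add_nodes_from(pear.region_names)
    vals = pear.values
    names = pear.region_names
    n = len(names)
    for i in range(n):
        for j in range(i + 1, n):
            if vals[i, j] > 0:
                g.add_edge(names[i], names[j], weight=float(vals[i, j]))
    return g


def degree_centrality(g: nx.Graph) -> dict:
    """DC(i) = sum of positive edge weights at node i (0 when isolated)."""
    return {node: float(deg) for node, deg in g.degree(weight="weight")}


def betweenness_centrality(g: nx.Graph, alpha: float = 1.0) -> dict:
    """Weighted betweenness with shortest-path cost w**(-alpha).

    Unnormalized Brandes counts: each unordered pair contributes the
    fraction of its minimum-cost paths (with multiplicity) through the
    node.  Disconnected pairs contribute nothing.
    """
    if alpha < 0:
        raise DataError("alpha must be non-negative")
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, data in g.edges(data=True):
        w = data["weight"]
        if w <= 0:
            raise DataError(f"non-positive weight on edge ({u}, {v})")
        h.add_edge(u, v, cost=w ** (-alpha))
    return {
        node: float(bc)
        for node, bc in nx.betweenness_centrality(
            h, weight="cost", normalized=False
        ).items()
    }


def participation_index(g: nx.Graph, partition: Partition | dict) -> dict:
    """Guimera-Amaral participation: P(i) = 1 - sum_s (kappa_is / k_i)^2.

    kappa_is is node i's summed weight into module s and k_i its total
    strength; P = 0 for isolated nodes.
    """
    mapping = (
        partition.as_dict() if isinstance(partition, Partition) else dict(partition)
    )
    missing = [n for n in g.nodes if n not in mapping]
    if missing:
        raise DataError(f"partition does not cover node(s) {missing[:5]}")
    out = {}
    for node in g.nodes:
        k_i = 0.0
        per_module: dict = {}
        for _, nbr, data in g.edges(node, data=True):
            w = data["weight"]
            k_i += w
            mod = mapping[nbr]
            per_module[mod] = per_module.get(mod, 0.0) + w
        if k_i == 0:
            out[node] = 0.0
        else:
            out[node] = 1.0 - sum((k / k_i) ** 2 for k in per_module.values())
    return out


@dataclass
class GraphMetricsTable:
    per_region: pd.DataFrame
    dc_threshold: float
    bc_threshold: float
    centrality_hubs: list
    connector_hubs: list
    provincial_hubs: list


def classify_hubs(
    dc_means: np.ndarray,
    bc_means: np.ndarray,
    names: list[str],
    sd_multiplier: float = 1.0,
):
    """Hub thresholds and flags from per-region mean centralities.

    Thresholds are mean + sd_multiplier * sample SD (ddof = 1) over the
    per-region means; a region is a centrality hub when it exceeds both.
    """
    dc_means = np.asarray(dc_means, float)
    bc_means = np.asarray(bc_means, float)
    if len(dc_means) < 3:
        raise DataError("need at least 3 regions to classify hubs")
    dc_sd = dc_means.std(ddof=1)
    bc_sd = bc_means.std(ddof=1)
    if dc_sd == 0 or bc_sd == 0:
        warnings.warn("zero spread across regions: no hubs", stacklevel=2)
    dc_thr = float(dc_means.mean() + sd_multiplier * dc_sd)
    bc_thr = float(bc_means.mean() + sd_multiplier * bc_sd)
    hubs = [
        n
        for n, dc, bc in zip(names, dc_means, bc_means)
        if dc > dc_thr and bc > bc_thr and dc_sd > 0 and bc_sd > 0
    ]
    return dc_thr, bc_thr, hubs


def summarize_and_classify(
    dc: pd.DataFrame,
    bc: pd.DataFrame,
    pindex: dict,
    config: AnalysisConfig | None = None,
    n_total_regions: int | None = None,
) -> GraphMetricsTable:
    """Cohort summaries and hub flags from per-subject centralities.

    ``dc`` and ``bc`` are subjects x regions frames; ``pindex`` maps the
    full selected-region set to participation indices (group graph).
    Connector hubs are the ceil(connector_top_fraction * N_total)
    regions with the highest participation, N_total defaulting to the
    size of ``pindex``; provincial hubs are the remaining centrality
    hubs.
    """
    config = config or AnalysisConfig()
    if dc.shape[0] < 2 or dc.shape[1] < 3:
        raise DataError("need >= 2 subjects and >= 3 regions")
    names = list(dc.columns)
    dc_mean = dc.mean(axis=0).to_numpy()
    bc_mean = bc.mean(axis=0).to_numpy()
    dc_thr, bc_thr, hubs = classify_hubs(
        dc_mean, bc_mean, names, config.hub_sd_multiplier
    )
    n_total = n_total_regions or len(pindex)
    n_conn = int(np.ceil(config.connector_top_fraction * n_total))
    ranked = sorted(pindex, key=pindex.get, reverse=True)
    connector = ranked[:n_conn]
    provincial = [h for h in hubs if h not in connector]
    per_region = pd.DataFrame(
        {
            "region": names,
            "dc_mean": dc_mean,
            "dc_sd": dc.std(axis=0, ddof=1).to_numpy(),
            "bc_mean": bc_mean,
            "bc_sd": bc.std(axis=0, ddof=1).to_numpy(),
            "bc_pct_null": 100.0 * (bc == 0).mean(axis=0).to_numpy(),
            "dc_skewness": stats.skew(dc.to_numpy(), axis=0, bias=False),
            "dc_kurtosis": stats.kurtosis(dc.to_numpy(), axis=0, bias=False),
            "dc_p_norm": [
                stats.shapiro(dc[c].to_numpy()).pvalue for c in names
            ],
            "participation": [pindex.get(n, np.nan) for n in names],
            "centrality_hub": [n in hubs for n in names],
            "connector_hub": [n in connector for n in names],
        }
    )
    per_region["provincial_hub"] = (
        per_region["centrality_hub"] & ~per_region["connector_hub"]
    )
    return GraphMetricsTable(
        per_region=per_region,
        dc_threshold=dc_thr,
        bc_threshold=bc_thr,
        centrality_hubs=hubs,
        connector_hubs=connector,
        provincial_hubs=provincial,
    )


def subject_centralities(
    matrices: list[ConnectivityMatrix],
    network_regions: list[str],
    alpha: float = 1.0,
    dc_over: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject DC and BC frames (subjects x network regions).

    ``dc_over`` optionally widens the DC neighbourhood (e.g. the whole
    left hemisphere) while BC stays within the network graph.
    """
    dc_rows, bc_rows = [], []
    for mat in matrices:
        net = mat.subset(network_regions)
        g = positive_graph(net)
        bc_rows.append(betweenness_centrality(g, alpha))
        if dc_over is None:
            dc_rows.append(degree_centrality(g))
        else:
            wide = mat.subset(dc_over).to_pearson()
            vals = np.where(wide.values > 0, wide.values, 0.0)
            sums = vals.sum(axis=1)
            lookup = dict(zip(wide.region_names, sums))
            dc_rows.append({r: float(lookup[r]) for r in network_regions})
    dc = pd.DataFrame(dc_rows)[network_regions]
    bc = pd.DataFrame(bc_rows)[network_regions]
    return dc, bc
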