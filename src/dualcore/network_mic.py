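"""Habitat-corrected MIC co-occurrence network and hub-taxon detection.

Pipeline: habitat-correct relative abundances -> score every core-ASV pair
with MIC (+ Pearson r and the non-linearity measure mic - r^2) -> per-pair
permutation p-values -> Benjamini-Hochberg FDR across pairs -> graph over
significant edges -> degree / closeness / betweenness centralities ->
hubs = nodes simultaneously in the top decile of all three.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from ._mic import mic_approx, mic_approx_batch, mic_exact
from .community_stats import bh_adjust
from .datatypes import AbundanceTable

__all__ = [
    "MicParams",
    "MicResult",
    "EdgeStats",
    "Network",
    "habitat_correct",
    "mic",
    "edge_scan",
    "classify_nonlinear",
    "build_network",
    "hub_taxa",
]

logger = logging.getLogger(__name__)

# above this sample count the exact (exponential) search is off the table
_EXACT_N_LIMIT = 25


@dataclass(frozen=True)
class MicParams:
    alpha_exponent: float = 0.6
    clumps_factor: int = 15
    n_permutations: int = 200
    fdr_alpha: float = 0.05
    seed: int = 0
    method: str = "auto"  # auto | exact | approx

    def __post_init__(self) -> None:
        if not 0 < self.alpha_exponent <= 1:
            raise ValueError("alpha_exponent must be in (0, 1]")
        if self.clumps_factor < 1:
            raise ValueError("clumps_factor must be a positive integer")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.method not in ("auto", "exact", "approx"):
            raise ValueError(f"unknown MIC method {self.method!r}")


@dataclass
class MicResult:
    mic: float
    pearson_r: float
    nonlinearity: float
    degenerate: bool = False


@dataclass
class EdgeStats:
    asv_a: str
    asv_b: str
    mic: float
    pearson_r: float
    nonlinearity: float
    p_raw: float = math.nan
    q_bh: float = math.nan
    significant: bool = False
    nonlinear: bool = False
    degenerate: bool = False


@dataclass
class Network:
    graph: nx.Graph
    edges: list[EdgeStats] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# ---------------------------------------------------------------------------
# habitat filtering correction


def habitat_correct(table: AbundanceTable, habitat_labels) -> AbundanceTable:
    """Divide each ASV's relative abundance by its within-habitat mean.

    Removes a shared multiplicative habitat effect: after correction the
    habitat mean of every present ASV is 1 (absent ASVs stay 0), so a pure
    per-habitat shift no longer induces spurious between-ASV correlation.
    Habitats with fewer than 3 samples are rejected (correction unstable).
    """
    missing = [s for s in table.sample_ids if s not in habitat_labels]
    if missing:
        raise ValueError(f"sample(s) without habitat label: {missing}")
    labels = pd.Series({s: habitat_labels[s] for s in table.sample_ids})
    counts = labels.value_counts()
    small = counts.index[counts < 3].tolist()
    if small:
        raise ValueError(f"habitat(s) with fewer than 3 samples: {small}")
    x = table.data.astype(float)
    if not table.is_relative:
        sums = x.sum(axis=0)
        if (sums == 0).any():
            raise ValueError("all-zero sample(s) cannot be habitat-corrected")
        x = x / sums
    corrected = x.copy()
    for habitat in counts.index:
        cols = labels.index[labels == habitat]
        mean = x[cols].mean(axis=1)
        present = mean > 0
        corrected.loc[present, cols] = x.loc[present, cols].div(mean[present], axis=0)
        corrected.loc[~present, cols] = 0.0
    return AbundanceTable(corrected, metadata=table.metadata, is_relative=False)


# ---------------------------------------------------------------------------
# MIC


def _mic_value(x: np.ndarray, y: np.ndarray, params: MicParams) -> float:
    method = params.method
    if method == "auto":
        method = "exact" if len(x) <= _EXACT_N_LIMIT else "approx"
    if method == "exact":
        return mic_exact(x, y, alpha_exponent=params.alpha_exponent)
    return mic_approx(
        x, y, alpha_exponent=params.alpha_exponent, clumps_factor=params.clumps_factor
    )


def mic(x, y, params: MicParams | None = None) -> MicResult:
    """MIC, Pearson r and the non-linearity measure mic - r^2 for one pair."""
    params = params or MicParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 10:
        raise ValueError("mic requires n >= 10")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("mic requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MicResult(mic=math.nan, pearson_r=math.nan, nonlinearity=math.nan,
                         degenerate=True)
    m = _mic_value(x, y, params)
    r = float(np.corrcoef(x, y)[0, 1])
    return MicResult(mic=m, pearson_r=r, nonlinearity=m - r * r)


# ---------------------------------------------------------------------------
# edge scan


def _pairs(nodes: list[str], core_labels: dict[str, str], mode: str):
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = nodes[i], nodes[j]
            if mode == "bipartite":
                la, lb = core_labels[a], core_labels[b]
                tax_a = la in ("taxonomic", "both")
                fun_a = la in ("functional", "both")
                tax_b = lb in ("taxonomic", "both")
                fun_b = lb in ("functional", "both")
                if not ((tax_a and fun_b) or (fun_a and tax_b)):
                    continue
            yield a, b


def edge_scan(
    table: AbundanceTable,
    core_labels: dict[str, str],
    params: MicParams | None = None,
    pairs_mode: str = "all",
) -> list[EdgeStats]:
    """Score all unordered core-ASV pairs; permutation p per pair, BH across pairs.

    ``core_labels`` maps ASV id -> {taxonomic, functional, both}; only labeled
    ASVs present in the table are scanned. ``pairs_mode='bipartite'`` keeps
    only taxonomic-vs-functional pairs.
    """
    params = params or MicParams()
    if pairs_mode not in ("all", "bipartite"):
        raise ValueError(f"unknown pairs_mode {pairs_mode!r}")
    nodes = [a for a in table.asv_ids if a in core_labels]
    if len(nodes) < 2:
        raise ValueError("edge_scan needs at least 2 labeled ASVs in the table")
    # scan-scale work always uses the approximate estimator unless the exact
    # search is explicitly requested
    method = "approx" if params.method == "auto" else params.method
    data = {a: table.data.loc[a].to_numpy(dtype=float) for a in nodes}
    ss = np.random.SeedSequence(params.seed)
    edges: list[EdgeStats] = []
    for idx, (a, b) in enumerate(_pairs(nodes, core_labels, pairs_mode)):
        x, y = data[a], data[b]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            edges.append(
                EdgeStats(a, b, mic=math.nan, pearson_r=math.nan,
                          nonlinearity=math.nan, degenerate=True)
            )
            continue
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=(idx,)))
        if method == "approx":
            obs = mic_approx(
                x, y, alpha_exponent=params.alpha_exponent,
                clumps_factor=params.clumps_factor,
            )
            perms = np.vstack(
                [rng.permutation(y) for _ in range(params.n_permutations)]
            )
            null = mic_approx_batch(
                x, perms, alpha_exponent=params.alpha_exponent,
                clumps_factor=params.clumps_factor,
            )
            count = int((null >= obs).sum())
        else:
            obs = mic_exact(x, y, alpha_exponent=params.alpha_exponent)
            count = 0
            for _ in range(params.n_permutations):
                if mic_exact(
                    x, rng.permutation(y), alpha_exponent=params.alpha_exponent
                ) >= obs:
                    count += 1
        r = float(np.corrcoef(x, y)[0, 1])
        p = (1 + count) / (params.n_permutations + 1)
        edges.append(
            EdgeStats(a, b, mic=obs, pearson_r=r,
                      nonlinearity=obs - r * r, p_raw=float(p))
        )
    tested = [e for e in edges if not e.degenerate]
    if tested:
        qvals = bh_adjust([e.p_raw for e in tested])
        for e, q in zip(tested, qvals):
            e.q_bh = float(q)
            e.significant = bool(q < params.fdr_alpha)
    n_deg = len(edges) - len(tested)
    if n_deg:
        logger.info("edge_scan: %d degenerate pair(s) excluded from testing", n_deg)
    return edges


def classify_nonlinear(
    edges: list[EdgeStats], threshold: float = 0.0
) -> tuple[list[EdgeStats], float]:
    """Flag edges with mic - r^2 > threshold; return (edges, flagged fraction)."""
    scored = [e for e in edges if not e.degenerate]
    for e in scored:
        e.nonlinear = e.nonlinearity > threshold
    frac = sum(e.nonlinear for e in scored) / len(scored) if scored else 0.0
    return edges, float(frac)


# ---------------------------------------------------------------------------
# network + hubs


def build_network(edges: list[EdgeStats], core_labels: dict[str, str]) -> Network:
    """Graph over endpoints of significant edges (isolated core ASVs excluded)."""
    g = nx.Graph()
    significant = [e for e in edges if e.significant]
    for e in significant:
        g.add_edge(
            e.asv_a,
            e.asv_b,
            mic=e.mic,
            pearson_r=e.pearson_r,
            nonlinearity=e.nonlinearity,
            nonlinear=e.nonlinear,
            p_raw=e.p_raw,
            q_value=e.q_bh,
        )
    for node in g.nodes:
        g.nodes[node]["core_label"] = core_labels.get(node, "unknown")
    return Network(graph=g, edges=significant)


def hub_taxa(network: Network, quantile: float = 0.90) -> pd.DataFrame:
    """Per-node centralities and hub flags.

    closeness = 1 / (sum of shortest-path distances to reachable nodes); on a
    disconnected graph distances are taken within the node's component
    (logged). betweenness = fraction of shortest paths through the node.

    Hubs are nodes simultaneously in the top (1 - quantile) of all three
    centralities. The per-centrality threshold is the ceil((1-quantile)*n)-th
    largest value, and ties at the threshold are included — so a graph where
    every node is equivalent (e.g. a cycle) flags every node.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("hub_taxa requires a non-empty network")
    if not nx.is_connected(g):
        logger.info(
            "hub_taxa: graph has %d components; closeness computed per component",
            nx.number_connected_components(g),
        )
    nodes = sorted(g.nodes)
    degree = {n: g.degree(n) for n in nodes}
    closeness = {}
    for n in nodes:
        dists = nx.single_source_shortest_path_length(g, n)
        total = sum(d for m, d in dists.items() if m != n)
        closeness[n] = 1.0 / total if total > 0 else 0.0
    betweenness = nx.betweenness_centrality(g, normalized=True)
    report = pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
        },
        index=pd.Index(nodes, name="asv_id"),
    )
    is_hub = np.ones(len(nodes), dtype=bool)
    top_k = max(1, math.ceil((1 - quantile) * len(nodes)))
    for col in ("degree", "closeness", "betweenness"):
        values = report[col].to_numpy()
        thr = np.sort(values)[::-1][top_k - 1]
        is_hub &= values >= thr
    report["is_hub"] = is_hub
    report["core_label"] = [g.nodes[n].get("core_label", "unknown") for n in nodes]
    for n in nodes:
        g.nodes[n]["degree"] = int(report.at[n, "degree"])
        g.nodes[n]["closeness"] = float(report.at[n, "closeness"])
        g.nodes[n]["betweenness"] = float(report.at[n, "betweenness"])
        g.nodes[n]["is_hub"] = bool(report.at[n, "is_hub"])
    return report
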