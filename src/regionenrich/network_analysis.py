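"""Gene co-region network: incidence, projection, centrality, communities.

Contributing genes (user-list genes flagging at least one significant region)
and the significant regions form a binary incidence matrix. Its one-mode
projection onto genes yields a weighted undirected graph whose edge weights
count shared significant regions. On that graph we compute nodal strength,
betweenness centrality (configurable distance transform), Louvain communities
and, per region, the percentage composition by community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .high_expression import HighExpressionIndex

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "build_incidence",
    "project_network",
    "nodal_strength",
    "betweenness",
    "louvain_cluster",
    "cluster_stability",
    "region_cluster_composition",
    "write_incidence",
    "write_edges",
    "write_graphml",
    "write_nodal_metrics",
    "write_composition",
    "write_cluster_gene_lists",
]

DISTANCE_MODES = ("inverse_weight", "unweighted", "weight_as_cost")


@dataclass(frozen=True)
class ClusterAssignment:
    """Gene → community label (1-based, ordered by descending cluster size)."""

    labels: dict[str, int]
    modularity: float  # NaN when the graph has no edges
    resolution: float
    seed: int

    def members(self, label: int) -> tuple[str, ...]:
        return tuple(g for g, c in self.labels.items() if c == label)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def build_incidence(
    index: HighExpressionIndex,
    resolved: Iterable[str],
    significant_regions: Sequence[str],
) -> pd.DataFrame:
    """Binary contributing-genes × significant-regions membership matrix.

    Rows are restricted to resolved genes whose highest-expression set hits at
    least one significant region; ``cell(g, r) = 1`` iff gene ``g`` flags
    region ``r``. Regions with no contributing gene are dropped with a
    warning (they cannot occur for regions found significant by scoring).
    """
    regions = list(significant_regions)
    if not regions:
        raise ValueError("significant_regions must be non-empty")
    pos = index._gene_pos
    rpos = {r: j for j, r in enumerate(index.regions)}
    unknown = [r for r in regions if r not in rpos]
    if unknown:
        raise KeyError(f"regions not in the index: {unknown}")
    cols = [rpos[r] for r in regions]
    symbols = [g for g in resolved if g in pos]
    sub = index.flags[[pos[g] for g in symbols]][:, cols].astype(np.int8)
    keep_rows = sub.any(axis=1)
    if not keep_rows.any():
        raise ValueError("no contributing genes: no list gene flags a significant region")
    inc = pd.DataFrame(
        sub[keep_rows],
        index=[g for g, k in zip(symbols, keep_rows) if k],
        columns=regions,
    )
    empty_cols = inc.columns[(inc.sum(axis=0) == 0)]
    if len(empty_cols):
        logger.warning("dropping region(s) with no contributing gene: %s", list(empty_cols))
        inc = inc.drop(columns=empty_cols)
    logger.info("incidence matrix: %d genes x %d regions", *inc.shape)
    return inc


def project_network(incidence: pd.DataFrame) -> nx.Graph:
    """One-mode projection: weight(u, v) = number of shared regions.

    All incidence genes become nodes (isolated ones retained); an edge joins
    every gene pair whose rows share at least one region, with integer weight
    equal to the row dot product.
    """
    genes = list(incidence.index)
    B = incidence.to_numpy(dtype=np.int64)
    W = B @ B.T
    n = len(genes)
    logger.info("projecting %d genes: %d candidate pairs", n, n * (n - 1) // 2)
    g = nx.Graph()
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    nz = w > 0
    g.add_weighted_edges_from(
        (genes[i], genes[j], int(wt)) for i, j, wt in zip(iu[nz], ju[nz], w[nz])
    )
    return g


def nodal_strength(net: nx.Graph) -> dict[str, float]:
    """Sum of incident edge weights per node (isolated nodes get 0)."""
    return {v: float(d) for v, d in net.degree(weight="weight")}


def _distance_attr(net: nx.Graph, mode: str) -> str | None:
    if mode not in DISTANCE_MODES:
        raise ValueError(f"unknown distance_mode: {mode!r}")
    if mode == "unweighted":
        return None
    attr = "_dist"
    for _, _, d in net.edges(data=True):
        d[attr] = 1.0 / d["weight"] if mode == "inverse_weight" else float(d["weight"])
    return attr


def betweenness(
    net: nx.Graph,
    distance_mode: str = "inverse_weight",
    normalized: bool = True,
) -> dict[str, float]:
    """Betweenness centrality under a configurable distance transform.

    ``inverse_weight`` (default) treats the co-region weight as a similarity,
    so distance = 1/weight; ``weight_as_cost`` uses the weight directly as a
    path cost; ``unweighted`` ignores weights. Normalisation divides by
    ``(n-1)(n-2)/2`` pair counts; disconnected pairs contribute nothing.
    """
    attr = _distance_attr(net, distance_mode)
    return {
        v: float(b)
        for v, b in nx.betweenness_centrality(
            net, normalized=normalized, weight=attr
        ).items()
    }


def _canonical_labels(communities: list[set[str]]) -> dict[str, int]:
    # descending size, ties broken by smallest member name
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    return {g: i + 1 for i, comm in enumerate(ordered) for g in sorted(comm)}


def louvain_cluster(
    net: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> ClusterAssignment:
    """Weighted-modularity Louvain partition, deterministic for a fixed seed.

    Labels are canonicalised by descending community size so repeated runs
    with the same seed produce identical assignments. An edgeless graph
    yields singleton clusters and NaN modularity.
    """
    if net.number_of_edges() == 0:
        labels = {v: i + 1 for i, v in enumerate(sorted(net.nodes))}
        return ClusterAssignment(
            labels=labels, modularity=float("nan"), resolution=resolution, seed=seed
        )
    communities = nx.community.louvain_communities(
        net, weight="weight", resolution=resolution, seed=seed
    )
    q = nx.community.modularity(net, communities, weight="weight", resolution=resolution)
    return ClusterAssignment(
        labels=_canonical_labels([set(c) for c in communities]),
        modularity=float(q),
        resolution=resolution,
        seed=seed,
    )


def cluster_stability(
    net: nx.Graph, resolution: float = 1.0, seeds: Sequence[int] = tuple(range(10))
) -> pd.DataFrame:
    """Partition stability across seeds: modularity and ARI vs the first seed."""
    runs = [louvain_cluster(net, resolution=resolution, seed=s) for s in seeds]
    nodes = sorted(net.nodes)
    ref = [runs[0].labels[v] for v in nodes]
    rows = [
        {
            "seed": s,
            "n_clusters": r.n_clusters,
            "modularity": r.modularity,
            "ari_vs_first": float(adjusted_rand_score(ref, [r.labels[v] for v in nodes])),
        }
        for s, r in zip(seeds, runs)
    ]
    return pd.DataFrame(rows)


def region_cluster_composition(
    incidence: pd.DataFrame, clusters: ClusterAssignment
) -> pd.DataFrame:
    """Percentage of each region's contributing genes belonging to each cluster.

    Rows are regions, columns cluster labels; each row sums to 100.
    """
    missing = [g for g in incidence.index if g not in clusters.labels]
    if missing:
        raise KeyError(f"genes without cluster label: {missing[:5]}")
    labels = sorted(set(clusters.labels.values()))
    out = pd.DataFrame(0.0, index=list(incidence.columns), columns=labels)
    for region in incidence.columns:
        members = incidence.index[incidence[region] == 1]
        for g in members:
            out.loc[region, clusters.labels[g]] += 1
        out.loc[region] *= 100.0 / len(members)
    out.index.name = "region"
    out.columns = [f"cluster_{c}" for c in labels]
    return out


def write_incidence(incidence: pd.DataFrame, path: str | Path) -> None:
    inc = incidence.copy()
    inc.index.name = "gene"
    inc.to_csv(path, sep="\t")


def write_edges(net: nx.Graph, path: str | Path) -> None:
    rows = sorted((u, v, d["weight"]) if u <= v else (v, u, d["weight"])
                  for u, v, d in net.edges(data=True))
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    g = net.copy()
    for _, _, d in g.edges(data=True):
        d.pop("_dist", None)
    nx.write_graphml(g, path)


def write_nodal_metrics(
    net: nx.Graph,
    strength: dict[str, float],
    betw: dict[str, float],
    clusters: ClusterAssignment,
    path: str | Path,
) -> None:
    rows = [
        {
            "gene": v,
            "strength": strength[v],
            "betweenness": betw[v],
            "cluster": clusters.labels[v],
        }
        for v in sorted(net.nodes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_composition(composition: pd.DataFrame, path: str | Path) -> None:
    composition.to_csv(path, sep="\t")


def write_cluster_gene_lists(clusters: ClusterAssignment, outdir: str | Path) -> list[Path]:
    """One plain-text gene list per cluster, usable by external GO tools."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label in sorted(set(clusters.labels.values())):
        p = outdir / f"cluster_{label}_genes.txt"
        p.write_text("\n".join(sorted(clusters.members(label))) + "\n", encoding="utf-8")
        paths.append(p)
    return paths
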