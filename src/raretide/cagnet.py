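"""Signed CAG-environment correlation network, clusters, and keystones.

CAG temporal profiles (per-date median of member-gene abundances) and
environmental series are rank-correlated (Spearman); edges are kept when
rho > threshold or rho < -threshold (strictly).  Redundant CAGs — near-
identical profiles with the same taxonomy and high amino-acid identity —
are collapsed to one representative before network construction.  Louvain
modularity clustering runs on |rho| (modularity is undefined for negative
weights; the sign is kept on the edges for display and for centrality), and
keystones are ranked by one-step ExpectedInfluence, the sum of signed
incident edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cagbin import CAG
from .tables import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class SignedNetwork:
    """Undirected signed correlation graph over CAG and environment nodes.

    ``graph`` edges carry ``rho`` (signed Spearman) and ``sign`` attributes;
    ``clusters`` and ``centrality`` are filled by :func:`louvain_clusters`
    and :func:`expected_influence`.
    """

    graph: nx.Graph
    edge_threshold: float
    clusters: dict[str, int] = field(default_factory=dict)
    centrality: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_rho(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["rho"]


def _spearman_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rho (average-rank ties) over rows (series x dates)."""
    rho = stats.spearmanr(values, axis=1).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return np.asarray(rho)


def cag_profiles(
    cags: Sequence[CAG],
    gene_table: AbundanceTable,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-date CAG profiles: median over member genes at each sampling date.

    With ``normalize`` (default) medians are taken over within-sample relative
    abundances, otherwise over raw counts.  Returns CAGs x samples.
    """
    data = (
        gene_table.relative_abundance() if normalize else gene_table.counts.astype(float)
    )
    rows = {}
    for cag in cags:
        missing = cag.member_genes - set(gene_table.feature_ids)
        if missing:
            raise ValueError(
                f"{cag.cag_id}: member genes not in table: {sorted(missing)[:5]}"
            )
        rows[cag.cag_id] = data.loc[sorted(cag.member_genes)].median(axis=0)
    return pd.DataFrame(rows).T


def spearman_network(
    profiles: pd.DataFrame,
    env: Optional[pd.DataFrame] = None,
    edge_threshold: float = 0.8,
) -> SignedNetwork:
    """Signed Spearman network over CAG profiles and environmental series.

    ``profiles`` and ``env`` are nodes x dates with a shared date axis
    (environment series are rank-transformed exactly like CAG profiles).
    Edges are kept iff rho > edge_threshold or rho < -edge_threshold
    (strict); constant series are dropped with a warning.
    """
    blocks = [profiles]
    if env is not None:
        if list(env.columns) != list(profiles.columns):
            raise ValueError("environment series must share the profile date axis")
        blocks.append(env)
    mat = pd.concat(blocks, axis=0)
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 dates for a rank correlation network")
    if mat.index.has_duplicates:
        raise ValueError("duplicate node names across profiles and environment")

    values = mat.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    if constant.any():
        dropped = list(mat.index[constant])
        logger.warning("dropping constant series (undefined rho): %s", dropped)
        mat = mat.loc[~constant]
        values = mat.to_numpy(dtype=float)

    nodes = list(mat.index)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    if len(nodes) >= 2:
        rho = _spearman_matrix(values)
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                r = float(rho[i, j])
                if r > edge_threshold or r < -edge_threshold:
                    graph.add_edge(
                        nodes[i], nodes[j], rho=r, weight=r,
                        abs_weight=abs(r), sign=1 if r > 0 else -1,
                    )
    return SignedNetwork(graph=graph, edge_threshold=edge_threshold)


def remove_redundant(
    cags: Sequence[CAG],
    profiles: pd.DataFrame,
    taxonomy: dict[str, str],
    aai: Optional[pd.DataFrame] = None,
    corr_cut: float = 0.95,
    aai_cut: float = 95.0,
) -> tuple[list[CAG], dict[str, str]]:
    """Collapse redundant CAGs to one representative each.

    Two CAGs are redundant when their full-profile Spearman correlation is
    > corr_cut, they carry the same taxonomy label, and their amino-acid
    identity is > aai_cut (strict comparisons).  Without an AAI matrix the
    identity condition is skipped with a logged notice.  Redundancy groups
    are the transitive closure of the pairwise predicate; the representative
    is the CAG with the most genes (ties by id).  Returns (kept CAGs,
    redundant-id -> representative-id map).
    """
    ids = [c.cag_id for c in cags]
    missing = [i for i in ids if i not in taxonomy]
    if missing:
        raise ValueError(f"taxonomy missing for CAGs: {missing[:5]}")
    if aai is None:
        logger.info("no AAI matrix supplied; the amino-acid identity condition is skipped")

    sub = profiles.loc[ids].to_numpy(dtype=float)
    rho = _spearman_matrix(sub) if len(ids) >= 2 else np.ones((1, 1))

    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if rho[i, j] <= corr_cut:
                continue
            if taxonomy[ids[i]] != taxonomy[ids[j]]:
                continue
            if aai is not None and not aai.loc[ids[i], ids[j]] > aai_cut:
                continue
            parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(len(ids)):
        groups.setdefault(find(i), []).append(i)

    by_id = {c.cag_id: c for c in cags}
    kept: list[CAG] = []
    representative: dict[str, str] = {}
    for members in groups.values():
        rep = max(members, key=lambda i: (len(by_id[ids[i]].member_genes), ids[i]))
        kept.append(by_id[ids[rep]])
        for i in members:
            if i != rep:
                representative[ids[i]] = ids[rep]
    kept.sort(key=lambda c: ids.index(c.cag_id))
    return kept, representative


def louvain_clusters(network: SignedNetwork, seed: int = 0) -> dict[str, int]:
    """Louvain modularity clustering on |rho| edge weights.

    Negative correlations contribute their magnitude to modularity; isolated
    nodes form their own singleton clusters.  The result is stored on the
    network and returned.
    """
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    communities = nx.community.louvain_communities(
        network.graph, weight="abs_weight", seed=seed
    )
    clusters: dict[str, int] = {}
    for cid, nodes in enumerate(
        sorted(communities, key=lambda c: min(str(n) for n in c))
    ):
        for node in nodes:
            clusters[node] = cid
    network.clusters = clusters
    return clusters


def expected_influence(network: SignedNetwork) -> tuple[dict[str, float], list[str]]:
    """One-step ExpectedInfluence: sum of signed incident rho per node.

    Negative edges subtract, so a node pulled down by inverse correlations
    ranks lower than its |rho| strength would suggest.  Returns the score
    map and the node ranking (descending score, ties by node id).
    """
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    ei = {
        node: float(sum(d["rho"] for _, _, d in network.graph.edges(node, data=True)))
        for node in network.graph.nodes
    }
    ranking = sorted(ei, key=lambda n: (-ei[n], str(n)))
    network.centrality = ei
    return ei, ranking


def strength(network: SignedNetwork) -> dict[str, float]:
    """Secondary centrality: sum of |rho| over incident edges."""
    return {
        node: float(sum(abs(d["rho"]) for _, _, d in network.graph.edges(node, data=True)))
        for node in network.graph.nodes
    }


# ---------------------------------------------------------------------------
# I/O


def write_network(network: SignedNetwork, path: str | Path) -> None:
    """GraphML export with rho, sign, cluster and expected_influence attributes."""
    g = network.graph.copy()
    for node in g.nodes:
        if network.clusters:
            g.nodes[node]["cluster"] = int(network.clusters.get(node, -1))
        if network.centrality:
            g.nodes[node]["expected_influence"] = float(network.centrality.get(node, 0.0))
    nx.write_graphml(g, path)


def write_edge_list(network: SignedNetwork, path: str | Path) -> None:
    rows = [
        {"node_a": a, "node_b": b, "rho": d["rho"], "sign": d["sign"]}
        for a, b, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "rho", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_keystones(
    ei: dict[str, float], ranking: list[str], path: str | Path
) -> None:
    pd.DataFrame(
        {"node": ranking, "expected_influence": [ei[n] for n in ranking]}
    ).to_csv(path, sep="\t", index=False)
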