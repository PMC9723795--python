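"""Co-abundance gene group (CAG) binning.

Two routes to bin covarying genes into genome proxies:

* **PLS + bipartite network** — a partial least squares regression predicts
  the gene (protein) CLR table from the OTU CLR table; the shared latent
  components are then turned into a relevance network whose edge weight
  between OTU *o* and gene *g* is sum_h cor(x_o, t_h) * cor(y_g, t_h) over
  the X-score vectors t_h.  Edges below a weight threshold and orphan nodes
  are pruned and each remaining OTU defines one CAG: the set of genes linked
  to it (its "anchor").
* **Canopy clustering** — a reference-free alternative grouping genes whose
  normalized abundance profiles correlate with a canopy centroid, with a
  final merge step for near-duplicate canopies.

The PLS is NIPALS in regression mode (Y deflated by the X scores), with an
optional per-component ``keep_x`` sparsity implemented as soft-thresholding
of the X weight vector, the sparse-PLS convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .tables import AbundanceTable, ClrTable

logger = logging.getLogger(__name__)


@dataclass
class PlsModel:
    """Fitted PLS regression (X = OTUs, Y = genes; rows = samples).

    ``x_scores`` are the latent sample trajectories t_h; successive score
    vectors are mutually orthogonal.  ``kept_x`` records which OTUs survived
    the sparsity constraint on each component (all of them when dense).
    """

    n_components: int
    x_scores: pd.DataFrame  # samples x components
    x_weights: pd.DataFrame  # otus x components (NIPALS w, post-threshold)
    x_loadings: pd.DataFrame  # otus x components (p)
    y_loadings: pd.DataFrame  # genes x components (c)
    kept_x: list[list[str]] = field(default_factory=list)
    x_mean: Optional[pd.Series] = None
    x_scale: Optional[pd.Series] = None


@dataclass
class BipartiteGraph:
    """Weighted OTU-gene graph; only edges at/above the build threshold remain."""

    otu_nodes: list[str]
    gene_nodes: list[str]
    edges: list[tuple[str, str, float]]  # (otu, gene, weight)

    def degree(self, node: str) -> int:
        return sum(1 for o, g, _ in self.edges if o == node or g == node)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.otu_nodes, bipartite="otu")
        g.add_nodes_from(self.gene_nodes, bipartite="gene")
        g.add_weighted_edges_from(self.edges)
        return g


@dataclass
class CAG:
    """A co-abundance gene group: genes covarying with one anchor OTU."""

    cag_id: str
    anchor_otu: Optional[str]
    member_genes: set[str]
    taxonomy: Optional[str] = None
    source: Literal["pls", "canopy"] = "pls"

    def __post_init__(self) -> None:
        if not self.member_genes:
            raise ValueError(f"{self.cag_id}: member_genes must be nonempty")


# ---------------------------------------------------------------------------
# PLS


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold w so that exactly ``keep`` entries stay nonzero."""
    if keep >= len(w) or keep < 1:
        return w
    mags = np.abs(w)
    lam = np.sort(mags)[::-1][keep]  # (keep+1)-th largest magnitude
    out = np.sign(w) * np.maximum(mags - lam, 0.0)
    return out


def fit_pls(
    otu_clr: ClrTable,
    gene_clr: ClrTable,
    n_components: int = 2,
    keep_x: Optional[Sequence[int]] = None,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PlsModel:
    """NIPALS PLS regression of the gene table on the OTU table.

    Both CLR tables are features x samples and must share sample ids; columns
    of the internal X and Y (samples x features) are centered and unit-scaled.
    With ``keep_x`` set (one count per component) the X weight vector is
    soft-thresholded to retain that many OTUs per component.  On rank-deficient
    input fewer components are returned with a warning.
    """
    if otu_clr.sample_ids != gene_clr.sample_ids:
        raise ValueError("OTU and gene CLR tables must share sample ids in order")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n_samples = len(otu_clr.sample_ids)
    n_otus = len(otu_clr.feature_ids)
    if n_components > min(n_samples - 1, n_otus):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, otus)="
            f"{min(n_samples - 1, n_otus)}"
        )
    if keep_x is not None and len(keep_x) != n_components:
        raise ValueError("keep_x needs one entry per component")

    X = otu_clr.values.T.to_numpy(dtype=float).copy()
    Y = gene_clr.values.T.to_numpy(dtype=float).copy()
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    X -= x_mean
    Y -= y_mean
    x_scale = X.std(axis=0, ddof=1)
    y_scale = Y.std(axis=0, ddof=1)
    x_scale[x_scale == 0] = 1.0
    y_scale[y_scale == 0] = 1.0
    X /= x_scale
    Y /= y_scale

    otus = otu_clr.feature_ids
    genes = gene_clr.feature_ids
    T, W, P, C = [], [], [], []
    kept: list[list[str]] = []
    for h in range(n_components):
        x_norm = np.linalg.norm(X)
        if x_norm < 1e-12 or np.linalg.norm(Y) < 1e-12:
            warnings.warn(
                f"rank-deficient input: stopping at {h} of {n_components} components",
                RuntimeWarning,
            )
            break
        u = Y[:, np.argmax(Y.var(axis=0))].copy()
        w = np.zeros(X.shape[1])
        for _ in range(max_iter):
            w_new = X.T @ u
            if keep_x is not None:
                w_new = _soft_threshold_keep(w_new, int(keep_x[h]))
            nrm = np.linalg.norm(w_new)
            if nrm < 1e-15:
                break
            w_new /= nrm
            t = X @ w_new
            tt = t @ t
            if tt < 1e-15:
                break
            c = Y.T @ t / tt
            cc = c @ c
            u = Y @ c / cc if cc > 0 else u
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = X @ w
        tt = t @ t
        if tt < 1e-15:
            warnings.warn(
                f"degenerate component {h + 1}; stopping early", RuntimeWarning
            )
            break
        p = X.T @ t / tt
        c = Y.T @ t / tt
        X = X - np.outer(t, p)
        Y = Y - np.outer(t, c)  # regression-mode deflation by X scores
        T.append(t)
        W.append(w)
        P.append(p)
        C.append(c)
        kept.append([otus[i] for i in np.flatnonzero(w)])

    if not T:
        raise ValueError("PLS failed: no informative component could be extracted")
    comp_ids = [f"comp{h + 1}" for h in range(len(T))]
    return PlsModel(
        n_components=len(T),
        x_scores=pd.DataFrame(np.column_stack(T), index=otu_clr.sample_ids, columns=comp_ids),
        x_weights=pd.DataFrame(np.column_stack(W), index=otus, columns=comp_ids),
        x_loadings=pd.DataFrame(np.column_stack(P), index=otus, columns=comp_ids),
        y_loadings=pd.DataFrame(np.column_stack(C), index=genes, columns=comp_ids),
        kept_x=kept,
        x_mean=pd.Series(x_mean, index=otus),
        x_scale=pd.Series(x_scale, index=otus),
    )


def _safe_corr_with_scores(mat: np.ndarray, scores: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """Pearson correlation of each row-feature (samples in columns of mat.T) with each score."""
    centered = mat - mat.mean(axis=0, keepdims=True)
    sd = centered.std(axis=0)
    zero = sd == 0
    if zero.any():
        logger.warning(
            "%d zero-variance features; their relevance correlations set to 0",
            int(zero.sum()),
        )
    sd = np.where(zero, 1.0, sd)
    s_centered = scores - scores.mean(axis=0, keepdims=True)
    s_sd = s_centered.std(axis=0)
    s_sd[s_sd == 0] = 1.0
    corr = (centered / sd).T @ (s_centered / s_sd) / mat.shape[0]
    corr[zero, :] = 0.0
    return corr


def relevance_weights(
    model: PlsModel, otu_clr: ClrTable, gene_clr: ClrTable
) -> pd.DataFrame:
    """Relevance-network weights: sum over components of cor(x,t)*cor(y,t).

    Reconstructs pairwise OTU-gene association from the shared latent
    components; values are clipped to [-1, 1].  Invariant to a joint sign
    flip of any component's scores.
    """
    scores = model.x_scores.to_numpy()
    cx = _safe_corr_with_scores(otu_clr.values.T.to_numpy(dtype=float), scores, otu_clr.feature_ids)
    cy = _safe_corr_with_scores(gene_clr.values.T.to_numpy(dtype=float), scores, gene_clr.feature_ids)
    w = np.clip(cx @ cy.T, -1.0, 1.0)
    return pd.DataFrame(w, index=otu_clr.feature_ids, columns=gene_clr.feature_ids)


# ---------------------------------------------------------------------------
# Bipartite network and CAG extraction


def build_bipartite(
    weights: pd.DataFrame,
    threshold: float = 0.8,
    mode: Literal["signed", "abs"] = "signed",
) -> BipartiteGraph:
    """Threshold the weight matrix into an OTU-gene graph and prune orphans.

    Keeps edges with weight >= threshold (``signed``, the default: negative
    associations never join a CAG) or |weight| >= threshold (``abs``); nodes
    left without any edge are removed.
    """
    arr = weights.to_numpy()
    if not np.isfinite(arr).all():
        raise ValueError("weight matrix contains non-finite values")
    keep = (np.abs(arr) >= threshold) if mode == "abs" else (arr >= threshold)
    rows, cols = np.nonzero(keep)
    edges = [
        (weights.index[r], weights.columns[c], float(arr[r, c]))
        for r, c in zip(rows, cols)
    ]
    otus = sorted({o for o, _, _ in edges}, key=list(weights.index).index)
    genes = sorted({g for _, g, _ in edges}, key=list(weights.columns).index)
    return BipartiteGraph(otu_nodes=otus, gene_nodes=genes, edges=edges)


def extract_cags(
    graph: BipartiteGraph,
    assignment: Literal["unique", "multi"] = "unique",
) -> list[CAG]:
    """One CAG per OTU node: the genes linked to it.

    In ``unique`` mode (default, so CAGs partition the genes) every gene joins
    only the OTU it is most strongly linked to, ties broken by lexicographic
    OTU id (logged); ``multi`` lets genes join every linked OTU.
    """
    by_gene: dict[str, list[tuple[str, float]]] = {}
    for otu, gene, w in graph.edges:
        by_gene.setdefault(gene, []).append((otu, w))

    members: dict[str, set[str]] = {o: set() for o in graph.otu_nodes}
    for gene, links in by_gene.items():
        if assignment == "multi":
            for otu, _ in links:
                members[otu].add(gene)
        else:
            best_w = max(w for _, w in links)
            tied = sorted(o for o, w in links if w == best_w)
            if len(tied) > 1:
                logger.info(
                    "gene %s tied at weight %.3g between %s; assigned to %s",
                    gene, best_w, tied, tied[0],
                )
            members[tied[0]].add(gene)

    cags = []
    for i, otu in enumerate(sorted(members, key=graph.otu_nodes.index)):
        if members[otu]:
            cags.append(
                CAG(
                    cag_id=f"pls_{otu}",
                    anchor_otu=otu,
                    member_genes=members[otu],
                    source="pls",
                )
            )
    return cags


def bin_pls(
    otu_clr: ClrTable,
    gene_clr: ClrTable,
    n_components: int = 2,
    keep_x: Optional[Sequence[int]] = None,
    threshold: float = 0.8,
    assignment: Literal["unique", "multi"] = "unique",
) -> tuple[list[CAG], PlsModel, BipartiteGraph]:
    """Full PLS-bipartite binning pipeline; returns (CAGs, model, graph)."""
    model = fit_pls(otu_clr, gene_clr, n_components=n_components, keep_x=keep_x)
    weights = relevance_weights(model, otu_clr, gene_clr)
    graph = build_bipartite(weights, threshold=threshold)
    return extract_cags(graph, assignment=assignment), model, graph


# ---------------------------------------------------------------------------
# Canopy alternative


def canopy_binning(
    gene_table: AbundanceTable,
    seed_corr: float = 0.9,
    merge_corr: float = 0.97,
    max_rounds: int = 100,
) -> list[CAG]:
    """Canopy clustering of per-gene normalized abundance profiles.

    Genes are visited in table order; each unassigned gene seeds a canopy
    that absorbs genes whose Pearson correlation to the canopy centroid is
    >= ``seed_corr``, recomputing the centroid until membership is stable.
    Canopies whose centroids correlate >= ``merge_corr`` are merged
    (transitively).  Deterministic given the table's gene order.
    """
    if gene_table.shape[1] < 3:
        raise ValueError("canopy binning needs at least 3 samples")
    rel = gene_table.relative_abundance().to_numpy(dtype=float)
    genes = gene_table.feature_ids
    centered = rel - rel.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    z = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    n = rel.shape[1]

    unassigned = list(range(len(genes)))
    canopies: list[list[int]] = []
    while unassigned:
        seed_idx = unassigned[0]
        member_set = {seed_idx}
        for _ in range(max_rounds):
            centroid = z[sorted(member_set)].mean(axis=0)
            csd = centroid.std()
            if csd == 0:
                break
            cz = (centroid - centroid.mean()) / csd
            corr = z[unassigned] @ cz / n
            new_set = {unassigned[i] for i in np.flatnonzero(corr >= seed_corr)}
            new_set.add(seed_idx)
            if new_set == member_set:
                break
            member_set = new_set
        canopies.append(sorted(member_set))
        unassigned = [i for i in unassigned if i not in member_set]

    # transitive merge of near-duplicate canopies
    centroids = np.array([z[c].mean(axis=0) for c in canopies])
    csd = centroids.std(axis=1, keepdims=True)
    czs = np.divide(
        centroids - centroids.mean(axis=1, keepdims=True),
        csd,
        out=np.zeros_like(centroids),
        where=csd > 0,
    )
    k = len(canopies)
    parent = list(range(k))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if czs[i] @ czs[j] / n >= merge_corr:
                parent[find(j)] = find(i)

    merged: dict[int, list[int]] = {}
    for i, canopy in enumerate(canopies):
        merged.setdefault(find(i), []).extend(canopy)

    cags = []
    for rank, root in enumerate(sorted(merged, key=lambda r: min(merged[r]))):
        cags.append(
            CAG(
                cag_id=f"canopy_{rank + 1:03d}",
                anchor_otu=None,
                member_genes={genes[i] for i in merged[root]},
                source="canopy",
            )
        )
    return cags


# ---------------------------------------------------------------------------
# I/O and evaluation helpers


def write_cags(cags: list[CAG], path: str | Path) -> None:
    rows = [
        {"cag_id": c.cag_id, "anchor_otu": c.anchor_otu or "none", "gene_id": g}
        for c in cags
        for g in sorted(c.member_genes)
    ]
    pd.DataFrame(rows, columns=["cag_id", "anchor_otu", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_edge_list(graph: BipartiteGraph, path: str | Path) -> None:
    pd.DataFrame(graph.edges, columns=["otu", "gene", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(graph: BipartiteGraph, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(graph.to_networkx(), path)


def partition_ari(
    truth: dict[str, Optional[str]],
    cags: list[CAG],
    genes: Optional[Sequence[str]] = None,
) -> float:
    """Adjusted Rand index between a planted gene partition and recovered CAGs.

    Evaluated over ``genes`` (default: all genes with a planted group).
    Unassigned genes each count as their own singleton cluster, so dropped
    genes are penalized rather than ignored.
    """
    from sklearn.metrics import adjusted_rand_score

    if genes is None:
        genes = [g for g, c in truth.items() if c is not None]
    assigned: dict[str, str] = {}
    for c in cags:
        for g in c.member_genes:
            assigned[g] = c.cag_id
    true_labels = [truth[g] if truth.get(g) else f"_bg_{g}" for g in genes]
    pred_labels = [assigned.get(g, f"_unassigned_{g}") for g in genes]
    return float(adjusted_rand_score(true_labels, pred_labels))
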