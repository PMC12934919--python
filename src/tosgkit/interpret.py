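"""Cohort-level target genes and core signaling subgraphs.

From per-sample latent node embeddings, a scaled-dot-product attention map
gives dense pairwise affinities; these are restricted to the PPI topology to
yield per-sample directed edge weights.  At the cohort level, weights of
identical source–target gene pairs are summed within each sample, reciprocal
directions are averaged into undirected weights, and identical gene pairs
are summed across the samples of a group.  Node scores combine network
saliency with expression: node attention is the mean incident undirected
weight, per-gene expression is the best transcript by mean min–max
normalized value, group means and two-sided Mann–Whitney U p-values compare
the groups, and the importance score is attention × group mean expression.
The core subgraph keeps the top-ξ nodes by importance, restricts to the
largest connected component, and prunes star-like leaf artifacts while
preserving at least ε leaves per hub — significant leaves (p below the
threshold) first, then the highest-weight ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data import EntityCatalog, TosgError, TosgTopology

__all__ = [
    "attention_affinity",
    "restrict_to_ppi",
    "aggregate_cohort_edges",
    "score_nodes",
    "extract_core",
    "CoreSubgraph",
    "gene_map_from_catalog",
    "mannwhitney_pvalue",
]

XI_DEFAULT = 120
EPSILON_DEFAULT = 3
P_THRESHOLD_DEFAULT = 0.05


def attention_affinity(Z: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention map with row normalization.

    ``Z`` is (M, d) or (N, M, d); scores are ``Z Z^T / sqrt(d)`` softmaxed
    over the last axis, so every row sums to one.  Identical embeddings give
    uniform rows.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise TosgError("embeddings must be finite")
    d = Z.shape[-1]
    scores = np.einsum("...id,...jd->...ij", Z, Z) / np.sqrt(d)
    scores = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=-1, keepdims=True)


def restrict_to_ppi(
    affinity: np.ndarray, topo: TosgTopology, catalog: EntityCatalog
) -> pd.DataFrame:
    """Keep only the PPI entries of a dense affinity matrix.

    ``affinity`` is (M, M) over the catalog's entity order.  Returns one row
    per *directed* PPI pair (both directions of every undirected edge) with
    columns source, target, weight.
    """
    m = catalog.size
    if affinity.shape != (m, m):
        raise TosgError("affinity size does not match catalog")
    idx = catalog.index_of()
    rows = []
    for a, b in topo.ppi_edges:
        ia, ib = idx[a], idx[b]
        rows.append((a, b, float(affinity[ia, ib])))
        rows.append((b, a, float(affinity[ib, ia])))
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


def gene_map_from_catalog(catalog: EntityCatalog) -> pd.DataFrame:
    """Entity → gene-symbol table derived from catalog names.

    A transcript's gene is its name with any trailing isoform suffix
    (``-NNN``) stripped; a protein inherits the gene of its lowest-index
    partner transcript.
    """
    tab = catalog.table
    gene_of: dict[str, str] = {}
    for eid, name, kind in zip(tab["entity_id"], tab["name"], tab["kind"]):
        if kind == "transcript":
            gene_of[eid] = str(name).rsplit("-", 1)[0]
    for eid, kind in zip(tab["entity_id"], tab["kind"]):
        if kind == "protein":
            partners = tab.loc[
                (tab["kind"] == "transcript") & (tab["partner"] == eid), "entity_id"
            ]
            gene_of[eid] = gene_of[sorted(partners)[0]] if len(partners) else eid
    return pd.DataFrame(
        {"entity_id": list(gene_of), "gene": [gene_of[k] for k in gene_of]}
    )


def aggregate_cohort_edges(
    tables: list[pd.DataFrame], gene_map: pd.DataFrame
) -> pd.DataFrame:
    """Group-level undirected gene-pair weights.

    Within each sample: map entities to genes (unmapped entities are skipped
    with a warning column in the log), sum weights of identical directed gene
    pairs, then average reciprocal directions.  Across samples: sum identical
    gene pairs.  Returns columns gene_u, gene_v (sorted), weight.
    """
    gmap = dict(zip(gene_map["entity_id"], gene_map["gene"]))
    totals: dict[tuple[str, str], float] = {}
    for tab in tables:
        directed: dict[tuple[str, str], float] = {}
        for s, t, w in zip(tab["source"], tab["target"], tab["weight"]):
            if s not in gmap or t not in gmap:
                continue
            gs, gt = gmap[s], gmap[t]
            if gs == gt:
                continue
            directed[(gs, gt)] = directed.get((gs, gt), 0.0) + float(w)
        seen: set[tuple[str, str]] = set()
        for (gs, gt), w in directed.items():
            key = tuple(sorted((gs, gt)))
            if key in seen:
                continue
            seen.add(key)
            und = (w + directed.get((gt, gs), 0.0)) / 2.0
            totals[key] = totals.get(key, 0.0) + und
    rows = [(u, v, w) for (u, v), w in sorted(totals.items())]
    return pd.DataFrame(rows, columns=["gene_u", "gene_v", "weight"])


def mannwhitney_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney U p-value.

    Exact enumeration when both groups have at most eight untied
    observations; otherwise the normal approximation with tie correction.
    Degenerate comparisons (a constant pooled sample) return 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.r_[x, y]
    if np.ptp(pooled) == 0 or len(x) == 0 or len(y) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def score_nodes(
    group_table: pd.DataFrame,
    expression: np.ndarray,
    columns: list[str],
    group_labels: np.ndarray,
    target_group: str,
    gene_map: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene saliency, expression, significance, and importance.

    ``group_table`` is the aggregated undirected gene-pair table of the
    target group; ``expression`` is the full cohort matrix (all groups) over
    ``columns`` (entity ids) with ``group_labels`` row-aligned.  For each
    gene the representative transcript is the one with the highest mean
    min–max normalized expression across the whole cohort (normalization per
    transcript).  Importance = node attention × target-group mean expression.
    Genes without incident edges get attention 0 and are flagged.
    """
    gmap = gene_map.set_index("entity_id")["gene"].to_dict()
    # min–max normalize each transcript column across the cohort
    X = np.asarray(expression, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xn = (X - lo) / span
    col_idx = {c: i for i, c in enumerate(columns)}
    transcripts_of: dict[str, list[str]] = {}
    for eid, gene in gmap.items():
        if eid in col_idx:
            transcripts_of.setdefault(gene, []).append(eid)

    incident: dict[str, list[float]] = {}
    for u, v, w in zip(group_table["gene_u"], group_table["gene_v"], group_table["weight"]):
        incident.setdefault(u, []).append(float(w))
        incident.setdefault(v, []).append(float(w))

    is_target = np.asarray(group_labels).astype(str) == str(target_group)
    genes = sorted(set(gmap.values()))
    rows = []
    for gene in genes:
        ents = [e for e in transcripts_of.get(gene, []) if e in col_idx]
        best_col, best_mean = None, -np.inf
        for e in ents:
            mval = Xn[:, col_idx[e]].mean()
            if mval > best_mean:
                best_col, best_mean = col_idx[e], mval
        if best_col is None:
            continue
        vals = Xn[:, best_col]
        target_mean = float(vals[is_target].mean()) if is_target.any() else np.nan
        other_mean = float(vals[~is_target].mean()) if (~is_target).any() else np.nan
        p = mannwhitney_pvalue(vals[is_target], vals[~is_target])
        wts = incident.get(gene, [])
        attention = float(np.mean(wts)) if wts else 0.0
        rows.append(
            {
                "gene": gene,
                "node_attention": attention,
                "incident_sum": float(np.sum(wts)) if wts else 0.0,
                "group_mean_expression": target_mean,
                "other_mean_expression": other_mean,
                "mannwhitney_p": p,
                "importance": attention * target_mean,
                "no_incident_edges": not wts,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["importance", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class CoreSubgraph:
    """Connected, pruned core signaling subgraph with provenance."""

    graph: nx.Graph
    group: str
    xi: int
    epsilon: int
    p_threshold: float
    pruning_log: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        rows = [
            (u, v, d.get("weight", 0.0)) for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["gene_u", "gene_v", "weight"]).to_csv(
            path, sep="\t", index=False
        )

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def extract_core(
    scores: pd.DataFrame,
    group_table: pd.DataFrame,
    xi: int = XI_DEFAULT,
    epsilon: int = EPSILON_DEFAULT,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    group: str = "",
) -> CoreSubgraph:
    """Top-ξ induced subgraph, largest component, leaf pruning.

    Hubs are processed in decreasing degree order; a hub's leaves
    (degree-one neighbors) beyond ε are removed unless significant, keeping
    significant leaves first and then the highest-weight ones.  Every pruned
    hub therefore retains at least min(ε, available) leaves, and a
    significant leaf is never removed while a non-significant sibling stays.
    """
    if xi < 1 or epsilon < 0:
        raise TosgError("xi must be >= 1 and epsilon >= 0")
    if scores.empty:
        raise TosgError("empty score table")
    ranked = scores.sort_values(
        ["importance", "gene"], ascending=[False, True], kind="mergesort"
    )
    keep = set(ranked["gene"].head(xi))
    sig = dict(zip(scores["gene"], scores["mannwhitney_p"] < p_threshold))
    g = nx.Graph()
    g.add_nodes_from(keep)
    for u, v, w in zip(group_table["gene_u"], group_table["gene_v"], group_table["weight"]):
        if u in keep and v in keep:
            g.add_edge(u, v, weight=float(w))
    log: list[str] = []
    if g.number_of_nodes() == 0:
        return CoreSubgraph(g, group, xi, epsilon, p_threshold, log)
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    largest = components[0]
    dropped = g.number_of_nodes() - len(largest)
    if dropped:
        log.append(f"dropped {dropped} nodes outside the largest component")
    g = g.subgraph(largest).copy()
    hubs = sorted(g.nodes, key=lambda n: (-g.degree(n), n))
    for hub in hubs:
        if hub not in g:
            continue
        leaves = sorted(n for n in g.neighbors(hub) if g.degree(n) == 1)
        if len(leaves) <= epsilon:
            continue
        sig_leaves = [n for n in leaves if sig.get(n, False)]
        rest = [n for n in leaves if not sig.get(n, False)]
        rest.sort(key=lambda n: (-g[hub][n]["weight"], n))
        retained = sig_leaves + rest[: max(0, epsilon - len(sig_leaves))]
        removed = [n for n in leaves if n not in retained]
        for n in removed:
            g.remove_node(n)
        if removed:
            log.append(
                f"hub {hub}: pruned {len(removed)} of {len(leaves)} leaves, "
                f"kept {len(retained)} ({len(sig_leaves)} significant)"
            )
    # node attributes for export
    meta = scores.set_index("gene")
    for n in g.nodes:
        if n in meta.index:
            g.nodes[n]["importance"] = float(meta.loc[n, "importance"])
            g.nodes[n]["p_value"] = float(meta.loc[n, "mannwhitney_p"])
            g.nodes[n]["significant"] = bool(sig.get(n, False))
    return CoreSubgraph(g, group, xi, epsilon, p_threshold, log)
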