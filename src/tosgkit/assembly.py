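"""Meta-cell preprocessing and TOSG assembly.

Pipeline order: partition raw cells into bounded chunks → total-count
normalization (target 10,000) with log1p → highly-variable-gene selection →
PCA embedding + KNN graph → meta-cell aggregation (pluggable; built-in
k-means grouping) with majority-vote attributes → attribute harmonization
(synonym/fuzzy mapping, age parsing, sex normalization) → expansion of the
measured gene space onto the entity catalog with zero-filled virtual protein
nodes → sharded serialization with a CSV manifest.
"""

from __future__ import annotations

import difflib
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .data import CohortMatrix, EntityCatalog, MappingTables, TosgError, TosgTopology

__all__ = [
    "partition_cells",
    "normalize_counts",
    "select_hvg",
    "embed_and_neighbor",
    "kmeans_aggregator",
    "aggregate_metacells",
    "vote_attributes",
    "token_sort_ratio",
    "parse_age_years",
    "harmonize_attributes",
    "assemble_tosg",
    "serialize_shards",
    "load_shards",
]

NORM_TARGET = 10_000.0
DEFAULT_CELL_CAP = 50_000
DEFAULT_HVG = 1_500
DEFAULT_PCA_COMPONENTS = 50
DEFAULT_KNN = 15
DEFAULT_SHARD_CAPACITY = 10_000


def partition_cells(raw: CohortMatrix, cap: int = DEFAULT_CELL_CAP) -> list[CohortMatrix]:
    """Split a cohort row-wise into consecutive chunks of at most ``cap`` rows."""
    if cap < 1:
        raise TosgError("cap must be >= 1")
    n = raw.n_samples
    return [raw.take(np.arange(i, min(i + cap, n))) for i in range(0, n, cap)]


def normalize_counts(raw: CohortMatrix, target: float = NORM_TARGET) -> CohortMatrix:
    """Scale each cell to a fixed total, then log1p.

    All-zero rows pass through unchanged; negative entries are rejected.
    """
    X = np.asarray(raw.features, dtype=float)
    if (X < 0).any():
        raise TosgError("count matrix has negative entries")
    sums = X.sum(axis=1, keepdims=True)
    scale = np.divide(target, sums, out=np.ones_like(sums), where=sums > 0)
    out = np.log1p(X * scale)
    return CohortMatrix(
        features=out,
        columns=list(raw.columns),
        attributes=raw.attributes.copy(),
        labels=raw.labels,
        topology=raw.topology,
    )


def select_hvg(norm: CohortMatrix, k: int = DEFAULT_HVG) -> CohortMatrix:
    """Retain the k most variable genes of the normalized matrix.

    Dispersion statistic: variance of the log-normalized expression per gene.
    Ties are broken by gene identifier (ascending) for determinism.
    """
    m = norm.n_features
    if k > m:
        raise TosgError(f"k={k} exceeds gene count {m}")
    var = np.asarray(norm.features, dtype=float).var(axis=0)
    order = sorted(range(m), key=lambda j: (-var[j], norm.columns[j]))
    keep = sorted(order[:k])  # keep original column order
    return CohortMatrix(
        features=norm.features[:, keep],
        columns=[norm.columns[j] for j in keep],
        attributes=norm.attributes.copy(),
        labels=norm.labels,
        topology=norm.topology,
    )


def embed_and_neighbor(
    norm: CohortMatrix,
    n_components: int = DEFAULT_PCA_COMPONENTS,
    n_neighbors: int = DEFAULT_KNN,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA embedding and a KNN graph over cells.

    Returns ``(embedding, neighbors)`` where ``neighbors[i]`` lists the
    ``n_neighbors`` nearest cells to cell ``i`` in the embedding (self
    excluded, Euclidean metric).
    """
    X = np.asarray(norm.features, dtype=float)
    if n_components > min(X.shape):
        raise TosgError("n_components exceeds matrix rank bound")
    emb = PCA(n_components=n_components, svd_solver="full").fit_transform(X)
    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, len(emb))).fit(emb)
    _, idx = nn.kneighbors(emb)
    neigh = np.empty((len(emb), min(n_neighbors, len(emb) - 1)), dtype=int)
    for i in range(len(emb)):
        row = [j for j in idx[i] if j != i][: neigh.shape[1]]
        neigh[i] = row
    return emb, neigh


def kmeans_aggregator(
    embedding: np.ndarray, group_size: int, seed: int = 0
) -> list[np.ndarray]:
    """Built-in aggregator: k-means grouping with k = ceil(cells / group_size).

    Returns disjoint member index arrays covering all cells.  Any external
    aggregator with this signature can replace it.
    """
    n = len(embedding)
    k = max(1, math.ceil(n / group_size))
    if k == 1:
        return [np.arange(n)]
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(embedding)
    return [np.where(km.labels_ == c)[0] for c in range(k) if (km.labels_ == c).any()]


def aggregate_metacells(
    norm: CohortMatrix,
    embedding: np.ndarray,
    group_size: int,
    aggregator: Callable[[np.ndarray, int, int], list[np.ndarray]] | None = None,
    seed: int = 0,
) -> tuple[CohortMatrix, list[np.ndarray]]:
    """Aggregate cells into meta-cells.

    Meta-cell features are member means in normalized space; attributes are
    member majority votes (see :func:`vote_attributes`).  Returns the
    meta-cell cohort and the member index lists.
    """
    if group_size < 1:
        raise TosgError("group_size must be >= 1")
    agg = aggregator or kmeans_aggregator
    groups = agg(embedding, group_size, seed)
    seen: set[int] = set()
    for g in groups:
        overlap = seen.intersection(g.tolist())
        if overlap:
            raise TosgError("aggregator produced overlapping member groups")
        seen.update(g.tolist())
    feats = np.stack([norm.features[g].mean(axis=0) for g in groups])
    attrs = pd.DataFrame([vote_attributes(norm.attributes.iloc[g]) for g in groups])
    labels = None
    if norm.labels is not None:
        labels = np.array(
            [vote_attributes(pd.DataFrame({"label": norm.labels[g]}))["label"] for g in groups]
        )
    meta = CohortMatrix(
        features=feats, columns=list(norm.columns), attributes=attrs, labels=labels,
        topology=norm.topology,
    )
    return meta, groups


def vote_attributes(member_attributes: pd.DataFrame) -> dict:
    """Majority vote per categorical field; numeric fields averaged.

    Ties take the lexicographically smallest value, which is deterministic
    and independent of member order.
    """
    if len(member_attributes) == 0:
        raise TosgError("empty member set")
    out: dict = {}
    for col in member_attributes.columns:
        vals = member_attributes[col]
        if pd.api.types.is_numeric_dtype(vals):
            out[col] = float(vals.mean())
        else:
            counts = vals.astype(str).value_counts()
            top = counts[counts == counts.max()].index
            out[col] = sorted(top)[0]
    return out


_token_re = re.compile(r"[A-Za-z0-9]+")


def token_sort_ratio(a: str, b: str) -> float:
    """Similarity of two strings after lowercasing and token sorting, 0–100.

    Sequence matching is evaluated in both argument orders and the larger
    ratio taken, so the score is symmetric.
    """
    ta = " ".join(sorted(_token_re.findall(a.lower())))
    tb = " ".join(sorted(_token_re.findall(b.lower())))
    return 100.0 * max(
        difflib.SequenceMatcher(None, ta, tb).ratio(),
        difflib.SequenceMatcher(None, tb, ta).ratio(),
    )


_age_patterns: list[tuple[re.Pattern, float]] = [
    (re.compile(r"(\d+(?:\.\d+)?)\s*(?:-|\s)?\s*year", re.I), 1.0),
    (re.compile(r"(\d+(?:\.\d+)?)\s*(?:-|\s)?\s*month", re.I), 1.0 / 12.0),
    (re.compile(r"(\d+(?:\.\d+)?)\s*(?:-|\s)?\s*week", re.I), 1.0 / 52.0),
    (re.compile(r"(\d+(?:\.\d+)?)\s*(?:-|\s)?\s*day", re.I), 1.0 / 365.0),
]
_bare_number_re = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*$")


def parse_age_years(text: str) -> float | None:
    """Parse free-text development stage into numeric years.

    Understands years/months/weeks/days with optional hyphenation (e.g.
    ``"18 months"`` → 1.5, ``"73-year-old"`` → 73); a bare number is read as
    years.  Returns ``None`` when nothing parses.
    """
    if text is None:
        return None
    s = str(text)
    m = _bare_number_re.match(s)
    if m:
        return float(m.group(1))
    for pat, factor in _age_patterns:
        m = pat.search(s)
        if m:
            return float(m.group(1)) * factor
    return None


def _bin_age(years: float | None, bounds: list[tuple[str, float]]) -> str:
    if years is None:
        return "unknown"
    label = "unknown"
    for name, low in bounds:
        if years >= low:
            label = name
    return label


def _map_term(
    term: str, synonyms: dict[str, tuple[str, str]], tables: MappingTables
) -> tuple[str, str, float]:
    """Anchor → exact → fuzzy lookup; returns (canonical id, label, score)."""
    key = str(term).strip().lower()
    if key in (t.lower() for t in tables.ignore_terms):
        return "unknown", "unknown", float("nan")
    if key in {k.lower(): k for k in tables.anchor_rules}:
        cid, lab = tables.anchor_rules[{k.lower(): k for k in tables.anchor_rules}[key]]
        return cid, lab, 100.0
    low_syn = {s.lower(): v for s, v in synonyms.items()}
    if key in low_syn:
        cid, lab = low_syn[key]
        return cid, lab, 100.0
    if not synonyms:
        return "unknown", "unknown", float("nan")
    best_syn, best_score = None, -1.0
    for syn in sorted(synonyms):
        score = token_sort_ratio(key, syn)
        if score > best_score:
            best_syn, best_score = syn, score
    cid, lab = synonyms[best_syn]
    return cid, lab, best_score


@dataclass
class HarmonizationResult:
    attributes: pd.DataFrame
    report: pd.DataFrame  # original term, matched term, id, score, field


def harmonize_attributes(
    attributes: pd.DataFrame,
    tables: MappingTables,
    fuzzy_threshold: float = 100.0,
) -> HarmonizationResult:
    """Standardize cell-type/disease terms, development stage, and sex.

    Term mapping applies anchor rules, then exact synonym lookup, then
    token-sort-ratio fuzzy matching; matches scoring below
    ``fuzzy_threshold`` are applied but flagged in the review report.
    Development-stage text is parsed to numeric years and binned into the
    configured ordered age groups plus a coarse birth phase; sex tokens are
    normalized with unrecognized values set to ``unknown``.
    """
    out = attributes.copy().reset_index(drop=True)
    report_rows = []
    for field_name, syn in (
        ("cell_type", tables.cell_type_synonyms),
        ("disease_name", tables.disease_synonyms),
    ):
        if field_name not in out.columns:
            continue
        mapped_ids, mapped_labels = [], []
        for term in out[field_name].astype(str):
            cid, lab, score = _map_term(term, syn, tables)
            mapped_ids.append(cid)
            mapped_labels.append(lab)
            if not np.isnan(score) and score < fuzzy_threshold:
                report_rows.append(
                    {"field": field_name, "original": term, "matched": lab,
                     "id": cid, "score": score}
                )
        out[field_name + "_id"] = mapped_ids
        out[field_name] = mapped_labels
    if "development_stage" in out.columns:
        years = [parse_age_years(v) for v in out["development_stage"]]
        out["age_years"] = [np.nan if y is None else y for y in years]
        out["age_group"] = [_bin_age(y, tables.age_group_bounds) for y in years]
        out["birth_phase"] = [
            "unknown" if y is None else ("post-birth" if y >= 0 else "pre-birth")
            for y in years
        ]
    if "sex" in out.columns:
        out["sex"] = [
            tables.sex_map.get(str(v).strip().lower(), "unknown") for v in out["sex"]
        ]
    report = pd.DataFrame(
        report_rows, columns=["field", "original", "matched", "id", "score"]
    )
    return HarmonizationResult(attributes=out, report=report)


def assemble_tosg(
    meta: CohortMatrix,
    catalog: EntityCatalog,
    topo: TosgTopology,
    gene_map: pd.DataFrame,
) -> CohortMatrix:
    """Expand a measured-gene matrix onto the full entity catalog.

    ``gene_map`` has columns ``gene`` (measured column name) and ``entity_id``
    (transcript entity).  One gene may populate several transcript entities
    (columns duplicated); unmeasured transcript entities and all protein
    entities are zero-filled (virtual nodes).  The topology is attached
    unchanged.
    """
    if not {"gene", "entity_id"}.issubset(gene_map.columns):
        raise TosgError("gene_map needs 'gene' and 'entity_id' columns")
    known = set(catalog.entity_ids)
    unknown = set(gene_map["entity_id"]) - known
    if unknown:
        raise TosgError(f"gene_map references unknown entities: {sorted(unknown)[:5]}")
    col_of = {g: i for i, g in enumerate(meta.columns)}
    ent_pos = catalog.index_of()
    n = meta.n_samples
    X = np.zeros((n, catalog.size), dtype=float)
    for gene, eid in zip(gene_map["gene"], gene_map["entity_id"]):
        if gene in col_of:
            X[:, ent_pos[eid]] = meta.features[:, col_of[gene]]
    # protein columns remain zero by construction
    return CohortMatrix(
        features=X,
        columns=catalog.entity_ids,
        attributes=meta.attributes.copy(),
        labels=meta.labels,
        topology=topo,
    )


def serialize_shards(
    cohort: CohortMatrix,
    out_dir,
    shard_capacity: int = DEFAULT_SHARD_CAPACITY,
) -> pd.DataFrame:
    """Write the cohort as NumPy shards plus a CSV manifest.

    Each shard file ``x_{i}.npy`` holds at most ``shard_capacity`` rows; the
    manifest carries ``matrix_file_path`` and ``matrix_row_idx`` per sample
    alongside the attribute columns, and is written as ``manifest.csv``.
    """
    if shard_capacity < 1:
        raise TosgError("shard_capacity must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = cohort.n_samples
    paths, rows = [], []
    for si, start in enumerate(range(0, n, shard_capacity)):
        stop = min(start + shard_capacity, n)
        fname = f"x_{si}.npy"
        np.save(out / fname, cohort.features[start:stop])
        paths.extend([fname] * (stop - start))
        rows.extend(range(stop - start))
    manifest = cohort.attributes.copy()
    manifest["matrix_file_path"] = paths
    manifest["matrix_row_idx"] = rows
    if cohort.labels is not None:
        manifest["label"] = cohort.labels
    manifest.insert(0, "sample_idx", np.arange(n))
    manifest.to_csv(out / "manifest.csv", index=False)
    with open(out / "columns.txt", "w") as fh:
        fh.write("\n".join(cohort.columns))
    return manifest


def load_shards(out_dir) -> CohortMatrix:
    """Inverse of :func:`serialize_shards`; bit-exact feature round trip."""
    out = Path(out_dir)
    manifest = pd.read_csv(out / "manifest.csv")
    columns = (out / "columns.txt").read_text().splitlines()
    cache: dict[str, np.ndarray] = {}
    feats = np.empty((len(manifest), len(columns)))
    for i, (fp, ri) in enumerate(zip(manifest["matrix_file_path"], manifest["matrix_row_idx"])):
        if fp not in cache:
            cache[fp] = np.load(out / fp)
        feats[i] = cache[fp][ri]
    attr_cols = [
        c for c in manifest.columns
        if c not in ("sample_idx", "matrix_file_path", "matrix_row_idx", "label")
    ]
    labels = manifest["label"].to_numpy() if "label" in manifest.columns else None
    return CohortMatrix(
        features=feats,
        columns=columns,
        attributes=manifest[attr_cols].copy(),
        labels=labels,
    )
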