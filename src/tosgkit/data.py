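"""Core containers for text-omic signaling graphs (TOSGs).

A TOSG couples two entity classes — transcripts carrying measured expression
and proteins included as *virtual* nodes with zero-initialized features — with
two edge classes: directed internal transcript→protein edges and undirected
protein–protein interaction (PPI) edges.  These containers hold the entity
catalog (identifiers plus textual annotation), the edge topology, and the
sample × entity feature matrix with its per-sample attribute table.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TosgError",
    "EntityCatalog",
    "TosgTopology",
    "CohortMatrix",
    "MappingTables",
]

CATALOG_COLUMNS = ["entity_id", "kind", "name", "description", "sequence", "partner"]


class TosgError(ValueError):
    """Base error for invalid specs, inputs, or configurations."""


@dataclass
class EntityCatalog:
    """Catalog of transcript and protein entities with textual annotation.

    ``table`` has columns ``entity_id, kind, name, description, sequence,
    partner``; ``kind`` is ``transcript`` or ``protein``; ``partner`` links a
    transcript to its protein product (empty for proteins).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CATALOG_COLUMNS if c not in self.table.columns]
        if missing:
            raise TosgError(f"catalog missing columns: {missing}")
        if self.table["entity_id"].duplicated().any():
            raise TosgError("catalog entity_id values must be unique")
        bad_kind = set(self.table["kind"]) - {"transcript", "protein"}
        if bad_kind:
            raise TosgError(f"unknown entity kinds: {sorted(bad_kind)}")
        self.table = self.table.reset_index(drop=True)
        kinds = dict(zip(self.table["entity_id"], self.table["kind"]))
        for eid, kind, partner in zip(
            self.table["entity_id"], self.table["kind"], self.table["partner"]
        ):
            if kind == "transcript":
                if partner not in kinds or kinds[partner] != "protein":
                    raise TosgError(f"transcript {eid} has non-protein partner {partner!r}")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.table["entity_id"])

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.table.loc[self.table["kind"] == "transcript", "entity_id"])

    @property
    def protein_ids(self) -> list[str]:
        return list(self.table.loc[self.table["kind"] == "protein", "entity_id"])

    @property
    def size(self) -> int:
        return len(self.table)

    def index_of(self) -> dict[str, int]:
        """Map entity_id → position in catalog order."""
        return {eid: i for i, eid in enumerate(self.table["entity_id"])}

    def checksum(self) -> str:
        buf = io.StringIO()
        self.table.to_csv(buf, sep="\t", index=False)
        return hashlib.md5(buf.getvalue().encode()).hexdigest()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EntityCatalog":
        tab = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return cls(tab)


@dataclass
class TosgTopology:
    """Edge sets of a TOSG.

    ``internal_edges``: ordered (transcript_id, protein_id) pairs.
    ``ppi_edges``: unordered protein pairs, stored as sorted id tuples.
    The overall relation count is |internal| + |PPI|.
    """

    internal_edges: list[tuple[str, str]]
    ppi_edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.internal_edges = [tuple(e) for e in self.internal_edges]
        self.ppi_edges = [tuple(sorted(e)) for e in self.ppi_edges]
        if any(a == b for a, b in self.ppi_edges):
            raise TosgError("PPI self-loops are not allowed")
        if len(set(self.ppi_edges)) != len(self.ppi_edges):
            raise TosgError("duplicate PPI edges")
        if len(set(self.internal_edges)) != len(self.internal_edges):
            raise TosgError("duplicate internal edges")

    @property
    def n_edges(self) -> int:
        return len(self.internal_edges) + len(self.ppi_edges)

    def validate_against(self, catalog: EntityCatalog) -> None:
        kinds = dict(zip(catalog.table["entity_id"], catalog.table["kind"]))
        for t, p in self.internal_edges:
            if kinds.get(t) != "transcript" or kinds.get(p) != "protein":
                raise TosgError(f"internal edge ({t}, {p}) has wrong endpoint kinds")
        for a, b in self.ppi_edges:
            if kinds.get(a) != "protein" or kinds.get(b) != "protein":
                raise TosgError(f"PPI edge ({a}, {b}) has non-protein endpoint")

    def to_tsv(self, path) -> None:
        rows = [(s, t, "internal") for s, t in self.internal_edges]
        rows += [(a, b, "ppi") for a, b in self.ppi_edges]
        pd.DataFrame(rows, columns=["source_id", "target_id", "relation_class"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "TosgTopology":
        tab = pd.read_csv(path, sep="\t", dtype=str)
        internal = [
            (r.source_id, r.target_id)
            for r in tab.itertuples()
            if r.relation_class == "internal"
        ]
        ppi = [
            (r.source_id, r.target_id) for r in tab.itertuples() if r.relation_class == "ppi"
        ]
        return cls(internal, ppi)


@dataclass
class CohortMatrix:
    """Sample × entity feature matrix with aligned attributes and labels.

    ``features`` is an ``N × M`` nonnegative array whose columns follow
    ``columns``; ``attributes`` is an ``N``-row table; ``labels`` (optional)
    is an ``N``-vector; ``shard_pointers`` (optional) records
    ``matrix_file_path``/``matrix_row_idx`` provenance per sample.
    """

    features: np.ndarray
    columns: list[str]
    attributes: pd.DataFrame
    labels: np.ndarray | None = None
    shard_pointers: pd.DataFrame | None = None
    topology: TosgTopology | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if self.features.ndim != 2:
            raise TosgError("features must be a 2-D matrix")
        n, m = self.features.shape
        if len(self.columns) != m:
            raise TosgError("columns length does not match feature width")
        if len(self.attributes) != n:
            raise TosgError("attributes rows must align with feature rows")
        self.attributes = self.attributes.reset_index(drop=True)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise TosgError("labels must align with feature rows")
        if self.shard_pointers is not None and len(self.shard_pointers) != n:
            raise TosgError("shard_pointers must align with feature rows")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def take(self, rows) -> "CohortMatrix":
        """Row subset (positional), preserving alignment of all blocks."""
        rows = np.asarray(rows, dtype=int)
        return CohortMatrix(
            features=self.features[rows],
            columns=list(self.columns),
            attributes=self.attributes.iloc[rows].reset_index(drop=True),
            labels=None if self.labels is None else self.labels[rows],
            shard_pointers=None
            if self.shard_pointers is None
            else self.shard_pointers.iloc[rows].reset_index(drop=True),
            topology=self.topology,
        )

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=np.asarray(self.features, dtype=float),
            obs=self.attributes.copy(),
            var=pd.DataFrame(index=pd.Index(self.columns, name="feature")),
        )

    @classmethod
    def from_anndata(cls, adata) -> "CohortMatrix":
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = X.toarray()
        return cls(
            features=np.asarray(X),
            columns=list(adata.var_names),
            attributes=adata.obs.reset_index(drop=True),
        )


# Default MeSH-style age bins: (label, inclusive lower bound in years).
DEFAULT_AGE_GROUP_BOUNDS: list[tuple[str, float]] = [
    ("infant", 0.0),
    ("child", 2.0),
    ("adolescent", 13.0),
    ("adult", 19.0),
    ("middle aged", 45.0),
    ("aged", 65.0),
]

DEFAULT_SEX_MAP = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
}

DEFAULT_IGNORE_TERMS = ["unknown", "unclassified", "na", "n/a", "none", ""]


@dataclass
class MappingTables:
    """Harmonization dictionaries: synonym → canonical (id, label) plus rules.

    ``anchor_rules`` are exact overrides applied before any lookup;
    ``ignore_terms`` are placeholders that pass through as ``unknown``;
    ``age_group_bounds`` is an ordered list of (label, lower bound in years).
    """

    cell_type_synonyms: dict[str, tuple[str, str]] = field(default_factory=dict)
    disease_synonyms: dict[str, tuple[str, str]] = field(default_factory=dict)
    anchor_rules: dict[str, tuple[str, str]] = field(default_factory=dict)
    ignore_terms: list[str] = field(default_factory=lambda: list(DEFAULT_IGNORE_TERMS))
    age_group_bounds: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_AGE_GROUP_BOUNDS)
    )
    sex_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SEX_MAP))

    def __post_init__(self) -> None:
        lows = [b for _, b in self.age_group_bounds]
        if any(b <= a for a, b in zip(lows, lows[1:])):
            raise TosgError("age_group_bounds must have strictly increasing lower bounds")
        for tab in (self.cell_type_synonyms, self.disease_synonyms):
            labels = {}
            for syn, (cid, lab) in tab.items():
                if cid in labels and labels[cid] != lab:
                    raise TosgError(f"canonical id {cid} mapped to conflicting labels")
                labels[cid] = lab
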