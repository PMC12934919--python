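"""Synthetic TOSG generator with known ground truth.

Every downstream stage — assembly, cohort retrieval, pretraining, downstream
classification and core-subgraph inference — is exercised on data from this
module.  It emulates the statistical structure those stages assume: a small
entity catalog with transcript→protein links, a community-structured PPI
network, and a cohort whose transcript features carry planted group effects
on protein modules, plus an attribute table with the retrieval metadata
fields (cell type, tissue, disease, sex, ordered age stage, donor, source).

The generative choices (Poisson counts, Gaussian noise clipped at zero,
round-robin transcript→protein multiplicity) are deliberately simple
stand-ins; see ``docs/methods.md`` for what they do and do not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CohortMatrix, EntityCatalog, TosgTopology, TosgError

__all__ = [
    "GroupSpec",
    "SyntheticSpec",
    "make_catalog",
    "make_ppi",
    "make_cohort",
    "make_raw_cells",
    "write_ground_truth",
]

RNA_ALPHABET = "ACGU"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_AGE_STAGES = ["infant", "child", "adolescent", "adult", "middle aged", "aged"]


@dataclass
class GroupSpec:
    """One sample group: a label, its cohort fraction, and a planted effect.

    ``planted_module`` lists protein entity ids whose upstream transcripts are
    shifted by ``effect_size`` (in units of the normalized feature scale) for
    samples of this group.
    """

    label: str
    fraction: float
    planted_module: list[str] = field(default_factory=list)
    effect_size: float = 0.0


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic TOSG world.

    Defaults describe the desk-scale study condition used throughout the
    package: a 5-community PPI network over 300 proteins (intra/inter edge
    probabilities 0.3/0.01, giving ≈3,000 PPI edges), 600 transcripts, and a
    200-sample two-group cohort whose disease group up-shifts a planted
    protein module by 2 normalized units against unit Gaussian noise.
    """

    n_transcripts: int = 600
    n_proteins: int = 300
    ppi_model: str = "community"  # "community" | "scale_free"
    n_communities: int = 5
    intra_edge_prob: float = 0.3
    inter_edge_prob: float = 0.01
    n_samples: int = 200
    groups: list[GroupSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline: float = 1.0
    age_stages: list[str] = field(default_factory=lambda: list(DEFAULT_AGE_STAGES))
    sex_values: list[str] = field(default_factory=lambda: ["female", "male"])
    n_donors: int = 20
    sources: list[str] = field(default_factory=lambda: ["src_a", "src_b"])
    tissues: list[str] = field(default_factory=lambda: ["brain", "lung"])
    cell_types: list[str] = field(default_factory=lambda: ["neuron", "astrocyte"])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0 or self.n_proteins <= 0:
            raise TosgError("entity counts must be positive")
        if self.n_transcripts < self.n_proteins:
            raise TosgError("need n_transcripts >= n_proteins for a surjective mapping")
        if self.n_samples <= 0 or self.n_donors <= 0:
            raise TosgError("n_samples and n_donors must be positive")
        for p in (self.intra_edge_prob, self.inter_edge_prob):
            if not 0.0 <= p <= 1.0:
                raise TosgError("edge probabilities must lie in [0, 1]")
        if self.ppi_model not in ("community", "scale_free"):
            raise TosgError(f"unknown ppi_model {self.ppi_model!r}")
        if self.n_communities <= 0:
            raise TosgError("n_communities must be positive")
        if self.noise_sd < 0:
            raise TosgError("noise_sd must be nonnegative")
        if not self.groups:
            # Default study condition: balanced control vs disease with a
            # 30-protein module planted in the first community.
            module = [f"p{i:04d}" for i in range(min(30, self.n_proteins))]
            self.groups = [
                GroupSpec("control", 0.5, [], 0.0),
                GroupSpec("disease", 0.5, module, 2.0),
            ]
        total = sum(g.fraction for g in self.groups)
        if abs(total - 1.0) > 1e-9:
            raise TosgError("group fractions must sum to 1")


def _protein_id(i: int) -> str:
    return f"p{i:04d}"


def _transcript_id(i: int) -> str:
    return f"t{i:04d}"


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def make_catalog(spec: SyntheticSpec) -> EntityCatalog:
    """Build a catalog of Mt transcripts and Mp proteins.

    Transcript i is linked to protein ``i mod Mp`` (round-robin), which is
    surjective whenever Mt >= Mp.  Names, descriptions and sequences are
    synthetic but deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for j in range(spec.n_proteins):
        pid = _protein_id(j)
        rows.append(
            {
                "entity_id": pid,
                "kind": "protein",
                "name": f"PROT{j}",
                "description": f"synthetic protein entity number {j}",
                "sequence": _random_seq(rng, AA_ALPHABET, 30),
                "partner": "",
            }
        )
    for i in range(spec.n_transcripts):
        tid = _transcript_id(i)
        rows.append(
            {
                "entity_id": tid,
                "kind": "transcript",
                "name": f"GENE{i}-201",
                "description": f"synthetic transcript entity number {i}",
                "sequence": _random_seq(rng, RNA_ALPHABET, 60),
                "partner": _protein_id(i % spec.n_proteins),
            }
        )
    return EntityCatalog(pd.DataFrame(rows))


def _community_of(spec: SyntheticSpec, j: int) -> int:
    size = -(-spec.n_proteins // spec.n_communities)  # ceil
    return j // size


def make_ppi(spec: SyntheticSpec, catalog: EntityCatalog) -> TosgTopology:
    """Sample the PPI edge set and attach the internal transcript→protein edges.

    ``community``: proteins split into ``n_communities`` contiguous blocks;
    each unordered pair is an edge with ``intra_edge_prob`` inside a block and
    ``inter_edge_prob`` across blocks.  ``scale_free``: Barabási–Albert
    preferential attachment.
    """
    rng = np.random.default_rng(spec.seed + 1)
    proteins = catalog.protein_ids
    mp = len(proteins)
    ppi: list[tuple[str, str]] = []
    if spec.ppi_model == "community":
        comm = np.array([_community_of(spec, j) for j in range(mp)])
        iu, ju = np.triu_indices(mp, k=1)
        probs = np.where(comm[iu] == comm[ju], spec.intra_edge_prob, spec.inter_edge_prob)
        keep = rng.random(len(probs)) < probs
        ppi = [(proteins[a], proteins[b]) for a, b in zip(iu[keep], ju[keep])]
    else:
        import networkx as nx

        m_attach = max(1, int(round(spec.intra_edge_prob * 10)))
        g = nx.barabasi_albert_graph(mp, m_attach, seed=int(rng.integers(2**31)))
        ppi = [(proteins[a], proteins[b]) for a, b in g.edges()]
    # internal edges are exactly the catalog's transcript→protein links
    tt = catalog.table[catalog.table["kind"] == "transcript"]
    internal = list(zip(tt["entity_id"], tt["partner"]))
    topo = TosgTopology(internal_edges=internal, ppi_edges=ppi)
    topo.validate_against(catalog)
    return topo


def _module_transcripts(catalog: EntityCatalog, module: list[str]) -> list[str]:
    known = set(catalog.protein_ids)
    for pid in module:
        if pid not in known:
            raise TosgError(f"planted module references unknown protein {pid!r}")
    mod = set(module)
    tt = catalog.table[catalog.table["kind"] == "transcript"]
    return [t for t, p in zip(tt["entity_id"], tt["partner"]) if p in mod]


def make_cohort(
    spec: SyntheticSpec, topo: TosgTopology, catalog: EntityCatalog | None = None
) -> CohortMatrix:
    """Generate the N × M cohort with planted group effects.

    Transcript features are ``baseline + effect + noise`` clipped at zero,
    where the effect applies to transcripts whose partner protein lies in the
    sample group's planted module.  Protein columns are all zero (virtual
    nodes).  Attributes are drawn per schema with donors reused across
    samples; labels are the group labels, row-aligned.
    """
    if catalog is None:
        catalog = make_catalog(spec)
    rng = np.random.default_rng(spec.seed + 2)
    entity_ids = catalog.entity_ids
    kinds = np.array(catalog.table["kind"])
    t_mask = kinds == "transcript"
    n, m = spec.n_samples, len(entity_ids)

    # group assignment by fractions, exact counts with remainder to the last
    counts = [int(round(g.fraction * n)) for g in spec.groups]
    counts[-1] = n - sum(counts[:-1])
    group_idx = np.repeat(np.arange(len(spec.groups)), counts)

    col_of = {e: i for i, e in enumerate(entity_ids)}
    X = np.zeros((n, m), dtype=float)
    base = np.full(t_mask.sum(), float(spec.baseline))
    t_cols = np.where(t_mask)[0]
    for gi, g in enumerate(spec.groups):
        rows = np.where(group_idx == gi)[0]
        shift = np.zeros(m)
        for tid in _module_transcripts(catalog, g.planted_module):
            shift[col_of[tid]] = g.effect_size
        vals = base[None, :] + shift[t_cols][None, :]
        noise = rng.normal(0.0, spec.noise_sd, size=(len(rows), len(t_cols)))
        X[np.ix_(rows, t_cols)] = np.clip(vals + noise, 0.0, None)

    donors = np.array([f"donor{rng.integers(spec.n_donors):03d}" for _ in range(n)])
    ages = rng.choice(spec.age_stages, size=n)
    attrs = pd.DataFrame(
        {
            "cell_type": rng.choice(spec.cell_types, size=n),
            "tissue_general": rng.choice(spec.tissues, size=n),
            "tissue_fine": rng.choice(spec.tissues, size=n),
            "disease_name": [spec.groups[gi].label for gi in group_idx],
            "sex": rng.choice(spec.sex_values, size=n),
            "age_group": ages,
            "age_years": rng.uniform(0, 90, size=n).round(1),
            "birth_phase": "post-birth",
            "donor": donors,
            "source": rng.choice(spec.sources, size=n),
            "suspension_type": "cell",
        }
    )
    labels = np.array([spec.groups[gi].label for gi in group_idx])
    return CohortMatrix(
        features=X, columns=entity_ids, attributes=attrs, labels=labels, topology=topo
    )


def make_raw_cells(
    spec: SyntheticSpec, n_cells: int | None = None, n_genes: int | None = None,
    mean: float = 5.0,
) -> CohortMatrix:
    """Integer count matrix emulating pre-normalization input.

    Counts are Poisson with the given mean — the simplest nonnegative integer
    model with a controllable expectation.  Gene columns are named ``gene{i}``
    and the attribute table follows the same schema as :func:`make_cohort`.
    """
    rng = np.random.default_rng(spec.seed + 3)
    n = spec.n_samples if n_cells is None else int(n_cells)
    g = spec.n_transcripts if n_genes is None else int(n_genes)
    X = rng.poisson(mean, size=(n, g)).astype(float)
    attrs = pd.DataFrame(
        {
            "cell_type": rng.choice(spec.cell_types, size=n),
            "tissue_general": rng.choice(spec.tissues, size=n),
            "tissue_fine": rng.choice(spec.tissues, size=n),
            "disease_name": "control",
            "sex": rng.choice(spec.sex_values, size=n),
            "age_group": rng.choice(spec.age_stages, size=n),
            "age_years": rng.uniform(0, 90, size=n).round(1),
            "birth_phase": "post-birth",
            "donor": [f"donor{rng.integers(spec.n_donors):03d}" for _ in range(n)],
            "source": rng.choice(spec.sources, size=n),
            "suspension_type": "cell",
        }
    )
    return CohortMatrix(
        features=X, columns=[f"gene{i}" for i in range(g)], attributes=attrs
    )


def write_ground_truth(spec: SyntheticSpec, path) -> None:
    """JSON sidecar recording the planted structure for later checking."""
    payload = {
        "seed": spec.seed,
        "n_transcripts": spec.n_transcripts,
        "n_proteins": spec.n_proteins,
        "ppi_model": spec.ppi_model,
        "n_communities": spec.n_communities,
        "groups": [
            {
                "label": g.label,
                "fraction": g.fraction,
                "planted_module": list(g.planted_module),
                "effect_size": g.effect_size,
            }
            for g in spec.groups
        ],
        "noise_sd": spec.noise_sd,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
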