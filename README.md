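# tosgkit

Text-omic signaling graphs for single-cell transcriptomics: graph assembly,
stratified cohort retrieval, masked-edge graph pretraining, downstream
cell-level classification, and interpretable core-signaling-subgraph
inference — runnable end to end on synthetic data at desk scale.

## The problem

Single-cell expression matrices describe cells as flat vectors, discarding
what is known about how the measured molecules interact. A **text-omic
signaling graph (TOSG)** re-expresses each cell (or meta-cell) over a
knowledge graph: transcript nodes carry measured expression, *virtual*
protein nodes are zero-initialized, directed internal edges link each
transcript to its protein product, and undirected protein–protein
interaction (PPI) edges carry signaling structure, so that
|E| = |E_in| + |E_PPI|. Every entity additionally carries frozen text
annotations (name, description, sequence) embedded by a pluggable language
encoder.

`tosgkit` implements the full computational path around that object:

- **graph assembly** — partitioning raw cells, total-count normalization to
  10,000 with log1p, top-1,500 highly-variable-gene selection, PCA + KNN,
  pluggable meta-cell aggregation with majority-vote attributes, synonym /
  fuzzy-match attribute harmonization, expansion onto an entity catalog,
  and sharded NumPy serialization with a CSV manifest;
- **stratified retrieval** — a two-phase algorithm: conjunctive attribute
  filtering R(q) = {x : ∀(a, V_a) ∈ q, u_a(x) ∈ V_a}, then per-stratum
  case–control matching exact on all covariates except an ordered age-stage
  key, whose rank offset is bounded by a tolerance δ; retained strata have
  equal case and control counts by construction;
- **pretraining** — PPI edges are masked with Bernoulli(p); a two-stage
  graph encoder (internal transcript→protein aggregation, then global
  message passing over visible edges) is trained to reconstruct held-out
  edges with a symmetric decoder σ(MLP(h_i ⊙ h_j)) against sampled
  non-edges, jointly with a node-degree regression that calibrates
  centrality: L = λ_e·L_edge + λ_d·L_deg;
- **downstream tasks** — donor-level train/test splits (no donor straddles
  the boundary) and seeded classifiers on pooled entity embeddings;
- **interpretation** — attention affinities restricted to the PPI topology,
  aggregated per cohort group into undirected gene-pair weights; node
  importance = mean incident attention × group mean expression (with
  Mann–Whitney U significance), and a core subgraph: top-ξ genes, largest
  connected component, leaf pruning that preserves ≥ ε leaves per hub.

The synthetic module generates catalogs, community-structured PPI networks,
and cohorts with planted group effects so every stage is testable without
downloading anything. See `docs/methods.md` for the models, defaults, and
design rationale.

## Worked example

```python
import tosgkit as tk
from tosgkit.encoder import encode_text
from tosgkit.pretrain import (
    PretrainConfig, PretrainState, sample_edge_mask, train,
    evaluate_reconstruction,
)

spec = tk.SyntheticSpec(seed=42)          # 300 proteins, 5 communities,
catalog = tk.make_catalog(spec)           # 600 transcripts, 200 samples
topo = tk.make_ppi(spec, catalog)
cohort = tk.make_cohort(spec, topo, catalog)

cfg = PretrainConfig(seed=42)
state = PretrainState(config=cfg, catalog=catalog,
                      text=encode_text(catalog, width=cfg.d_prime))
plan = sample_edge_mask(topo, p=0.1, seed=42)
trace = train(state, cohort, topo, plan, epochs=600)
rate, auc = evaluate_reconstruction(state, cohort, topo, plan, seed=42)
print(f"PPI edges {len(topo.ppi_edges)} (masked {len(plan.masked)}); "
      f"final loss {trace[-1]:.4f}; "
      f"masked-edge AUC {auc:.3f}; reconstruction {100 * rate:.1f}%")
```

Output (about three minutes on one CPU):

```
PPI edges 2988 (masked 293); final loss 0.6745; masked-edge AUC 0.859; reconstruction 88.7%
```

The 2,988 PPI edges arise from the 5-community topology (intra/inter edge
probabilities 0.3/0.01); 293 of them were masked for reconstruction. The
AUC says masked edges are ranked above sampled non-edges 86% of the time;
the reconstruction rate says 88.7% of masked edges receive a predicted
edge probability above one half. A shell interface wraps the same pipeline
(`tosgkit synth | assemble | load | pretrain | finetune | interpret`); run
`tosgkit --help`.

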