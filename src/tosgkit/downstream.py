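"""Downstream adaptation: cell-level classification with donor-level splits.

The pretrained encoder stack is carried over as a transferable
initialization: the downstream stack copies every pretrained component whose
shape matches and embeds cohorts over the full (unmasked) topology.  The
per-sample entity embeddings (N × M × d) are pooled (mean by default) and fed
to a linear classifier with softmax-normalized scores, trained with
cross-entropy.  Train/test splits assign whole donors to one side so no
donor's cells leak across the partition.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor
from .data import CohortMatrix, TosgError, TosgTopology
from .pretrain import PretrainState, propagate

__all__ = [
    "SplitPlan",
    "DownstreamHead",
    "embed_cohort",
    "donor_split",
    "finetune",
    "predict",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """Donor-disjoint train/test partition (positional row indices)."""

    train_rows: np.ndarray
    test_rows: np.ndarray
    split_key: str = "donor"
    realized_test_fraction: float = 0.0


def embed_cohort(
    state: PretrainState,
    cohort: CohortMatrix,
    topo: TosgTopology,
    batch_size: int = 32,
) -> np.ndarray:
    """Entity embeddings for every sample from the pretrained stack.

    Returns an N × M × d array; runs over the full topology with no mask and
    never touches labels.  Batched to bound memory; batching does not change
    the result because samples are independent in the forward pass.
    """
    if cohort.n_features != state.catalog.size:
        raise TosgError("cohort feature width does not match the model catalog")
    out = []
    for start in range(0, cohort.n_samples, batch_size):
        X = cohort.features[start:start + batch_size]
        out.append(propagate(state, X, topo, plan=None).data)
    return np.concatenate(out, axis=0)


def donor_split(
    cohort: CohortMatrix,
    test_fraction_band: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
    split_key: str = "donor",
) -> SplitPlan:
    """Assign whole donors to train or test.

    Donors are shuffled under the seed and accumulated into the test side
    until the realized sample fraction enters the band; if donor granularity
    makes the band unreachable, the nearest achievable fraction is used with
    a warning.  A single donor cannot be split.
    """
    if split_key not in cohort.attributes.columns:
        raise TosgError(f"split key {split_key!r} not in attributes")
    lo, hi = test_fraction_band
    donors = cohort.attributes[split_key].astype(str)
    unique = sorted(donors.unique())
    if len(unique) < 2:
        raise TosgError("cannot split a single-donor cohort by donor")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(unique))
    n = cohort.n_samples
    sizes = donors.value_counts()
    best_set: list[str] = []
    best_frac = 0.0
    test_set: list[str] = []
    count = 0
    for d in order:
        candidate = count + sizes[d]
        if len(test_set) + 1 == len(unique):
            break  # keep at least one donor in training
        test_set.append(d)
        count = candidate
        frac = count / n
        if abs(frac - np.clip(frac, lo, hi)) < abs(best_frac - np.clip(best_frac, lo, hi)):
            best_set, best_frac = list(test_set), frac
        if frac >= lo:
            break
    frac = count / n
    if not (lo <= frac <= hi):
        # fall back to the closest fraction seen while accumulating
        if best_set and abs(best_frac - np.clip(best_frac, lo, hi)) < abs(
            frac - np.clip(frac, lo, hi)
        ):
            test_set, frac = best_set, best_frac
        logger.warning(
            "donor granularity cannot realize test fraction in [%.2f, %.2f]; using %.3f",
            lo, hi, frac,
        )
    mask = donors.isin(test_set).to_numpy()
    return SplitPlan(
        train_rows=np.where(~mask)[0],
        test_rows=np.where(mask)[0],
        split_key=split_key,
        realized_test_fraction=frac,
    )


@dataclass
class DownstreamHead:
    """Pooling + linear classifier over pooled entity embeddings.

    ``task`` is one of cell_type / disease_status / sex; ``pooling`` reduces
    the entity axis (``mean`` or ``max``).  The classifier is trained by
    :func:`finetune`; scores are softmax-normalized.
    """

    task: str
    classes: list[str] = field(default_factory=list)
    pooling: str = "mean"
    seed: int = 0
    W: Tensor | None = None
    b: Tensor | None = None

    def pool(self, embeddings: np.ndarray) -> np.ndarray:
        if self.pooling == "mean":
            return embeddings.mean(axis=1)
        if self.pooling == "max":
            return embeddings.max(axis=1)
        raise TosgError(f"unknown pooling {self.pooling!r}")

    @property
    def trained(self) -> bool:
        return self.W is not None


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def finetune(
    head: DownstreamHead,
    embeddings: np.ndarray,
    labels: np.ndarray,
    split: SplitPlan,
    epochs: int = 200,
    learning_rate: float = 0.05,
) -> dict:
    """Train the classifier on training rows; report test metrics.

    Cross-entropy with softmax normalization, full-batch Adam, seeded and
    deterministic.  Raises when the training rows contain fewer than two
    classes.  Returns accuracy and the per-class confusion table on the test
    rows.
    """
    labels = np.asarray(labels).astype(str)
    train_y = labels[split.train_rows]
    classes = sorted(set(train_y))
    if len(classes) < 2:
        raise TosgError("degenerate task: training labels contain a single class")
    head.classes = classes
    cls_idx = {c: i for i, c in enumerate(classes)}
    pooled = head.pool(embeddings)
    # standardize pooled features on the training rows only
    mu = pooled[split.train_rows].mean(axis=0)
    sd = pooled[split.train_rows].std(axis=0) + 1e-8
    pooled = (pooled - mu) / sd
    head._norm = (mu, sd)  # type: ignore[attr-defined]
    Xtr = pooled[split.train_rows]
    ytr = np.array([cls_idx[c] for c in train_y])
    onehot = np.eye(len(classes))[ytr]
    rng = np.random.default_rng(head.seed)
    d = Xtr.shape[1]
    head.W = Tensor(0.01 * rng.standard_normal((d, len(classes))), requires_grad=True)
    head.b = Tensor(np.zeros(len(classes)), requires_grad=True)
    opt = Adam({"W": head.W, "b": head.b}, lr=learning_rate)
    xt = Tensor(Xtr)
    for _ in range(epochs):
        z = xt @ head.W + head.b.reshape(1, -1)
        zmax = z.data.max(axis=1, keepdims=True)  # constant shift for stability
        zs = z - zmax
        lse = zs.exp().sum(axis=1, keepdims=True).log()
        logp = zs - lse
        loss = -(logp * onehot).sum(axis=1).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    pred_labels, _ = predict(head, embeddings, _pooled=pooled)
    test_true = labels[split.test_rows]
    test_pred = pred_labels[split.test_rows]
    all_classes = sorted(set(labels))
    conf = pd.crosstab(
        pd.Series(test_true, name="true"), pd.Series(test_pred, name="pred"),
        dropna=False,
    ).reindex(index=all_classes, columns=classes, fill_value=0)
    return {
        "accuracy": float((test_pred == test_true).mean()),
        "confusion": conf,
        "n_train": int(len(split.train_rows)),
        "n_test": int(len(split.test_rows)),
    }


def predict(
    head: DownstreamHead, embeddings: np.ndarray, _pooled: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and softmax scores per sample (scores sum to one)."""
    if not head.trained:
        raise TosgError("head is untrained; call finetune first")
    if _pooled is None:
        pooled = head.pool(embeddings)
        mu, sd = head._norm  # type: ignore[attr-defined]
        pooled = (pooled - mu) / sd
    else:
        pooled = _pooled
    scores = _softmax(pooled @ head.W.data + head.b.data)
    idx = scores.argmax(axis=1)
    return np.array([head.classes[i] for i in idx]), scores
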