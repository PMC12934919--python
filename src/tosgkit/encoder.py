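"""Fused entity representations from textual priors and omic features.

Each entity carries three frozen text embeddings (name, description,
biochemical sequence) produced by a pluggable encoder, plus a per-sample
scalar omic feature lifted to d' dimensions by a shared trainable affine map.
A cross-modality fusion step concatenates the four blocks and projects back
to d' with a trainable affine map.  Text embeddings are computed once and
never updated during training; a disk cache keyed by the catalog checksum
avoids recomputation.

The built-in text encoder is a deterministic hashed bag-of-tokens stub: each
token is mapped to a fixed pseudo-random vector derived from its MD5 digest,
and a text embeds as the mean of its token vectors (zero vector for empty
text).  It preserves the property the rest of the pipeline relies on —
distinct text generally yields distinct embeddings — without any model
download.  RNA sequences are normalized to the U alphabet (T→U) before
encoding.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ._autodiff import Tensor, concat
from .data import EntityCatalog, TosgError

__all__ = [
    "TextEmbeddings",
    "HashedTextEncoder",
    "encode_text",
    "OmicEncoder",
    "CrossFusion",
]

D_PRIME_DEFAULT = 64
D_DEFAULT = 32


@dataclass
class TextEmbeddings:
    """Frozen per-entity text blocks, each M × d'."""

    name_block: np.ndarray
    description_block: np.ndarray
    sequence_block: np.ndarray

    def __post_init__(self) -> None:
        shapes = {b.shape for b in (self.name_block, self.description_block, self.sequence_block)}
        if len(shapes) != 1:
            raise TosgError("text blocks must share one shape")

    @property
    def width(self) -> int:
        return self.name_block.shape[1]

    def checksum(self) -> str:
        h = hashlib.md5()
        for b in (self.name_block, self.description_block, self.sequence_block):
            h.update(np.ascontiguousarray(b).tobytes())
        return h.hexdigest()


class HashedTextEncoder:
    """Deterministic hashed bag-of-tokens text encoder (see module docstring)."""

    def __init__(self, width: int = D_PRIME_DEFAULT, seed: int = 0):
        self.width = width
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        if token not in self._cache:
            digest = hashlib.md5(f"{self.seed}:{token}".encode()).digest()
            rng = np.random.default_rng(int.from_bytes(digest[:4], "little"))
            self._cache[token] = rng.standard_normal(self.width)
        return self._cache[token]

    def __call__(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.width))
        for i, text in enumerate(texts):
            tokens = str(text).split()
            if tokens:
                out[i] = np.mean([self._token_vector(t) for t in tokens], axis=0)
        return out


def _rna_normalize(seq: str) -> str:
    return str(seq).upper().replace("T", "U")


def encode_text(
    catalog: EntityCatalog,
    encoder: Callable[[Sequence[str]], np.ndarray] | None = None,
    cache_dir=None,
    width: int = D_PRIME_DEFAULT,
) -> TextEmbeddings:
    """Encode entity names, descriptions, and sequences into frozen blocks.

    Transcript sequences have T substituted by U before encoding.  When
    ``cache_dir`` is given, blocks are cached keyed by the catalog checksum
    and reloaded on identical inputs.
    """
    if encoder is None:
        encoder = HashedTextEncoder(width=width)
    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"text_{catalog.checksum()}.npz"
        if cache_path.exists():
            z = np.load(cache_path)
            return TextEmbeddings(z["name"], z["description"], z["sequence"])
    tab = catalog.table
    seqs = [
        _rna_normalize(s) if k == "transcript" else str(s)
        for s, k in zip(tab["sequence"], tab["kind"])
    ]
    emb = TextEmbeddings(
        name_block=encoder(list(tab["name"])),
        description_block=encoder(list(tab["description"])),
        sequence_block=encoder(seqs),
    )
    if emb.name_block.shape != (catalog.size, emb.width):
        raise TosgError("encoder output width mismatch")
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(
            cache_path,
            name=emb.name_block,
            description=emb.description_block,
            sequence=emb.sequence_block,
        )
    return emb


class OmicEncoder:
    """Shared affine lift of per-entity scalars to d' dimensions.

    ``encode(X)`` maps an N × M matrix to an N × M × d' tensor via
    ``X[..., None] * w + b`` with trainable ``w, b`` of width d'.
    """

    def __init__(self, width: int = D_PRIME_DEFAULT, seed: int = 0, zero_init: bool = False):
        rng = np.random.default_rng(seed)
        scale = 0.0 if zero_init else 1.0
        self.w = Tensor(scale * rng.standard_normal(width) / np.sqrt(width),
                        requires_grad=True)
        self.b = Tensor(np.zeros(width), requires_grad=True)

    @property
    def params(self) -> dict[str, Tensor]:
        return {"omic.w": self.w, "omic.b": self.b}

    def encode(self, features: np.ndarray) -> Tensor:
        X = np.asarray(features, dtype=float)
        if not np.isfinite(X).all():
            raise TosgError("omic features must be finite")
        x = Tensor(X[..., None])  # N × M × 1
        return x * self.w.reshape(1, 1, -1) + self.b.reshape(1, 1, -1)


class CrossFusion:
    """Concatenate-project fusion of omic and text blocks.

    ``fuse`` concatenates [omic, name, description, sequence] per entity
    (width 4d') and applies a trainable affine projection back to d'.
    ``identity_init=True`` starts as the identity on the omic slots with the
    text slots zero-weighted, so an untrained fusion passes omic embeddings
    through unchanged.
    """

    def __init__(self, width: int = D_PRIME_DEFAULT, seed: int = 0,
                 identity_init: bool = True):
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((4 * width, width)) / np.sqrt(4 * width)
        if identity_init:
            W[:] = 0.0
            W[:width, :] = np.eye(width)
            W[width:] = 0.1 * rng.standard_normal((3 * width, width)) / np.sqrt(width)
        self.W = Tensor(W, requires_grad=True)
        self.b = Tensor(np.zeros(width), requires_grad=True)
        self.width = width

    @property
    def params(self) -> dict[str, Tensor]:
        return {"fuse.W": self.W, "fuse.b": self.b}

    def fuse(self, omic: Tensor, text: TextEmbeddings) -> Tensor:
        n, m, dp = omic.shape
        if text.name_block.shape != (m, dp):
            raise TosgError("omic/text shape mismatch")
        blocks = [omic]
        for block in (text.name_block, text.description_block, text.sequence_block):
            t = Tensor(np.broadcast_to(block[None, :, :], (n, m, dp)).copy())
            blocks.append(t)
        fused = concat(blocks, axis=-1)  # N × M × 4d'
        return fused @ self.W + self.b.reshape(1, 1, -1)
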