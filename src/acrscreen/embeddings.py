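"""Per-protein embedding vectors behind a uniform backend interface.

A protein language model summarizes a sequence as one fixed-width real
vector (default 1280 components, the width of large ESM-style models).
Three backends share the ``embed`` contract:

``table``
    Lookup of precomputed vectors by protein id from a TSV file.
``stub``
    A deterministic pseudo-random vector seeded from a stable hash of the
    sequence bytes; reproducible across processes and platforms, with
    components in [-1, 1]. Used by the test suite and the synthetic data
    generator.
``esm``
    A real pretrained-language-model backend. Loading it requires the
    model weights and the fair-esm package; when unavailable the backend
    raises immediately with instructions to use ``table`` or ``stub``.
    Per-residue representations are reduced to one vector by mean pooling
    over residue positions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .io import EmbeddingTable, ProteinRecord

DEFAULT_DIMENSION = 1280


def sequence_seed(sequence: str, salt: int = 0) -> int:
    """Stable 31-bit seed derived from the sequence bytes (plus a salt)."""
    digest = hashlib.sha256(
        sequence.encode("ascii") + salt.to_bytes(8, "little", signed=True)
    ).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class StubEmbedding:
    """Deterministic content-seeded pseudo-embedding for tests and synthesis."""

    dimension: int = DEFAULT_DIMENSION
    salt: int = 0
    name: str = field(default="stub", init=False)

    def embed(self, record: ProteinRecord) -> np.ndarray:
        if not record.sequence:
            raise ValueError("cannot embed an empty sequence")
        rng = np.random.Generator(
            np.random.PCG64(sequence_seed(record.sequence, self.salt))
        )
        return rng.uniform(-1.0, 1.0, size=self.dimension)


@dataclass
class TableEmbedding:
    """File-backed embeddings: looks vectors up by protein id."""

    table: EmbeddingTable
    name: str = field(default="table", init=False)

    @property
    def dimension(self) -> int:
        return self.table.dimension

    def embed(self, record: ProteinRecord) -> np.ndarray:
        return self.table[record.id]


class EsmUnavailableError(RuntimeError):
    pass


@dataclass
class EsmEmbedding:
    """Pretrained protein-language-model backend (optional).

    Requires the ``esm`` package and downloaded weights; per-residue
    representations of the final layer are mean-pooled into one vector.
    """

    dimension: int = DEFAULT_DIMENSION
    name: str = field(default="esm", init=False)

    def __post_init__(self) -> None:
        try:
            import esm  # noqa: F401
        except ImportError:
            raise EsmUnavailableError(
                "the ESM language-model backend is not installed; use the "
                "'stub' backend for testing or the 'table' backend with "
                "precomputed embedding vectors"
            ) from None

    def embed(self, record: ProteinRecord) -> np.ndarray:  # pragma: no cover
        import esm
        import torch

        model, alphabet = esm.pretrained.esm1b_t33_650M_UR50S()
        converter = alphabet.get_batch_converter()
        model.eval()
        _, _, tokens = converter([(record.id, record.sequence)])
        with torch.no_grad():
            out = model(tokens, repr_layers=[33])
        rep = out["representations"][33][0, 1 : len(record.sequence) + 1]
        return rep.mean(dim=0).numpy()


def get_backend(
    name: str,
    table: EmbeddingTable | None = None,
    dimension: int = DEFAULT_DIMENSION,
):
    """Construct an embedding backend by name ('stub', 'table' or 'esm')."""
    if name == "stub":
        return StubEmbedding(dimension=dimension)
    if name == "table":
        if table is None:
            raise ValueError("the table backend requires an embedding table")
        return TableEmbedding(table=table)
    if name == "esm":
        return EsmEmbedding(dimension=dimension)
    raise ValueError(f"unknown embedding backend {name!r}")
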