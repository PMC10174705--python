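"""One-hot channel encodings of sequence, secondary structure and solvent
accessibility.

The classifier's convolutional front end consumes an L x 34 binary matrix
per protein: 20 amino-acid channels, 3 three-class secondary-structure
channels, 8 eight-class secondary-structure channels and 3 solvent-
accessibility channels, concatenated in that fixed order. Nonstandard
residues (X/B/Z/U/O) encode as all-zero amino-acid rows, keeping the
20-column convention aligned with the PSSM columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    AA_ORDER,
    ANNOTATION_ALPHABETS,
    SEQUENCE_ALPHABET,
    ProteinRecord,
)

#: Fixed channel-block order and widths.
BLOCK_WIDTHS = {"aa": 20, "ss3": 3, "ss8": 8, "rsa": 3}
BLOCK_ORDER = ("aa", "ss3", "ss8", "rsa")
TOTAL_CHANNELS = sum(BLOCK_WIDTHS.values())  # 34

_AA_INDEX = {ch: i for i, ch in enumerate(AA_ORDER)}


@dataclass
class ChannelMatrix:
    """Binary channel matrix plus a validity mask for batching.

    ``values`` has one row per residue and one column per channel; ``mask``
    is true exactly at real (non-padding) positions.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape[0] != self.mask.shape[0]:
            raise ValueError("values and mask must share the length axis")

    @property
    def length(self) -> int:
        return int(self.mask.sum())

    @property
    def width(self) -> int:
        return self.values.shape[1]


def one_hot_sequence(sequence: str) -> np.ndarray:
    """Encode an amino-acid sequence as an L x 20 one-hot matrix.

    Rows of nonstandard residues (X/B/Z/U/O) are all zero.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    out = np.zeros((len(sequence), 20))
    for i, ch in enumerate(sequence):
        if ch not in SEQUENCE_ALPHABET:
            raise ValueError(f"invalid residue {ch!r} at position {i}")
        j = _AA_INDEX.get(ch)
        if j is not None:
            out[i, j] = 1.0
    return out


def one_hot_annotation(s: str, kind: str) -> np.ndarray:
    """Encode an annotation string as an L x k one-hot matrix (k = 3, 8, 3).

    Column order follows the fixed alphabet of ``kind``: ss3 H,E,C;
    ss8 H,G,I,E,B,T,S,C; rsa B,M,E.
    """
    alphabet = ANNOTATION_ALPHABETS.get(kind)
    if alphabet is None:
        raise ValueError(f"unknown annotation kind {kind!r}")
    if not s:
        raise ValueError("cannot encode an empty annotation string")
    index = {ch: i for i, ch in enumerate(alphabet)}
    out = np.zeros((len(s), len(alphabet)))
    for i, ch in enumerate(s):
        j = index.get(ch)
        if j is None:
            raise ValueError(
                f"invalid {kind} symbol {ch!r} at position {i}"
            )
        out[i, j] = 1.0
    return out


def stack_channels(
    record: ProteinRecord,
    blocks: tuple[str, ...] = BLOCK_ORDER,
) -> ChannelMatrix:
    """Concatenate the enabled one-hot blocks of a record horizontally.

    ``blocks`` selects which channel blocks to include, in the fixed order
    [aa | ss3 | ss8 | rsa]; a block may be omitted only when the model is
    configured without it. A present annotation of the wrong length raises
    an error naming the block.
    """
    unknown = set(blocks) - set(BLOCK_ORDER)
    if unknown:
        raise ValueError(f"unknown channel blocks: {sorted(unknown)}")
    parts = []
    for block in BLOCK_ORDER:
        if block not in blocks:
            continue
        if block == "aa":
            parts.append(one_hot_sequence(record.sequence))
            continue
        ann = getattr(record, block)
        if ann is None:
            raise ValueError(
                f"{record.id}: {block} annotation required but missing "
                "(disable the block or supply the annotation)"
            )
        if len(ann) != len(record.sequence):
            raise ValueError(
                f"{record.id}: {block} length {len(ann)} != sequence "
                f"length {len(record.sequence)}"
            )
        parts.append(one_hot_annotation(ann, block))
    if not parts:
        raise ValueError("at least one channel block must be enabled")
    values = np.hstack(parts)
    return ChannelMatrix(values=values, mask=np.ones(len(record), dtype=bool))
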