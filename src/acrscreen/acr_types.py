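"""Grouping of the twelve anti-CRISPR types into the five-class scheme.

Known Acr types are named after the CRISPR-Cas subtype they inhibit.
The four largest types (II-A, I-F, I-D, II-C) keep their own class; the
eight rare types (I-E, V-A, I-C, VI-A, VI-B, III-I, III-B, I-B) are
pooled into an "others" class, giving the 5-way classification target.
Class indices are frozen for checkpoint compatibility.
"""

from __future__ import annotations

from typing import Callable, Sequence

from .io import LABEL_POSITIVE, ProteinRecord
from .model import FeatureBundle

#: The four majority types, in descending order of dataset frequency.
MAJOR_TYPES = ("II-A", "I-F", "I-D", "II-C")
#: The eight minority types pooled into the "others" class.
MINOR_TYPES = ("I-E", "V-A", "I-C", "VI-A", "VI-B", "III-I", "III-B", "I-B")
KNOWN_TYPES = MAJOR_TYPES + MINOR_TYPES

CLASS_NAMES = MAJOR_TYPES + ("others",)
OTHERS_INDEX = 4
N_CLASSES = 5

_TYPE_TO_CLASS = {t: i for i, t in enumerate(MAJOR_TYPES)}
_TYPE_TO_CLASS.update({t: OTHERS_INDEX for t in MINOR_TYPES})


def group_type(acr_type: str) -> int:
    """Map an Acr type string to its class index (0..4).

    II-A, I-F, I-D and II-C map to 0..3; the eight known minority types
    map to 4 ("others"). Unknown type strings are an error — never a
    silent "others".
    """
    if not acr_type:
        raise ValueError("empty Acr type string")
    try:
        return _TYPE_TO_CLASS[acr_type]
    except KeyError:
        raise ValueError(
            f"unknown Acr type {acr_type!r}; known types: "
            f"{', '.join(KNOWN_TYPES)}"
        ) from None


def build_type_dataset(
    records: Sequence[ProteinRecord],
    featurize: Callable[[ProteinRecord], FeatureBundle],
) -> list[tuple[FeatureBundle, int]]:
    """Assemble the type-classification dataset from labeled records.

    Non-Acr records are excluded; each remaining record must carry an Acr
    type, which is grouped to its class index. ``featurize`` turns a
    record into the model's input bundle.
    """
    out: list[tuple[FeatureBundle, int]] = []
    for rec in records:
        if rec.label != LABEL_POSITIVE:
            continue
        if rec.acr_type is None:
            raise ValueError(f"{rec.id}: Acr record lacks an Acr type")
        out.append((featurize(rec), group_type(rec.acr_type)))
    return out
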