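"""Readers and writers for every external file format the pipeline touches.

This module is the single source of truth for format dialects:

* FASTA for amino-acid sequences (and FASTA-like framing for per-residue
  annotation strings),
* the PSI-BLAST ``-out_ascii_pssm`` dialect for position-specific scoring
  matrices,
* TSV manifests mapping protein ids to binary labels and anti-CRISPR types,
* TSV embedding tables mapping protein ids to fixed-width real vectors.

All readers are pure functions of the file bytes and validate their input
eagerly, naming the offending record in the error message.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

#: PSI-BLAST amino-acid column order; also the one-hot channel order.
AA_ORDER = "ARNDCQEGHILKMFPSTVWY"
#: Residue letters accepted in sequences beyond the 20 standard ones.
NONSTANDARD_AA = "XBZUO"
SEQUENCE_ALPHABET = frozenset(AA_ORDER + NONSTANDARD_AA)

SS3_ALPHABET = "HEC"
SS8_ALPHABET = "HGIEBTSC"
#: Buried / medium / exposed three-state solvent-accessibility alphabet.
RSA_ALPHABET = "BME"

ANNOTATION_ALPHABETS: Mapping[str, str] = {
    "ss3": SS3_ALPHABET,
    "ss8": SS8_ALPHABET,
    "rsa": RSA_ALPHABET,
}

LABEL_POSITIVE = "Acr"
LABEL_NEGATIVE = "non-Acr"


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class ProteinRecord:
    """One protein with optional per-residue annotations and labels.

    ``ss3``/``ss8`` are 3-class and 8-class secondary-structure strings,
    ``rsa`` a 3-state solvent-accessibility string; each, when present, has
    the same length as ``sequence``. ``label`` is ``"Acr"``/``"non-Acr"``;
    ``acr_type`` the inhibited CRISPR-Cas subtype (e.g. ``"II-A"``).
    """

    id: str
    sequence: str
    ss3: str | None = None
    ss8: str | None = None
    rsa: str | None = None
    label: str | None = None
    acr_type: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be nonempty")
        for ch in self.sequence:
            if ch not in SEQUENCE_ALPHABET:
                raise FormatError(
                    f"{self.id}: invalid residue character {ch!r}"
                )
        for kind in ("ss3", "ss8", "rsa"):
            s = getattr(self, kind)
            if s is None:
                continue
            if len(s) != len(self.sequence):
                raise FormatError(
                    f"{self.id}: {kind} length {len(s)} != sequence length "
                    f"{len(self.sequence)}"
                )
            _validate_annotation(self.id, s, kind)
        if self.label is not None and self.label not in (
            LABEL_POSITIVE,
            LABEL_NEGATIVE,
        ):
            raise ValueError(f"{self.id}: unknown label {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PSSM:
    """Position-specific scoring matrix aligned to a sequence.

    ``scores`` is an L x 20 real matrix of log-odds scores with columns in
    the fixed PSI-BLAST order :data:`AA_ORDER`.
    """

    sequence: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM scores must be L x 20, got {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.sequence):
            raise ValueError(
                f"PSSM has {self.scores.shape[0]} rows but sequence length "
                f"{len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class EmbeddingTable:
    """Mapping from protein id to a fixed-width embedding vector."""

    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def dimension(self) -> int:
        if not self.vectors:
            raise ValueError("empty embedding table has no dimension")
        return next(iter(self.vectors.values())).shape[0]

    def __getitem__(self, protein_id: str) -> np.ndarray:
        try:
            return self.vectors[protein_id]
        except KeyError:
            raise KeyError(
                f"no embedding for protein id {protein_id!r}"
            ) from None

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


def _validate_annotation(rec_id: str, s: str, kind: str) -> None:
    alphabet = ANNOTATION_ALPHABETS[kind]
    for pos, ch in enumerate(s):
        if ch not in alphabet:
            raise FormatError(
                f"{rec_id}: invalid {kind} character {ch!r} at position {pos}"
                f" (alphabet {alphabet})"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences from a FASTA file.

    Wrapped sequence lines are concatenated, sequences are uppercased, and
    the record id is the first whitespace-delimited token of the header.
    Residues outside the permitted alphabet raise :class:`FormatError`
    naming the record and character.
    """
    records = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        rec = ProteinRecord(id=seq_rec.id, sequence=str(seq_rec.seq).upper())
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(rec)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm(path: str | Path) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Data rows carry a position index, the residue letter and at least 20
    integer log-odds scores; trailing weighted-percentage and information
    columns are ignored. Rows with fewer than 20 parseable scores raise
    :class:`FormatError` with the line number.
    """
    letters: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            # Data rows start with an integer position then a residue letter.
            if len(parts) < 2 or not parts[0].isdigit():
                continue
            if len(parts[1]) != 1 or not parts[1].isalpha():
                continue
            scores = parts[2:22]
            if len(scores) < 20:
                raise FormatError(
                    f"{path}:{lineno}: expected 20 scores, found {len(scores)}"
                )
            try:
                row = [float(x) for x in scores]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            letters.append(parts[1].upper())
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no PSSM data rows found")
    return PSSM(sequence="".join(letters), scores=np.array(rows))


def write_pssm(pssm: PSSM, path: str | Path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII layout (scores only)."""
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write(" " * 11 + "  ".join(AA_ORDER) + "\n")
        for i, (letter, row) in enumerate(zip(pssm.sequence, pssm.scores)):
            cells = "".join(f"{v:7g}" for v in row)
            fh.write(f"{i + 1:5d} {letter}{cells}\n")


# ---------------------------------------------------------------------------
# Annotations (FASTA-like framing)
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, kind: str) -> dict[str, str]:
    """Read per-residue annotation strings from a FASTA-like file.

    ``kind`` selects the alphabet: ``ss3`` ({H,E,C}), ``ss8``
    ({H,G,I,E,B,T,S,C}) or ``rsa`` ({B,M,E}).
    """
    if kind not in ANNOTATION_ALPHABETS:
        raise ValueError(f"unknown annotation kind {kind!r}")
    out: dict[str, str] = {}
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        s = str(seq_rec.seq).upper()
        _validate_annotation(seq_rec.id, s, kind)
        if seq_rec.id in out:
            raise FormatError(f"duplicate id {seq_rec.id!r} in {path}")
        out[seq_rec.id] = s
    return out


def write_annotations(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, s in mapping.items():
            fh.write(f">{rec_id}\n{s}\n")


# ---------------------------------------------------------------------------
# Label / type manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> dict[str, tuple[str, str | None]]:
    """Read a TSV manifest with columns id, label, type.

    Returns a mapping id -> (label, acr_type) where ``acr_type`` is ``None``
    for rows with an empty type column. Unknown type strings are preserved
    verbatim; labels outside {Acr, non-Acr} and duplicate ids are errors.
    """
    out: dict[str, tuple[str, str | None]] = {}
    with open(path) as fh:
        header = fh.readline()
        cols = header.rstrip("\n").split("\t")
        if [c.strip().lower() for c in cols[:3]] != ["id", "label", "type"]:
            raise FormatError(
                f"{path}: expected header id/label/type, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 columns")
            rec_id, label = parts[0], parts[1]
            acr_type = parts[2] if len(parts) > 2 and parts[2] else None
            if rec_id in out:
                raise FormatError(f"{path}:{lineno}: duplicate id {rec_id!r}")
            if label not in (LABEL_POSITIVE, LABEL_NEGATIVE):
                raise FormatError(
                    f"{path}:{lineno}: unknown label {label!r} "
                    f"(expected {LABEL_POSITIVE} or {LABEL_NEGATIVE})"
                )
            out[rec_id] = (label, acr_type)
    return out


def write_manifest(
    rows: Mapping[str, tuple[str, str | None]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\ttype\n")
        for rec_id, (label, acr_type) in rows.items():
            fh.write(f"{rec_id}\t{label}\t{acr_type or ''}\n")


# ---------------------------------------------------------------------------
# Embedding tables
# ---------------------------------------------------------------------------

def read_embeddings(path: str | Path) -> EmbeddingTable:
    """Read a TSV embedding table: id then D real values per row.

    All rows must share one dimension; ragged rows are an error.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rec_id = parts[0]
            try:
                vec = np.array([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if dim is None:
                dim = vec.shape[0]
            elif vec.shape[0] != dim:
                raise FormatError(
                    f"{path}:{lineno}: row has {vec.shape[0]} values, "
                    f"expected {dim}"
                )
            if rec_id in vectors:
                raise FormatError(f"{path}:{lineno}: duplicate id {rec_id!r}")
            vectors[rec_id] = vec
    return EmbeddingTable(vectors=vectors)


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, vec in table.vectors.items():
            vals = "\t".join(repr(float(v)) for v in vec)
            fh.write(f"{rec_id}\t{vals}\n")


def records_to_string(records: Iterable[ProteinRecord]) -> str:
    """Render records as FASTA text (mainly for tests and logging)."""
    buf = _io.StringIO()
    for rec in records:
        buf.write(f">{rec.id}\n{rec.sequence}\n")
    return buf.getvalue()
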