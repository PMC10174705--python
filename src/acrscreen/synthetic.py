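"""Self-consistent synthetic datasets with plantable class signal.

The generator emulates every input the pipeline consumes — protein
records, per-protein PSSMs, secondary-structure and solvent-accessibility
strings, an embedding table, a label/type manifest and the true motif
spans — so the whole package builds and tests without any download.

Signal design. Each Acr type gets its own random motif (default 21
residues). Positive sequences carry their type's motif exactly once at a
random position; negatives never contain a motif. The class signal is
planted twice, mirroring the idea that sequence, evolutionary and
language-model features complement each other:

* the motif substring itself (visible to the one-hot CNN branch and,
  through residue conservation, to the PSSM descriptors), and
* an embedding offset of configurable magnitude along a fixed random
  direction, added whenever a sequence contains a planted motif.

Because every derived feature (PSSM, SS3/SS8, RSA, embedding) is a
deterministic function of the sequence bytes, mutated sequences can be
re-featurized consistently — exactly what the motif-mutation experiment
needs.

Emulated envelope: sequence lengths 50–350 and integer PSSM scores in
the typical iterated-homology-search range; the generator does not mimic
real Acr residue statistics or inter-sequence similarity structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import io as io_formats
from .acr_types import KNOWN_TYPES, group_type
from .embeddings import StubEmbedding, sequence_seed
from .encoders import stack_channels
from .io import (
    AA_ORDER,
    EmbeddingTable,
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    PSSM,
    ProteinRecord,
)
from .model import FeatureBundle, ModelConfig, build_model
from .motifs import MotifSpan
from .pssm_features import evolutionary_dimension, evolutionary_features

#: Default type proportions among positives: the four majority classes
#: dominate, with two minority types standing in for the "others" pool.
DEFAULT_TYPE_MIX: Mapping[str, float] = {
    "II-A": 0.35,
    "I-F": 0.20,
    "I-D": 0.15,
    "II-C": 0.15,
    "I-E": 0.08,
    "V-A": 0.07,
}


@dataclass
class SynthConfig:
    """Knobs of the synthetic dataset generator.

    ``noise_sd`` is the standard deviation of the integer-rounded
    Gaussian noise on non-true-residue PSSM entries; ``embedding_signal``
    the magnitude of the positive-class embedding offset. Setting
    ``plant_motif=False`` and ``embedding_signal=0`` yields a
    no-information null dataset.
    """

    n_pos: int = 400
    n_neg: int = 400
    length_range: tuple[int, int] = (50, 350)
    motif_length: int = 21
    type_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX)
    )
    noise_sd: float = 1.5
    embedding_signal: float = 2.0
    embedding_dim: int = 256
    plant_motif: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid length range {self.length_range}")
        if self.motif_length > lo:
            raise ValueError(
                f"motif length {self.motif_length} exceeds minimum "
                f"sequence length {lo}"
            )
        total = sum(self.type_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"type proportions sum to {total}, not 1")
        unknown = set(self.type_mix) - set(KNOWN_TYPES)
        if unknown:
            raise ValueError(f"unknown Acr types in mix: {sorted(unknown)}")


@dataclass
class SynthBundle:
    """One generated dataset: records, features and ground truth."""

    config: SynthConfig
    records: list[ProteinRecord]
    pssms: dict[str, PSSM]
    embeddings: EmbeddingTable
    motif_spans: dict[str, MotifSpan]
    motifs: dict[str, str]

    def manifest(self) -> dict[str, tuple[str, str | None]]:
        return {r.id: (r.label, r.acr_type) for r in self.records}

    def write(self, directory: str | Path) -> None:
        """Write the dataset in the exact formats the io module reads."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        io_formats.write_fasta(self.records, directory / "sequences.fasta")
        for kind in ("ss3", "ss8", "rsa"):
            io_formats.write_annotations(
                {r.id: getattr(r, kind) for r in self.records},
                directory / f"{kind}.fasta",
            )
        pssm_dir = directory / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        for rec_id, pssm in self.pssms.items():
            io_formats.write_pssm(pssm, pssm_dir / f"{rec_id}.pssm")
        io_formats.write_embeddings(
            self.embeddings, directory / "embeddings.tsv"
        )
        io_formats.write_manifest(self.manifest(), directory / "manifest.tsv")
        from .motifs import write_spans

        write_spans(
            sorted(self.motif_spans.values(), key=lambda s: s.seq_id),
            directory / "motif_spans.tsv",
        )
        cfg = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.config.__dict__.items()
        }
        cfg["type_mix"] = dict(self.config.type_mix)
        with open(directory / "synth_config.json", "w") as fh:
            json.dump({"config": cfg, "motifs": self.motifs}, fh, indent=1)


def signal_direction(config: SynthConfig) -> np.ndarray:
    """Fixed unit vector along which positives are offset in embedding space."""
    rng = np.random.Generator(np.random.PCG64(config.seed ^ 0x5EED))
    v = rng.normal(size=config.embedding_dim)
    return v / np.linalg.norm(v)


def _type_motifs(config: SynthConfig) -> dict[str, str]:
    """One fixed motif string per type, drawn from a type-specific
    residue pair.

    Real anti-CRISPR motifs are low-complexity conserved patterns tied
    to shared local structure, not uniform random strings; emulating
    that composition bias is what makes the motifs learnable (and
    type-discriminative) at desk scale. Each type is assigned a disjoint
    pair of residues (seeded shuffle of the alphabet) and its motif is
    drawn iid from that pair.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed + 101))
    letters = list(AA_ORDER)
    rng.shuffle(letters)
    motifs = {}
    for i, t in enumerate(sorted(config.type_mix)):
        pair = letters[(2 * i) % 20 : (2 * i) % 20 + 2]
        motifs[t] = "".join(
            pair[j] for j in rng.integers(2, size=config.motif_length)
        )
    return motifs


def synth_pssm(sequence: str, config: SynthConfig) -> PSSM:
    """Deterministic PSSM for a sequence: +7 at the true residue, integer
    Gaussian noise clipped to [-5, 5] elsewhere."""
    rng = np.random.Generator(
        np.random.PCG64(sequence_seed(sequence, config.seed + 1))
    )
    scores = np.clip(
        np.rint(rng.normal(0.0, config.noise_sd, size=(len(sequence), 20))),
        -5,
        5,
    )
    aa_index = {ch: i for i, ch in enumerate(AA_ORDER)}
    for k, ch in enumerate(sequence):
        j = aa_index.get(ch)
        if j is not None:
            scores[k, j] = 7.0
    return PSSM(sequence=sequence, scores=scores)


def synth_annotations(
    sequence: str, config: SynthConfig
) -> tuple[str, str, str]:
    """SS3/SS8 by a 2-state helix/coil persistence process; RSA by
    thresholding a smoothed random walk."""
    length = len(sequence)
    rng = np.random.Generator(
        np.random.PCG64(sequence_seed(sequence, config.seed + 2))
    )
    ss3 = []
    ss8 = []
    state = "H" if rng.random() < 0.5 else "C"
    for _ in range(length):
        if rng.random() > 0.9:  # leave the current run
            state = "C" if state == "H" else "H"
        ss3.append(state)
        if state == "H":
            ss8.append(rng.choice(["H", "G", "I"], p=[0.8, 0.1, 0.1]))
        else:
            ss8.append(rng.choice(["C", "T", "S"], p=[0.8, 0.1, 0.1]))
    walk = np.cumsum(rng.normal(size=length))
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(walk, kernel, mode="same")
    lo, hi = np.quantile(smooth, [1 / 3, 2 / 3])
    rsa = np.where(smooth < lo, "B", np.where(smooth < hi, "M", "E"))
    return "".join(ss3), "".join(ss8), "".join(rsa)


def synth_embedding(
    sequence: str,
    motifs: Mapping[str, str],
    config: SynthConfig,
) -> np.ndarray:
    """Stub embedding plus the class-signal offset when a motif is present.

    The offset depends only on the sequence content (does it contain any
    planted motif?), so re-featurizing a mutated sequence is consistent
    with the generation-time embedding.
    """
    stub = StubEmbedding(dimension=config.embedding_dim, salt=config.seed)
    vec = stub.embed(ProteinRecord(id="_", sequence=sequence))
    if config.embedding_signal and any(m in sequence for m in motifs.values()):
        vec = vec + config.embedding_signal * signal_direction(config)
    return vec


def featurize_sequence(
    sequence: str,
    motifs: Mapping[str, str],
    config: SynthConfig,
) -> tuple[PSSM, str, str, str, np.ndarray]:
    """All derived features of a sequence, deterministic in its bytes."""
    pssm = synth_pssm(sequence, config)
    ss3, ss8, rsa = synth_annotations(sequence, config)
    emb = synth_embedding(sequence, motifs, config)
    return pssm, ss3, ss8, rsa, emb


def generate(config: SynthConfig | None = None) -> SynthBundle:
    """Generate a complete dataset bundle; byte-deterministic in the seed."""
    config = config or SynthConfig()
    rng = np.random.Generator(np.random.PCG64(config.seed))
    motifs = _type_motifs(config) if config.plant_motif else {}
    lo, hi = config.length_range

    # multinomial-by-proportion type assignment, largest remainder on ties
    types = sorted(config.type_mix)
    counts = {t: int(config.type_mix[t] * config.n_pos) for t in types}
    while sum(counts.values()) < config.n_pos:
        t = types[int(rng.integers(len(types)))]
        counts[t] += 1

    records: list[ProteinRecord] = []
    pssms: dict[str, PSSM] = {}
    vectors: dict[str, np.ndarray] = {}
    spans: dict[str, MotifSpan] = {}

    def random_sequence(length: int) -> str:
        return "".join(AA_ORDER[i] for i in rng.integers(20, size=length))

    idx = 0
    for acr_type in types:
        for _ in range(counts[acr_type]):
            rec_id = f"acr{idx:04d}"
            idx += 1
            length = int(rng.integers(lo, hi + 1))
            seq = random_sequence(length)
            if config.plant_motif:
                motif = motifs[acr_type]
                start = int(rng.integers(0, length - config.motif_length + 1))
                seq = seq[:start] + motif + seq[start + config.motif_length:]
                while seq.count(motif) != 1:  # astronomically rare
                    seq = random_sequence(length)
                    seq = (
                        seq[:start] + motif + seq[start + config.motif_length:]
                    )
                spans[rec_id] = MotifSpan(
                    seq_id=rec_id,
                    start=start,
                    end=start + config.motif_length,
                )
            pssm, ss3, ss8, rsa, emb = featurize_sequence(
                seq, motifs, config
            )
            records.append(
                ProteinRecord(
                    id=rec_id,
                    sequence=seq,
                    ss3=ss3,
                    ss8=ss8,
                    rsa=rsa,
                    label=LABEL_POSITIVE,
                    acr_type=acr_type,
                )
            )
            pssms[rec_id] = pssm
            vectors[rec_id] = emb
    for n in range(config.n_neg):
        rec_id = f"neg{n:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = random_sequence(length)
        while any(m in seq for m in motifs.values()):  # astronomically rare
            seq = random_sequence(length)
        pssm, ss3, ss8, rsa, emb = featurize_sequence(seq, motifs, config)
        records.append(
            ProteinRecord(
                id=rec_id,
                sequence=seq,
                ss3=ss3,
                ss8=ss8,
                rsa=rsa,
                label=LABEL_NEGATIVE,
            )
        )
        pssms[rec_id] = pssm
        vectors[rec_id] = emb
    return SynthBundle(
        config=config,
        records=records,
        pssms=pssms,
        embeddings=EmbeddingTable(vectors=vectors),
        motif_spans=spans,
        motifs=motifs,
    )


def load_bundle(directory: str | Path) -> SynthBundle:
    """Reload a dataset previously written by :meth:`SynthBundle.write`."""
    directory = Path(directory)
    with open(directory / "synth_config.json") as fh:
        meta = json.load(fh)
    cfg_dict = dict(meta["config"])
    cfg_dict["length_range"] = tuple(cfg_dict["length_range"])
    config = SynthConfig(**cfg_dict)
    records = io_formats.read_fasta(directory / "sequences.fasta")
    anns = {
        kind: io_formats.read_annotations(directory / f"{kind}.fasta", kind)
        for kind in ("ss3", "ss8", "rsa")
    }
    manifest = io_formats.read_manifest(directory / "manifest.tsv")
    records = [
        ProteinRecord(
            id=r.id,
            sequence=r.sequence,
            ss3=anns["ss3"].get(r.id),
            ss8=anns["ss8"].get(r.id),
            rsa=anns["rsa"].get(r.id),
            label=manifest[r.id][0],
            acr_type=manifest[r.id][1],
        )
        for r in records
    ]
    pssms = {
        r.id: io_formats.read_pssm(directory / "pssm" / f"{r.id}.pssm")
        for r in records
    }
    embeddings = io_formats.read_embeddings(directory / "embeddings.tsv")
    from .motifs import read_spans

    spans = read_spans(
        directory / "motif_spans.tsv",
        {r.id: len(r.sequence) for r in records},
    )
    return SynthBundle(
        config=config,
        records=records,
        pssms=pssms,
        embeddings=embeddings,
        motif_spans={s.seq_id: s for s in spans},
        motifs=dict(meta["motifs"]),
    )


# ---------------------------------------------------------------------------
# Model-ready bundles
# ---------------------------------------------------------------------------

def default_model_config(
    config: SynthConfig, lag_bound: int = 10, **overrides
) -> ModelConfig:
    """Model config whose block dimensions match a generated bundle."""
    base = dict(
        evolutionary_dim=evolutionary_dimension(lag_bound),
        embedding_dim=config.embedding_dim,
    )
    base.update(overrides)
    return ModelConfig(**base)


def featurize_record(
    record: ProteinRecord,
    bundle: SynthBundle,
    lag_bound: int = 10,
    blocks: tuple[str, ...] = ("onehot", "evolutionary", "embedding"),
) -> FeatureBundle:
    """Model input for a record, regenerating features for unseen sequences.

    Records already in the bundle reuse its stored PSSM and embedding;
    any other record (e.g. a motif mutant) is featurized from scratch via
    the deterministic generators.
    """
    if record.id in bundle.pssms and record.id in bundle.embeddings:
        pssm = bundle.pssms[record.id]
        emb = bundle.embeddings[record.id]
        rec = record
    else:
        pssm, ss3, ss8, rsa, emb = featurize_sequence(
            record.sequence, bundle.motifs, bundle.config
        )
        rec = ProteinRecord(
            id=record.id,
            sequence=record.sequence,
            ss3=ss3,
            ss8=ss8,
            rsa=rsa,
            label=record.label,
            acr_type=record.acr_type,
        )
    return FeatureBundle(
        id=record.id,
        channels=(
            stack_channels(rec) if "onehot" in blocks else None
        ),
        evolutionary=(
            evolutionary_features(pssm, lag_bound).concatenated
            if "evolutionary" in blocks
            else None
        ),
        embedding=emb if "embedding" in blocks else None,
    )


def binary_dataset(
    bundle: SynthBundle,
    lag_bound: int = 10,
    blocks: tuple[str, ...] = ("onehot", "evolutionary", "embedding"),
) -> tuple[list[tuple[FeatureBundle, int]], list[str]]:
    """(FeatureBundle, 0/1 label) pairs plus the parallel id list."""
    dataset = []
    ids = []
    for rec in bundle.records:
        fb = featurize_record(rec, bundle, lag_bound, blocks)
        dataset.append((fb, 1 if rec.label == LABEL_POSITIVE else 0))
        ids.append(rec.id)
    return dataset, ids


def type_dataset(
    bundle: SynthBundle,
    lag_bound: int = 10,
    blocks: tuple[str, ...] = ("onehot", "evolutionary", "embedding"),
) -> tuple[list[tuple[FeatureBundle, int]], list[str]]:
    """(FeatureBundle, class 0..4) pairs for the positives only."""
    dataset = []
    ids = []
    for rec in bundle.records:
        if rec.label != LABEL_POSITIVE:
            continue
        fb = featurize_record(rec, bundle, lag_bound, blocks)
        dataset.append((fb, group_type(rec.acr_type)))
        ids.append(rec.id)
    return dataset, ids


def separability_check(
    bundle: SynthBundle,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> float:
    """Train the default binary model on 80% and return test accuracy."""
    from sklearn.model_selection import train_test_split

    from .train_eval import TrainConfig, train

    dataset, _ids = binary_dataset(bundle)
    labels = np.array([y for _, y in dataset])
    train_idx, test_idx = train_test_split(
        np.arange(len(dataset)),
        test_size=test_fraction,
        random_state=seed % (2**31),
        stratify=labels,
    )
    mc = default_model_config(bundle.config, seed=seed)
    model = build_model(mc)
    result = train(
        model,
        [dataset[i] for i in train_idx],
        TrainConfig(seed=seed),
    )
    probs = result.model.forward([dataset[i][0] for i in test_idx])
    pred = (probs[:, 1] >= 0.5).astype(int)
    return float((pred == labels[test_idx]).mean())
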