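"""Synthetic study generator: sequences, annotations, embeddings and
planted-ground-truth ddG datasets.

The generator emulates the statistical structure the predictor assumes:

* random sequences over the 20 residues;
* deterministic, residue-dependent per-position annotations standing in for
  a structure-annotation predictor's output;
* hash-seeded pseudo-embeddings whose pooled difference is exactly
  antisymmetric under direct/reverse swap;
* a planted *linear* ground truth over the fused feature space whose local
  weights are constrained so the noise-free ddG is antisymmetric by
  construction (the two secondary-structure triples carry opposite weights);
* matched direct and reverse records with **independently** drawn Gaussian
  noise, so that learned — not hard-coded — antisymmetry is testable.

Everything is a pure function of the configuration; equal configurations
give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .embeddings import SyntheticEmbeddingProvider
from .featurize import VariantFeaturizer, chain_keys
from .local_features import ResidueAnnotation, write_netsurfp_csv
from .variants import (AMINO_ACIDS, PointMutation, ProteinSequence,
                       VariantRecord, ValidationError, reverse_variant,
                       write_fasta, write_variant_csv)


def _hash_rng(*parts) -> np.random.Generator:
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic planted-model dataset.

    ``noise_sd`` is the experimental-noise standard deviation in kcal/mol;
    ``global_weight`` / ``local_weight`` set the ddG standard deviation
    contributed by each branch's planted signal, so the defaults give a
    noise-free ddG spread of about 1.4 kcal/mol — comparable to curated
    single-mutation stability data.
    """

    seed: int
    n_proteins: int = 40
    n_variants: int = 500
    length_range: tuple[int, int] = (50, 150)
    embed_dim: int = 32
    noise_sd: float = 0.3
    global_weight: float = 1.0
    local_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValidationError(f"bad length range {self.length_range}")


@dataclass(frozen=True)
class PlantedModel:
    """The linear ground truth over [local(25) | global(d)] features."""

    w_local: np.ndarray
    w_global: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X[:, :25] @ self.w_local + X[:, 25:] @ self.w_global


class SyntheticAnnotationProvider:
    """Deterministic stand-in for a per-residue structure annotator.

    Each residue's annotation is drawn around residue-letter-dependent base
    values (so a substitution genuinely moves the annotation) with
    per-position jitter keyed by (seed, sequence, position, letter).
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self._memo: dict[str, list[ResidueAnnotation]] = {}

    @staticmethod
    def _letter_base(letter: str) -> tuple:
        rng = _hash_rng("aa-annotation-base", letter)
        return (rng.uniform(0.1, 0.9),          # rsa
                rng.uniform(0.0, 0.5),          # disorder
                rng.normal(0.0, 1.0, size=3),   # ss logits
                rng.uniform(-180.0, 180.0),     # phi
                rng.uniform(-180.0, 180.0))     # psi

    def annotate(self, seq: ProteinSequence) -> list[ResidueAnnotation]:
        memo = self._memo.get(seq.residues)
        if memo is not None:
            return memo
        out = []
        for i, aa in enumerate(seq.residues):
            base_rsa, base_dis, base_logits, base_phi, base_psi = \
                self._letter_base(aa)
            rng = _hash_rng("annotation", self.seed, seq.residues, i, aa)
            logits = base_logits + 0.5 * rng.normal(size=3)
            probs = np.exp(logits - logits.max())
            probs /= probs.sum()
            wrap = lambda a: ((a + 180.0) % 360.0) - 180.0  # noqa: E731
            out.append(ResidueAnnotation(
                p_helix=float(probs[0]), p_sheet=float(probs[1]),
                p_coil=float(probs[2]),
                rsa=float(np.clip(base_rsa + 0.15 * rng.normal(), 0, 1)),
                disorder=float(np.clip(base_dis + 0.1 * rng.normal(), 0, 1)),
                phi=float(wrap(base_phi + 20.0 * rng.normal())),
                psi=float(wrap(base_psi + 20.0 * rng.normal())),
            ))
        if len(self._memo) < 4096:
            self._memo[seq.residues] = out
        return out

    # AnnotationSource protocol: key is ignored, annotations are a pure
    # function of the chain itself.
    def get(self, key: str, seq: ProteinSequence) -> list[ResidueAnnotation]:
        return self.annotate(seq)


def gen_sequences(cfg: SimConfig) -> list[ProteinSequence]:
    """Uniform-random sequences within the configured length range."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    letters = np.array(list(AMINO_ACIDS))
    out = []
    for i in range(cfg.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(letters, size=length))
        out.append(ProteinSequence(f"P{i + 1:04d}", residues))
    return out


def gen_sequence_clusters(seed: int, n_clusters: int = 10,
                          cluster_size: int = 5, length: int = 80,
                          within_mutations: int = 3) -> list[ProteinSequence]:
    """Sequence set with planted near-duplicate clusters, for exercising the
    homology splitter: each cluster is an ancestor plus members differing by
    at most ``within_mutations`` substitutions (identity ~ 1 - m/L)."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    out = []
    for c in range(n_clusters):
        ancestor = rng.choice(letters, size=length)
        for m in range(cluster_size):
            member = ancestor.copy()
            n_mut = int(rng.integers(0, within_mutations + 1)) if m else 0
            for pos in rng.choice(length, size=n_mut, replace=False):
                member[pos] = rng.choice(letters)
            out.append(ProteinSequence(f"C{c + 1:02d}M{m + 1:02d}",
                                       "".join(member)))
    return out


def gen_annotations(seq: ProteinSequence, seed: int) -> list[ResidueAnnotation]:
    """Convenience wrapper around :class:`SyntheticAnnotationProvider`."""
    return SyntheticAnnotationProvider(seed).annotate(seq)


@dataclass
class SyntheticDataset:
    config: SimConfig
    sequences: dict[str, ProteinSequence]
    records: list[VariantRecord]       # directs then matched reverses
    X: np.ndarray                      # one row per record, [local | global]
    y: np.ndarray                      # noisy ddG actually stored on records
    y_true: np.ndarray                 # noise-free planted ddG
    planted: PlantedModel
    featurizer: VariantFeaturizer = field(repr=False)

    @property
    def n_pairs(self) -> int:
        return len(self.records) // 2


def gen_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Sample variants, compute their true features, and plant a linear,
    antisymmetric ground truth with independent per-record noise."""
    sequences = gen_sequences(cfg)
    seq_by_id = {s.id: s for s in sequences}
    rng = np.random.default_rng(cfg.seed + 1)

    # distinct (protein, position, target) triples
    chosen: set[tuple[str, int, str]] = set()
    directs: list[VariantRecord] = []
    while len(directs) < cfg.n_variants:
        seq = sequences[int(rng.integers(len(sequences)))]
        pos = int(rng.integers(1, len(seq) + 1))
        wt = seq.residues[pos - 1]
        mut = AMINO_ACIDS[int(rng.integers(20))]
        if mut == wt or (seq.id, pos, mut) in chosen:
            continue
        chosen.add((seq.id, pos, mut))
        directs.append(VariantRecord(seq.id, seq,
                                     PointMutation(wt, pos, mut)))

    provider = SyntheticEmbeddingProvider(seed=cfg.seed, dim=cfg.embed_dim)
    annotator = SyntheticAnnotationProvider(seed=cfg.seed)
    featurizer = VariantFeaturizer(provider, annotator)

    X_direct, _, _ = featurizer.transform(directs)

    # Planted weights; the two P(SS) triples carry opposite weights so the
    # noise-free ddG is exactly antisymmetric under direct/reverse swap.
    wrng = np.random.default_rng(cfg.seed + 2)
    w_local = wrng.normal(size=25)
    w_local[22:25] = -w_local[19:22]
    w_global = wrng.normal(size=cfg.embed_dim)
    c_local = X_direct[:, :25] @ w_local
    c_global = X_direct[:, 25:] @ w_global
    if c_local.std() > 0:
        w_local *= cfg.local_weight / c_local.std()
    if c_global.std() > 0:
        w_global *= cfg.global_weight / c_global.std()
    planted = PlantedModel(w_local=w_local, w_global=w_global)

    y_true_direct = planted.predict(X_direct)
    noise_rng = np.random.default_rng(cfg.seed + 3)
    noise = noise_rng.normal(0.0, cfg.noise_sd, size=2 * cfg.n_variants)

    directs = [
        VariantRecord(r.protein_id, r.wildtype, r.mutation,
                      ddg=float(y_true_direct[i] + noise[i]))
        for i, r in enumerate(directs)
    ]
    reverses = [reverse_variant(r) for r in directs]
    # reverse_variant negates the *noisy* ddG; re-noise independently around
    # the antisymmetric truth instead
    reverses = [
        VariantRecord(r.protein_id, r.wildtype, r.mutation,
                      ddg=float(-y_true_direct[i]
                                + noise[cfg.n_variants + i]),
                      direction="reverse")
        for i, r in enumerate(reverses)
    ]
    records = directs + reverses
    X_reverse, _, _ = featurizer.transform(reverses)
    X = np.vstack([X_direct, X_reverse])
    y = np.array([r.ddg for r in records])
    y_true = np.concatenate([y_true_direct, -y_true_direct])
    return SyntheticDataset(cfg, seq_by_id, records, X, y, y_true, planted,
                            featurizer)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact formats the real pipeline consumes:
    FASTA (base chains), variant CSV, annotation CSV (base + mutated chains,
    keyed by the featurizer's chain-id convention), and the planted truth as
    JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "proteins.fasta",
        "variants": out_dir / "variants.csv",
        "annotations": out_dir / "annotations.csv",
        "planted": out_dir / "planted_model.json",
    }
    write_fasta(ds.sequences.values(), paths["fasta"])
    write_variant_csv(ds.records, paths["variants"])

    annotator = SyntheticAnnotationProvider(seed=ds.config.seed)
    ann_map: dict[str, tuple[str, list[ResidueAnnotation]]] = {}
    for seq in ds.sequences.values():
        ann_map[seq.id] = (seq.residues, annotator.annotate(seq))
    for rec in ds.records:
        for key, chain in zip(chain_keys(rec), (rec.wildtype, rec.mutant)):
            if key not in ann_map:
                ann_map[key] = (chain.residues, annotator.annotate(chain))
    write_netsurfp_csv(ann_map, paths["annotations"])

    with open(paths["planted"], "w", encoding="utf-8") as fh:
        json.dump({
            "config": asdict(ds.config),
            "w_local": ds.planted.w_local.tolist(),
            "w_global": ds.planted.w_global.tolist(),
        }, fh, indent=1)
    return paths
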