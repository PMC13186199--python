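"""Global sequence-change features from protein-language-model embeddings.

A mutation's global signature is the difference of mean-pooled per-residue
embeddings of the mutant and wild-type chains::

    g = mean_pool(embed(mutant)) - mean_pool(embed(wildtype))

which is exactly antisymmetric under swapping the two chains — the structural
hook the downstream model exploits to learn antisymmetric ddG predictions.

Embedding backends are pluggable:

* :class:`SyntheticEmbeddingProvider` — deterministic, hash-seeded
  pseudo-Gaussian rows; no downloads, any width; the backend used in tests.
* :class:`ESM2EmbeddingProvider` — the real ESM-2 checkpoint
  (``esm2_t36_650M_UR50D`` by default) through ``fair-esm``; optional,
  imported lazily, frozen (final representation layer, special tokens
  excluded from pooling).

Embeddings are cacheable on disk keyed by (provider id, sequence hash); a
cache hit never changes any downstream number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Protocol

import numpy as np

from .variants import ProteinSequence, ValidationError

logger = logging.getLogger(__name__)


class EmbeddingProvider(Protocol):
    """Contract every embedding backend satisfies."""

    #: stable identifier, part of the cache key and checkpoint metadata
    provider_id: str
    #: embedding width d
    dim: int

    def embed(self, seq: ProteinSequence) -> np.ndarray:
        """Return an L x d matrix, row i corresponding to residue i
        (special tokens excluded).  Deterministic per (provider, sequence)."""
        ...


class SyntheticEmbeddingProvider:
    """Deterministic stand-in embedding backend.

    Row ``i`` of the matrix for a sequence is drawn from a generator seeded by
    ``sha256(seed | sequence | i | residue_letter)``, so a single-residue
    substitution perturbs every row — and therefore every pooled dimension —
    slightly, mimicking a real language model's global sensitivity to local
    changes.
    """

    def __init__(self, seed: int = 0, dim: int = 32):
        if dim < 1:
            raise ValidationError(f"embedding dim must be >= 1, got {dim}")
        self.seed = int(seed)
        self.dim = int(dim)
        self.provider_id = f"synthetic-v1-seed{self.seed}-d{self.dim}"
        self._memo: dict[str, np.ndarray] = {}

    def embed(self, seq: ProteinSequence) -> np.ndarray:
        memo = self._memo.get(seq.residues)
        if memo is not None:
            return memo.copy()
        rows = np.empty((len(seq), self.dim))
        for i, aa in enumerate(seq.residues):
            key = f"{self.seed}|{seq.residues}|{i}|{aa}".encode()
            digest = hashlib.sha256(key).digest()
            rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
            rows[i] = rng.standard_normal(self.dim)
        if len(self._memo) < 4096:
            self._memo[seq.residues] = rows.copy()
        return rows


class ESM2EmbeddingProvider:
    """Frozen ESM-2 backend via the ``fair-esm`` package (optional extra).

    Uses the final representation layer; BOS/EOS rows are stripped so row i
    corresponds to residue i.  Sequences longer than the 1022-residue token
    limit are reduced to a 1000-residue window centred on ``window_center``
    (the mutation site), which callers must apply identically to wild-type
    and mutant chains.
    """

    TOKEN_LIMIT = 1022
    WINDOW = 1000

    def __init__(self, model_name: str = "esm2_t36_650M_UR50D"):
        try:
            import esm  # noqa: F401  (optional dependency)
            import torch  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional backend
            raise ImportError(
                "the real ESM-2 backend needs the 'fair-esm' and 'torch' "
                "packages; install them or use SyntheticEmbeddingProvider"
            ) from exc
        import esm as _esm
        self._model, alphabet = getattr(_esm.pretrained, model_name)()
        self._model.eval()
        self._batch_converter = alphabet.get_batch_converter()
        self._n_layers = self._model.num_layers
        self.dim = self._model.embed_dim
        self.provider_id = f"esm2-{model_name}"

    def embed(self, seq: ProteinSequence,
              window_center: int | None = None) -> np.ndarray:  # pragma: no cover
        import torch
        residues = seq.residues
        if len(residues) > self.TOKEN_LIMIT:
            if window_center is None:
                raise ValidationError(
                    f"sequence {seq.id!r} exceeds the token limit; a window "
                    "centre (mutation position) is required"
                )
            half = self.WINDOW // 2
            start = min(max(window_center - 1 - half, 0),
                        len(residues) - self.WINDOW)
            residues = residues[start:start + self.WINDOW]
        _, _, tokens = self._batch_converter([(seq.id, residues)])
        with torch.no_grad():
            out = self._model(tokens, repr_layers=[self._n_layers])
        rep = out["representations"][self._n_layers][0]
        return rep[1:len(residues) + 1].cpu().numpy().astype(np.float64)


def mean_pool(matrix: np.ndarray) -> np.ndarray:
    """Average over the residue dimension: L x d -> d."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValidationError(f"expected a non-empty L x d matrix, "
                              f"got shape {matrix.shape}")
    return matrix.mean(axis=0)


def global_delta(
    wildtype: ProteinSequence,
    mutant: ProteinSequence,
    provider: EmbeddingProvider,
    cache: "EmbeddingCache | None" = None,
) -> np.ndarray:
    """Mean-pooled embedding difference, mutant minus wild type."""
    diff = sum(a != b for a, b in zip(wildtype.residues, mutant.residues))
    if len(wildtype) != len(mutant) or diff != 1:
        logger.warning(
            "global_delta called on sequences differing at %s positions "
            "(expected exactly 1)",
            "length+" if len(wildtype) != len(mutant) else diff,
        )

    def pooled(seq: ProteinSequence) -> np.ndarray:
        if cache is not None:
            return mean_pool(cache.get(seq, provider))
        return mean_pool(provider.embed(seq))

    return pooled(mutant) - pooled(wildtype)


class EmbeddingCache:
    """On-disk embedding cache keyed by (provider id, sequence hash).

    Each entry is a ``.npy`` matrix plus a JSON sidecar stamping the provider
    id, width and sequence length; entries failing these checks are treated
    as corrupt and recomputed.
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _paths(self, seq: ProteinSequence,
               provider: EmbeddingProvider) -> tuple[Path, Path]:
        seq_hash = hashlib.sha256(seq.residues.encode()).hexdigest()[:24]
        stem = f"{provider.provider_id}_{seq_hash}"
        return (self.directory / f"{stem}.npy",
                self.directory / f"{stem}.json")

    def get(self, seq: ProteinSequence,
            provider: EmbeddingProvider) -> np.ndarray:
        npy_path, meta_path = self._paths(seq, provider)
        if npy_path.exists() and meta_path.exists():
            try:
                meta = json.loads(meta_path.read_text())
                matrix = np.load(npy_path)
                if (meta.get("provider_id") == provider.provider_id
                        and meta.get("dim") == provider.dim
                        and matrix.shape == (len(seq), provider.dim)
                        and np.all(np.isfinite(matrix))):
                    return matrix
                logger.warning("corrupt cache entry %s; recomputing", npy_path)
            except (ValueError, OSError, json.JSONDecodeError):
                logger.warning("unreadable cache entry %s; recomputing",
                               npy_path)
        matrix = provider.embed(seq)
        np.save(npy_path, matrix)
        meta_path.write_text(json.dumps({
            "provider_id": provider.provider_id,
            "dim": provider.dim,
            "length": len(seq),
        }))
        return matrix
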