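"""Turn variant records into model-ready feature rows.

A feature row is ``[local descriptor (25) | pooled embedding delta (d)]``.
Annotations for the mutant chain come from running the annotation source on
the full mutant sequence (never by copying wild-type values).

Annotation keys
---------------
File-backed annotation sources index chains by id.  The convention: the base
wild-type chain of protein ``P`` has key ``P``; the chain carrying the direct
mutation ``A123G`` has key ``P_A123G``.  A reverse record's wild type is
therefore the ``P_A123G`` chain and its mutant the base chain.
"""

from __future__ import annotations

from typing import Protocol, Sequence

import numpy as np

from .embeddings import EmbeddingCache, EmbeddingProvider, global_delta
from .local_features import AAPTable, ResidueAnnotation, build_local_vector
from .variants import ProteinSequence, VariantRecord


class MissingAnnotationError(KeyError):
    """No annotations available for a chain the featurizer needs."""


class AnnotationSource(Protocol):
    def get(self, key: str, seq: ProteinSequence) -> list[ResidueAnnotation]:
        """Per-residue annotations for a chain, addressed by key and/or
        sequence.  Raises MissingAnnotationError when unavailable."""
        ...


class CSVAnnotationSource:
    """Annotation lookup backed by a NetSurfP-dialect CSV already in memory."""

    def __init__(self, table: dict[str, list[ResidueAnnotation]]):
        self.table = table

    def get(self, key: str, seq: ProteinSequence) -> list[ResidueAnnotation]:
        try:
            anns = self.table[key]
        except KeyError:
            raise MissingAnnotationError(key) from None
        if len(anns) != len(seq):
            raise MissingAnnotationError(
                f"{key}: {len(anns)} annotation rows for a "
                f"{len(seq)}-residue chain"
            )
        return anns


def chain_keys(rec: VariantRecord) -> tuple[str, str]:
    """(wild-type key, mutant key) for a record under the id convention."""
    if rec.direction == "direct":
        return rec.protein_id, f"{rec.protein_id}_{rec.mutation.code}"
    return (f"{rec.protein_id}_{rec.mutation.inverse().code}",
            rec.protein_id)


class VariantFeaturizer:
    """Compose local and global feature extraction for variant records."""

    def __init__(self, embedding_provider: EmbeddingProvider,
                 annotation_source: AnnotationSource,
                 aap_table: AAPTable | None = None,
                 cache: EmbeddingCache | None = None):
        self.embedding_provider = embedding_provider
        self.annotation_source = annotation_source
        self.aap_table = aap_table if aap_table is not None else AAPTable.default()
        self.cache = cache

    @property
    def n_features(self) -> int:
        return 25 + self.embedding_provider.dim

    def site_annotations(
        self, rec: VariantRecord
    ) -> tuple[ResidueAnnotation, ResidueAnnotation]:
        """(wild-type, mutant) annotations at the mutated position."""
        wt_key, mut_key = chain_keys(rec)
        wt_anns = self.annotation_source.get(wt_key, rec.wildtype)
        mut_anns = self.annotation_source.get(mut_key, rec.mutant)
        pos = rec.mutation.position - 1
        return wt_anns[pos], mut_anns[pos]

    def feature_row(self, rec: VariantRecord) -> np.ndarray:
        wt_ann, mut_ann = self.site_annotations(rec)
        local = build_local_vector(wt_ann, mut_ann, rec.mutation,
                                   self.aap_table)
        delta = global_delta(rec.wildtype, rec.mutant,
                             self.embedding_provider, cache=self.cache)
        return np.concatenate([local, delta])

    def transform(
        self, records: Sequence[VariantRecord], skip_missing: bool = False
    ) -> tuple[np.ndarray, list[int], list[tuple[int, str]]]:
        """Feature matrix for a batch of records.

        Returns ``(X, kept_indices, skipped)``; with ``skip_missing=False``
        the first missing annotation raises.
        """
        rows, kept, skipped = [], [], []
        for i, rec in enumerate(records):
            try:
                rows.append(self.feature_row(rec))
            except MissingAnnotationError as exc:
                if not skip_missing:
                    raise
                skipped.append((i, str(exc)))
                continue
            kept.append(i)
        X = (np.vstack(rows) if rows
             else np.empty((0, self.n_features)))
        return X, kept, skipped


def predict_variant(rec: VariantRecord, model,
                    featurizer: VariantFeaturizer) -> float:
    """End-to-end single-variant prediction through a fitted model or
    fold ensemble."""
    row = featurizer.feature_row(rec)
    return float(model.predict(row[None, :])[0])
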