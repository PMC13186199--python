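"""Mutation datasets: parsing, validation, reverse augmentation, deduplication,
homology-aware fold splitting, and FASTA / variant-CSV round-tripping.

Conventions
-----------
* Mutation codes use the field-standard ``A123G`` notation with **1-based**
  positions: wild-type residue, position, mutant residue.
* Sign convention: positive ddG is stabilizing.  Public datasets disagree on
  this, so the CSV reader accepts ``flip_sign=True``.
* A *reverse* variant is the formally antisymmetric mutation B->A applied to
  the mutant sequence; its experimental ddG is the negation of the direct one.
  Reverse records inherit the fold label of their direct counterpart so a
  mutation pair never straddles a train/validation boundary.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class ValidationError(ValueError):
    """Raised when an input fails a domain invariant."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein chain over the 20-letter amino-acid alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PointMutation:
    """A single-residue substitution, 1-based position."""

    wt_residue: str
    position: int
    mut_residue: str

    def __post_init__(self) -> None:
        for letter in (self.wt_residue, self.mut_residue):
            if letter not in _AA_SET:
                raise ValidationError(f"invalid amino-acid letter {letter!r}")
        if self.wt_residue == self.mut_residue:
            raise ValidationError(
                f"wild-type and mutant residue are both {self.wt_residue!r}"
            )
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")

    @property
    def code(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"

    def inverse(self) -> "PointMutation":
        return PointMutation(self.mut_residue, self.position, self.wt_residue)


@dataclass(frozen=True)
class VariantRecord:
    """One mutation event with optional experimental ddG (kcal/mol).

    ``wildtype`` is the sequence the mutation applies to: for a reverse
    record that is the mutant chain of its direct counterpart.
    """

    protein_id: str
    wildtype: ProteinSequence
    mutation: PointMutation
    ddg: float | None = None
    direction: str = "direct"
    fold_label: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("direct", "reverse"):
            raise ValidationError(f"invalid direction {self.direction!r}")
        validate_mutation(self.wildtype, self.mutation)

    @property
    def mutant(self) -> ProteinSequence:
        return apply_mutation(self.wildtype, self.mutation)

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        m = self.mutation
        return (self.protein_id, m.wt_residue, m.position, m.mut_residue,
                self.direction)


def validate_mutation(seq: ProteinSequence, mut: PointMutation) -> None:
    if mut.position > len(seq):
        raise ValidationError(
            f"position {mut.position} out of range for sequence {seq.id!r} "
            f"of length {len(seq)}"
        )
    actual = seq.residues[mut.position - 1]
    if actual != mut.wt_residue:
        raise ValidationError(
            f"sequence {seq.id!r} has {actual!r} at position {mut.position}, "
            f"not {mut.wt_residue!r}"
        )


def parse_mutation(code: str, sequence: ProteinSequence) -> PointMutation:
    """Parse a mutation code such as ``"A123G"`` and validate it.

    The wild-type letter must match ``sequence`` at the (1-based) position.
    """
    m = _MUTATION_RE.match(code.strip())
    if m is None:
        raise ValidationError(f"malformed mutation code {code!r}")
    mut = PointMutation(m.group(1).upper(), int(m.group(2)), m.group(3).upper())
    validate_mutation(sequence, mut)
    return mut


def apply_mutation(seq: ProteinSequence, mut: PointMutation) -> ProteinSequence:
    """Return the mutant sequence; differs from the input at exactly one site."""
    validate_mutation(seq, mut)
    residues = (seq.residues[: mut.position - 1] + mut.mut_residue
                + seq.residues[mut.position:])
    return ProteinSequence(seq.id, residues)


def reverse_variant(rec: VariantRecord) -> VariantRecord:
    """The antisymmetric counterpart: sequences swapped, mutation inverted,
    ddG negated.  An involution: ``reverse_variant(reverse_variant(r)) == r``.
    """
    if rec.ddg is None:
        raise ValidationError("cannot reverse a record without a ddG value")
    return VariantRecord(
        protein_id=rec.protein_id,
        wildtype=rec.mutant,
        mutation=rec.mutation.inverse(),
        ddg=-rec.ddg,
        direction="reverse" if rec.direction == "direct" else "direct",
        fold_label=rec.fold_label,
    )


def augment_with_reverse(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Append the reverse of every direct record that carries a ddG."""
    out = list(records)
    out.extend(reverse_variant(r) for r in list(out)
               if r.direction == "direct" and r.ddg is not None)
    return out


def deduplicate_average(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Collapse duplicate (protein, mutation, direction) keys to one record
    whose ddG is the arithmetic mean of the duplicates.  Output sorted by key.
    """
    groups: dict[tuple, list[VariantRecord]] = {}
    for rec in records:
        groups.setdefault(rec.key, []).append(rec)
    out = []
    for key in sorted(groups):
        members = groups[key]
        ddgs = [r.ddg for r in members if r.ddg is not None]
        mean = sum(ddgs) / len(ddgs) if ddgs else None
        out.append(replace(members[0], ddg=mean))
    return out


# ---------------------------------------------------------------------------
# Homology-aware fold splitting
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Needleman-Wunsch edit distance (edlib ``NW`` task) normalised by the
    longer sequence: identity = 1 - d / max(|a|, |b|).
    """
    if a == b:
        return 1.0
    d = edlib.align(a, b, task="distance", mode="NW")["editDistance"]
    return max(0.0, 1.0 - d / max(len(a), len(b)))


def _single_linkage_clusters(
    sequences: Sequence[ProteinSequence], threshold: float
) -> list[list[int]]:
    n = len(sequences)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(sequences[i].residues,
                                 sequences[j].residues) >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def homology_fold_split(
    sequences: Sequence[ProteinSequence],
    k: int = 5,
    identity_threshold: float = 0.25,
) -> dict[str, int]:
    """Partition sequences into ``k`` folds (labels 1..k) such that no two
    sequences with pairwise identity >= ``identity_threshold`` are separated.

    Single-linkage clustering on global-alignment identity, then greedy
    balanced assignment: largest cluster first, to the currently smallest fold.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if not 0.0 < identity_threshold < 1.0:
        raise ValidationError(
            f"identity threshold must be in (0, 1), got {identity_threshold}"
        )
    ids = [s.id for s in sequences]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sequence ids in fold-split input")

    clusters = _single_linkage_clusters(sequences, identity_threshold)
    if len(clusters) < k:
        logger.warning(
            "only %d homology clusters for %d folds; some folds will be empty",
            len(clusters), k,
        )
    # Largest first; ties broken by the smallest member id for determinism.
    clusters.sort(key=lambda c: (-len(c), min(ids[i] for i in c)))
    fold_sizes = [0] * k
    assignment: dict[str, int] = {}
    for cluster in clusters:
        fold = min(range(k), key=lambda f: (fold_sizes[f], f))
        fold_sizes[fold] += len(cluster)
        for i in cluster:
            assignment[ids[i]] = fold + 1
    return assignment


# ---------------------------------------------------------------------------
# FASTA and variant-CSV input/output
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, ProteinSequence]:
    """Read a multi-record FASTA into an id -> ProteinSequence mapping."""
    out: dict[str, ProteinSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = ProteinSequence(rec.id, str(rec.seq).upper())
    return out


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="")
               for s in sequences]
    SeqIO.write(records, str(path), "fasta")


VARIANT_CSV_COLUMNS = ("protein_id", "mutation", "ddg", "direction", "fold")


def read_variant_csv(
    path: str | Path,
    sequences: Mapping[str, ProteinSequence],
    flip_sign: bool = False,
) -> list[VariantRecord]:
    """Read a variant table (columns ``protein_id,mutation,ddg``; optional
    ``direction,fold``).  ``ddg`` may be empty or ``NA`` for prediction-only
    rows.  For ``direction=reverse`` rows the mutation code is written
    relative to the row's own wild type, i.e. the mutant chain of the direct
    counterpart.
    """
    records: list[VariantRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: missing header row")
        missing = {"protein_id", "mutation", "ddg"} - set(reader.fieldnames)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            pid = row["protein_id"].strip()
            if pid not in sequences:
                raise ValidationError(
                    f"{path}:{line_no}: unknown protein id {pid!r}"
                )
            base = sequences[pid]
            direction = (row.get("direction") or "direct").strip() or "direct"
            raw_ddg = (row["ddg"] or "").strip()
            ddg = None if raw_ddg in ("", "NA") else float(raw_ddg)
            if ddg is not None and flip_sign:
                ddg = -ddg
            raw_fold = (row.get("fold") or "").strip()
            fold = int(raw_fold) if raw_fold else None
            try:
                if direction == "reverse":
                    # The row's wild type is the base protein carrying the
                    # inverse mutation.
                    m = _MUTATION_RE.match(row["mutation"].strip())
                    if m is None:
                        raise ValidationError(
                            f"malformed mutation code {row['mutation']!r}"
                        )
                    inverse = PointMutation(m.group(3).upper(),
                                            int(m.group(2)),
                                            m.group(1).upper())
                    wildtype = apply_mutation(base, inverse)
                    mutation = parse_mutation(row["mutation"], wildtype)
                else:
                    wildtype = base
                    mutation = parse_mutation(row["mutation"], base)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{line_no}: {exc}") from exc
            records.append(VariantRecord(pid, wildtype, mutation, ddg,
                                         direction, fold))
    return records


def write_variant_csv(records: Iterable[VariantRecord],
                      path: str | Path) -> None:
    """Write records in the standard variant-CSV schema.  ddG is written with
    9 significant digits so it round-trips to at least 6.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(VARIANT_CSV_COLUMNS)
        for rec in records:
            ddg = "" if rec.ddg is None else f"{rec.ddg:.9g}"
            fold = "" if rec.fold_label is None else str(rec.fold_label)
            writer.writerow([rec.protein_id, rec.mutation.code, ddg,
                             rec.direction, fold])
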