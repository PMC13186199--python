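"""The 25-dimensional local mutation descriptor.

For a mutated position the descriptor stacks, in fixed block order::

    [dRSA(1), dV_phipsi(4), dDisorder(1), dAAP(13), P(SS)_wt(3), P(SS)_mut(3)]

where the difference blocks are mutant minus wild type, dV_phipsi is the
difference of [sin(phi), cos(phi), sin(psi), cos(psi)] encodings (removing the
+/-180 degree periodicity artifact), dAAP is the difference of 13 z-normalised
amino-acid physicochemical properties, and the two P(SS) triples are the
three-state secondary-structure probabilities (helix, sheet, coil) of the
wild-type and mutant residue.

Annotations come from NetSurfP-3.0-style per-residue predictions (or the
synthetic annotation provider); mutant annotations are computed on the full
mutant sequence, not copied from the wild type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .variants import AMINO_ACIDS, PointMutation, ValidationError

N_LOCAL_FEATURES = 25
N_AAP = 13

#: block layout of the local vector: name -> (start, stop)
LOCAL_BLOCKS = {
    "dRSA": (0, 1),
    "dV_phipsi": (1, 5),
    "dDisorder": (5, 6),
    "dAAP": (6, 19),
    "PSS_wt": (19, 22),
    "PSS_mut": (22, 25),
}


@dataclass(frozen=True)
class ResidueAnnotation:
    """Per-residue structural descriptors in the NetSurfP-3.0 convention.

    Secondary-structure probabilities are renormalised to sum to 1; RSA is
    clamped to [0, 1]; angles are degrees in [-180, 180].
    """

    p_helix: float
    p_sheet: float
    p_coil: float
    rsa: float
    disorder: float
    phi: float
    psi: float

    def __post_init__(self) -> None:
        total = self.p_helix + self.p_sheet + self.p_coil
        if not math.isfinite(total) or total <= 0:
            raise ValidationError(f"invalid P(SS) triple summing to {total}")
        if abs(total - 1.0) > 1e-3:
            object.__setattr__(self, "p_helix", self.p_helix / total)
            object.__setattr__(self, "p_sheet", self.p_sheet / total)
            object.__setattr__(self, "p_coil", self.p_coil / total)
        object.__setattr__(self, "rsa", min(max(self.rsa, 0.0), 1.0))
        for name in ("disorder", "phi", "psi"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"non-finite {name}")

    @property
    def pss(self) -> np.ndarray:
        return np.array([self.p_helix, self.p_sheet, self.p_coil])

    @property
    def ss_class(self) -> str:
        return ("helix", "sheet", "coil")[int(np.argmax(self.pss))]


class AAPTable:
    """20 residues x 13 physicochemical properties, z-normalised per column
    across the 20 residues (population standard deviation)."""

    def __init__(self, raw: pd.DataFrame):
        if set(raw.index) != set(AMINO_ACIDS):
            raise ValidationError(
                "property table must index exactly the 20 standard residues"
            )
        if raw.shape[1] != N_AAP:
            raise ValidationError(
                f"property table must have {N_AAP} columns, got {raw.shape[1]}"
            )
        raw = raw.loc[list(AMINO_ACIDS)].astype(float)
        self.property_names = list(raw.columns)
        values = raw.to_numpy()
        mean = values.mean(axis=0)
        std = values.std(axis=0)
        if np.any(std == 0):
            raise ValidationError("constant property column cannot be z-scored")
        self._normalized = (values - mean) / std
        self._row = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    def __getitem__(self, residue: str) -> np.ndarray:
        try:
            return self._normalized[self._row[residue]]
        except KeyError:
            raise ValidationError(f"unknown residue {residue!r}") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "AAPTable":
        raw = pd.read_csv(path, index_col=0)
        return cls(raw)

    @classmethod
    def default(cls) -> "AAPTable":
        with resources.as_file(
            resources.files("ddgfuse.data") / "aa_properties.csv"
        ) as path:
            return cls.from_csv(path)


#: Theoretical maximum accessible surface areas (A^2) per residue, used to
#: turn absolute ASA into relative solvent accessibility.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


def rsa_from_asa(asa: float, max_asa: float) -> float:
    """Relative solvent accessibility: ASA over the residue's maximum ASA,
    clamped to [0, 1]."""
    if max_asa <= 0:
        raise ValidationError(f"max ASA must be positive, got {max_asa}")
    if asa < 0 or not math.isfinite(asa):
        raise ValidationError(f"invalid ASA {asa}")
    return min(asa / max_asa, 1.0)


def dihedral_encoding(phi: float, psi: float) -> np.ndarray:
    """[sin(phi), cos(phi), sin(psi), cos(psi)] with angles in degrees.

    Periodic by construction, so the +/-180 degree wrap-around of raw
    dihedral angles cannot produce a spurious feature jump.
    """
    if not (math.isfinite(phi) and math.isfinite(psi)):
        raise ValidationError("non-finite dihedral angle")
    phi_r, psi_r = math.radians(phi), math.radians(psi)
    return np.array([math.sin(phi_r), math.cos(phi_r),
                     math.sin(psi_r), math.cos(psi_r)])


def delta_aap(wt: str, mut: str, table: AAPTable) -> np.ndarray:
    """Componentwise property change: table[mut] - table[wt]."""
    return table[mut] - table[wt]


def build_local_vector(
    wt_ann: ResidueAnnotation,
    mut_ann: ResidueAnnotation,
    mut: PointMutation,
    table: AAPTable,
) -> np.ndarray:
    """Assemble the 25-dimensional local descriptor at the mutated position.

    Under direct/reverse swap the difference blocks (indices 0-18) negate
    exactly and the two P(SS) triples exchange.
    """
    drsa = mut_ann.rsa - wt_ann.rsa
    dv = (dihedral_encoding(mut_ann.phi, mut_ann.psi)
          - dihedral_encoding(wt_ann.phi, wt_ann.psi))
    ddis = mut_ann.disorder - wt_ann.disorder
    daap = delta_aap(mut.wt_residue, mut.mut_residue, table)
    vec = np.concatenate([[drsa], dv, [ddis], daap, wt_ann.pss, mut_ann.pss])
    if not np.all(np.isfinite(vec)):
        raise ValidationError("non-finite local feature vector")
    assert vec.shape == (N_LOCAL_FEATURES,)
    return vec


# ---------------------------------------------------------------------------
# NetSurfP-3.0 CSV dialect reader
# ---------------------------------------------------------------------------

_SS8_TO_3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def collapse_ss8(probs: dict[str, float]) -> tuple[float, float, float]:
    """Collapse 8-state secondary-structure probabilities to 3 states
    (H,G,I -> helix; E,B -> sheet; rest -> coil) and renormalise."""
    h = e = c = 0.0
    for state, p in probs.items():
        cls = _SS8_TO_3.get(state.upper(), "C")
        if cls == "H":
            h += p
        elif cls == "E":
            e += p
        else:
            c += p
    total = h + e + c
    if total <= 0:
        raise ValidationError("secondary-structure probabilities sum to zero")
    return h / total, e / total, c / total


def read_netsurfp_csv(path: str | Path) -> dict[str, list[ResidueAnnotation]]:
    """Read per-residue annotations in the NetSurfP-3.0 CSV dialect.

    Required columns: ``id, seq, n, rsa, asa, q3, p[q3_H], p[q3_E], p[q3_C],
    phi, psi, disorder`` (extra columns ignored; ``n`` is the 1-based residue
    index).  When ``rsa`` is missing or empty it is derived from ``asa`` and
    the residue's maximum ASA.  Returns id -> annotation list ordered by
    residue index.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    required = {"id", "seq", "n", "p[q3_H]", "p[q3_E]", "p[q3_C]",
                "phi", "psi", "disorder"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[ResidueAnnotation]] = {}
    for seq_id, group in df.groupby("id", sort=False):
        group = group.sort_values("n")
        expected = np.arange(1, len(group) + 1)
        if not np.array_equal(group["n"].to_numpy(), expected):
            raise ValidationError(
                f"{path}: residue indices for {seq_id!r} are not 1..L"
            )
        if "rsa" in group.columns:
            rsa_col = group["rsa"].to_numpy(dtype=float)
        else:
            rsa_col = np.full(len(group), np.nan)
        missing = ~np.isfinite(rsa_col)
        if missing.any():
            asa = group["asa"].to_numpy(dtype=float)
            letters = group["seq"].astype(str).str.upper().to_numpy()
            rsa_col = rsa_col.copy()
            rsa_col[missing] = [
                rsa_from_asa(a, MAX_ASA[aa])
                for a, aa in zip(asa[missing], letters[missing])
            ]
        out[str(seq_id)] = [
            ResidueAnnotation(p_helix=h, p_sheet=e, p_coil=c, rsa=r,
                              disorder=d, phi=f, psi=p)
            for h, e, c, r, d, f, p in zip(
                group["p[q3_H]"].to_numpy(dtype=float),
                group["p[q3_E]"].to_numpy(dtype=float),
                group["p[q3_C]"].to_numpy(dtype=float),
                rsa_col,
                group["disorder"].to_numpy(dtype=float),
                group["phi"].to_numpy(dtype=float),
                group["psi"].to_numpy(dtype=float))
        ]
    return out


def write_netsurfp_csv(
    annotations: dict[str, tuple[str, list[ResidueAnnotation]]],
    path: str | Path,
) -> None:
    """Write annotations in the NetSurfP CSV dialect.

    ``annotations`` maps id -> (sequence, per-residue annotations).
    """
    rows = []
    for seq_id, (seq, anns) in annotations.items():
        if len(seq) != len(anns):
            raise ValidationError(
                f"sequence/annotation length mismatch for {seq_id!r}"
            )
        for i, (aa, ann) in enumerate(zip(seq, anns), start=1):
            q3 = "HEC"[int(np.argmax(ann.pss))]
            rows.append({
                "id": seq_id, "seq": aa, "n": i,
                "rsa": f"{ann.rsa:.6f}",
                "asa": f"{ann.rsa * MAX_ASA[aa]:.3f}",
                "q3": q3,
                "p[q3_H]": f"{ann.p_helix:.6f}",
                "p[q3_E]": f"{ann.p_sheet:.6f}",
                "p[q3_C]": f"{ann.p_coil:.6f}",
                "phi": f"{ann.phi:.3f}",
                "psi": f"{ann.psi:.3f}",
                "disorder": f"{ann.disorder:.6f}",
            })
    pd.DataFrame(rows).to_csv(path, index=False)
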