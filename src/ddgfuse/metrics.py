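"""Evaluation suite: regression metrics, antisymmetry diagnostics, and
stratified analyses.

Metrics
-------
* RMSE (kcal/mol) and Pearson correlation between predicted and experimental
  ddG.
* ACC: sign-classification accuracy with ddG >= 0 classed stabilizing
  (exact zero is stabilizing on both sides).
* Antisymmetry r_d-r: Pearson correlation between predictions on matched
  direct and reverse variants (-1 is ideal).
* Bias <delta>: mean of (direct + reverse)/2 over matched pairs (0 is ideal).

Stratifications follow the field's conventions: solvent exposure (RSA > 0.5
exposed, < 0.1 buried), wild-type secondary-structure class (argmax of the
P(SS) triple), mutation direction, and experimentally stabilizing subsets.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricReport:
    label: str
    n: int
    rmse: float | None
    pcc: float | None
    acc: float | None

    def as_dict(self) -> dict:
        return {"subset": self.label, "n": self.n, "rmse": self.rmse,
                "pcc": self.pcc, "acc": self.acc}


@dataclass(frozen=True)
class AntisymmetryReport:
    rd_r: float
    delta_bias: float
    n_pairs: int


def _check_lengths(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError(
            f"expected matching 1-D vectors, got {pred.shape} vs {truth.shape}"
        )
    return pred, truth


def rmse(pred, truth) -> float:
    """Root-mean-square error."""
    pred, truth = _check_lengths(pred, truth)
    if len(pred) < 1:
        raise ValueError("rmse needs at least one element")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def pcc(pred, truth) -> float:
    """Pearson product-moment correlation; NaN (with a warning) when either
    input is constant."""
    pred, truth = _check_lengths(pred, truth)
    if len(pred) < 2:
        raise ValueError("pcc needs at least two elements")
    if np.std(pred) == 0 or np.std(truth) == 0:
        logger.warning("pcc undefined for constant input; returning NaN")
        return float("nan")
    return float(stats.pearsonr(pred, truth).statistic)


def acc(pred, truth) -> float:
    """Sign-classification accuracy: stabilizing iff ddG >= 0."""
    pred, truth = _check_lengths(pred, truth)
    if len(pred) < 1:
        raise ValueError("acc needs at least one element")
    return float(np.mean((pred >= 0) == (truth >= 0)))


def antisymmetry_metrics(pred_direct, pred_reverse) -> AntisymmetryReport:
    """Antisymmetry correlation and bias over matched direct/reverse pairs.

    ``rd_r`` is the Pearson correlation of the two prediction vectors;
    ``delta_bias`` is the mean of delta_i = (direct_i + reverse_i) / 2.
    """
    pred_direct, pred_reverse = _check_lengths(pred_direct, pred_reverse)
    if len(pred_direct) < 2:
        raise ValueError("antisymmetry metrics need at least two pairs")
    delta = (pred_direct + pred_reverse) / 2.0
    return AntisymmetryReport(
        rd_r=pcc(pred_direct, pred_reverse),
        delta_bias=float(np.mean(delta)),
        n_pairs=len(pred_direct),
    )


def metric_report(label: str, pred, truth) -> MetricReport:
    """All three point metrics for one subset; NA metrics for empty subsets."""
    pred = np.asarray(pred, dtype=float)
    if len(pred) == 0:
        return MetricReport(label, 0, None, None, None)
    truth = np.asarray(truth, dtype=float)
    return MetricReport(
        label, len(pred), rmse(pred, truth),
        pcc(pred, truth) if len(pred) >= 2 else None,
        acc(pred, truth),
    )


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

def rsa_class(rsa: float) -> str:
    """Solvent exposure class: exposed (RSA > 0.5), buried (RSA < 0.1),
    intermediate otherwise."""
    if rsa > 0.5:
        return "exposed"
    if rsa < 0.1:
        return "buried"
    return "intermediate"


STRATIFICATION_SCHEMES = ("rsa_class", "ss_class", "direction", "stabilizing")


def stratify(
    pred: Sequence[float],
    truth: Sequence[float],
    scheme: str,
    *,
    rsa: Sequence[float] | None = None,
    ss: Sequence[str] | None = None,
    direction: Sequence[str] | None = None,
) -> list[MetricReport]:
    """Partition predictions into subsets under one scheme and score each.

    ``rsa`` and ``ss`` are the wild-type mutated-residue annotation values
    (RSA fraction; secondary-structure class from the P(SS) argmax).
    The subsets of a scheme partition the input; empty subsets are reported
    with n = 0 and NA metrics.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if scheme == "rsa_class":
        if rsa is None:
            raise ValueError("rsa_class stratification needs RSA values")
        labels = np.array([rsa_class(r) for r in rsa])
        classes = ["buried", "intermediate", "exposed"]
    elif scheme == "ss_class":
        if ss is None:
            raise ValueError("ss_class stratification needs SS classes")
        labels = np.asarray(ss)
        classes = ["helix", "sheet", "coil"]
    elif scheme == "direction":
        if direction is None:
            raise ValueError("direction stratification needs directions")
        labels = np.asarray(direction)
        classes = ["direct", "reverse"]
    elif scheme == "stabilizing":
        labels = np.where(truth >= 0, "stabilizing", "destabilizing")
        classes = ["stabilizing", "destabilizing"]
    else:
        raise ValueError(f"unknown stratification scheme {scheme!r}")
    if len(labels) != len(pred):
        raise ValueError("label vector length mismatch")
    return [
        metric_report(f"{scheme}={cls}", pred[labels == cls],
                      truth[labels == cls])
        for cls in classes
    ]


def pair_direct_reverse(
    records: Sequence, pred: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Match predictions on direct records with their reverse counterparts.

    Pairing key: (protein id, direct-orientation mutation code).  Returns the
    two aligned prediction vectors (direct, reverse).
    """
    direct: dict[tuple[str, str], float] = {}
    reverse: dict[tuple[str, str], float] = {}
    for rec, p in zip(records, pred):
        if rec.direction == "direct":
            direct[(rec.protein_id, rec.mutation.code)] = p
        else:
            reverse[(rec.protein_id, rec.mutation.inverse().code)] = p
    keys = sorted(set(direct) & set(reverse))
    return (np.array([direct[k] for k in keys]),
            np.array([reverse[k] for k in keys]))


# ---------------------------------------------------------------------------
# Fusion-weight export
# ---------------------------------------------------------------------------

def export_fusion_weights(model, path: str | Path | None = None) -> pd.DataFrame:
    """Absolute values of the learned element-wise fusion weights.

    One row per latent dimension with |g_weight| and |r_weight|, plus the two
    mean absolute weights — the quantities summarising how much each branch
    contributes to the fused representation.  Only defined for
    linear-combination fusion.
    """
    g, r = model.fusion_weights()
    table = pd.DataFrame({
        "dimension": np.arange(len(g)),
        "abs_g_weight": np.abs(g),
        "abs_r_weight": np.abs(r),
    })
    table.attrs["mean_abs_g_weight"] = float(np.abs(g).mean())
    table.attrs["mean_abs_r_weight"] = float(np.abs(r).mean())
    if path is not None:
        table.to_csv(path, index=False)
    return table


def write_report_csv(reports: Sequence[MetricReport], path: str | Path,
                     antisymmetry: AntisymmetryReport | None = None) -> None:
    """One row per subset; antisymmetry appended as its own rows when given."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subset", "n", "rmse", "pcc", "acc"])
        for rep in reports:
            writer.writerow([
                rep.label, rep.n,
                "" if rep.rmse is None else f"{rep.rmse:.6g}",
                "" if rep.pcc is None or math.isnan(rep.pcc)
                else f"{rep.pcc:.6g}",
                "" if rep.acc is None else f"{rep.acc:.6g}",
            ])
        if antisymmetry is not None:
            writer.writerow(["antisymmetry_rd_r", antisymmetry.n_pairs,
                             "", f"{antisymmetry.rd_r:.6g}", ""])
            writer.writerow(["bias_delta", antisymmetry.n_pairs,
                             f"{antisymmetry.delta_bias:.6g}", "", ""])


def format_report(reports: Sequence[MetricReport],
                  antisymmetry: AntisymmetryReport | None = None) -> str:
    """Human-readable summary of subset metrics."""
    lines = [f"{'subset':<28}{'n':>6}{'rmse':>10}{'pcc':>10}{'acc':>10}"]
    for rep in reports:
        def fmt(v):
            return "NA" if v is None or (isinstance(v, float)
                                         and math.isnan(v)) else f"{v:.3f}"
        lines.append(f"{rep.label:<28}{rep.n:>6}{fmt(rep.rmse):>10}"
                     f"{fmt(rep.pcc):>10}{fmt(rep.acc):>10}")
    if antisymmetry is not None:
        lines.append(
            f"antisymmetry: r_d-r = {antisymmetry.rd_r:.3f}, "
            f"<delta> = {antisymmetry.delta_bias:.3f} kcal/mol "
            f"over {antisymmetry.n_pairs} pairs"
        )
    return "\n".join(lines)
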