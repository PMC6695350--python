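"""Diel-vs-circadian conservation calls and qPCR relative quantification.

``response_correlation`` asks whether a gene's four-condition response
profile measured under entrained (diel) conditions is reproduced in a
constant-light (circadian) experiment sequenced at single-replicate depth:
the per-condition mean normalized counts of the diel experiment are
correlated (Pearson) with the single circadian replicate, and the r value
is banded into ``conserved`` (r above the strong-correlation threshold),
``review`` (intermediate band, mirroring a manual-evaluation step) and
``not_conserved``.

``delta_delta_cq`` implements standard qPCR relative quantification: the
target Cq is normalized against the mean of one or more reference-gene
Cqs (arithmetic mean of Cq = geometric mean of linear quantities), then
against the mean of a calibrator group, and converted to a linear ratio
via the amplification efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix, Thresholds, ValidationError, normalized_counts, GROUPS


@dataclass
class ConservationCall:
    """Per-gene Pearson r between diel and circadian profiles plus class."""

    table: pd.DataFrame  # index gene: r, cls, flag

    def __len__(self) -> int:
        return len(self.table)


def _condition_profile(m: CountMatrix, genes, log_scale: bool) -> pd.DataFrame:
    """Gene x 4 condition means of normalized counts in canonical order."""
    expr = normalized_counts(m).loc[list(genes)]
    labels = m.group_labels()
    prof = pd.DataFrame(
        {g: expr.loc[:, (labels == g).to_numpy()].mean(axis=1) for g in GROUPS}
    )
    if log_scale:
        prof = np.log2(prof + 1.0)
    return prof


def response_correlation(
    diel: CountMatrix,
    circadian: CountMatrix,
    genes=None,
    thresholds: Thresholds | None = None,
    log_scale: bool = False,
) -> ConservationCall:
    """Pearson correlation of the 4-condition profiles of two experiments.

    Both matrices must contain all four time-condition groups.  Genes with
    zero variance in either profile have undefined r; they are reported
    with ``r`` missing, class ``not_conserved`` and flag ``zero_variance``.
    """
    thresholds = thresholds or Thresholds()
    for name, m in (("diel", diel), ("circadian", circadian)):
        present = set(m.group_labels())
        missing = [g for g in GROUPS if g not in present]
        if missing:
            raise ValidationError(f"{name} matrix lacks group(s): {missing}")
    if genes is None:
        genes = diel.genes.intersection(circadian.genes)
    genes = list(genes)

    a = _condition_profile(diel, genes, log_scale).to_numpy()
    b = _condition_profile(circadian, genes, log_scale).to_numpy()
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (ac * bc).sum(axis=1) / denom, np.nan)

    cls = np.where(
        np.isnan(r),
        "not_conserved",
        np.where(
            r > thresholds.r_conserved,
            "conserved",
            np.where(r > thresholds.r_review, "review", "not_conserved"),
        ),
    )
    flag = np.where(np.isnan(r), "zero_variance", "ok")
    return ConservationCall(
        pd.DataFrame({"r": r, "cls": cls, "flag": flag}, index=pd.Index(genes, name="gene"))
    )


def delta_delta_cq(
    cq: pd.DataFrame,
    target_col: str = "target_cq",
    reference_cols: tuple[str, ...] | list[str] = ("ref_cq",),
    group_col: str = "group",
    calibrator_group: str = "PM_control",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative expression by the delta-delta-Cq method.

    Per sample: ``dCq = target Cq - mean(reference Cqs)``; ``ddCq = dCq -
    mean dCq of the calibrator group``; ``rel_expr = efficiency**(-ddCq)``.
    The calibrator group therefore averages a ddCq of zero; its mean
    relative expression is 1 by construction (up to the arithmetic/
    geometric mean distinction on the linear scale).
    """
    for col in (target_col, group_col, *reference_cols):
        if col not in cq.columns:
            raise ValidationError(f"Cq table lacks column {col!r}")
        if col != group_col and cq[col].isna().any():
            bad = cq.index[cq[col].isna()][0]
            raise ValidationError(f"missing Cq in column {col!r} (sample {bad!r})")
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must exceed 1")
    if not (cq[group_col] == calibrator_group).any():
        raise ValidationError(f"calibrator group {calibrator_group!r} is empty")

    ref_mean = cq[list(reference_cols)].mean(axis=1)
    dcq = cq[target_col] - ref_mean
    calib = dcq[cq[group_col] == calibrator_group].mean()
    ddcq = dcq - calib
    out = cq.copy()
    out["dCq"] = dcq
    out["ddCq"] = ddcq
    out["rel_expr"] = np.power(float(efficiency), -ddcq)
    return out
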