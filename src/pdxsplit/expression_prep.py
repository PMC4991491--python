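"""Expression-matrix preparation and small threshold classifiers.

Covers the pre-clustering gene filters (species-specific FPKM floor plus a
coefficient-of-variation floor), the non-negative log transform
log2(FPKM + 1.1) used by clustering and correlation, and three bespoke
classifiers: CAF-marker flags for retained patient stroma, the Y-index
gender call for the mouse host, and the MIF/Ddx6 hypoxia grouping.

Thresholds quoted as "log2 FPKM" (CAF, MIF/Ddx6) are applied to the raw
log2 of FPKM with zero mapped to -infinity, not to the offset transform.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import Species
from .matrices import CountMatrix, ExpressionMatrix, Scale


@dataclass
class FilterSpec:
    """Gene-retention thresholds for clustering/correlation input."""

    min_fpkm_human: float = 10.0
    min_fpkm_mouse: float = 2.0
    min_cv: float = 0.20
    log_offset: float = 1.1

    def __post_init__(self) -> None:
        for name in ("min_fpkm_human", "min_fpkm_mouse", "min_cv", "log_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def min_fpkm(self, species: Species) -> float:
        return self.min_fpkm_human if species is Species.HUMAN else self.min_fpkm_mouse


@dataclass
class GenderCall:
    sample_id: str
    y_index: float  # per-mille units
    call: str  # "male" | "female"
    y_gene_counts: dict[str, int]


@dataclass
class StromaFlag:
    sample_id: str
    fap_log2_fpkm: float
    cspg4_log2_fpkm: float
    flag: str  # "none" | "low_evidence" | "high_evidence"


@dataclass
class HypoxiaGroup:
    sample_id: str
    group: str  # "MIF_high_Ddx6_low" | "MIF_low_Ddx6_high" | "unassigned"


def filter_genes(
    expr: ExpressionMatrix, spec: FilterSpec, species: Species
) -> ExpressionMatrix:
    """Retain genes exceeding the species FPKM floor in >= 1 sample and CV > min_cv.

    Both thresholds are strict; CV is sd/mean of raw FPKM across samples with
    the n-1 sample standard deviation.
    """
    if expr.scale is not Scale.FPKM:
        raise ValueError("filter_genes expects an FPKM-scale matrix")
    values = expr.values
    if expr.gene_species is not None:
        mask = (expr.gene_species.loc[values.index] == species).values
        values = values.loc[values.index[mask]]
    if values.shape[1] < 2:
        raise ValueError("coefficient of variation undefined on a single sample")
    threshold = spec.min_fpkm(species)
    vmax = values.max(axis=1)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    keep = (vmax > threshold) & (cv > spec.min_cv)
    out = values.loc[keep.values]
    return ExpressionMatrix(
        values=out,
        scale=Scale.FPKM,
        filters_applied=expr.filters_applied
        + [f"max_fpkm>{threshold}({species.value})", f"cv>{spec.min_cv}"],
        gene_species=None if expr.gene_species is None else expr.gene_species.loc[out.index],
    )


def to_nonneg_log(expr: ExpressionMatrix, offset: float = 1.1) -> ExpressionMatrix:
    """log2(FPKM + offset): a strictly positive matrix suitable for NMF."""
    if expr.scale is not Scale.FPKM:
        raise ValueError("to_nonneg_log expects an FPKM-scale matrix")
    if (expr.values.values < 0).any():
        raise ValueError("negative FPKM input")
    return ExpressionMatrix(
        values=np.log2(expr.values + offset),
        scale=Scale.LOG2_OFFSET,
        filters_applied=expr.filters_applied + [f"log2(x+{offset})"],
        gene_species=expr.gene_species,
    )


def _log2_raw(row: pd.Series) -> pd.Series:
    with np.errstate(divide="ignore"):
        return np.log2(row.astype(float))


def flag_patient_stroma(
    expr_human: ExpressionMatrix,
    low: float = 2.0,
    high: float = 4.0,
    fap_gene: str = "FAP",
    cspg4_gene: str = "CSPG4",
) -> list[StromaFlag]:
    """Flag samples retaining patient stroma by human CAF-marker expression.

    low_evidence: either marker's log2 FPKM strictly above ``low``;
    high_evidence: above ``high``.  Zero FPKM maps to -infinity.
    """
    if expr_human.scale is not Scale.FPKM:
        raise ValueError("flag_patient_stroma expects FPKM-scale expression")
    missing = [g for g in (fap_gene, cspg4_gene) if g not in expr_human.values.index]
    if missing:
        raise ValueError(f"CAF marker genes absent from matrix: {missing}")
    fap = _log2_raw(expr_human.values.loc[fap_gene])
    cspg4 = _log2_raw(expr_human.values.loc[cspg4_gene])
    flags = []
    for sample in expr_human.samples:
        best = max(fap[sample], cspg4[sample])
        if best > high:
            flag = "high_evidence"
        elif best > low:
            flag = "low_evidence"
        else:
            flag = "none"
        flags.append(
            StromaFlag(
                sample_id=sample,
                fap_log2_fpkm=float(fap[sample]),
                cspg4_log2_fpkm=float(cspg4[sample]),
                flag=flag,
            )
        )
    return flags


Y_INDEX_GENES = ("Eif2s3y", "Ddx3y", "Kdm5d", "Uty")


def predict_gender(
    counts_mouse: CountMatrix,
    y_genes: Sequence[str] = Y_INDEX_GENES,
    threshold: float = 10.0,
) -> list[GenderCall]:
    """Call mouse host gender from the Y index.

    Y index = 1000 * (summed counts over the four Y-chromosome genes) /
    (total counts over all mouse genes); strictly above ``threshold`` calls
    male.  The index is a ratio, so it is invariant to library size.
    """
    mouse_genes = counts_mouse.genes_of(Species.MOUSE)
    missing = [g for g in y_genes if g not in mouse_genes]
    if missing:
        raise ValueError(f"Y-index genes absent from mouse gene universe: {missing}")
    sub = counts_mouse.counts.loc[mouse_genes]
    calls = []
    for sample in counts_mouse.samples:
        total = int(sub[sample].sum())
        if total == 0:
            raise ValueError(f"sample {sample}: zero total mouse counts")
        y_counts = {g: int(sub.loc[g, sample]) for g in y_genes}
        y_index = 1000.0 * sum(y_counts.values()) / total
        calls.append(
            GenderCall(
                sample_id=sample,
                y_index=y_index,
                call="male" if y_index > threshold else "female",
                y_gene_counts=y_counts,
            )
        )
    return calls


def hypoxia_grouping(
    expr_human: ExpressionMatrix,
    expr_mouse: ExpressionMatrix,
    mif_hi: float = 11.5,
    ddx6_lo: float = 1.05,
    mif_lo: float = 7.0,
    ddx6_hi: float = 1.8,
    mif_gene: str = "MIF",
    ddx6_gene: str = "Ddx6",
) -> list[HypoxiaGroup]:
    """Divide samples into putative hypoxic / normoxic groups.

    Hypoxic-like: human MIF log2 FPKM > mif_hi AND mouse Ddx6 < ddx6_lo;
    normoxic-like: MIF < mif_lo AND Ddx6 > ddx6_hi; everything else is
    unassigned.
    """
    for expr, gene, label in ((expr_human, mif_gene, "human"), (expr_mouse, ddx6_gene, "mouse")):
        if expr.scale is not Scale.FPKM:
            raise ValueError("hypoxia_grouping expects FPKM-scale matrices")
        if gene not in expr.values.index:
            raise ValueError(f"{label} marker gene {gene!r} absent from matrix")
    if list(expr_human.samples) != list(expr_mouse.samples):
        raise ValueError("human and mouse matrices must share the sample set")
    mif = _log2_raw(expr_human.values.loc[mif_gene])
    ddx6 = _log2_raw(expr_mouse.values.loc[ddx6_gene])
    groups = []
    for sample in expr_human.samples:
        if mif[sample] > mif_hi and ddx6[sample] < ddx6_lo:
            group = "MIF_high_Ddx6_low"
        elif mif[sample] < mif_lo and ddx6[sample] > ddx6_hi:
            group = "MIF_low_Ddx6_high"
        else:
            group = "unassigned"
        groups.append(HypoxiaGroup(sample_id=sample, group=group))
    return groups


def signature_score(
    expr: ExpressionMatrix, signature_genes: Sequence[str]
) -> tuple[pd.Series, int]:
    """Mean log-scale expression over the signature genes present in the matrix.

    Returns the per-sample score and the number of signature genes missing
    from the matrix.  A crude stand-in for external stromal-content scores.
    """
    if expr.scale is not Scale.LOG2_OFFSET:
        raise ValueError("signature_score expects a log-scale matrix")
    present = [g for g in dict.fromkeys(signature_genes) if g in expr.values.index]
    n_missing = len(set(signature_genes)) - len(present)
    if not present:
        raise ValueError("no signature genes present in the matrix")
    if n_missing:
        warnings.warn(f"{n_missing} signature genes absent from matrix")
    return expr.values.loc[present].mean(axis=0), n_missing
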