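"""Differential expression and compartment-specific marker triangulation.

Two-group differential expression on counts follows a negative-binomial Wald
contract: median-of-ratios size factors, a moment-based pooled dispersion
estimate, log2 fold changes on pseudocounted normalized means, a Wald
statistic under the NB variance function mu + alpha mu^2, and
Benjamini-Hochberg FDR.  Gene-set overlaps are scored with the
hypergeometric upper tail.  Triangulation intersects over-expressed genes
across tumor-pure platforms and removes anything significant in mixed
tumor-stroma platforms, leaving markers that only high-purity samples can
reveal ("masked" markers).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrices import ExpressionMatrix


@dataclass
class DERecord:
    gene_id: str
    base_mean: float
    log2_fc: float
    p: float
    fdr: float
    status: str  # "tested" | "low_expression_skipped"


@dataclass
class PlatformDESet:
    """One platform's DE results with its purity class and threshold dialect.

    ``thresholds`` is (fc, cutoff, which) with which in {"fdr", "p"}; e.g.
    RNA-seq platforms use (1.5, 0.05, "fdr") while array-based cell-line
    panels use (1.5, 0.01, "p").
    """

    platform_name: str
    purity_class: str  # "tumor_pure" | "mixed"
    records: list[DERecord]
    thresholds: tuple[float, float, str] = (1.5, 0.05, "fdr")

    def overexpressed(self) -> set[str]:
        fc, cutoff, which = self.thresholds
        out = set()
        for r in self.records:
            if r.status != "tested":
                continue
            stat = r.fdr if which == "fdr" else r.p
            if r.log2_fc > fc and stat < cutoff:
                out.add(r.gene_id)
        return out

    def significant_any_fc(self, fdr_thresh: float) -> set[str]:
        return {
            r.gene_id
            for r in self.records
            if r.status == "tested" and r.fdr < fdr_thresh
        }

    def universe(self) -> set[str]:
        return {r.gene_id for r in self.records}


@dataclass
class OverlapResult:
    k_overlap: int
    K_signature: int
    n_list: int
    N_universe: int
    p_upper: float
    overlap_genes: tuple[str, ...] = ()


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, scaled to geometric mean 1.

    Reference genes are those with no zero counts; each sample's factor is
    the median over reference genes of its count divided by the gene's
    geometric mean across samples.
    """
    arr = counts.to_numpy(dtype=float)
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has all-positive counts; supply a pseudo-reference or prefilter"
        )
    logs = np.log(arr[ref])
    log_geomean = logs.mean(axis=1)
    log_ratios = logs - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def de_test(
    counts: pd.DataFrame,
    group_labels: pd.Series | dict[str, str],
    min_fpkm_gate: ExpressionMatrix | None = None,
    min_fpkm: float = 1.0,
    dispersion_floor: float = 1e-8,
    pseudocount: float = 0.5,
    reference: str | None = None,
) -> list[DERecord]:
    """Two-group NB Wald differential expression on raw counts.

    Counts are normalized by median-of-ratios size factors; per-gene
    dispersion is a moment estimate pooled across the two groups (floored);
    log2_fc = log2((mean2 + 0.5) / (mean1 + 0.5)) on normalized counts with
    group order alphabetical, so positive fold change means higher in the
    later-sorted group; the Wald p is two-sided Student t with n1+n2-2 df
    (small-sample reference for the plug-in statistic).  BH FDR runs over
    tested genes only; genes failing the optional FPKM > ``min_fpkm`` gate
    are reported as low_expression_skipped.
    """
    labels = pd.Series(group_labels)
    labels = labels.loc[counts.columns]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if reference is not None:
        if reference not in groups:
            raise ValueError(f"reference group {reference!r} not among {groups}")
        groups = [reference] + [g for g in groups if g != reference]
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
    arr = arr.astype(float)

    sf = size_factors(counts).to_numpy()
    norm = arr / sf[None, :]
    idx1 = (labels == groups[0]).to_numpy()
    idx2 = (labels == groups[1]).to_numpy()
    n1, n2 = int(idx1.sum()), int(idx2.sum())

    m1 = norm[:, idx1].mean(axis=1)
    m2 = norm[:, idx2].mean(axis=1)
    v1 = norm[:, idx1].var(axis=1, ddof=1)
    v2 = norm[:, idx2].var(axis=1, ddof=1)
    # moment estimate of NB dispersion pooled across groups:
    # var = mu + alpha mu^2  =>  alpha = (var - mu) / mu^2
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    pooled_mean = (m1 + m2) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean**2
    alpha = np.where(np.isfinite(alpha), alpha, dispersion_floor)
    alpha = np.maximum(alpha, dispersion_floor)

    log2_fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    # delta-method SE of log2 of the pseudocounted group means under NB
    var_m1 = (m1 + alpha * m1**2) / n1
    var_m2 = (m2 + alpha * m2**2) / n2
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(
        var_m1 / ((m1 + pseudocount) ** 2 * ln2sq)
        + var_m2 / ((m2 + pseudocount) ** 2 * ln2sq)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(se > 0, log2_fc / se, 0.0)
    # small-sample reference: the plug-in Wald statistic has heavy tails at
    # a handful of replicates, so p-values use Student t with n1+n2-2 df
    # (a normal reference is anticonservative by ~1.7x at 5v5)
    pvals = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)

    gate_pass = np.ones(len(counts.index), dtype=bool)
    if min_fpkm_gate is not None:
        fpkm = min_fpkm_gate.values
        for i, g in enumerate(counts.index):
            if g in fpkm.index:
                gate_pass[i] = (fpkm.loc[g] > min_fpkm).any()
            else:
                gate_pass[i] = False

    records: list[DERecord] = [None] * len(counts.index)  # type: ignore[list-item]
    tested_idx = np.where(gate_pass)[0]
    fdr = np.ones(len(counts.index))
    if tested_idx.size:
        fdr[tested_idx] = bh_fdr(pvals[tested_idx])
    for i, g in enumerate(counts.index):
        tested = bool(gate_pass[i])
        records[i] = DERecord(
            gene_id=g,
            base_mean=float((m1[i] * n1 + m2[i] * n2) / (n1 + n2)),
            log2_fc=float(log2_fc[i]),
            p=float(pvals[i]) if tested else 1.0,
            fdr=float(fdr[i]) if tested else 1.0,
            status="tested" if tested else "low_expression_skipped",
        )
    return records


def bh_fdr(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, order-preserving on the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return fdr


def hypergeom_overlap(
    list_genes,
    signature_genes,
    universe_genes,
) -> OverlapResult:
    """Upper-tail hypergeometric test of signature enrichment in a gene list.

    The signature is intersected with the universe first; p_upper =
    P(X >= k) for X ~ Hypergeom(N=|universe|, K=|signature|, n=|list|).
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty universe")
    glist = set(list_genes)
    if not glist <= universe:
        raise ValueError("gene list must be a subset of the universe")
    signature = set(signature_genes) & universe
    overlap = glist & signature
    N, K, n, k = len(universe), len(signature), len(glist), len(overlap)
    p_upper = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(
        k_overlap=k, K_signature=K, n_list=n, N_universe=N,
        p_upper=min(p_upper, 1.0), overlap_genes=tuple(sorted(overlap)),
    )


def stroma_stratify(
    samples,
    stromal_scores: dict[str, float] | pd.Series,
    cutoff: float,
    direction: str = "<",
) -> list[str]:
    """Subset samples by a strict stromal-score cutoff ('<' or '>')."""
    if direction not in ("<", ">"):
        raise ValueError("direction must be '<' or '>'")
    scores = pd.Series(stromal_scores)
    missing = [s for s in samples if s not in scores.index or pd.isna(scores[s])]
    if missing:
        raise ValueError(f"missing stromal score for samples: {missing}")
    if direction == "<":
        subset = [s for s in samples if scores[s] < cutoff]
    else:
        subset = [s for s in samples if scores[s] > cutoff]
    if not subset:
        warnings.warn("stroma stratification yields an empty sample set")
    return subset


def triangulate_markers(
    pure_sets: list[PlatformDESet],
    mixed_sets: list[PlatformDESet],
    fc_thresh: float = 1.5,
    fdr_thresh: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Derive tumor-pure consensus markers and the subset masked by stroma.

    consensus_pure intersects, over the tumor-pure platforms, the genes
    over-expressed under each platform's own threshold dialect (fold change
    above ``fc_thresh`` plus its fdr-or-p cutoff); masked markers are the
    consensus genes that no mixed platform finds significant at
    ``fdr_thresh`` even ignoring fold-change magnitude.
    """
    if not pure_sets or not mixed_sets:
        raise ValueError("need at least one tumor-pure and one mixed platform")
    universes = [ps.universe() for ps in pure_sets + mixed_sets]
    shared = universes[0]
    for u in universes[1:]:
        if u != shared:
            raise ValueError("platforms do not share a gene universe")

    consensus: set[str] | None = None
    for ps in pure_sets:
        thresholds = (fc_thresh, ps.thresholds[1], ps.thresholds[2])
        sig = PlatformDESet(
            ps.platform_name, ps.purity_class, ps.records, thresholds
        ).overexpressed()
        consensus = sig if consensus is None else consensus & sig
    mixed_significant: set[str] = set()
    for ms in mixed_sets:
        mixed_significant |= ms.significant_any_fc(fdr_thresh)
    masked = consensus - mixed_significant
    return consensus, masked
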