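"""Cross-species co-expression network inference.

All-against-all Pearson correlation between (log-scale) human and mouse
expression profiles across the shared sample set, a hard |r| threshold to
build the network (the threshold, not multiple-testing correction, controls
false positives), edge-class partitioning (human-human / mouse-mouse /
cross-species), hub ranking by cross-species degree, and targeted partner
ranking for a single query gene with analytic two-sided p-values from the
t transform of r.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Species
from .matrices import ExpressionMatrix

EDGE_HUMAN = "human_human"
EDGE_MOUSE = "mouse_mouse"
EDGE_CROSS = "cross_species"


@dataclass(frozen=True)
class CorrelationEdge:
    gene_a: tuple[str, Species]
    gene_b: tuple[str, Species]
    r: float
    edge_class: str


@dataclass
class CorrelationNetwork:
    edges: list[CorrelationEdge]
    threshold: float

    @property
    def nodes(self) -> set[tuple[str, Species]]:
        out: set[tuple[str, Species]] = set()
        for e in self.edges:
            out.add(e.gene_a)
            out.add(e.gene_b)
        return out

    def edge_counts(self) -> dict[str, int]:
        counts = {EDGE_HUMAN: 0, EDGE_MOUSE: 0, EDGE_CROSS: 0}
        for e in self.edges:
            counts[e.edge_class] += 1
        return counts

    def rethreshold(self, threshold: float) -> "CorrelationNetwork":
        # edges store exact r, so a stricter cut needs no recomputation
        return CorrelationNetwork(
            edges=[e for e in self.edges if abs(e.r) > threshold],
            threshold=threshold,
        )


@dataclass
class PartnerRanking:
    query: tuple[str, Species]
    partners: list[tuple[str, Species, float, float]]  # gene, species, r, p
    n_samples: int
    top_subset: list[tuple[str, Species, float, float]] = field(default_factory=list)


@dataclass
class CorrelationResult:
    """Pairwise Pearson r over species-labeled genes with shared samples."""

    genes: list[tuple[str, Species]]
    matrix: np.ndarray  # len(genes) x len(genes), symmetric
    n_samples: int
    scope: str  # "all" | "cross_only"


def _edge_class(sp_a: Species, sp_b: Species) -> str:
    if sp_a is Species.HUMAN and sp_b is Species.HUMAN:
        return EDGE_HUMAN
    if sp_a is Species.MOUSE and sp_b is Species.MOUSE:
        return EDGE_MOUSE
    return EDGE_CROSS


def pairwise_correlation(
    expr_human: ExpressionMatrix,
    expr_mouse: ExpressionMatrix,
    scope: str = "all",
) -> CorrelationResult:
    """Pearson r for every unordered gene pair in scope.

    Both matrices must share an identical ordered sample set with >= 3
    samples; constant profiles have undefined r and are excluded with a
    warning.
    """
    if scope not in ("all", "cross_only"):
        raise ValueError(f"unknown scope {scope!r}")
    if list(expr_human.samples) != list(expr_mouse.samples):
        raise ValueError("human and mouse matrices must share an identical sample order")
    n = len(expr_human.samples)
    if n < 3:
        raise ValueError("need >= 3 samples for correlation")

    labeled = [(g, Species.HUMAN) for g in expr_human.genes] + [
        (g, Species.MOUSE) for g in expr_mouse.genes
    ]
    values = np.vstack([
        expr_human.values.to_numpy(dtype=float),
        expr_mouse.values.to_numpy(dtype=float),
    ])
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} constant profiles excluded (undefined correlation)"
        )
    labeled = [g for g, k in zip(labeled, keep) if k]
    values = values[keep]
    R = np.corrcoef(values)
    R = np.clip(R, -1.0, 1.0)
    return CorrelationResult(genes=labeled, matrix=R, n_samples=n, scope=scope)


def build_network(
    correlations: CorrelationResult, threshold: float = 0.85
) -> CorrelationNetwork:
    """Edges where |r| strictly exceeds the threshold, labeled by species pair."""
    R = correlations.matrix
    genes = correlations.genes
    iu, ju = np.triu_indices(len(genes), k=1)
    strong = np.abs(R[iu, ju]) > threshold
    edges = []
    for i, j in zip(iu[strong], ju[strong]):
        cls = _edge_class(genes[i][1], genes[j][1])
        if correlations.scope == "cross_only" and cls != EDGE_CROSS:
            continue
        edges.append(
            CorrelationEdge(
                gene_a=genes[i], gene_b=genes[j], r=float(R[i, j]), edge_class=cls
            )
        )
    return CorrelationNetwork(edges=edges, threshold=threshold)


def cross_species_hubs(network: CorrelationNetwork) -> list[tuple[tuple[str, Species], int]]:
    """Nodes ranked by count of incident cross-species edges (desc, ties lexicographic)."""
    degree: dict[tuple[str, Species], int] = {node: 0 for node in network.nodes}
    for e in network.edges:
        if e.edge_class == EDGE_CROSS:
            degree[e.gene_a] += 1
            degree[e.gene_b] += 1
    return sorted(degree.items(), key=lambda kv: (-kv[1], kv[0][0]))


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson coefficient via t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: p-value reported as 0")
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def rank_partners(
    expr_human: ExpressionMatrix,
    expr_mouse: ExpressionMatrix,
    query_gene: str,
    target_species: Species,
    top_fraction: float = 0.06,
    by_abs: bool = False,
) -> PartnerRanking:
    """Correlate one query gene against every target-species gene.

    Partners are ranked by descending r (or |r| when ``by_abs``); the subset
    within ``top_fraction`` of the ranking is returned alongside the full
    list.
    """
    by_species = {Species.HUMAN: expr_human, Species.MOUSE: expr_mouse}
    query_expr = None
    query_sp = None
    for sp, expr in by_species.items():
        if query_gene in expr.values.index:
            query_expr = expr.values.loc[query_gene].to_numpy(dtype=float)
            query_sp = sp
            break
    if query_expr is None:
        raise ValueError(f"query gene {query_gene!r} absent from both matrices")
    target = by_species[target_species]
    if list(expr_human.samples) != list(expr_mouse.samples):
        raise ValueError("matrices must share an identical sample order")
    n = len(target.samples)
    if n < 3:
        raise ValueError("need >= 3 samples")

    tvals = target.values.to_numpy(dtype=float)
    qc = query_expr - query_expr.mean()
    tc = tvals - tvals.mean(axis=1, keepdims=True)
    qsd = np.sqrt((qc**2).sum())
    tsd = np.sqrt((tc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (tc @ qc) / (tsd * qsd)
    partners = []
    for gene, r in zip(target.genes, rs):
        if gene == query_gene and target_species is query_sp:
            continue
        if not np.isfinite(r):
            continue
        r = float(np.clip(r, -1.0, 1.0))
        partners.append((gene, target_species, r, pearson_pvalue(r, n)))
    key = (lambda t: -abs(t[2])) if by_abs else (lambda t: -t[2])
    partners.sort(key=key)
    n_top = int(np.ceil(top_fraction * len(partners)))
    return PartnerRanking(
        query=(query_gene, query_sp),
        partners=partners,
        n_samples=n,
        top_subset=partners[:n_top],
    )
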