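"""Consensus non-negative matrix factorization subtyping.

V (genes x samples, non-negative) is factorized as V ~ W H with Brunet-style
multiplicative updates minimizing the generalized Kullback-Leibler
divergence; columns of W are meta-genes, columns of H assign samples to
meta-genes.  Cluster stability is assessed by consensus clustering over
repeated random initializations, and the factorization rank k is selected by
the largest gap between the cophenetic correlation of the actual matrix and
that of a row-permuted null matrix — a permutation calibration that guards
against the cophenetic coefficient staying high on structureless data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency

_EPS = 1e-12


@dataclass
class NMFFactors:
    W: np.ndarray  # genes x k
    H: np.ndarray  # k x samples
    objective: float
    objective_trace: list[float]
    n_iterations: int
    seed: int


@dataclass
class ConsensusResult:
    k: int
    consensus: np.ndarray  # samples x samples in [0, 1]
    cophenetic: float
    assignments: dict[str, int]
    mean_consensus_per_cluster: dict[int, float]
    n_runs: int


@dataclass
class RankSelection:
    k_range: list[int]
    cophenetic_actual: dict[int, float]
    cophenetic_permuted: dict[int, float]
    selected_k: int


@dataclass
class MetaGeneReport:
    # per factor: list of (gene, relative_contribution) ranked by
    # relative_contribution * max loading of the gene
    ranked: list[list[tuple[str, float]]]
    driver_genes: list[list[str]]
    relative_contribution: pd.DataFrame  # genes x factors, rows sum to 1


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    # generalized KL: sum v*log(v/vh) - v + vh, with 0*log0 = 0
    mask = V > 0
    div = np.sum(WH - V)
    div += np.sum(V[mask] * np.log(V[mask] / WH[mask]))
    return float(div)


def nmf_factorize(
    V: np.ndarray | pd.DataFrame,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    check_every: int = 10,
) -> NMFFactors:
    """Multiplicative-update NMF under generalized KL divergence.

    Random uniform initialization scaled to the matrix mean; stops when the
    relative objective change over ``check_every`` iterations falls below
    ``tol`` or at ``max_iter``.  Deterministic under ``seed``.
    """
    A = np.asarray(V, dtype=float)
    if (A < 0).any():
        raise ValueError("V must be non-negative")
    zero_rows = np.where(A.sum(axis=1) == 0)[0]
    if zero_rows.size:
        labels = (
            list(V.index[zero_rows]) if isinstance(V, pd.DataFrame) else zero_rows.tolist()
        )
        raise ValueError(f"all-zero rows in V: {labels[:5]}")
    n, m = A.shape
    if not 2 <= k < min(n, m):
        raise ValueError(f"k={k} out of range for a {n}x{m} matrix")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(A.mean() / k)
    W = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, m)) * scale

    trace: list[float] = []
    prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        WH = W @ H + _EPS
        # H <- H * (W^T (V / WH)) / (W^T 1)
        H *= (W.T @ (A / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        # W <- W * ((V / WH) H^T) / (1 H^T)
        W *= ((A / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        if it % check_every == 0 or it == max_iter:
            obj = _kl_divergence(A, W @ H + _EPS)
            trace.append(obj)
            if np.isfinite(prev) and prev - obj < tol * max(abs(prev), 1.0):
                break
            prev = obj
    final = _kl_divergence(A, W @ H + _EPS)
    return NMFFactors(
        W=W, H=H, objective=final, objective_trace=trace, n_iterations=it, seed=seed
    )


def run_labels(factors: NMFFactors) -> np.ndarray:
    """Per-run cluster membership: argmax of H per sample (ties -> lowest factor)."""
    return np.argmax(factors.H, axis=0)


def consensus_cluster(
    V: np.ndarray | pd.DataFrame,
    k: int,
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    subsample_fraction: float = 1.0,
) -> ConsensusResult:
    """Consensus clustering over ``n_runs`` randomly initialized NMF runs.

    Each run starts from a fresh random initialization; optionally
    (``subsample_fraction`` < 1) the matrix is additionally perturbed by
    subsampling a fraction of the gene rows without replacement per run.
    consensus(i, j) = fraction of runs assigning samples i and j to the same
    meta-gene; final assignments cut an average-linkage dendrogram of
    1 - consensus into k groups; the cophenetic coefficient is the Pearson
    correlation between 1 - consensus distances and the dendrogram's
    cophenetic distances.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    A = np.asarray(V, dtype=float)
    n, m = A.shape
    samples = (
        list(V.columns) if isinstance(V, pd.DataFrame) else [f"s{i}" for i in range(m)]
    )
    n_sub = max(int(round(subsample_fraction * n)), k)
    together = np.zeros((m, m))
    rng = np.random.default_rng(seed)
    for _ in range(n_runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        if n_sub < n:
            rows = rng.choice(n, size=n_sub, replace=False)
            rows = rows[A[rows].sum(axis=1) > 0]
            sub = A[rows]
        else:
            sub = A
        factors = nmf_factorize(sub, k, seed=run_seed, max_iter=max_iter, tol=tol)
        labels = run_labels(factors)
        together += labels[:, None] == labels[None, :]
    consensus = together / n_runs
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = average(condensed)
    flat = fcluster(Z, t=k, criterion="maxclust")
    if len(set(flat)) < k:
        warnings.warn(
            f"consensus dendrogram yields only {len(set(flat))} distinct clusters at k={k}"
        )

    coph_dists = cophenet(Z)
    if condensed.std() == 0 or coph_dists.std() == 0:
        warnings.warn("degenerate consensus matrix: cophenetic reported as 1.0")
        cophenetic = 1.0
    else:
        cophenetic = float(np.corrcoef(condensed, coph_dists)[0, 1])

    assignments = {s: int(c) for s, c in zip(samples, flat)}
    mean_consensus = {}
    for c in sorted(set(flat)):
        idx = np.where(flat == c)[0]
        if len(idx) == 1:
            mean_consensus[int(c)] = 1.0
        else:
            block = consensus[np.ix_(idx, idx)]
            off = block[np.triu_indices(len(idx), 1)]
            mean_consensus[int(c)] = float(off.mean())
    return ConsensusResult(
        k=k,
        consensus=consensus,
        cophenetic=cophenetic,
        assignments=assignments,
        mean_consensus_per_cluster=mean_consensus,
        n_runs=n_runs,
    )


def permute_matrix(V: np.ndarray | pd.DataFrame, seed: int = 0):
    """Independently permute each gene row across samples (null matrix)."""
    rng = np.random.default_rng(seed)
    A = np.asarray(V, dtype=float).copy()
    for i in range(A.shape[0]):
        A[i] = A[i, rng.permutation(A.shape[1])]
    if isinstance(V, pd.DataFrame):
        return pd.DataFrame(A, index=V.index, columns=V.columns)
    return A


def select_rank(
    V: np.ndarray | pd.DataFrame,
    k_range: range | list[int] = range(2, 12),
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    subsample_fraction: float = 1.0,
) -> RankSelection:
    """Choose k maximizing cophenetic(actual) - cophenetic(permuted).

    Ties break toward the smallest k.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range is empty")
    m = np.asarray(V).shape[1]
    if max(ks) >= m:
        raise ValueError("max k must be below the number of samples")
    permuted = permute_matrix(V, seed=seed)
    actual_c: dict[int, float] = {}
    permuted_c: dict[int, float] = {}
    for i, k in enumerate(ks):
        actual_c[k] = consensus_cluster(
            V, k, n_runs=n_runs, seed=seed + 1000 + i, max_iter=max_iter, tol=tol,
            subsample_fraction=subsample_fraction,
        ).cophenetic
        permuted_c[k] = consensus_cluster(
            permuted, k, n_runs=n_runs, seed=seed + 2000 + i, max_iter=max_iter, tol=tol,
            subsample_fraction=subsample_fraction,
        ).cophenetic
    diffs = {k: actual_c[k] - permuted_c[k] for k in ks}
    best = max(diffs.values())
    selected = min(k for k in ks if diffs[k] == best)
    return RankSelection(
        k_range=ks,
        cophenetic_actual=actual_c,
        cophenetic_permuted=permuted_c,
        selected_k=selected,
    )


def extract_metagenes(
    factors: NMFFactors,
    gene_ids: list[str] | None = None,
    top_n: int = 50,
) -> MetaGeneReport:
    """Rank per-factor driver genes by relative contribution.

    relative_contribution(g, f) = W[g, f] / sum_f' W[g, f']; per factor genes
    are ranked by relative_contribution * (max loading of the gene across
    factors), combining specificity with magnitude.  All-zero gene rows are
    excluded with a warning.
    """
    W = factors.W
    n, k = W.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    row_sums = W.sum(axis=1)
    nonzero = row_sums > 0
    if not nonzero.all():
        warnings.warn(f"{int((~nonzero).sum())} all-zero gene rows excluded from meta-genes")
    rel = np.zeros_like(W)
    rel[nonzero] = W[nonzero] / row_sums[nonzero, None]
    row_max = W.max(axis=1)
    score = rel * row_max[:, None]

    ranked, drivers = [], []
    kept = np.where(nonzero)[0]
    for f in range(k):
        order = kept[np.argsort(-score[kept, f], kind="stable")]
        ranked.append([(gene_ids[i], float(rel[i, f])) for i in order])
        drivers.append([gene_ids[i] for i in order[:top_n]])
    rel_df = pd.DataFrame(
        rel[kept], index=[gene_ids[i] for i in kept],
        columns=[f"factor_{f + 1}" for f in range(k)],
    )
    return MetaGeneReport(ranked=ranked, driver_genes=drivers, relative_contribution=rel_df)


def association_test(
    assignments: dict[str, int], metadata_values: dict[str, str]
) -> tuple[float, int, float]:
    """Pearson chi-squared test of cluster membership vs a metadata category.

    No continuity correction; warns when any expected count is below 5.
    """
    samples = sorted(set(assignments) & set(metadata_values))
    clusters = sorted({assignments[s] for s in samples})
    categories = sorted({metadata_values[s] for s in samples})
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters for an association test")
    if len(categories) < 2:
        raise ValueError("need >= 2 metadata categories for an association test")
    table = np.zeros((len(clusters), len(categories)), dtype=int)
    for s in samples:
        table[clusters.index(assignments[s]), categories.index(metadata_values[s])] += 1
    chi2, p, dof, expected = chi2_contingency(table, correction=False)
    if (expected < 5).any():
        warnings.warn("chi-squared expected counts below 5; p-value is approximate")
    return float(chi2), int(dof), float(p)
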