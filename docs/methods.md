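# Methods

This note documents the models implemented in `pdxsplit`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that were genuinely open.

## Species read disambiguation

Reads from a PDX sample are aligned against the union of a human and a
mouse reference ("concatenated genome"). The aligner is an exact-k-mer
seed-and-extend: every k-mer of both genomes is indexed on both strands
(default k = 21; at 15% coding divergence the chance that a 21-mer is
conserved between orthologs is ≈ 0.85²¹ ≈ 0.03, so seeds are effectively
species-specific), seeds are taken at the two ends and the middle of each
mate so that a single sequencing error cannot eliminate all of them, and
candidate loci are extended ungapped over the full mate.

A candidate fragment locus pairs one alignment per mate on the same
chromosome, on opposite strands, within a 1 kb fragment bound. A locus is
valid when each mate has at most `max_mismatch = 3` mismatches **and** the
fragment's total mismatches divided by total mapped length is at most
`max_mm_ratio = 0.10`. The call is the species of the unique best valid
locus (minimum total mismatches); a tie across two or more distinct loci —
in particular across species in conserved regions — yields AMBIGUOUS and
the fragment is discarded, mirroring unique-best-alignment semantics.
Splice-aware alignment is deliberately out of scope: the synthetic genes
are single-exon, so the ungapped contract is exercised faithfully, and the
species-decision filters (the bespoke content) are exact.

Counting is union-mode: a fragment increments a gene iff the union of its
two mate intervals overlaps the exons of exactly one gene, strand ignored;
fragments touching zero or ≥ 2 genes are not counted but still contribute
to the per-species library size (the number of species-assigned
fragments). Expression is

```
FPKM(g, s) = counts(g, s) · 1e9 / (exon_union_length(g) · library(s, species(g)))
```

after removing non-protein-coding genes and genes whose largest transcript
is under 400 bp (shorter than a typical fragment, hence prone to
over-estimation). Exon-union length is used rather than per-transcript
effective length: it is deterministic and depends only on the annotation.
The human fraction of a sample is computed over assigned *fragments*.

## Expression preparation and threshold classifiers

Genes enter clustering/correlation when their FPKM strictly exceeds the
species floor (10 human / 2 mouse) in at least one sample and their
coefficient of variation (sample SD over mean of raw FPKM, n−1 denominator)
strictly exceeds 0.20. Values are then transformed as `log2(FPKM + 1.1)`,
which is strictly positive — a requirement for NMF.

Three small classifiers use raw `log2(FPKM)` (zero FPKM → −∞), not the
offset transform, because their thresholds are quoted on that scale:

- **Patient-stroma flags**: low evidence when human *FAP* or *CSPG4*
  log2 FPKM > 2.0; high evidence when > 4.0. High implies low.
- **Hypoxia grouping**: MIF-high/Ddx6-low when human *MIF* > 11.5 and
  mouse *Ddx6* < 1.05; MIF-low/Ddx6-high when *MIF* < 7.0 and
  *Ddx6* > 1.8; otherwise unassigned.
- **Y-index gender**: `1000 · Σ counts(Eif2s3y, Ddx3y, Kdm5d, Uty) /
  Σ counts(all mouse genes)`; strictly above 10 calls the host male. The
  four-gene list is fixed; the index is a ratio and thus invariant to
  library size. A generic signature-mean score (mean log-scale expression
  over present signature genes) stands in where external stromal-content
  scores would be consumed.

## Consensus NMF subtyping

V (genes × samples, non-negative) is factorized as V ≈ WH by Brunet-style
multiplicative updates minimizing the generalized Kullback–Leibler
divergence, with random uniform initialization scaled to `sqrt(mean(V)/k)`
and a relative-change stopping rule. Per run, each sample joins the factor
with its maximal H coefficient (ties → lowest index). The consensus matrix
over n runs holds co-assignment frequencies; final assignments cut an
average-linkage dendrogram of (1 − consensus) into k groups, and the
cophenetic coefficient is the Pearson correlation between (1 − consensus)
distances and the dendrogram's cophenetic distances. Rank k is selected
over k = 2…11 (desk-scale experiments use 2…8) as the argmax of
cophenetic(actual) − cophenetic(permuted), ties to the smallest k, where
the permuted matrix shuffles each gene row independently across samples
(destroying sample structure, preserving gene marginals). Consensus runs
differ by random initialization; an optional per-run gene-subsampling
perturbation (`subsample_fraction`) is available but defaults to off.

Meta-gene drivers: relative contribution of gene g to factor f is
`W[g,f] / Σ_f' W[g,f']`; per factor, genes are ranked by relative
contribution × the gene's maximum loading, combining specificity with
magnitude (the normalization behind published "relative contribution"
values is not standardized; this row-normalized convention is the
package's choice). Cluster–metadata association uses the Pearson
chi-squared test without continuity correction, warning when expected
counts fall below 5.

**Known limitation — cophenetic rank selection.** On strongly clustered
data the actual-cophenetic curve saturates near 1.0 for every k at or
above the true rank: run-to-run disagreement above the true rank mostly
blurs consensus *within* clusters roughly uniformly, and such blur is
still well fitted by an ultrametric, so the Pearson cophenetic barely
drops. Meanwhile the permuted-matrix cophenetic at moderate run counts
(n = 30) carries seed noise of roughly ±0.03–0.05 per k. The difference
criterion therefore has a peak prominence comparable to its noise, and on
the package's synthetic cohorts it recovers the planted rank in only
~30–50% of seeds even when the consensus *assignments at the true rank are
exactly correct* (adjusted Rand index 1.0 across all tested seeds). The
behaviour was cross-checked by swapping in scikit-learn's mu/KL NMF as the
factorizer — the curves are the same, so this is a property of the
selection statistic, not of the implementation. Practical advice: treat
the selection as a screen, inspect the consensus matrices over the k range
visually, and prefer larger run counts.

## Cross-species correlation networks

Pearson correlations are computed on the log2(FPKM + 1.1) matrices over
the identical ordered sample set; constant profiles are excluded. Edges
require |r| strictly above the threshold (default 0.85, at which
p < 2.2e-16 for n = 79 — the hard threshold, not multiple-testing
correction, controls false positives) and carry exact r, so networks can
be re-thresholded without recomputation. Hubs are ranked by the count of
incident cross-species edges (ties lexicographic). Two-sided p-values use
the t transform `t = r·sqrt(n−2)/sqrt(1−r²)` with n − 2 degrees of
freedom, with n the number of samples (matrices are complete; missing data
are unsupported).

## Differential expression and marker triangulation

The two-group test is a negative-binomial Wald contract on raw counts:

1. median-of-ratios size factors (reference genes = genes with no zeros),
   rescaled to geometric mean 1;
2. per-gene dispersion α by the method of moments on normalized counts,
   pooled across the two groups and floored at 1e-8
   (`var = μ + αμ²`);
3. `log2FC = log2((m₂ + 0.5)/(m₁ + 0.5))` on normalized group means (the
   0.5 pseudocount keeps fold changes finite for zero-count groups; the
   reference/denominator group is configurable);
4. Wald statistic `log2FC / SE` with the delta-method SE under the NB
   variance function, read against a **Student t with n₁+n₂−2 degrees of
   freedom**. With a handful of replicates the plug-in statistic has
   noticeably heavier tails than normal (a normal reference inflates the
   null rejection rate at α = 0.05 to ≈ 0.085 at 5v5; the t reference
   restores ≈ 0.05 while keeping > 90% power for 4-fold markers);
5. Benjamini–Hochberg FDR over tested genes only; genes failing the
   optional FPKM > 1 gate are reported as `low_expression_skipped` and are
   excluded from the FDR computation.

Exact dispersion shrinkage, outlier replacement and the other refinements
of full RNA-seq DE frameworks are intentionally not replicated: downstream
logic consumes only (log2FC, FDR) lists, and the contract above is
calibrated (see the validation suite).

Signature overlaps use the hypergeometric upper tail
`P(X ≥ k), X ~ Hypergeom(N, K, n)` with the signature intersected with the
universe first; the default universe is the 15,984-gene cross-platform
core set (configurable). Triangulation intersects, across tumor-pure
platforms, the genes over-expressed under each platform's own threshold
dialect (RNA-seq platforms: log2FC > 1.5 and FDR < 0.05; array cell-line
panels: log2FC > 1.5 and p < 0.01), then removes anything any mixed
platform finds significant at FDR < 0.05 *ignoring fold-change magnitude*;
what remains are markers only observable at high tumor purity ("masked"
markers). Stroma stratification subsets samples by a strict cutoff on an
externally supplied stromal score.

## Synthetic data

The generator provides every input with serialized ground truth.

- **Toy genomes**: one chromosome per species; ortholog pairs differ by
  i.i.d. substitutions at a controllable rate (default 0.15, the
  human–mouse coding ballpark); private genes are independent random
  sequences; all genes single-exon, protein-coding, ≥ 400 bp, separated by
  100 bp random spacers.
- **Reads**: unstranded paired-end; a pair picks human with probability
  `human_proportion` (default 0.88, the typical human fraction of a PDX
  library), a gene uniformly, a fragment of fixed length uniformly within
  the gene body, either strand; sequencing errors are i.i.d. substitutions
  (default 0.005). No indels, PCR duplicates, GC/positional bias, or
  insert-size spread.
- **Counts**: negative binomial with variance μ + αμ² (default α = 0.1,
  ordinary bulk RNA-seq overdispersion). The mean matrix is a cell-type
  mixture: each sample draws graded membership weights over the k stromal
  programs (Dirichlet plus a dominant-cluster boost, dominant weight
  ≈ 0.78), and each program elevates its disjoint marker-gene block
  (30% of genes split evenly) by `1 + cluster_strength ·
  membership` — i.e. base + (rank-k marker basis) × (membership weights),
  scaled per sample by a lognormal library factor. `cluster_strength = 0`
  removes the structure entirely. On top: coupled human–mouse pairs share
  a per-sample latent log2 factor (SD 2.0; negative loading on one member
  for anti-correlation, giving |r| ≈ 0.95 — the strong end of what such
  couplings show in real cohorts), an optional hub gene coupled to several
  mouse partners, planted subtype markers multiplied by `2^de_log2fc` in
  the BTNBC samples, and the four Y genes at a few percent of the male
  mouse library versus essentially zero in females. Coupled/hub genes get
  a solid base mean (300) — interesting hubs are well-expressed genes, and
  this keeps the latent factor rather than counting noise in charge of
  their correlation. Default scale: 79 samples, 2,000 human + 800 mouse
  genes (tests use smaller panels; experiment sizes are stated in the
  validation suite).
- **Multi-platform counts** for triangulation: tumor-pure platforms sample
  the tumor compartment (markers at log2FC 3 in BTNBC); in mixed platforms
  the tumor contributes 2% of the signal against a stroma that expresses
  every gene at 5× the tumor's base level — abundant stromal expression in
  both subtypes is precisely what masks a tumor-compartment contrast — and
  a subset of markers also carries a stromal subtype contrast, so they
  remain significant in mixed samples and only the rest are masked.
- **Signatures**: one GMT record drawn from the planted DE genes and one
  pure-decoy record, byte-stable under a fixed seed.

Clustering experiments use a single-sex (all-female) host cohort: at
desk-scale panels the four Y genes are ~3% of the mouse gene universe
(versus ~0.1% in a real annotation) and their on/off gender signal would
otherwise dominate the clustering; single-sex host cohorts are themselves
standard practice in breast-cancer PDX work. The generator's default
cohort remains mixed-sex for the gender-call experiments.

What passing tests on these data do **not** show: robustness to splicing,
mapping bias, batch effects, varying insert sizes, or to cluster structure
entangled with library composition — real cohorts are messier in all of
these respects.

## Numerical choices and degenerate inputs

- Intervals are 0-based half-open internally; GTF I/O converts from/to
  1-based inclusive.
- Strict inequalities everywhere a threshold is quoted (FPKM floors, CV,
  |r|, Y index, stromal score cutoffs).
- KL-NMF guards denominators with 1e-12; all-zero gene rows are an error
  for factorization and are excluded (with a warning) from meta-gene
  reports; a degenerate all-identical consensus reports cophenetic 1.0
  with a warning.
- Chi-squared association warns on expected counts < 5; |r| = 1 reports
  p = 0 with a warning; BH validates p ∈ (0, 1].
- One global pipeline seed expands into per-stage seeds via SHA-256, so
  enabling or disabling one stage does not shift another's stream.
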