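"""Synthetic two-species data with serialized ground truth.

Three generators cover the pipeline's inputs:

* :func:`make_toy_genomes` — a pair of toy single-chromosome genomes whose
  ortholog genes differ by i.i.d. substitutions at a controllable divergence
  (mimicking the ~15% human–mouse coding divergence), plus species-private
  genes.  Genes are single-exon and protein-coding so they pass the length
  and biotype filters downstream.
* :func:`simulate_reads` — unstranded paired-end reads drawn from a
  controllable human/mouse mixture with i.i.d. substitution sequencing
  errors and a fixed fragment length.
* :func:`simulate_counts` — a negative-binomial count matrix whose mean is a
  non-negative rank-``planted_k`` product (per-cluster marker blocks times a
  one-hot cluster membership), scaled per sample, with planted cross-species
  coupled gene pairs, subtype-specific differential expression, and
  gender-dependent Y-chromosome genes.

Every generator is deterministic under a fixed seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, SampleMetadata, Species
from .matrices import CountMatrix

Y_GENES = ("Eif2s3y", "Ddx3y", "Kdm5d", "Uty")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimTruth:
    """Ground truth of a simulation run, serializable to JSON."""

    read_species: dict[str, str] = field(default_factory=dict)
    read_gene: dict[str, str] = field(default_factory=dict)
    planted_k: int = 2
    cluster_of_sample: dict[str, int] = field(default_factory=dict)
    coupled_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    de_genes: dict[str, float] = field(default_factory=dict)
    gender_of_sample: dict[str, str] = field(default_factory=dict)
    species_proportion: float | None = None
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    hub_gene: str | None = None
    gene_universe: list[str] = field(default_factory=list)
    mean_matrix: np.ndarray | None = field(default=None, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "read_species": self.read_species,
            "read_gene": self.read_gene,
            "planted_k": self.planted_k,
            "cluster_of_sample": self.cluster_of_sample,
            "coupled_pairs": [list(t) for t in self.coupled_pairs],
            "de_genes": self.de_genes,
            "gender_of_sample": self.gender_of_sample,
            "species_proportion": self.species_proportion,
            "ortholog_pairs": [list(t) for t in self.ortholog_pairs],
            "hub_gene": self.hub_gene,
            "gene_universe": self.gene_universe,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["coupled_pairs"] = [tuple(t) for t in payload.get("coupled_pairs", [])]
        payload["ortholog_pairs"] = [tuple(t) for t in payload.get("ortholog_pairs", [])]
        return cls(**payload)


@dataclass
class ToyGenomes:
    """Toy two-species reference: sequences plus single-exon gene models."""

    fasta_human: dict[str, str]
    fasta_mouse: dict[str, str]
    models_human: list[GeneModel]
    models_mouse: list[GeneModel]

    @property
    def chrom_species(self) -> dict[str, Species]:
        table = {c: Species.HUMAN for c in self.fasta_human}
        table.update({c: Species.MOUSE for c in self.fasta_mouse})
        return table

    @property
    def all_models(self) -> list[GeneModel]:
        return self.models_human + self.models_mouse

    def gene_sequence(self, gene_id: str) -> str:
        for gm, fasta in (
            *((m, self.fasta_human) for m in self.models_human),
            *((m, self.fasta_mouse) for m in self.models_mouse),
        ):
            if gm.gene_id == gene_id:
                start, end = gm.span
                return fasta[gm.chrom][start:end]
        raise KeyError(gene_id)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _single_exon_model(
    gene_id: str, species: Species, chrom: str, start: int, length: int
) -> GeneModel:
    return GeneModel(
        gene_id=gene_id,
        species=species,
        chrom=chrom,
        strand="+",
        biotype="protein_coding",
        transcripts=((f"{gene_id}.t1", ((start, start + length),)),),
    )


def make_toy_genomes(
    n_ortholog_genes: int = 30,
    n_private_per_species: int = 10,
    gene_length_bp: int = 1000,
    divergence: float = 0.15,
    seed: int = 0,
    spacer_bp: int = 100,
) -> tuple[ToyGenomes, SimTruth]:
    """Build a toy human/mouse genome pair with diverged ortholog genes.

    Each ortholog pair differs by i.i.d. substitutions at rate ``divergence``;
    private genes are independent random sequences.  All genes are unspliced,
    protein-coding, and at least 400 bp so they survive the expression filters.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError(f"divergence {divergence} outside [0, 0.5]")
    if gene_length_bp < 400:
        raise ValueError("gene_length_bp must be >= 400 to pass the length filter")
    rng = np.random.default_rng(seed)

    def build(species: Species, chrom: str, gene_seqs: list[tuple[str, np.ndarray]]):
        parts, models, cursor = [], [], 0
        for gene_id, seq in gene_seqs:
            spacer = _random_seq(rng, spacer_bp)
            parts.extend([spacer, seq])
            cursor += spacer_bp
            models.append(
                _single_exon_model(gene_id, species, chrom, cursor, len(seq))
            )
            cursor += len(seq)
        parts.append(_random_seq(rng, spacer_bp))
        genome = b"".join(p.tobytes() for p in parts).decode()
        return {chrom: genome}, models

    human_genes: list[tuple[str, np.ndarray]] = []
    mouse_genes: list[tuple[str, np.ndarray]] = []
    ortholog_pairs: list[tuple[str, str]] = []
    for i in range(1, n_ortholog_genes + 1):
        hs_id, mm_id = f"hsG{i:04d}", f"mmG{i:04d}"
        hs_seq = _random_seq(rng, gene_length_bp)
        mm_seq = _mutate(rng, hs_seq, divergence)
        human_genes.append((hs_id, hs_seq))
        mouse_genes.append((mm_id, mm_seq))
        ortholog_pairs.append((hs_id, mm_id))
    for i in range(1, n_private_per_species + 1):
        human_genes.append((f"hsP{i:04d}", _random_seq(rng, gene_length_bp)))
        mouse_genes.append((f"mmP{i:04d}", _random_seq(rng, gene_length_bp)))

    fasta_h, models_h = build(Species.HUMAN, "hs_chr1", human_genes)
    fasta_m, models_m = build(Species.MOUSE, "mm_chr1", mouse_genes)
    genomes = ToyGenomes(fasta_h, fasta_m, models_h, models_m)
    truth = SimTruth(ortholog_pairs=ortholog_pairs)
    return genomes, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_reads(
    genomes: ToyGenomes,
    human_proportion: float = 0.88,
    n_read_pairs: int = 20000,
    read_length: int = 100,
    error_rate: float = 0.005,
    fragment_length: int = 300,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], SimTruth]:
    """Simulate unstranded paired-end reads from a two-species mixture.

    Each pair is drawn from one species with probability ``human_proportion``,
    then uniformly from that species' gene bodies; mate 1 reads the fragment
    5' end, mate 2 the reverse complement of its 3' end, with the fragment
    itself taken from either strand.
    """
    if not 0.0 <= human_proportion <= 1.0:
        raise ValueError("human_proportion outside [0, 1]")
    if n_read_pairs <= 0:
        raise ValueError("n_read_pairs must be positive")
    gene_len = min(
        gm.largest_transcript_length for gm in genomes.all_models
    )
    if not read_length <= fragment_length <= gene_len:
        raise ValueError(
            f"need read_length <= fragment_length <= gene length "
            f"({read_length}, {fragment_length}, {gene_len})"
        )
    rng = np.random.default_rng(seed)
    by_species = {
        Species.HUMAN: (genomes.fasta_human, genomes.models_human),
        Species.MOUSE: (genomes.fasta_mouse, genomes.models_mouse),
    }
    reads: list[tuple[str, str, str]] = []
    truth = SimTruth(species_proportion=human_proportion)
    for i in range(n_read_pairs):
        species = (
            Species.HUMAN if rng.random() < human_proportion else Species.MOUSE
        )
        fasta, models = by_species[species]
        gm = models[rng.integers(0, len(models))]
        start, end = gm.span
        frag_start = start + rng.integers(0, end - start - fragment_length + 1)
        frag = fasta[gm.chrom][frag_start : frag_start + fragment_length]
        if rng.random() < 0.5:
            frag = _revcomp(frag)
        mate1 = frag[:read_length]
        mate2 = _revcomp(frag[-read_length:])
        if error_rate > 0:
            mate1 = _apply_errors(rng, mate1, error_rate)
            mate2 = _apply_errors(rng, mate2, error_rate)
        read_id = f"pair{i:06d}"
        reads.append((read_id, mate1, mate2))
        truth.read_species[read_id] = species.value
        truth.read_gene[read_id] = gm.gene_id
    return reads, truth


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def write_fastq_pair(
    reads: Sequence[tuple[str, str, str]], path1: str | Path, path2: str | Path
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for read_id, mate1, mate2 in reads:
            f1.write(f"@{read_id}/1\n{mate1}\n+\n{'I' * len(mate1)}\n")
            f2.write(f"@{read_id}/2\n{mate2}\n+\n{'I' * len(mate2)}\n")


def read_fastq_pair(path1: str | Path, path2: str | Path) -> list[tuple[str, str, str]]:
    from Bio import SeqIO

    r1 = list(SeqIO.parse(str(path1), "fastq"))
    r2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("FASTQ mates have different record counts")
    reads = []
    for a, b in zip(r1, r2):
        rid = a.id.rsplit("/", 1)[0]
        reads.append((rid, str(a.seq), str(b.seq)))
    return reads


# ---------------------------------------------------------------------------
# Count simulation with planted structure
# ---------------------------------------------------------------------------

def simulate_counts(
    n_samples: int = 79,
    n_human_genes: int = 2000,
    n_mouse_genes: int = 800,
    planted_k: int = 5,
    cluster_strength: float = 8.0,
    n_coupled_pairs: int = 4,
    n_hub_partners: int = 0,
    n_de_genes: int = 50,
    de_log2fc: float = 2.0,
    nb_dispersion: float = 0.1,
    gender_ratio: float = 0.5,
    coupled_log2_sd: float = 2.0,
    marker_fraction: float = 0.30,
    named_markers: bool = False,
    seed: int = 0,
) -> tuple[CountMatrix, list[SampleMetadata], SimTruth]:
    """Simulate a two-species count matrix with planted analysis structure.

    The mean matrix is a rank-``planted_k`` non-negative product: per-cluster
    marker-gene blocks (elevated ``1 + cluster_strength``-fold in their own
    cluster) times one-hot cluster membership, scaled per sample.  On top of
    that base: coupled human/mouse pairs share a latent per-sample log2
    factor (with a negative loading on one member for anti-correlation), an
    optional hub gene couples to several mouse partners, ``n_de_genes`` human
    genes gain ``de_log2fc`` in the BTNBC subtype, and the four Y-chromosome
    genes are high in male and near-zero in female hosts.  Counts are drawn
    from a negative binomial with variance mu + dispersion * mu^2.
    """
    if planted_k < 2:
        raise ValueError("planted_k must be >= 2")
    if n_samples < 2 * planted_k:
        raise ValueError("need n_samples >= 2 * planted_k")
    if n_mouse_genes < len(Y_GENES) + n_hub_partners + n_coupled_pairs + 10:
        raise ValueError("n_mouse_genes too small for the requested structure")
    if n_human_genes < n_de_genes + n_coupled_pairs + 10:
        raise ValueError("n_human_genes too small for the requested structure")

    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    human_genes = [f"hsG{i + 1:05d}" for i in range(n_human_genes)]
    mouse_genes = list(Y_GENES) + [
        f"mmG{i + 1:05d}" for i in range(n_mouse_genes - len(Y_GENES))
    ]
    if named_markers:
        # give field-standard names to a few genes so the bespoke
        # classifiers and the hub example run on familiar symbols
        mid = n_human_genes // 2
        human_genes[mid] = "FAP"
        human_genes[mid + 1] = "CSPG4"
        if n_hub_partners:
            human_genes[-(n_de_genes + n_coupled_pairs + 1)] = "MIF"
            plain_tail = n_mouse_genes - len(Y_GENES)
            mouse_genes[len(Y_GENES) + plain_tail - n_coupled_pairs - n_hub_partners] = "Ddx6"
    genes = human_genes + mouse_genes
    n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    # sample-level structure
    clusters = np.array([i % planted_k + 1 for i in range(n_samples)])
    genders = np.where(rng.random(n_samples) < gender_ratio, "male", "female")
    subtypes = np.array(["BTNBC" if i % 2 == 0 else "luminalB" for i in range(n_samples)])

    # gene roles; markers come from the head of each species' plain genes,
    # coupled/DE genes from the tail, so roles never overlap
    def blocks(pool: list[str]) -> list[list[str]]:
        n_mark = int(len(pool) * marker_fraction)
        per = n_mark // planted_k
        return [pool[b * per : (b + 1) * per] for b in range(planted_k)]

    plain_mouse = mouse_genes[len(Y_GENES):]
    human_blocks = blocks(human_genes)
    mouse_blocks = blocks(plain_mouse)

    de_genes = human_genes[-n_de_genes:] if n_de_genes else []
    coupled_h = human_genes[-(n_de_genes + n_coupled_pairs): len(human_genes) - n_de_genes]
    coupled_m = plain_mouse[-n_coupled_pairs:] if n_coupled_pairs else []
    hub_gene = None
    hub_partners: list[str] = []
    if n_hub_partners:
        hub_gene = human_genes[-(n_de_genes + n_coupled_pairs + 1)]
        hub_partners = plain_mouse[-(n_coupled_pairs + n_hub_partners): len(plain_mouse) - n_coupled_pairs]

    # Cell-type mixture model: each sample is a graded mixture of the k
    # stromal programs with one dominant type (its cluster); marker-block
    # genes scale with the sample's membership weight, so the mean matrix is
    # base + (rank-k marker-block basis) x (membership weights).
    memberships = rng.dirichlet(np.full(planted_k, 0.3), size=n_samples).T
    for j in range(n_samples):
        memberships[clusters[j] - 1, j] += 3.0
    memberships /= memberships.sum(axis=0, keepdims=True)

    base = rng.lognormal(mean=np.log(150.0), sigma=1.0, size=n_genes)
    # coupled genes model well-expressed regulators (the interesting hubs in
    # real data are highly expressed); a solid base mean keeps the latent
    # factor, not counting noise, in charge of their correlation
    for g in [*coupled_h, *coupled_m, *( [hub_gene] if hub_gene else []), *hub_partners]:
        base[gene_index[g]] = 300.0
    mu = np.tile(base[:, None], (1, n_samples))
    for b in range(planted_k):
        for g in human_blocks[b] + mouse_blocks[b]:
            mu[gene_index[g]] *= 1.0 + cluster_strength * memberships[b]

    # coupled cross-species pairs: shared latent log2 factor, sign alternating
    coupled_pairs: list[tuple[str, str, int]] = []
    for p, (hg, mg) in enumerate(zip(coupled_h, coupled_m)):
        u = rng.normal(0.0, coupled_log2_sd, size=n_samples)
        sign = -1 if p % 2 == 0 else 1
        mu[gene_index[hg]] *= 2.0 ** u
        mu[gene_index[mg]] *= 2.0 ** (sign * u)
        coupled_pairs.append((hg, mg, sign))
    if hub_gene is not None:
        u = rng.normal(0.0, coupled_log2_sd, size=n_samples)
        mu[gene_index[hub_gene]] *= 2.0 ** u
        for mg in hub_partners:
            mu[gene_index[mg]] *= 2.0 ** (-u)
            coupled_pairs.append((hub_gene, mg, -1))

    # subtype differential expression in the human compartment
    btnbc = subtypes == "BTNBC"
    for g in de_genes:
        mu[gene_index[g], btnbc] *= 2.0 ** de_log2fc

    # gender-dependent Y-chromosome genes: in males the four genes carry a
    # few percent of the mouse library (so the Y index sits well above the
    # 10 per-mille call threshold at any panel size); in females they are
    # essentially silent
    male = genders == "male"
    y_male_mean = 3.0 * n_mouse_genes  # ~5% of an average-expression library
    for g in Y_GENES:
        mu[gene_index[g], male] = y_male_mean
        mu[gene_index[g], ~male] = 0.05

    # per-sample library scaling
    sample_factor = rng.lognormal(mean=0.0, sigma=0.2, size=n_samples)
    mu *= sample_factor[None, :]

    if nb_dispersion > 0:
        size = 1.0 / nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples, dtype=int)

    gene_species = pd.Series(
        {g: (Species.HUMAN if g in set(human_genes) else Species.MOUSE) for g in genes}
    )
    library = {}
    hs_idx = np.arange(n_human_genes)
    mm_idx = np.arange(n_human_genes, n_genes)
    for j, s in enumerate(samples):
        library[(s, Species.HUMAN)] = int(counts[hs_idx, j].sum())
        library[(s, Species.MOUSE)] = int(counts[mm_idx, j].sum())

    matrix = CountMatrix(counts=counts_df, gene_species=gene_species, library_size=library)
    metadata = [
        SampleMetadata(
            sample_id=s,
            model_id=s,
            cancer_type="breast",
            provider="sim",
            mouse_strain=("NSG", "SCID", "nude")[i % 3],
            tumor_stage="unknown",
            subtype=subtypes[i],
        )
        for i, s in enumerate(samples)
    ]
    truth = SimTruth(
        planted_k=planted_k,
        cluster_of_sample={s: int(c) for s, c in zip(samples, clusters)},
        coupled_pairs=coupled_pairs,
        de_genes={g: float(de_log2fc) for g in de_genes},
        gender_of_sample={s: g for s, g in zip(samples, genders)},
        hub_gene=hub_gene,
        gene_universe=genes,
        mean_matrix=mu,
    )
    return matrix, metadata, truth


def count_sim_gene_models(matrix: CountMatrix, gene_length_bp: int = 1000) -> list[GeneModel]:
    """Single-exon gene models for a simulated count matrix (for FPKM)."""
    models = []
    cursors = {Species.HUMAN: 0, Species.MOUSE: 0}
    chroms = {Species.HUMAN: "hs_chrV", Species.MOUSE: "mm_chrV"}
    for g in matrix.genes:
        sp = matrix.gene_species[g]
        start = cursors[sp]
        models.append(_single_exon_model(g, sp, chroms[sp], start, gene_length_bp))
        cursors[sp] = start + gene_length_bp + 100
    return models


def make_signatures(
    truth: SimTruth,
    n_in_signature: int = 20,
    n_decoys: int = 50,
    seed: int = 0,
) -> list[tuple[str, str, list[str]]]:
    """Build one signature enriched in planted DE genes and one pure decoy."""
    rng = np.random.default_rng(seed)
    de = sorted(truth.de_genes)
    if n_in_signature > len(de):
        raise ValueError(
            f"requested {n_in_signature} signature genes but only {len(de)} planted DE genes"
        )
    non_de = [g for g in truth.gene_universe if g not in truth.de_genes]
    if n_decoys > len(non_de):
        raise ValueError("not enough non-DE genes for the decoy signature")
    sig = sorted(rng.choice(de, size=n_in_signature, replace=False).tolist())
    decoy = sorted(rng.choice(non_de, size=n_decoys, replace=False).tolist())
    return [
        ("planted_de", "genes drawn from the planted DE set", sig),
        ("decoy", "genes disjoint from the planted DE set", decoy),
    ]


# ---------------------------------------------------------------------------
# Multi-platform counts for marker triangulation
# ---------------------------------------------------------------------------

def simulate_platform_counts(
    n_genes: int = 1000,
    n_tumor_markers: int = 30,
    n_stroma_responsive: int = 10,
    n_pure_platforms: int = 2,
    n_mixed_platforms: int = 1,
    n_per_group: int = 8,
    tumor_log2fc: float = 3.0,
    nb_dispersion: float = 0.05,
    tumor_fraction_mixed: float = 0.02,
    stroma_level: float = 5.0,
    seed: int = 0,
) -> tuple[list[tuple[str, pd.DataFrame, list[str]]],
           list[tuple[str, pd.DataFrame, list[str]]],
           dict[str, set[str]]]:
    """Simulate tumor-pure and stroma-dominated platforms for triangulation.

    ``n_tumor_markers`` genes are up-regulated ``tumor_log2fc`` in the BTNBC
    tumor compartment.  Pure platforms sample the tumor compartment alone; in
    mixed platforms the tumor contributes only ``tumor_fraction_mixed`` of
    the signal, swamped by stroma, so the tumor contrast is lost — except for
    ``n_stroma_responsive`` of the markers whose *stromal* expression also
    differs between subtypes and which therefore stay significant.  The
    expected masked-marker set is the remaining tumor-only genes.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    markers = genes[:n_tumor_markers]
    stroma_resp = markers[:n_stroma_responsive]
    tumor_only = markers[n_stroma_responsive:]
    labels = ["luminalB"] * n_per_group + ["BTNBC"] * n_per_group
    btnbc = np.array([l == "BTNBC" for l in labels])

    def nb(mu: np.ndarray) -> np.ndarray:
        size = 1.0 / nb_dispersion
        return rng.negative_binomial(size, size / (size + mu))

    # stroma expresses each gene at stroma_level x the tumor's base level
    # (shared base): abundant stromal expression in both subtypes is exactly
    # what masks a tumor-compartment contrast in a mixed sample
    base = rng.lognormal(np.log(200.0), 0.8, size=n_genes)

    def tumor_mean() -> np.ndarray:
        mu = np.tile(base[:, None], (1, len(labels)))
        for g in markers:
            mu[genes.index(g), btnbc] *= 2.0 ** tumor_log2fc
        return mu

    def stroma_mean() -> np.ndarray:
        mu = np.tile(base[:, None] * stroma_level, (1, len(labels)))
        for g in stroma_resp:
            mu[genes.index(g), btnbc] *= 2.0 ** tumor_log2fc
        return mu

    pure, mixed = [], []
    cols = [f"P{i + 1:02d}" for i in range(len(labels))]
    for p in range(n_pure_platforms):
        counts = nb(tumor_mean())
        pure.append(
            (f"pure_{p + 1}", pd.DataFrame(counts, index=genes, columns=cols), list(labels))
        )
    for p in range(n_mixed_platforms):
        mu = tumor_fraction_mixed * tumor_mean() + (1 - tumor_fraction_mixed) * stroma_mean()
        counts = nb(mu)
        mixed.append(
            (f"mixed_{p + 1}", pd.DataFrame(counts, index=genes, columns=cols), list(labels))
        )
    truth_sets = {
        "tumor_markers": set(markers),
        "stroma_responsive": set(stroma_resp),
        "expected_masked": set(tumor_only),
    }
    return pure, mixed, truth_sets
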