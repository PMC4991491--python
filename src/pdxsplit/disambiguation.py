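"""Species-specific read disambiguation on a concatenated two-species reference.

Each paired-end fragment is aligned (ungapped seed-and-extend) against the
union of the human and mouse genomes.  A fragment is assigned to a species
only when a single best valid locus exists; reads tying across multiple loci
— in particular across species, as happens in perfectly conserved regions —
are discarded as ambiguous.  Valid loci obey the alignment filters: at most
``max_mismatch`` mismatches per mate and a total mismatch-to-mapped-length
ratio of at most ``max_mm_ratio``.  Assigned fragments are then counted per
gene in union mode (a fragment counts for a gene iff it overlaps the exons of
exactly that one gene) and converted to FPKM over the exon-union gene length.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, Species, merge_intervals
from .matrices import CountMatrix, ExpressionMatrix, Scale

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Call(str, Enum):
    HUMAN = "HUMAN"
    MOUSE = "MOUSE"
    AMBIGUOUS = "AMBIGUOUS"
    UNMAPPED = "UNMAPPED"


@dataclass
class SpeciesIndex:
    """Exact k-mer seed index over both genomes (both strands)."""

    k: int
    seed_table: dict[str, list[tuple[str, int, str]]]
    chrom_species: dict[str, Species]
    seqs: dict[str, str]

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError(f"seed length k={self.k} too short (need >= 11)")


@dataclass
class SpeciesAssignment:
    read_id: str
    call: Call
    best_locus: tuple[str, int, str] | None = None
    mismatches_per_end: tuple[int, int] | None = None
    mate_intervals: tuple[tuple[int, int], tuple[int, int]] | None = None


def build_species_index(
    fasta_by_species: Mapping[Species, Mapping[str, str]], k: int = 21
) -> SpeciesIndex:
    """Index every k-mer occurrence of both genomes on both strands."""
    chrom_species: dict[str, Species] = {}
    seqs: dict[str, str] = {}
    for species, fasta in fasta_by_species.items():
        if not fasta:
            raise ValueError(f"empty FASTA for {species.value}")
        for chrom, seq in fasta.items():
            if chrom in chrom_species:
                raise ValueError(f"duplicate chromosome name across species: {chrom}")
            chrom_species[chrom] = species
            seqs[chrom] = seq.upper()

    seed_table: dict[str, list[tuple[str, int, str]]] = {}
    for chrom, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            seed_table.setdefault(kmer, []).append((chrom, i, "+"))
            seed_table.setdefault(revcomp(kmer), []).append((chrom, i, "-"))
    return SpeciesIndex(k=k, seed_table=seed_table, chrom_species=chrom_species, seqs=seqs)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _mate_candidates(
    seq: str, index: SpeciesIndex, max_mismatch: int
) -> dict[tuple[str, int, str], int]:
    """Seed-and-extend one mate; return {(chrom, start, strand): mismatches}.

    ``strand`` '+' means the mate sequence matches the forward genome strand;
    '-' means its reverse complement does.  Seeds are taken at the two ends
    and the middle of the mate so a single sequencing error cannot knock out
    every seed.
    """
    k = index.k
    L = len(seq)
    offsets = sorted({0, (L - k) // 2, L - k})
    candidates: dict[tuple[str, int, str], int] = {}
    seen: set[tuple[str, int, str]] = set()
    for off in offsets:
        kmer = seq[off : off + k]
        for chrom, pos, strand in index.seed_table.get(kmer, ()):
            if strand == "+":
                start = pos - off
            else:
                start = pos - (L - k - off)
            key = (chrom, start, strand)
            if key in seen:
                continue
            seen.add(key)
            ref = index.seqs[chrom]
            if start < 0 or start + L > len(ref):
                continue
            query = seq if strand == "+" else revcomp(seq)
            mm = _hamming(query, ref[start : start + L])
            if mm <= max_mismatch:
                candidates[key] = mm
    return candidates


def assign_read_pair(
    pair: tuple[str, str, str],
    index: SpeciesIndex,
    max_mismatch: int = 3,
    max_mm_ratio: float = 0.10,
    max_fragment: int = 1000,
) -> SpeciesAssignment:
    """Assign one read pair to HUMAN, MOUSE, AMBIGUOUS or UNMAPPED.

    A candidate fragment locus pairs one alignment per mate on the same
    chromosome, opposite strands, within ``max_fragment``.  The single best
    valid locus (minimum total mismatches) decides the call; a tie across two
    or more distinct loci yields AMBIGUOUS, mirroring the discard of
    multi-mapping reads.
    """
    read_id, seq1, seq2 = pair
    if min(len(seq1), len(seq2)) < index.k:
        warnings.warn(f"read {read_id}: mate shorter than seed length; unmapped")
        return SpeciesAssignment(read_id=read_id, call=Call.UNMAPPED)

    cands1 = _mate_candidates(seq1.upper(), index, max_mismatch)
    cands2 = _mate_candidates(seq2.upper(), index, max_mismatch)
    total_len = len(seq1) + len(seq2)

    loci: list[tuple[int, tuple, tuple]] = []  # (total_mm, locus1, locus2)
    for (chrom1, start1, strand1), mm1 in cands1.items():
        for (chrom2, start2, strand2), mm2 in cands2.items():
            if chrom1 != chrom2 or strand1 == strand2:
                continue
            span = max(start1 + len(seq1), start2 + len(seq2)) - min(start1, start2)
            if span > max_fragment:
                continue
            total_mm = mm1 + mm2
            if total_mm / total_len > max_mm_ratio:
                continue
            loci.append((total_mm, (chrom1, start1, strand1, mm1, len(seq1)),
                         (chrom2, start2, strand2, mm2, len(seq2))))

    if not loci:
        return SpeciesAssignment(read_id=read_id, call=Call.UNMAPPED)

    loci.sort(key=lambda t: t[0])
    best_mm = loci[0][0]
    best = [l for l in loci if l[0] == best_mm]
    if len(best) > 1:
        return SpeciesAssignment(read_id=read_id, call=Call.AMBIGUOUS)

    _, (chrom, s1, strand1, mm1, l1), (_, s2, strand2, mm2, l2) = best[0]
    species = index.chrom_species[chrom]
    return SpeciesAssignment(
        read_id=read_id,
        call=Call.HUMAN if species is Species.HUMAN else Call.MOUSE,
        best_locus=(chrom, s1, strand1),
        mismatches_per_end=(mm1, mm2),
        mate_intervals=((s1, s1 + l1), (s2, s2 + l2)),
    )


def disambiguate_pairs(
    pairs: Iterable[tuple[str, str, str]],
    index: SpeciesIndex,
    max_mismatch: int = 3,
    max_mm_ratio: float = 0.10,
    max_fragment: int = 1000,
) -> list[SpeciesAssignment]:
    return [
        assign_read_pair(p, index, max_mismatch, max_mm_ratio, max_fragment)
        for p in pairs
    ]


# ---------------------------------------------------------------------------
# Union-mode fragment counting
# ---------------------------------------------------------------------------

def _fragment_intervals(
    mate_intervals: tuple[tuple[int, int], tuple[int, int]]
) -> list[tuple[int, int]]:
    # union of the two mates' aligned intervals; the inner gap is not counted
    return merge_intervals(mate_intervals)


def count_union(
    assignments: Sequence[SpeciesAssignment],
    gene_models: Sequence[GeneModel],
    sample_id: str,
) -> CountMatrix:
    """Count species-assigned fragments per gene in union mode (strand ignored).

    A fragment increments a gene iff its mate-interval union overlaps the
    exons of exactly one gene; fragments hitting zero or >= 2 genes stay
    uncounted but still contribute to the species library size.
    """
    exons_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    known_chroms: set[str] = set()
    for gm in gene_models:
        known_chroms.add(gm.chrom)
        for _, exons in gm.transcripts:
            for start, end in exons:
                exons_by_chrom.setdefault(gm.chrom, []).append((start, end, gm.gene_id))
    for chrom in exons_by_chrom:
        exons_by_chrom[chrom].sort()

    gene_ids = [gm.gene_id for gm in gene_models]
    gene_species = pd.Series({gm.gene_id: gm.species for gm in gene_models})
    counts = pd.Series(0, index=gene_ids, dtype=int)
    library: dict[Species, int] = {Species.HUMAN: 0, Species.MOUSE: 0}

    for asn in assignments:
        if asn.call not in (Call.HUMAN, Call.MOUSE):
            continue
        chrom = asn.best_locus[0]
        if chrom not in known_chroms:
            raise ValueError(f"assignment on unknown chromosome {chrom!r}")
        species = Species.HUMAN if asn.call is Call.HUMAN else Species.MOUSE
        library[species] += 1
        hit_genes: set[str] = set()
        for fs, fe in _fragment_intervals(asn.mate_intervals):
            for es, ee, gid in exons_by_chrom.get(chrom, ()):
                if es < fe and fs < ee:
                    hit_genes.add(gid)
        if len(hit_genes) == 1:
            counts[hit_genes.pop()] += 1

    return CountMatrix(
        counts=counts.to_frame(sample_id),
        gene_species=gene_species,
        library_size={
            (sample_id, Species.HUMAN): library[Species.HUMAN],
            (sample_id, Species.MOUSE): library[Species.MOUSE],
        },
    )


def merge_count_columns(columns: Sequence[CountMatrix]) -> CountMatrix:
    """Concatenate single-sample count columns over a shared gene universe."""
    counts = pd.concat([c.counts for c in columns], axis=1)
    if counts.isna().any().any():
        raise ValueError("count columns do not share a gene universe")
    library: dict[tuple[str, Species], int] = {}
    for c in columns:
        library.update(c.library_size)
    return CountMatrix(
        counts=counts.astype(int),
        gene_species=columns[0].gene_species,
        library_size=library,
    )


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def compute_fpkm(
    count_matrix: CountMatrix,
    gene_models: Sequence[GeneModel],
    min_transcript_bp: int = 400,
    coding_only: bool = True,
) -> ExpressionMatrix:
    """FPKM over exon-union gene length with biotype and length filters.

    FPKM(g, s) = counts(g, s) * 1e9 / (exon_union_length(g) * library(s, species(g))).
    Non-protein-coding genes and genes whose largest transcript is shorter
    than ``min_transcript_bp`` are removed before output (short transcripts
    over-estimate expression when shorter than the typical fragment).
    """
    models = {gm.gene_id: gm for gm in gene_models}
    filters = []
    keep: list[str] = []
    for gid in count_matrix.genes:
        gm = models.get(gid)
        if gm is None:
            raise ValueError(f"gene {gid} in counts but not in gene models")
        if coding_only and gm.biotype != "protein_coding":
            continue
        if gm.largest_transcript_length < min_transcript_bp:
            continue
        keep.append(gid)
    if coding_only:
        filters.append("biotype=protein_coding")
    filters.append(f"largest_transcript>={min_transcript_bp}bp")

    species_present = {models[g].species for g in keep}
    for sample in count_matrix.samples:
        for sp in species_present:
            if count_matrix.library_size.get((sample, sp), 0) == 0:
                raise ValueError(
                    f"zero {sp.value} library size for sample {sample}: FPKM undefined"
                )

    values = pd.DataFrame(index=keep, columns=count_matrix.samples, dtype=float)
    samples = count_matrix.samples
    for sp in species_present:
        genes_sp = [g for g in keep if models[g].species is sp]
        lengths = np.array([models[g].exon_union_length for g in genes_sp], dtype=float)
        libs = np.array([count_matrix.library_size[(s, sp)] for s in samples], dtype=float)
        block = count_matrix.counts.loc[genes_sp, samples].to_numpy(dtype=float)
        values.loc[genes_sp, samples] = block * 1e9 / (lengths[:, None] * libs[None, :])
    return ExpressionMatrix(
        values=values,
        scale=Scale.FPKM,
        filters_applied=filters,
        gene_species=pd.Series({g: models[g].species for g in keep}),
    )


def species_proportion(count_matrix: CountMatrix, sample_id: str) -> float:
    """Human fraction of species-assigned fragments in one sample."""
    h = count_matrix.library_size.get((sample_id, Species.HUMAN), 0)
    m = count_matrix.library_size.get((sample_id, Species.MOUSE), 0)
    if h + m == 0:
        raise ValueError(f"sample {sample_id}: no species-assigned fragments")
    return h / (h + m)
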