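"""Readers and writers for the external formats the pipeline touches.

FASTA and GTF inputs follow the Ensembl dialect; gene signatures use GMT;
matrices and metadata travel as TSV; run reports as JSON.  All genomic
intervals are converted to 0-based half-open coordinates on read and back to
1-based inclusive on write, so interval arithmetic inside the package is
uniform.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO


class Species(str, Enum):
    HUMAN = "HUMAN"
    MOUSE = "MOUSE"


#: sequence-name prefixes used when no chromosome→species sidecar is given
SPECIES_PREFIXES = {"hs_": Species.HUMAN, "mm_": Species.MOUSE}


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 0-based half-open intervals into a sorted disjoint union."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass(frozen=True)
class GeneModel:
    """One gene with its transcript/exon structure.

    ``transcripts`` maps transcript_id to a tuple of 0-based half-open exon
    intervals.  Exon-union length (basis of FPKM) and the largest summed
    transcript length (basis of the short-transcript filter) are derived.
    """

    gene_id: str
    species: Species
    chrom: str
    strand: str
    biotype: str
    transcripts: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]

    def __post_init__(self) -> None:
        for tx_id, exons in self.transcripts:
            if not exons:
                raise ValueError(f"transcript {tx_id} of {self.gene_id} has no exons")
            for start, end in exons:
                if start >= end:
                    raise ValueError(
                        f"empty/inverted exon [{start}, {end}) in {self.gene_id}/{tx_id}"
                    )

    @property
    def exon_union_length(self) -> int:
        all_exons = [iv for _, exons in self.transcripts for iv in exons]
        return sum(end - start for start, end in merge_intervals(all_exons))

    @property
    def largest_transcript_length(self) -> int:
        return max(
            sum(end - start for start, end in exons) for _, exons in self.transcripts
        )

    @property
    def span(self) -> tuple[int, int]:
        all_exons = [iv for _, exons in self.transcripts for iv in exons]
        return min(s for s, _ in all_exons), max(e for _, e in all_exons)


@dataclass
class SampleMetadata:
    sample_id: str
    model_id: str = ""
    cancer_type: str = ""
    provider: str = ""
    mouse_strain: str = ""
    tumor_stage: str = "unknown"
    stromal_score: float | None = None
    subtype: str | None = None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: uppercase sequence}`` map."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record ID: {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path, species: Species) -> list[GeneModel]:
    """Parse an Ensembl-style GTF into gene models for one species.

    Only ``exon`` features are consulted; genes and transcripts are grouped by
    their ``gene_id``/``transcript_id`` attributes.  Coordinates are converted
    from GTF 1-based inclusive to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by="start"):
        if feat.start > feat.end:
            raise ValueError(
                f"exon with start > end at {feat.seqid}:{feat.start}-{feat.end}"
            )
        gene_id = feat.attributes.get("gene_id", [None])[0]
        tx_id = feat.attributes.get("transcript_id", [None])[0]
        if gene_id is None:
            raise ValueError(f"exon without gene_id at {feat.seqid}:{feat.start}")
        if tx_id is None:
            raise ValueError(f"exon of gene {gene_id} lacks transcript_id")
        biotype = feat.attributes.get("gene_biotype", ["protein_coding"])[0]
        entry = genes.setdefault(
            gene_id,
            {"chrom": feat.seqid, "strand": feat.strand, "biotype": biotype, "tx": {}},
        )
        entry["tx"].setdefault(tx_id, []).append((feat.start - 1, feat.end))

    models = []
    for gene_id, entry in genes.items():
        transcripts = tuple(
            (tx_id, tuple(sorted(exons))) for tx_id, exons in entry["tx"].items()
        )
        models.append(
            GeneModel(
                gene_id=gene_id,
                species=species,
                chrom=entry["chrom"],
                strand=entry["strand"] if entry["strand"] in "+-" else "+",
                biotype=entry["biotype"],
                transcripts=transcripts,
            )
        )
    return models


def write_gtf(models: Sequence[GeneModel], path: str | Path, source: str = "pdxsplit") -> None:
    """Write gene models as exon lines in Ensembl GTF dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        for gm in models:
            for tx_id, exons in gm.transcripts:
                for start, end in exons:
                    attrs = (
                        f'gene_id "{gm.gene_id}"; transcript_id "{tx_id}"; '
                        f'gene_biotype "{gm.biotype}";'
                    )
                    fh.write(
                        f"{gm.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t"
                        f"{gm.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# GMT gene signatures
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read a GMT file into ``(signature_name, gene list)`` pairs.

    Gene lists are deduplicated preserving first occurrence; the description
    column is ignored.
    """
    signatures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 fields, got {len(fields)}")
            name = fields[0]
            seen = set()
            genes = []
            for g in fields[2:]:
                if g and g not in seen:
                    seen.add(g)
                    genes.append(g)
            if not genes:
                raise ValueError(f"GMT line {lineno}: signature {name} has no genes")
            signatures.append((name, genes))
    return signatures


def write_gmt(
    signatures: Sequence[tuple[str, str, Sequence[str]]], path: str | Path
) -> None:
    """Write ``(name, description, genes)`` triples as GMT."""
    with open(path, "w") as fh:
        for name, desc, genes in signatures:
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices and metadata
# ---------------------------------------------------------------------------

def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample TSV matrix (first column gene_id, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"matrix {path} contains missing values; all cells are required")
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    if df.isna().any().any():
        raise ValueError("refusing to write matrix with missing values")
    df.to_csv(path, sep="\t", index_label="gene_id")


_META_COLUMNS = [
    "sample_id", "model_id", "cancer_type", "provider", "mouse_strain",
    "tumor_stage", "stromal_score", "subtype",
]


def read_metadata_tsv(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dups}")
    out = []
    for _, row in df.iterrows():
        score = row.get("stromal_score")
        out.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                model_id=str(row.get("model_id", "") or ""),
                cancer_type=str(row.get("cancer_type", "") or ""),
                provider=str(row.get("provider", "") or ""),
                mouse_strain=str(row.get("mouse_strain", "") or ""),
                tumor_stage=str(row.get("tumor_stage", "unknown") or "unknown"),
                stromal_score=None if pd.isna(score) else float(score),
                subtype=None if pd.isna(row.get("subtype")) else str(row.get("subtype")),
            )
        )
    return out


def write_metadata_tsv(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id, "model_id": m.model_id,
            "cancer_type": m.cancer_type, "provider": m.provider,
            "mouse_strain": m.mouse_strain, "tumor_stage": m.tumor_stage,
            "stromal_score": m.stromal_score, "subtype": m.subtype,
        }
        for m in metadata
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Chromosome → species sidecar table
# ---------------------------------------------------------------------------

def read_species_table(path: str | Path) -> dict[str, Species]:
    """Read a two-column chrom→species TSV (values HUMAN/MOUSE)."""
    table = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"species table line {lineno}: expected 2 columns")
            table[parts[0]] = Species(parts[1].upper())
    return table


def write_species_table(table: Mapping[str, Species], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, sp in table.items():
            fh.write(f"{chrom}\t{sp.value}\n")


def infer_species_from_chrom(chrom: str) -> Species:
    """Prefix fallback when no sidecar table is supplied ('hs_'/'mm_')."""
    for prefix, sp in SPECIES_PREFIXES.items():
        if chrom.startswith(prefix):
            return sp
    raise ValueError(
        f"cannot infer species of chromosome {chrom!r}: no sidecar table and no "
        f"hs_/mm_ prefix"
    )


# ---------------------------------------------------------------------------
# Network edge lists
# ---------------------------------------------------------------------------

_SP_TO_PREFIX = {Species.HUMAN: "hs", Species.MOUSE: "mm"}
_PREFIX_TO_SP = {v: k for k, v in _SP_TO_PREFIX.items()}


def _node_label(gene_id: str, species: Species) -> str:
    return f"{_SP_TO_PREFIX[species]}:{gene_id}"


def _parse_node_label(label: str) -> tuple[str, Species]:
    prefix, _, gene_id = label.partition(":")
    return gene_id, _PREFIX_TO_SP[prefix]


def write_edge_list(network, path: str | Path) -> None:
    """Serialize a correlation network as TSV (node_a, node_b, r, edge_class).

    One row per undirected edge with node_a < node_b lexicographically on the
    species-prefixed labels.
    """
    rows = []
    for edge in network.edges:
        a = _node_label(*edge.gene_a)
        b = _node_label(*edge.gene_b)
        if a > b:
            a, b = b, a
        rows.append((a, b, edge.r, edge.edge_class))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tr\tedge_class\n")
        for a, b, r, cls in rows:
            fh.write(f"{a}\t{b}\t{r!r}\t{cls}\n")


def read_edge_list(path: str | Path):
    from .crossnet import CorrelationEdge, CorrelationNetwork

    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    edges = []
    for _, row in df.iterrows():
        edges.append(
            CorrelationEdge(
                gene_a=_parse_node_label(row["node_a"]),
                gene_b=_parse_node_label(row["node_b"]),
                r=float(row["r"]),
                edge_class=str(row["edge_class"]),
            )
        )
    return CorrelationNetwork(edges=edges, threshold=float("nan"))


# ---------------------------------------------------------------------------
# Run reports
# ---------------------------------------------------------------------------

def write_run_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_run_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
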