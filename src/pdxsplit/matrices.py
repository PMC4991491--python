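"""In-memory containers for count and expression matrices.

Counts are integer fragments per gene per sample, with each gene tagged by its
species of origin and per-(sample, species) library sizes (the number of
species-assigned fragments).  Expression values are FPKM or the non-negative
log2(FPKM + offset) transform used for clustering and correlation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .io_formats import Species


class Scale(str, Enum):
    FPKM = "FPKM"
    LOG2_OFFSET = "LOG2_OFFSET"


@dataclass
class CountMatrix:
    """Integer fragment counts, genes x samples."""

    counts: pd.DataFrame
    gene_species: pd.Series
    library_size: dict[tuple[str, Species], int]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.gene_species.index)
        if missing:
            raise ValueError(f"genes without species tag: {sorted(missing)[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def genes_of(self, species: Species) -> list[str]:
        mask = self.gene_species.loc[self.counts.index] == species
        return list(self.counts.index[mask.values])

    def subset_species(self, species: Species) -> "CountMatrix":
        genes = self.genes_of(species)
        return CountMatrix(
            counts=self.counts.loc[genes],
            gene_species=self.gene_species.loc[genes],
            library_size={
                key: v for key, v in self.library_size.items() if key[1] == species
            },
        )


@dataclass
class ExpressionMatrix:
    """Real-valued expression, genes x samples, on FPKM or log2-offset scale."""

    values: pd.DataFrame
    scale: Scale
    filters_applied: list[str] = field(default_factory=list)
    gene_species: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale is Scale.FPKM and (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def species_of(self, gene_id: str) -> Species | None:
        if self.gene_species is None:
            return None
        return self.gene_species.get(gene_id)

    def subset_species(self, species: Species) -> "ExpressionMatrix":
        if self.gene_species is None:
            raise ValueError("matrix carries no species tags")
        mask = self.gene_species.loc[self.values.index] == species
        genes = self.values.index[mask.values]
        return ExpressionMatrix(
            values=self.values.loc[genes],
            scale=self.scale,
            filters_applied=list(self.filters_applied),
            gene_species=self.gene_species.loc[genes],
        )
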