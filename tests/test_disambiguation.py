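import warnings

import numpy as np
import pandas as pd
import pytest

from pdxsplit.disambiguation import (
    Call,
    SpeciesAssignment,
    assign_read_pair,
    build_species_index,
    compute_fpkm,
    count_union,
    disambiguate_pairs,
    merge_count_columns,
    revcomp,
    species_proportion,
)
from pdxsplit.io_formats import GeneModel, Species
from pdxsplit.matrices import CountMatrix
from pdxsplit.synthetic_data import simulate_reads


@pytest.fixture(scope="module")
def toy_index(toy_genomes):
    genomes, _ = toy_genomes
    return build_species_index(
        {Species.HUMAN: genomes.fasta_human, Species.MOUSE: genomes.fasta_mouse}, k=21
    )


def _pair_from(seq, start, frag=200, read=80):
    frag_seq = seq[start : start + frag]
    return frag_seq[:read], revcomp(frag_seq[-read:])


class TestIndex:
    def test_seed_table_counting_bound(self):
        rng = np.random.default_rng(0)
        seqs = {
            "hs_c": "".join(rng.choice(list("ACGT"), 1000)),
            "mm_c": "".join(rng.choice(list("ACGT"), 1000)),
        }
        idx = build_species_index(
            {Species.HUMAN: {"hs_c": seqs["hs_c"]}, Species.MOUSE: {"mm_c": seqs["mm_c"]}},
            k=15,
        )
        fwd = sum(1 for hits in idx.seed_table.values() for h in hits if h[2] == "+")
        assert fwd <= 2 * (1000 - 14)

    def test_shared_sequence_indexed_on_both_species(self):
        seq = "ACGTACGGTTACGATCGATTACGCGATCGA" * 3
        idx = build_species_index(
            {Species.HUMAN: {"hs_c": seq}, Species.MOUSE: {"mm_c": seq}}, k=21
        )
        kmer = seq[:21]
        assert len(idx.seed_table[kmer]) >= 2

    def test_empty_fasta_rejected(self):
        with pytest.raises(ValueError):
            build_species_index({Species.HUMAN: {}, Species.MOUSE: {"c": "ACGT"}})

    def test_duplicate_chromosome_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_species_index(
                {Species.HUMAN: {"c": "ACGT" * 10}, Species.MOUSE: {"c": "ACGT" * 10}}
            )

    def test_short_seed_rejected(self):
        with pytest.raises(ValueError):
            build_species_index(
                {Species.HUMAN: {"h": "ACGT" * 10}, Species.MOUSE: {"m": "AACC" * 10}}, k=9
            )


class TestAssignment:
    def test_verbatim_human_pair_called_human(self, toy_genomes, toy_index):
        genomes, truth = toy_genomes
        gm = genomes.models_human[0]
        start, _ = gm.span
        m1, m2 = _pair_from(genomes.fasta_human[gm.chrom], start + 10)
        asn = assign_read_pair(("r1", m1, m2), toy_index)
        assert asn.call is Call.HUMAN
        assert asn.mismatches_per_end == (0, 0)

    def test_conserved_region_ambiguous(self):
        rng = np.random.default_rng(1)
        shared = "".join(rng.choice(list("ACGT"), 400))
        idx = build_species_index(
            {Species.HUMAN: {"hs_c": shared}, Species.MOUSE: {"mm_c": shared}}, k=21
        )
        m1, m2 = _pair_from(shared, 50)
        asn = assign_read_pair(("r1", m1, m2), idx)
        assert asn.call is Call.AMBIGUOUS

    def test_four_errors_in_one_mate_unmapped(self, toy_genomes):
        genomes, _ = toy_genomes
        # private gene: exactly one candidate locus exists
        gm = next(g for g in genomes.models_human if g.gene_id.startswith("hsP"))
        idx = build_species_index(
            {Species.HUMAN: genomes.fasta_human, Species.MOUSE: genomes.fasta_mouse}, k=21
        )
        start, _ = gm.span
        m1, m2 = _pair_from(genomes.fasta_human[gm.chrom], start + 5)
        corrupted = list(m1)
        for pos in (30, 40, 50, 60):  # away from the seed offsets
            corrupted[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[corrupted[pos]]
        asn = assign_read_pair(("r1", "".join(corrupted), m2), idx)
        assert asn.call is Call.UNMAPPED

    def test_mate_shorter_than_seed_warns_unmapped(self, toy_index):
        with pytest.warns(UserWarning):
            asn = assign_read_pair(("r1", "ACGT", "ACGTACGTACGTACGTACGTACGT"), toy_index)
        assert asn.call is Call.UNMAPPED

    def test_calls_partition_input_and_are_order_invariant(self, toy_genomes, toy_index):
        genomes, _ = toy_genomes
        reads, _ = simulate_reads(genomes, human_proportion=0.6, n_read_pairs=300,
                                  read_length=80, fragment_length=200,
                                  error_rate=0.01, seed=21)
        forward = disambiguate_pairs(reads, toy_index)
        backward = disambiguate_pairs(list(reversed(reads)), toy_index)
        assert len(forward) == len(reads)
        by_id_fwd = {a.read_id: a.call for a in forward}
        by_id_bwd = {a.read_id: a.call for a in backward}
        assert by_id_fwd == by_id_bwd
        assert all(isinstance(a.call, Call) for a in forward)

    def test_species_recovery_small_mixture(self, toy_genomes, toy_index):
        genomes, _ = toy_genomes
        reads, truth = simulate_reads(genomes, human_proportion=0.88, n_read_pairs=2000,
                                      read_length=80, fragment_length=200,
                                      error_rate=0.005, seed=22)
        assignments = disambiguate_pairs(reads, toy_index)
        wrong = sum(
            1 for a in assignments
            if a.call in (Call.HUMAN, Call.MOUSE)
            and a.call.value != truth.read_species[a.read_id]
        )
        called = sum(1 for a in assignments if a.call in (Call.HUMAN, Call.MOUSE))
        assert called / len(reads) > 0.95
        assert wrong / called < 0.005


def _single_exon(gene_id, species, chrom, start, end):
    return GeneModel(gene_id, species, chrom, "+", "protein_coding",
                     ((f"{gene_id}.t", ((start, end),)),))


def _assignment(read_id, call, chrom, iv1, iv2):
    return SpeciesAssignment(
        read_id=read_id, call=call, best_locus=(chrom, iv1[0], "+"),
        mismatches_per_end=(0, 0), mate_intervals=(iv1, iv2),
    )


class TestUnionCounting:
    models = [
        _single_exon("gA", Species.HUMAN, "hs_c", 100, 400),
        _single_exon("gB", Species.HUMAN, "hs_c", 380, 700),
        _single_exon("gM", Species.MOUSE, "mm_c", 0, 500),
    ]

    def test_fragment_inside_single_gene_counts(self):
        asn = [_assignment("r1", Call.HUMAN, "hs_c", (120, 200), (250, 330))]
        out = count_union(asn, self.models, "s1")
        assert out.counts.loc["gA", "s1"] == 1
        assert out.library_size[("s1", Species.HUMAN)] == 1

    def test_fragment_spanning_two_genes_uncounted(self):
        asn = [_assignment("r1", Call.HUMAN, "hs_c", (300, 380), (390, 470))]
        out = count_union(asn, self.models, "s1")
        assert out.counts["s1"].sum() == 0
        assert out.library_size[("s1", Species.HUMAN)] == 1

    def test_intergenic_fragment_in_library_only(self):
        asn = [_assignment("r1", Call.HUMAN, "hs_c", (800, 880), (900, 980))]
        out = count_union(asn, self.models, "s1")
        assert out.counts["s1"].sum() == 0
        assert out.library_size[("s1", Species.HUMAN)] == 1

    def test_unknown_chromosome_rejected(self):
        asn = [_assignment("r1", Call.HUMAN, "hs_unknown", (0, 80), (100, 180))]
        with pytest.raises(ValueError, match="hs_unknown"):
            count_union(asn, self.models, "s1")


class TestFpkm:
    def _count_matrix(self, counts_by_gene, library):
        models = [
            _single_exon("g1", Species.HUMAN, "hs_c", 0, 2000),
            _single_exon("gshort", Species.HUMAN, "hs_c", 3000, 3399),
            _single_exon("gzero", Species.HUMAN, "hs_c", 4000, 5000),
        ]
        counts = pd.DataFrame({"s1": counts_by_gene})
        gene_species = pd.Series({g: Species.HUMAN for g in counts.index})
        cm = CountMatrix(counts=counts, gene_species=gene_species,
                         library_size={("s1", Species.HUMAN): library})
        return cm, models

    def test_fpkm_formula(self):
        cm, models = self._count_matrix({"g1": 100, "gshort": 5, "gzero": 0}, 1_000_000)
        out = compute_fpkm(cm, models)
        assert out.values.loc["g1", "s1"] == pytest.approx(50.0)

    def test_short_transcript_filtered(self):
        cm, models = self._count_matrix({"g1": 100, "gshort": 5, "gzero": 0}, 1_000_000)
        out = compute_fpkm(cm, models)
        assert "gshort" not in out.values.index  # largest transcript 399 bp

    def test_zero_counts_zero_fpkm(self):
        cm, models = self._count_matrix({"g1": 100, "gshort": 5, "gzero": 0}, 1_000_000)
        out = compute_fpkm(cm, models)
        assert out.values.loc["gzero", "s1"] == 0.0

    def test_zero_library_rejected(self):
        cm, models = self._count_matrix({"g1": 0, "gshort": 0, "gzero": 0}, 0)
        with pytest.raises(ValueError, match="s1"):
            compute_fpkm(cm, models)

    def test_noncoding_filtered(self):
        models = [
            _single_exon("g1", Species.HUMAN, "hs_c", 0, 2000),
            GeneModel("gnc", Species.HUMAN, "hs_c", "+", "lincRNA",
                      (("gnc.t", ((3000, 4000),)),)),
        ]
        counts = pd.DataFrame({"s1": {"g1": 10, "gnc": 10}})
        cm = CountMatrix(counts=counts,
                         gene_species=pd.Series({"g1": Species.HUMAN, "gnc": Species.HUMAN}),
                         library_size={("s1", Species.HUMAN): 1000})
        out = compute_fpkm(cm, models)
        assert list(out.values.index) == ["g1"]
        out_all = compute_fpkm(cm, models, coding_only=False)
        assert "gnc" in out_all.values.index

    def test_fpkm_column_identity(self, toy_genomes, toy_index):
        """Sum over genes of FPKM*len/1e9*library equals counted fragments."""
        genomes, _ = toy_genomes
        reads, _ = simulate_reads(genomes, human_proportion=0.7, n_read_pairs=1500,
                                  read_length=80, fragment_length=200, seed=30)
        assignments = disambiguate_pairs(reads, toy_index)
        cm = count_union(assignments, genomes.all_models, "s1")
        fpkm = compute_fpkm(cm, genomes.all_models)
        lengths = {g.gene_id: g.exon_union_length for g in genomes.all_models}
        for sp in (Species.HUMAN, Species.MOUSE):
            genes = [g for g in fpkm.values.index if fpkm.gene_species[g] is sp]
            lib = cm.library_size[("s1", sp)]
            total = sum(
                fpkm.values.loc[g, "s1"] * lengths[g] / 1e9 * lib for g in genes
            )
            assert total == pytest.approx(cm.counts.loc[genes, "s1"].sum())


class TestSpeciesProportion:
    def _cm(self, h, m):
        counts = pd.DataFrame({"s1": {"hg": h, "mg": m}})
        return CountMatrix(
            counts=counts,
            gene_species=pd.Series({"hg": Species.HUMAN, "mg": Species.MOUSE}),
            library_size={("s1", Species.HUMAN): h, ("s1", Species.MOUSE): m},
        )

    def test_equal_totals(self):
        assert species_proportion(self._cm(500, 500), "s1") == 0.5

    def test_mouse_only(self):
        assert species_proportion(self._cm(0, 500), "s1") == 0.0

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            species_proportion(self._cm(0, 0), "s1")


def test_merge_count_columns(toy_genomes, toy_index):
    genomes, _ = toy_genomes
    cols = []
    for i, seed in enumerate((40, 41)):
        reads, _ = simulate_reads(genomes, human_proportion=0.8, n_read_pairs=300,
                                  read_length=80, fragment_length=200, seed=seed)
        asn = disambiguate_pairs(reads, toy_index)
        cols.append(count_union(asn, genomes.all_models, f"s{i}"))
    merged = merge_count_columns(cols)
    assert merged.samples == ["s0", "s1"]
    assert merged.counts["s0"].equals(cols[0].counts["s0"])
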