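import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from pdxsplit.markers import (
    DERecord,
    PlatformDESet,
    bh_fdr,
    de_test,
    hypergeom_overlap,
    size_factors,
    stroma_stratify,
    triangulate_markers,
)


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_ratio_two(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 200, 50)
        counts = pd.DataFrame({"s1": base, "s2": base, "s3": base * 2})
        f = size_factors(counts)
        assert f["s3"] / f["s1"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 500, (40, 4)),
                              index=[f"g{i}" for i in range(40)])
        shuffled = counts.sample(frac=1.0, random_state=2)
        assert np.allclose(size_factors(counts), size_factors(shuffled))

    def test_no_reference_gene_rejected(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)


def _nb_counts(rng, mu, alpha, shape):
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mu), size=shape)


class TestDeTest:
    def _frame(self, arr):
        return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                            columns=[f"s{i}" for i in range(arr.shape[1])])

    def _labels(self, n1, n2):
        return {f"s{i}": ("A" if i < n1 else "B") for i in range(n1 + n2)}

    def test_sign_matches_mean_difference(self):
        rng = np.random.default_rng(3)
        arr = _nb_counts(rng, 100.0, 0.05, (50, 10))
        arr[:10, 5:] *= 4
        records = de_test(self._frame(arr), self._labels(5, 5))
        sf_norm = arr / size_factors(self._frame(arr)).to_numpy()[None, :]
        for i, r in enumerate(records):
            diff = sf_norm[i, 5:].mean() - sf_norm[i, :5].mean()
            assert np.sign(r.log2_fc) == np.sign(diff) or diff == 0

    def test_low_expression_gate(self):
        from pdxsplit.matrices import ExpressionMatrix, Scale

        rng = np.random.default_rng(4)
        arr = _nb_counts(rng, 50.0, 0.05, (5, 8))
        counts = self._frame(arr)
        fpkm = pd.DataFrame(
            np.full((5, 8), 10.0), index=counts.index, columns=counts.columns
        )
        fpkm.loc["g2"] = 0.5  # below the FPKM > 1 gate everywhere
        gate = ExpressionMatrix(values=fpkm, scale=Scale.FPKM)
        records = de_test(counts, self._labels(4, 4), min_fpkm_gate=gate)
        by_gene = {r.gene_id: r for r in records}
        assert by_gene["g2"].status == "low_expression_skipped"
        assert by_gene["g2"].fdr == 1.0
        assert by_gene["g0"].status == "tested"

    def test_small_group_rejected(self):
        counts = self._frame(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError):
            de_test(counts, {"s0": "A", "s1": "B", "s2": "B"})

    def test_non_integer_counts_rejected(self):
        counts = self._frame(np.full((3, 4), 1.5))
        with pytest.raises(ValueError):
            de_test(counts, self._labels(2, 2))

    def test_reference_group_controls_sign(self):
        rng = np.random.default_rng(5)
        arr = _nb_counts(rng, 100.0, 0.05, (20, 8))
        arr[:5, 4:] *= 8  # up in group B
        counts = self._frame(arr)
        rec_default = de_test(counts, self._labels(4, 4), reference="A")
        rec_flipped = de_test(counts, self._labels(4, 4), reference="B")
        for a, b in zip(rec_default, rec_flipped):
            assert a.log2_fc == pytest.approx(-b.log2_fc)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]).tolist() == [0.03]

    def test_hand_computed_case(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.001, 1.0, 50)
        perm = rng.permutation(50)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestHypergeomOverlap:
    def test_paper_scale_stromal_overlap(self):
        universe = [f"g{i}" for i in range(15984)]
        gene_list = universe[:1127]
        signature = universe[:20] + universe[1127 : 1127 + 117]
        res = hypergeom_overlap(gene_list, signature, universe)
        assert res.k_overlap == 20 and res.K_signature == 137
        assert res.p_upper == pytest.approx(1.48e-3, rel=0.05)

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(30)]
        res = hypergeom_overlap(universe[:10], universe[20:], universe)
        assert res.k_overlap == 0 and res.p_upper == 1.0

    def test_small_exact_case(self):
        universe = list("abcdefghij")
        gene_list = universe[:5]
        signature = universe[:3] + [universe[7]]  # K=4, k=3
        res = hypergeom_overlap(gene_list, signature, universe)
        assert res.p_upper == pytest.approx(66 / 252, abs=1e-12)

    def test_agrees_with_exhaustive_enumeration(self):
        """Upper-tail p matches brute-force enumeration of all draws, N <= 15."""
        rng = np.random.default_rng(7)
        for _ in range(8):
            N = int(rng.integers(6, 16))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = [f"g{i}" for i in range(N)]
            signature = universe[:K]
            gene_list = list(rng.choice(universe, size=n, replace=False))
            k = len(set(gene_list) & set(signature))
            total = hits = 0
            for draw in itertools.combinations(range(N), n):
                total += 1
                if sum(1 for i in draw if i < K) >= k:
                    hits += 1
            res = hypergeom_overlap(gene_list, signature, universe)
            assert res.p_upper == pytest.approx(hits / total, abs=1e-12)

    def test_complement_identity(self):
        from scipy import stats

        for N, K, n, k in [(100, 30, 20, 5), (500, 60, 100, 20)]:
            upper = float(stats.hypergeom.sf(k - 1, N, K, n))
            lower = float(stats.hypergeom.cdf(k - 1, N, K, n))
            assert upper == pytest.approx(1 - lower, abs=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap([], [], [])

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(["x"], ["a"], ["a", "b"])


class TestStromaStratify:
    scores = {"s1": -900.0, "s2": -700.0, "s3": -100.0}

    def test_all_below_cutoff(self):
        assert stroma_stratify(["s1", "s2", "s3"], self.scores, 0.0, "<") == [
            "s1", "s2", "s3"
        ]

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning):
            out = stroma_stratify(["s1"], self.scores, -1000.0, "<")
        assert out == []

    def test_boundary_excluded(self):
        assert stroma_stratify(["s1", "s2", "s3"], self.scores, -700.0, "<") == ["s1"]

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError, match="s4"):
            stroma_stratify(["s1", "s4"], self.scores, 0.0, "<")


def _deset(name, purity, sig_genes, universe, fc=3.0, fdr=1e-4, which="fdr",
           thresholds=(1.5, 0.05, "fdr")):
    records = []
    for g in universe:
        if g in sig_genes:
            records.append(DERecord(g, 100.0, fc, fdr, fdr, "tested"))
        else:
            records.append(DERecord(g, 100.0, 0.0, 0.9, 0.95, "tested"))
    return PlatformDESet(name, purity, records, thresholds)


class TestTriangulate:
    universe = [chr(ord("A") + i) for i in range(10)]

    def test_set_algebra_example(self):
        pure1 = _deset("p1", "tumor_pure", {"A", "B", "C"}, self.universe)
        pure2 = _deset("p2", "tumor_pure", {"B", "C", "D"}, self.universe)
        mixed = _deset("m1", "mixed", {"C"}, self.universe)
        consensus, masked = triangulate_markers([pure1, pure2], [mixed])
        assert consensus == {"B", "C"}
        assert masked == {"B"}

    def test_no_mixed_significance_masks_nothing(self):
        pure = _deset("p1", "tumor_pure", {"A", "B"}, self.universe)
        mixed = _deset("m1", "mixed", set(), self.universe)
        consensus, masked = triangulate_markers([pure], [mixed])
        assert masked == consensus == {"A", "B"}

    def test_containment_invariant(self):
        rng = np.random.default_rng(8)
        pures, sigs = [], []
        for i in range(3):
            sig = set(rng.choice(self.universe, size=5, replace=False))
            sigs.append(sig)
            pures.append(_deset(f"p{i}", "tumor_pure", sig, self.universe))
        mixed = _deset("m", "mixed", set(rng.choice(self.universe, 3, replace=False)),
                       self.universe)
        consensus, masked = triangulate_markers(pures, [mixed])
        assert masked <= consensus
        for sig in sigs:
            assert consensus <= sig

    def test_platform_p_dialect_honored(self):
        # cell-line style platform: p < 0.01 instead of FDR
        pure_p = _deset("cl", "tumor_pure", {"A"}, self.universe,
                        fdr=0.2, thresholds=(1.5, 0.01, "p"))
        for r in pure_p.records:
            if r.gene_id == "A":
                r.p = 0.005
        mixed = _deset("m", "mixed", set(), self.universe)
        consensus, masked = triangulate_markers([pure_p], [mixed])
        assert consensus == {"A"}

    def test_universe_mismatch_rejected(self):
        pure = _deset("p", "tumor_pure", {"A"}, self.universe)
        mixed = _deset("m", "mixed", set(), self.universe[:5])
        with pytest.raises(ValueError):
            triangulate_markers([pure], [mixed])

    def test_needs_both_platform_classes(self):
        pure = _deset("p", "tumor_pure", {"A"}, self.universe)
        with pytest.raises(ValueError):
            triangulate_markers([pure], [])
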