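"""Polygenic-score engine: harmonization, clumping, scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogslope.errors import ConsistencyError, ParameterError
from cogslope.pgs import ClumpResult, build_pgs, harmonize, ld_clump, score
from cogslope.simulate import (
    GenotypeMatrix,
    SummaryStats,
    simulate_genotypes,
    simulate_summary_stats,
    simulate_trait_architecture,
)


def make_sumstats(geno: GenotypeMatrix, betas=None, p=None, a1=None, a2=None):
    tab = geno.snps[["snp", "chrom", "pos", "a1", "a2"]].copy()
    m = len(tab)
    tab["beta"] = betas if betas is not None else np.zeros(m)
    tab["se"] = np.full(m, 0.01)
    tab["p"] = p if p is not None else np.full(m, 0.5)
    if a1 is not None:
        tab["a1"] = a1
    if a2 is not None:
        tab["a2"] = a2
    return SummaryStats(tab)


@pytest.fixture(scope="module")
def panel():
    geno = simulate_genotypes(400, 60, block_size=6, within_block_r=0.7, seed=1)
    # force unambiguous alleles so harmonization keeps everything
    geno.snps["a1"] = "A"
    geno.snps["a2"] = "C"
    return geno


class TestHarmonize:
    def test_identical_coding_keeps_betas(self, panel):
        ss = make_sumstats(panel, betas=np.arange(panel.m, dtype=float))
        harm = harmonize(ss, panel)
        assert np.allclose(harm.table["beta"], np.arange(panel.m))

    def test_swapped_alleles_flip_sign(self, panel):
        ss = make_sumstats(panel, betas=np.ones(panel.m), a1="C", a2="A")
        harm = harmonize(ss, panel)
        assert np.allclose(harm.table["beta"], -1.0)

    def test_strand_flip_resolved(self, panel):
        # T/G complements to A/C: same orientation, beta unchanged
        ss = make_sumstats(panel, betas=np.ones(panel.m), a1="T", a2="G")
        harm = harmonize(ss, panel)
        assert len(harm) == panel.m
        assert np.allclose(harm.table["beta"], 1.0)

    def test_ambiguous_snp_dropped(self, panel):
        geno = GenotypeMatrix(panel.dosage.copy(), panel.snps.copy())
        geno.snps.loc[0, ["a1", "a2"]] = ["A", "T"]
        ss = make_sumstats(geno)
        harm = harmonize(ss, geno)
        assert geno.snps.loc[0, "snp"] not in set(harm.table["snp"])
        assert len(harm) == geno.m - 1

    def test_irreconcilable_dropped_not_error(self, panel):
        ss = make_sumstats(panel, a1="G", a2="C")  # ambiguous pair -> dropped
        assert len(harmonize(ss, panel)) == 0
        ss2 = make_sumstats(panel)
        ss2.table.loc[0, ["a1", "a2"]] = ["A", "G"]  # neither match nor flip
        harm = harmonize(ss2, panel)
        assert len(harm) == panel.m - 1


class TestLdClump:
    def test_single_snp_is_its_own_index(self, panel):
        one = SummaryStats(make_sumstats(panel).table.iloc[[0]])
        res = ld_clump(one, panel)
        assert res.index_snps == [panel.snps.loc[0, "snp"]]
        assert res.removed_by == {}

    def test_perfect_ld_pair_keeps_smaller_p(self):
        dosage = np.tile(np.random.default_rng(0).integers(0, 3, size=(100, 1)), (1, 2)).astype(float)
        snps = pd.DataFrame(
            {
                "snp": ["rsA", "rsB"],
                "chrom": [1, 1],
                "pos": [1000, 2000],
                "a1": ["A", "A"],
                "a2": ["C", "C"],
                "maf": [0.3, 0.3],
            }
        )
        geno = GenotypeMatrix(dosage, snps)
        ss = make_sumstats(geno, p=np.array([1e-8, 1e-4]))
        res = ld_clump(ss, geno)
        assert res.index_snps == ["rsA"]
        assert res.removed_by == {"rsB": "rsA"}

    def test_empty_sumstats_gives_empty_result(self, panel):
        empty = SummaryStats(make_sumstats(panel).table.iloc[:0])
        res = ld_clump(empty, panel)
        assert res.index_snps == [] and res.removed_by == {}

    @staticmethod
    def brute_force(tab, geno, r2_max=0.25, window_kb=250.0):
        """Independent re-statement of the greedy rule with explicit pairwise r^2."""
        col_of = {s: i for i, s in enumerate(geno.snps["snp"])}
        m = len(tab)
        dos = geno.dosage
        snps = list(tab["snp"])
        r2 = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                if i != j:
                    r2[i, j] = np.corrcoef(dos[:, col_of[snps[i]]], dos[:, col_of[snps[j]]])[0, 1] ** 2
        order = tab.sort_values(["p", "chrom", "pos", "snp"], kind="mergesort")
        state = {s: "free" for s in snps}
        removed_by = {}
        index = []
        pos_of = dict(zip(tab["snp"], tab["pos"]))
        chrom_of = dict(zip(tab["snp"], tab["chrom"]))
        for _, row in order.iterrows():
            s = row["snp"]
            if state[s] != "free":
                continue
            state[s] = "index"
            index.append(s)
            for o in snps:
                if state[o] != "free" or chrom_of[o] != chrom_of[s]:
                    continue
                if abs(pos_of[o] - pos_of[s]) > window_kb * 1000:
                    continue
                if r2[snps.index(s), snps.index(o)] > r2_max:
                    state[o] = "removed"
                    removed_by[o] = s
        return index, removed_by

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle_on_random_panels(self, seed):
        geno = simulate_genotypes(300, 50, block_size=5, within_block_r=0.75, seed=seed)
        geno.snps["a1"], geno.snps["a2"] = "A", "C"
        rng = np.random.default_rng(100 + seed)
        ss = make_sumstats(geno, p=rng.uniform(1e-10, 1, size=50))
        res = ld_clump(ss, geno)
        oi, orm = self.brute_force(ss.table, geno)
        assert res.index_snps == oi
        assert res.removed_by == orm

    def test_retained_set_invariant_to_input_order(self, panel):
        rng = np.random.default_rng(3)
        ss = make_sumstats(panel, p=rng.uniform(size=panel.m))
        res1 = ld_clump(ss, panel)
        shuffled = SummaryStats(ss.table.sample(frac=1, random_state=1).reset_index(drop=True))
        res2 = ld_clump(shuffled, panel)
        assert res1.index_snps == res2.index_snps

    def test_invalid_parameters(self, panel):
        ss = make_sumstats(panel)
        with pytest.raises(ParameterError):
            ld_clump(ss, panel, r2_max=0.0)
        with pytest.raises(ParameterError):
            ld_clump(ss, panel, window_kb=0)


class TestScore:
    def test_zero_betas_give_zero_scores(self, panel):
        ss = make_sumstats(panel)
        clump = ld_clump(ss, panel)
        vec = score(panel, ss, clump, 1.0)
        assert np.allclose(vec.scores, 0.0)

    def test_single_snp_arithmetic(self):
        dosage = np.array([[0.0], [1.0], [2.0]])
        snps = pd.DataFrame(
            {"snp": ["rs1"], "chrom": [1], "pos": [100], "a1": ["A"], "a2": ["C"], "maf": [0.3]}
        )
        geno = GenotypeMatrix(dosage, snps)
        ss = make_sumstats(geno, betas=np.array([0.5]), p=np.array([0.001]))
        vec = score(geno, ss, ClumpResult(["rs1"]), 1.0)
        assert np.allclose(vec.scores, [0.0, 0.5, 1.0])

    def test_matches_dense_matrix_product_oracle(self, panel):
        rng = np.random.default_rng(4)
        betas = rng.normal(size=panel.m)
        ss = make_sumstats(panel, betas=betas, p=rng.uniform(size=panel.m))
        keep = list(panel.snps["snp"].iloc[:20])
        vec = score(panel, ss, ClumpResult(keep), 1.0)
        cols = [list(panel.snps["snp"]).index(s) for s in keep]
        expected = panel.dosage[:, cols] @ betas[cols]
        assert np.allclose(vec.scores, expected)

    def test_unknown_snp_in_clump_rejected(self, panel):
        ss = make_sumstats(panel)
        with pytest.raises(ConsistencyError):
            score(panel, ss, ClumpResult(["rs_missing"]), 1.0)

    @given(a=st.floats(min_value=-5, max_value=5, allow_nan=False))
    @settings(max_examples=20, deadline=None)
    def test_scoring_is_linear_in_betas(self, a):
        geno = simulate_genotypes(50, 10, within_block_r=0.0, seed=6)
        geno.snps["a1"], geno.snps["a2"] = "A", "C"
        rng = np.random.default_rng(7)
        betas = rng.normal(size=10)
        clump = ClumpResult(list(geno.snps["snp"]))
        base = score(geno, make_sumstats(geno, betas=betas, p=np.full(10, 0.01)), clump, 1.0)
        scaled = score(geno, make_sumstats(geno, betas=a * betas, p=np.full(10, 0.01)), clump, 1.0)
        assert np.allclose(scaled.scores, a * base.scores, atol=1e-10)

    def test_lower_threshold_never_more_snps(self, panel):
        rng = np.random.default_rng(8)
        ss = make_sumstats(panel, betas=rng.normal(size=panel.m), p=rng.uniform(size=panel.m))
        clump = ld_clump(ss, panel)
        counts = [
            score(panel, ss, clump, thr).n_snps_used for thr in (1.0, 0.5, 0.1, 0.01, 1e-4)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_strict_threshold_tracks_large_effect_locus(self):
        """A p=0.01 score concentrates on a genuine large-effect locus more
        than the all-SNP score does."""
        geno = simulate_genotypes(2000, 200, within_block_r=0.2, seed=9)
        geno.snps["a1"], geno.snps["a2"] = "A", "C"
        true = np.zeros(200)
        true[57] = 0.4  # one large-effect SNP
        ss = simulate_summary_stats(geno, true, gwas_n=5_000, seed=10)
        strict = build_pgs(geno, ss, p_threshold=0.01)
        loose = build_pgs(geno, ss, p_threshold=1.0)
        locus = geno.dosage[:, 57]
        r_strict = abs(np.corrcoef(strict.scores, locus)[0, 1])
        r_loose = abs(np.corrcoef(loose.scores, locus)[0, 1])
        assert r_strict > r_loose
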