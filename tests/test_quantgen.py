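import numpy as np
import pandas as pd
import pytest

import introlink as il


def expression_fixture(n_genes=60, n_strains=8, seed=0, intro_frac=0.3):
    rng = np.random.default_rng(seed)
    counts = rng.integers(40, 4000, size=(n_genes, n_strains))
    genes = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(n_genes)],
            "chrom": "C",
            "start": np.arange(n_genes) * 2000 + 1,
            "end": np.arange(n_genes) * 2000 + 1500,
            "introgressed": rng.random(n_genes) < intro_frac,
        }
    )
    return il.ExpressionMatrix(
        counts=pd.DataFrame(
            counts, index=genes["gene"], columns=[f"s{j}" for j in range(n_strains)]
        ),
        genes=genes,
    )


class TestFitnessRatio:
    def test_basic_ratios(self):
        test = pd.DataFrame({"r1": [400.0]}, index=["s1"])
        ref = pd.DataFrame({"r1": [800.0]}, index=["s1"])
        assert il.fitness_ratio(test, ref)["s1"] == 0.5

    def test_equal_sizes_give_one(self):
        x = pd.DataFrame(np.full((3, 4), 555.0), index=list("abc"))
        assert (il.fitness_ratio(x, x) == 1.0).all()

    def test_mean_of_ratios_across_replicates(self):
        test = pd.DataFrame({"r1": [400.0], "r2": [600.0]}, index=["s1"])
        ref = pd.DataFrame({"r1": [800.0], "r2": [800.0]}, index=["s1"])
        # independent computation: mean of per-replicate ratios
        expected = np.mean([400 / 800, 600 / 800])
        assert il.fitness_ratio(test, ref)["s1"] == pytest.approx(expected)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        test = pd.DataFrame(rng.uniform(100, 900, (5, 4)))
        ref = pd.DataFrame(rng.uniform(100, 900, (5, 4)))
        a = il.fitness_ratio(test, ref)
        b = il.fitness_ratio(test * 7.3, ref * 7.3)
        pd.testing.assert_series_equal(a, b)

    def test_zero_reference_gives_na(self):
        test = pd.DataFrame({"r1": [400.0], "r2": [500.0]}, index=["s1"])
        ref = pd.DataFrame({"r1": [0.0], "r2": [1000.0]}, index=["s1"])
        assert il.fitness_ratio(test, ref)["s1"] == pytest.approx(0.5)
        ref_all_zero = pd.DataFrame({"r1": [0.0], "r2": [0.0]}, index=["s1"])
        assert np.isnan(il.fitness_ratio(test, ref_all_zero)["s1"])

    def test_raw_reference_condition(self):
        test = pd.DataFrame({"r1": [400.0], "r2": [600.0]}, index=["s1"])
        ref = pd.DataFrame({"r1": [1.0], "r2": [1.0]}, index=["s1"])
        assert il.fitness_ratio(test, ref, raw_reference=True)["s1"] == 500.0


class TestNormalizeCounts:
    def test_identical_libraries_unit_factors(self):
        em = expression_fixture()
        em.counts.loc[:, :] = np.tile(em.counts.iloc[:, [0]].to_numpy(), (1, 8))
        _, sf = il.normalize_counts(em)
        assert np.allclose(sf.to_numpy(), 1.0)

    def test_scaled_library_recovers_factor_ratio(self):
        """Doubling one library with no differential genes doubles its size
        factor relative to the others (the absolute factors carry the
        geometric-mean reference scale)."""
        em = expression_fixture()
        base = em.counts.iloc[:, 0]
        for j in range(em.counts.shape[1]):
            em.counts.iloc[:, j] = base
        em.counts.iloc[:, 3] = (base * 2).astype(int)
        _, sf = il.normalize_counts(em)
        ratio = sf.iloc[:, 3] / sf.iloc[:, 0]
        assert np.allclose(ratio, 2.0, rtol=1e-9)

    def test_invariant_under_global_scaling(self):
        """Scaling every library by the same constant rescales the pseudo-
        reference identically, leaving median-of-ratios factors unchanged."""
        em = expression_fixture(seed=2)
        sf1 = il.size_factors(em)
        em2 = il.ExpressionMatrix(em.counts * 3, em.genes)
        sf2 = il.size_factors(em2)
        assert np.allclose(sf2.to_numpy(), sf1.to_numpy())

    def test_low_count_filter(self):
        em = expression_fixture()
        em.counts.iloc[0, :] = 31  # below threshold in every sample
        em.counts.iloc[1, :] = 31
        em.counts.iloc[1, 4] = 32  # crosses threshold once -> kept
        log2, _ = il.normalize_counts(em)
        assert "g0" not in log2.index
        assert "g1" in log2.index

    def test_matches_deseq2_size_factors(self):
        """Independent oracle: pydeseq2's median-of-ratios normalization."""
        from pydeseq2.preprocessing import deseq2_norm

        em = expression_fixture(seed=3, intro_frac=0.0)
        sf_ours = il.size_factors(em, split_introgression=False).loc["all"]
        _, sf_ref = deseq2_norm(em.counts.T)  # pydeseq2 is samples x genes
        np.testing.assert_allclose(sf_ours.to_numpy(), np.asarray(sf_ref), rtol=1e-10)

    def test_constant_gc_bias_shifts_introgressed_set_under_joint(self, f1_small, small_genome):
        """A constant 2x quantification bias on introgressed genes shows up
        as a ~1 log2 set-level shift when factors come from the whole
        transcriptome (the introgressed minority cannot move the joint
        factors)."""
        gm, _ = f1_small
        genes = il.default_genes(small_genome, n_genes=300, seed=4)
        assert genes["introgressed"].sum() > 20
        base = np.full(300, 8.0)
        em, _ = il.simulate_expression(
            gm, genes, baseline_log2=base, gc_bias_factor=2.0,
            library_sizes=np.ones(gm.n_strains), seed=5,
        )
        intro = genes["introgressed"].to_numpy()
        log2e, _ = il.normalize_counts(em, split_introgression=False)
        keep_intro = log2e.index.isin(genes.loc[intro, "gene"])
        shift = (
            log2e.loc[keep_intro].mean(axis=None)
            - log2e.loc[~keep_intro].mean(axis=None)
        )
        assert abs(shift - 1.0) < 0.15

    def test_split_normalization_removes_sample_varying_gc_bias(self, f1_small, small_genome):
        """Paired runs with a per-sample GC bias: joint normalization leaves
        introgressed gene profiles tracking the bias across samples, split
        normalization absorbs it into the set's own size factors."""
        gm, _ = f1_small
        rng = np.random.default_rng(13)
        genes = il.default_genes(small_genome, n_genes=300, seed=4)
        base = np.full(300, 8.0)
        gc = 2.0 ** rng.uniform(-1, 1, size=gm.n_strains)
        em, _ = il.simulate_expression(
            gm, genes, baseline_log2=base, gc_bias_factor=gc,
            library_sizes=np.ones(gm.n_strains), seed=5,
        )
        intro_genes = genes.loc[genes["introgressed"].to_numpy(), "gene"]
        log_gc = np.log2(gc)
        residual_corr = {}
        for split in (False, True):
            log2e, _ = il.normalize_counts(em, split_introgression=split)
            block = log2e.loc[log2e.index.isin(intro_genes)]
            corrs = [
                np.corrcoef(row, log_gc)[0, 1] for _, row in block.iterrows()
            ]
            residual_corr[split] = np.nanmean(np.abs(corrs))
        assert residual_corr[False] > 0.8  # joint: profiles track the bias
        assert residual_corr[True] < 0.3  # split: bias absorbed


class TestHeritability:
    @staticmethod
    def group_with_variance(var, n=2, center=10.0):
        d = np.sqrt(var / 2)
        return np.array([center - d, center + d] + [center] * (n - 2))

    def test_arithmetic_example(self):
        """noise groups with variances (0.5, 0.3, 0.4) and total variance 2.0
        give noise 0.4 and H^2 = 0.8; verified against a direct independent
        variance computation."""
        groups = [self.group_with_variance(v) for v in (0.5, 0.3, 0.4)]
        seg = np.array([0.0, 2.0, 4.0])  # sample variance 4.0
        seg = (seg - seg.mean()) / np.sqrt(np.var(seg, ddof=1)) * np.sqrt(2.0)
        assert np.var(seg, ddof=1) == pytest.approx(2.0)
        est = il.broad_sense_heritability(seg, groups)
        assert est.noise_variance == pytest.approx(np.mean([0.5, 0.3, 0.4]))
        assert est.h2 == pytest.approx(1 - 0.4 / 2.0)

    def test_zero_noise_gives_one(self):
        est = il.broad_sense_heritability(
            np.array([1.0, 2.0, 3.0]), [np.array([5.0, 5.0])]
        )
        assert est.h2 == 1.0

    def test_noise_equal_total_gives_zero(self):
        seg = np.array([9.0, 10.0, 11.0])
        est = il.broad_sense_heritability(
            seg, [self.group_with_variance(np.var(seg, ddof=1))]
        )
        assert est.h2 == pytest.approx(0.0)

    def test_clipping_keeps_raw_value(self):
        seg = np.array([9.9, 10.0, 10.1])
        est = il.broad_sense_heritability(seg, [self.group_with_variance(5.0)])
        assert est.h2 == 0.0 and est.h2_raw < 0

    def test_zero_total_variance_flagged(self):
        est = il.broad_sense_heritability(
            np.array([1.0, 1.0, 1.0]), [np.array([1.0, 2.0])]
        )
        assert est.flagged and np.isnan(est.h2)

    def test_fitness_heritability_pipeline(self, f1_small):
        gm, _ = f1_small
        spec = il.make_qtl_spec([("t", "1", 250_000, 0.4)])
        table, _ = il.simulate_phenotypes(gm, spec, noise_sd=0.1, seed=6)
        h2 = il.fitness_heritability(table)
        assert 0.5 < h2.loc[h2["trait"] == "t", "h2"].iloc[0] <= 1.0

    def test_expression_heritability_uses_replicate_noise(self, f1_small, small_genome):
        gm, _ = f1_small
        genes = il.default_genes(small_genome, n_genes=80, seed=7)
        base = np.full(80, 8.0)
        spec = il.make_eqtl_spec(genes, gm.markers, n_local=20, seed=8)
        em, _ = il.simulate_expression(gm, genes, spec, baseline_log2=base, seed=9)
        log2e, _ = il.normalize_counts(em)
        reps = il.simulate_expression_replicates(genes, base, n_replicates=24, seed=10)
        log2r = np.log2(reps + 1)
        h2 = il.expression_heritability(log2e, log2r)
        spec_genes = set(spec["gene"])
        with_eqtl = h2[h2["gene"].isin(spec_genes)]["h2"]
        without = h2[~h2["gene"].isin(spec_genes)]["h2"]
        assert with_eqtl.median() > without.median()


class TestTraitProjection:
    def test_rank_one_matrix(self):
        u = np.array([1.0, -1.0, 2.0, 0.5])
        v = np.array([1.0, 2.0, 3.0])
        m = pd.DataFrame(np.outer(u, v))
        coords, frac = il.trait_projection(m)
        assert frac[0] == pytest.approx(1.0)

    def test_invariant_to_strain_order(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(size=(10, 6)), index=[f"s{i}" for i in range(10)])
        coords, _ = il.trait_projection(m)
        perm = rng.permutation(10)
        coords_p, _ = il.trait_projection(m.iloc[perm])
        np.testing.assert_allclose(
            coords_p.loc[coords.index].to_numpy(), coords.to_numpy(), atol=1e-8
        )

    def test_single_strain_rejected(self):
        with pytest.raises(ValueError, match="2 strains"):
            il.trait_projection(pd.DataFrame([[1.0, 2.0]]))

    def test_mating_type_separates_with_introgression_linked_traits(self, f1_small, small_genome):
        """Many traits driven by loci inside the nonrecombining interval make
        MATa and MATalpha strains separable in the leading components."""
        gm, _ = f1_small
        rows = [(f"t{k}", "2", 50_000 + 7_000 * k, 0.6) for k in range(12)]
        table, _ = il.simulate_phenotypes(
            gm, il.make_qtl_spec(rows), noise_sd=0.1, seed=12
        )
        matrix = il.segregant_trait_matrix(table)
        coords, _ = il.trait_projection(matrix, n_components=4)
        mat = pd.Series(gm.mating_types, index=gm.strains).loc[coords.index]
        separated = False
        for pc in coords.columns:
            a = coords.loc[(mat == "a").to_numpy(), pc]
            b = coords.loc[(mat == "alpha").to_numpy(), pc]
            if a.max() < b.min() or b.max() < a.min():
                separated = True
        assert separated
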