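import itertools

import numpy as np
import pandas as pd
import pytest

import introlink as il
from introlink.genome import NA, P1, P2
from introlink.linkage import haldane_r


def probs_from_array(p, chrom="1", positions=None):
    p = np.asarray(p, dtype=float)
    n, L = p.shape
    if positions is None:
        positions = np.arange(1, L + 1) * 1000
    loci = pd.DataFrame({"chrom": chrom, "pos": positions})
    return il.GenotypeProbabilities(
        strains=[f"s{i}" for i in range(n)], loci=loci, p=p, eps=0.0
    )


def brute_force_conditional(calls, positions, cm_per_kb):
    """Exact conditional P(locus = P1 | all observed loci) by enumeration of
    the full hidden Markov chain over one chromosome."""
    L = len(calls)
    rs = haldane_r(np.diff(positions), cm_per_kb)
    states = []
    weights = []
    for hidden in itertools.product([P1, P2], repeat=L):
        ok = all(c == NA or h == c for h, c in zip(hidden, calls))
        if not ok:
            continue
        w = 0.5
        for k in range(L - 1):
            w *= rs[k] if hidden[k] != hidden[k + 1] else 1 - rs[k]
        states.append(hidden)
        weights.append(w)
    weights = np.array(weights)
    weights /= weights.sum()
    return np.array(
        [sum(w for s, w in zip(states, weights) if s[j] == P1) for j in range(L)]
    )


class TestGenotypeProbabilities:
    def build(self, calls, positions, genome=None, cm_per_kb=0.12, eps=0.0):
        positions = np.asarray(positions)
        ms = il.MarkerSet(
            pd.DataFrame(
                {
                    "chrom": "1",
                    "pos": positions,
                    "p1_allele": "A",
                    "p2_allele": "C",
                    "coding": True,
                }
            )
        )
        gm = il.GenotypeMatrix(
            strains=["s0"], markers=ms, calls=np.array([calls], dtype=np.int8)
        )
        genome = genome or il.GenomeMap(chromosomes=[("1", int(positions[-1]) + 1000)])
        return il.genotype_probabilities(gm, genome, cm_per_kb=cm_per_kb, eps=eps)

    def test_observed_loci_get_one_minus_eps(self):
        probs = self.build([P1, P2], [1000, 2000], eps=0.001)
        assert probs.p[0, 0] == pytest.approx(0.999)
        assert probs.p[0, 1] == pytest.approx(0.001)

    def test_midway_na_between_opposite_flanks_is_half(self):
        probs = self.build([P1, NA, P2], [1000, 51000, 101000])
        assert probs.p[0, 1] == pytest.approx(0.5)

    def test_na_between_close_p1_flanks_tends_to_one(self):
        probs = self.build([P1, NA, P1], [1000, 1010, 1020])
        assert probs.p[0, 1] > 0.999999

    def test_chromosome_end_uses_single_flank(self):
        probs = self.build([NA, P1], [1000, 2000])
        r = haldane_r(np.array([1000.0]), 0.12)[0]
        assert probs.p[0, 0] == pytest.approx(1 - r)

    def test_uninformative_chromosome_gets_half(self):
        probs = self.build([NA, NA], [1000, 2000])
        np.testing.assert_allclose(probs.p[0], 0.5)

    def test_matches_brute_force_enumeration(self):
        """Exhaustive oracle on random small chains, equal within 1e-12."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            L = int(rng.integers(3, 8))
            positions = np.sort(rng.choice(np.arange(1, 300) * 1000, L, replace=False))
            calls = rng.choice([NA, P1, P2], size=L, p=[0.4, 0.3, 0.3])
            if (calls != NA).sum() == 0:
                continue
            probs = self.build(list(calls), positions, cm_per_kb=0.3)
            expected = brute_force_conditional(calls, positions, 0.3)
            np.testing.assert_allclose(probs.p[0], expected, atol=1e-12)


class TestHKScan:
    def test_worked_four_strain_example(self):
        """p = (0,0,1,1), y = (1,2,3,4): RSS0 = 5, RSS1 = 1,
        LOD = 2 log10 5 ~ 1.3979; variance explained 0.8 both ways."""
        probs = probs_from_array([[0.0], [0.0], [1.0], [1.0]])
        scan = il.hk_scan(probs, np.array([1.0, 2.0, 3.0, 4.0]))
        assert scan.lod[0] == pytest.approx(2 * np.log10(5.0), abs=1e-12)
        ve = il.variance_explained(scan.lod[0], 4)
        assert ve == pytest.approx(0.8, abs=1e-12)
        assert ve == pytest.approx(1 - 1.0 / 5.0, abs=1e-12)  # 1 - RSS1/RSS0

    def test_constant_trait_gives_zero_everywhere(self, default_cross):
        *_, probs = default_cross
        scan = il.hk_scan(probs, np.full(180, 3.3))
        np.testing.assert_allclose(scan.lod, 0.0)

    def test_constant_probability_locus_gives_zero(self):
        probs = probs_from_array([[0.5, 0.0], [0.5, 0.0], [0.5, 1.0], [0.5, 1.0]])
        scan = il.hk_scan(probs, np.array([1.0, 2.0, 3.0, 4.0]))
        assert scan.lod[0] == 0.0
        assert scan.lod[1] > 0

    def test_agrees_with_least_squares_oracle(self):
        """Independent OLS route (numpy lstsq residuals) on random small
        instances, within 1e-10."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(4, 12))
            L = int(rng.integers(1, 6))
            p = rng.random((n, L))
            y = rng.normal(size=n)
            probs = probs_from_array(p)
            lod = il.hk_scan(probs, y).lod
            yc = y - y.mean()
            rss0 = float(yc @ yc)
            for j in range(L):
                X = np.column_stack([np.ones(n), p[:, j]])
                res = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
                rss1 = float(res @ res)
                expected = max((n / 2) * np.log10(rss0 / rss1), 0.0)
                assert abs(lod[j] - expected) < 1e-10

    def test_missing_trait_values_dropped_scanwide(self, default_cross):
        *_, probs = default_cross
        rng = np.random.default_rng(5)
        y = rng.normal(size=180)
        y[:30] = np.nan
        scan = il.hk_scan(probs, y)
        assert scan.n == 150

    def test_indicator_trait_peaks_at_causal_locus(self, default_cross):
        genome, _, _, _, pseudo, probs = default_cross
        rng = np.random.default_rng(8)
        for j in [50, 700, 2000]:
            y = (pseudo.calls[:, j] == P1).astype(float)
            y[pseudo.calls[:, j] == NA] = 0.5
            scan = il.hk_scan(probs, y)
            jmax = int(np.argmax(scan.lod))
            same = probs.loci.iloc[jmax]["chrom"] == probs.loci.iloc[j]["chrom"]
            # accept any locus in near-perfect LD with the causal one
            r = np.corrcoef(probs.p[:, jmax], probs.p[:, j])[0, 1]
            assert same and abs(r) > 0.95

    def test_cold_region_loci_share_identical_lod(self, default_cross):
        genome, _, _, _, _, probs = default_cross
        cold = genome.nonrecombining[0]
        mask = (
            (probs.loci["chrom"] == cold.chrom)
            & (probs.loci["pos"] >= cold.start)
            & (probs.loci["pos"] <= cold.end)
        ).to_numpy()
        rng = np.random.default_rng(9)
        scan = il.hk_scan(probs, rng.normal(size=180))
        lods = scan.lod[mask]
        np.testing.assert_allclose(lods, lods[0], atol=1e-9)


class TestPermutationThreshold:
    def test_seed_reproducibility(self, default_cross):
        *_, probs = default_cross
        y = np.random.default_rng(1).normal(size=180)
        t1 = il.permutation_threshold(probs, y, n_perm=200, seed=4)
        t2 = il.permutation_threshold(probs, y, n_perm=200, seed=4)
        t3 = il.permutation_threshold(probs, y, n_perm=200, seed=5)
        assert t1 == t2
        assert t1 != t3

    def test_monotone_in_alpha(self, default_cross):
        *_, probs = default_cross
        y = np.random.default_rng(2).normal(size=180)
        strict = il.permutation_threshold(probs, y, n_perm=400, alpha=0.05, seed=6)
        loose = il.permutation_threshold(probs, y, n_perm=400, alpha=0.20, seed=6)
        assert strict >= loose

    def test_too_few_permutations_rejected(self, default_cross):
        *_, probs = default_cross
        with pytest.raises(ValueError, match="n_perm"):
            il.permutation_threshold(probs, np.zeros(180), n_perm=5)


class TestCallQTL:
    def test_empty_when_below_threshold(self, default_cross):
        *_, probs = default_cross
        scan = il.hk_scan(probs, np.random.default_rng(3).normal(size=180))
        assert il.call_qtl(scan, threshold=scan.lod.max() + 1) == []

    def test_support_contains_peak_and_ve_identity(self, default_cross):
        genome, _, _, _, pseudo, probs = default_cross
        rng = np.random.default_rng(4)
        j = 1800
        y = (pseudo.calls[:, j] == P1).astype(float) + rng.normal(0, 0.3, 180)
        scan = il.hk_scan(probs, y)
        calls = il.call_qtl(scan, threshold=3.0, genome=genome)
        assert calls
        for c in calls:
            assert c.support.start <= c.peak_pos <= c.support.end
            assert 0 <= c.var_explained <= 1

    def test_cold_region_peak_reported_at_region_midpoint(self, default_cross):
        genome, _, f1, _, pseudo, probs = default_cross
        cold = genome.nonrecombining[0]
        mat = (np.asarray(f1.mating_types) == "a").astype(float)
        y = mat + np.random.default_rng(5).normal(0, 0.2, 180)
        scan = il.hk_scan(probs, y)
        calls = [
            c
            for c in il.call_qtl(scan, 3.0, genome=genome)
            if cold.contains(c.chrom, c.peak_pos)
        ]
        assert len(calls) == 1
        assert calls[0].peak_pos == (cold.start + cold.end) // 2
        assert (calls[0].support.start, calls[0].support.end) == (cold.start, cold.end)
        assert calls[0].peak_lod == scan.lod[
            (probs.loci["chrom"] == cold.chrom).to_numpy()
        ].max()


class TestEQTL:
    def test_single_gene_reduces_to_hk_scan(self, default_cross):
        *_, probs = default_cross
        rng = np.random.default_rng(6)
        y = rng.normal(size=180)
        expr = pd.DataFrame([y], index=["g"], columns=probs.strains)
        genes, lod = il.eqtl_scan_all(probs, expr)
        np.testing.assert_allclose(lod[0], il.hk_scan(probs, y).lod, atol=1e-10)

    def test_duplicated_genes_get_identical_curves(self, default_cross):
        *_, probs = default_cross
        rng = np.random.default_rng(7)
        y = rng.normal(size=180)
        expr = pd.DataFrame([y, y], index=["g1", "g2"], columns=probs.strains)
        _, lod = il.eqtl_scan_all(probs, expr)
        np.testing.assert_array_equal(lod[0], lod[1])

    def test_fdr_counts_monotone_and_deterministic(self, default_cross):
        *_, probs = default_cross
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(
            rng.normal(size=(100, 180)),
            index=[f"g{i}" for i in range(100)],
            columns=probs.strains,
        )
        grid = [2.0, 2.5, 3.0, 3.5, 4.0]
        a = il.eqtl_fdr(probs, expr, grid, n_perm=20, seed=9)
        b = il.eqtl_fdr(probs, expr, grid, n_perm=20, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)
        obs = a.table["observed"].to_numpy()
        false = a.table["mean_false"].to_numpy()
        assert (np.diff(obs) <= 0).all()
        assert (np.diff(false) <= 0).all()

    def test_fdr_arithmetic(self, default_cross):
        """FDR(t) is mean false count over permutations divided by observed
        count (e.g. 100 observed with mean 4 false -> 4%)."""
        *_, probs = default_cross
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(
            rng.normal(size=(50, 180)),
            index=[f"g{i}" for i in range(50)],
            columns=probs.strains,
        )
        curve = il.eqtl_fdr(probs, expr, [2.0, 3.0], n_perm=10, seed=11)
        row = curve.table.iloc[0]
        if row["observed"] > 0:
            assert row["fdr"] == pytest.approx(row["mean_false"] / row["observed"])
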