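"""Polygenic risk scores: threshold grid, clumping, scoring, Delta R^2 and
permutation correction of the threshold scan."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

import genconn as g
from genconn.datatypes import GenotypeTable, SummaryStats


def _genotypes(dosages, alleles=None):
    dosages = np.atleast_2d(np.asarray(dosages, float))
    n, p = dosages.shape
    snps = [f"rs{i}" for i in range(p)]
    meta = pd.DataFrame({
        "effect_allele": alleles or ["A"] * p,
        "phenotype": ["schizophrenia"] * p,
        "phenotype_group": ["psychiatric"] * p,
        "gwas_p": [1e-9] * p,
    }, index=pd.Index(snps, name="snp_id"))
    df = pd.DataFrame(dosages, columns=snps,
                      index=[f"s{i}" for i in range(n)])
    return GenotypeTable(dosages=df, snp_meta=meta)


def _sumstats(betas, ps, alleles=None):
    p = len(betas)
    return SummaryStats(table=pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(p)],
        "effect_allele": alleles or ["A"] * p,
        "beta": betas, "p": ps}))


class TestThresholdGrid:
    def test_full_grid_start_and_step(self):
        grid = g.build_threshold_grid(1.0)
        assert grid[0] == 5e-8
        assert grid[1] == pytest.approx(5.005e-5)
        # constant 5e-5 step except the appended upper bound
        assert np.allclose(np.diff(grid[1:-1]), 5e-5)
        assert grid[-1] == 1.0

    def test_degenerate_upper_bounds(self):
        assert list(g.build_threshold_grid(5e-8)) == [5e-8]
        assert list(g.build_threshold_grid(1e-9)) == [1e-9]

    def test_enumerated_small_grid(self):
        grid = g.build_threshold_grid(1.3e-4)
        assert np.allclose(grid, [5e-8, 5.005e-5, 1.0005e-4, 1.3e-4])

    @given(st.floats(min_value=1e-7, max_value=1.0))
    def test_grid_properties(self, upper):
        grid = g.build_threshold_grid(upper)
        assert np.all(np.diff(grid) > 0)
        assert grid[-1] == pytest.approx(upper, rel=1e-12)
        assert grid[0] == 5e-8


class TestClump:
    def test_no_ld_table_is_identity(self):
        ss = _sumstats([0.1, 0.2], [1e-8, 1e-4])
        out = g.clump(ss, ld=None)
        pd.testing.assert_frame_equal(out.table, ss.table)

    def test_correlated_pair_keeps_smaller_p(self):
        ss = _sumstats([0.1, 0.2], [1e-8, 1e-4])
        ld = pd.DataFrame({"index_snp_id": ["rs0"],
                           "proxy_snp_id": ["rs1"],
                           "r_squared": [0.5]})
        out = g.clump(ss, ld=ld, r2=0.1)
        assert list(out.table["snp_id"]) == ["rs0"]

    def test_block_ld_keeps_one_snp_per_block(self):
        n_blocks, k = 5, 4
        ids = [f"rs{i}" for i in range(n_blocks * k)]
        rows = []
        for b in range(n_blocks):
            members = ids[b * k:(b + 1) * k]
            for i, a in enumerate(members):
                for c in members[i + 1:]:
                    rows.append((a, c, 0.9))
        ld = pd.DataFrame(rows, columns=["index_snp_id", "proxy_snp_id",
                                         "r_squared"])
        rng = np.random.default_rng(0)
        ss = _sumstats(rng.normal(size=len(ids)), rng.uniform(size=len(ids)))
        out = g.clump(ss, ld=ld, r2=0.1)
        assert len(out.table) == n_blocks


class TestScorePrs:
    def test_single_snp_scores(self):
        geno = _genotypes([[0], [1], [2]])
        ss = _sumstats([0.5], [1e-9])
        s = g.score_prs(geno, ss, 5e-8)
        assert list(s) == [0.0, 0.5, 1.0]

    def test_three_snp_hand_sum(self):
        geno = _genotypes([[2, 1, 0]])
        ss = _sumstats([0.2, -0.1, 0.4], [1e-9, 1e-9, 1e-9])
        s = g.score_prs(geno, ss, 5e-8)
        assert s.iloc[0] == pytest.approx(0.3)

    def test_threshold_excludes_all_gives_zeros(self):
        geno = _genotypes([[2, 1]])
        ss = _sumstats([0.2, 0.3], [0.5, 0.9])
        s = g.score_prs(geno, ss, 1e-8)
        assert (s == 0).all()

    def test_threshold_inclusive(self):
        geno = _genotypes([[1]])
        ss = _sumstats([0.5], [0.05])
        assert g.score_prs(geno, ss, 0.05).iloc[0] == pytest.approx(0.5)

    def test_allele_mismatch_dropped(self):
        geno = _genotypes([[2, 2]], alleles=["A", "A"])
        ss = _sumstats([0.5, 0.5], [1e-9, 1e-9], alleles=["A", "G"])
        s = g.score_prs(geno, ss, 1.0)
        assert s.iloc[0] == pytest.approx(1.0)  # only rs0 scored

    def test_missing_dosage_imputed_with_twice_maf(self):
        geno = _genotypes([[0.0], [2.0], [np.nan]])
        ss = _sumstats([1.0], [1e-9])
        s = g.score_prs(geno, ss, 1.0)
        assert s.iloc[2] == pytest.approx(1.0)  # 2 * MAF = mean dosage = 1

    def test_additive_over_disjoint_sets_and_beta_scaling(self, rng):
        D = rng.integers(0, 3, size=(20, 6)).astype(float)
        betas = rng.normal(size=6)
        ps = np.full(6, 1e-9)
        geno = _genotypes(D)
        total = g.score_prs(geno, _sumstats(betas, ps), 1.0)
        part1 = betas.copy(); part1[3:] = 0.0
        part2 = betas.copy(); part2[:3] = 0.0
        s1 = g.score_prs(geno, _sumstats(part1, ps), 1.0)
        s2 = g.score_prs(geno, _sumstats(part2, ps), 1.0)
        assert np.allclose(total, s1 + s2)
        scaled = g.score_prs(geno, _sumstats(3.0 * betas, ps), 1.0)
        assert np.allclose(scaled, 3.0 * total)


class TestDeltaR2:
    def test_target_equal_to_prs_no_covariates(self, rng):
        s = rng.standard_normal(50)
        d, p = g.delta_r2(s, s, None)
        assert d == pytest.approx(1.0)
        assert p < 1e-30

    def test_orthogonal_prs_explains_nothing(self, rng):
        y = rng.standard_normal(2000)
        s = rng.standard_normal(2000)
        gafs = pd.DataFrame({"gaf1": rng.standard_normal(2000)})
        d, p = g.delta_r2(y, s, gafs)
        assert d < 0.01

    def test_matches_statsmodels(self, rng):
        n = 100
        y = rng.standard_normal(n)
        s = rng.standard_normal(n)
        gafs = pd.DataFrame({"gaf1": rng.standard_normal(n),
                             "gaf2": rng.standard_normal(n)})
        d, p = g.delta_r2(y, s, gafs)
        Xf = sm.add_constant(np.column_stack([gafs, s]))
        Xn = sm.add_constant(gafs.to_numpy())
        full = sm.OLS(y, Xf).fit()
        null = sm.OLS(y, Xn).fit()
        assert d == pytest.approx(full.rsquared - null.rsquared, abs=1e-10)
        assert p == pytest.approx(full.pvalues[-1], abs=1e-10)

    def test_invariant_to_affine_gaf_transform(self, rng):
        n = 150
        y = rng.standard_normal(n)
        s = rng.standard_normal(n)
        gafs = pd.DataFrame({"gaf1": rng.standard_normal(n)})
        d1, _ = g.delta_r2(y, s, gafs)
        d2, _ = g.delta_r2(y, s, 5.0 * gafs + 2.0)
        assert d1 == pytest.approx(d2, abs=1e-10)

    def test_collinear_prs_rejected(self, rng):
        n = 50
        gafs = pd.DataFrame({"gaf1": rng.standard_normal(n)})
        with pytest.raises(ValueError, match="collinear"):
            g.delta_r2(rng.standard_normal(n), gafs["gaf1"] * 2.0, gafs)


class TestPermutationCorrect:
    def _planted(self, rng, n=150, p=30):
        D = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        betas = np.zeros(p); betas[:5] = 0.5
        ps = np.concatenate([np.full(5, 1e-10), rng.uniform(0.1, 1, p - 5)])
        geno = _genotypes(D)
        ss = _sumstats(betas, ps)
        target = g.score_prs(geno, ss, 5e-8).to_numpy()
        target = (target - target.mean()) / target.std()
        return geno, ss, target

    def test_strong_association_attains_floor(self, rng):
        geno, ss, target = self._planted(rng)
        grid = g.build_threshold_grid(0.5)
        cp, best_thr, best_p = g.permutation_correct(
            target, geno, ss, None, grid, B=99, seed=3)
        assert cp == 0.01
        assert best_p < 1e-20

    def test_single_threshold_matches_plain_permutation_test(self, rng):
        geno, ss, _ = self._planted(rng)
        y = rng.standard_normal(150)  # null target
        grid = [0.5]
        cp, _, _ = g.permutation_correct(y, geno, ss, None, grid,
                                         B=199, seed=11)
        # independent oracle: plain permutation test of |corr| at the
        # single threshold, replaying the same permutation stream
        s = g.score_prs(geno, ss, 0.5).to_numpy()
        sz = (s - s.mean()) / np.linalg.norm(s - s.mean())
        yz = (y - y.mean()) / np.linalg.norm(y - y.mean())
        obs = abs(sz @ yz)
        rng2 = np.random.default_rng(11)
        exceed = sum(
            abs(sz @ ((yp := y[rng2.permutation(150)]) - yp.mean())
                / np.linalg.norm(yp - yp.mean())) >= obs - 1e-15
            for _ in range(199))
        assert cp == pytest.approx((1 + exceed) / 200)

    def test_corrected_p_not_below_single_threshold_p(self, rng):
        geno, ss, _ = self._planted(rng)
        y = rng.standard_normal(150)
        multi = g.permutation_correct(y, geno, ss, None,
                                      g.build_threshold_grid(0.9),
                                      B=299, seed=5)[0]
        single = g.permutation_correct(y, geno, ss, None, [0.9],
                                       B=299, seed=5)[0]
        assert multi >= single - 1e-12

    def test_invalid_B_rejected(self, rng):
        geno, ss, target = self._planted(rng)
        with pytest.raises(ValueError, match="B"):
            g.permutation_correct(target, geno, ss, None, [0.5], B=0)
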