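"""Group inference layer: partial-F ANOVA, permutation cluster correction,
stratified folds, post-hoc pairwise tests and Spearman correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from boldmse.stats import (
    Cluster,
    anova_designs,
    cluster_correct,
    correlation_table,
    fivefold_roi_selection,
    posthoc_pairwise,
    spearman_clinical,
    stratified_folds,
    voxelwise_anova,
)


def make_manifest(rng, sizes=(30, 33, 32, 29)):
    groups = np.repeat(["NC", "EMCI", "LMCI", "AD"], sizes)
    n = len(groups)
    return pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "group": groups,
            "age": rng.normal(73, 6, n),
            "sex": rng.integers(0, 2, n),
            "education": rng.normal(16, 2, n),
        }
    )


class TestVoxelwiseAnova:
    def test_two_group_f_equals_t_squared(self, rng):
        """With two groups and no covariates the partial F is the square of
        the pooled-variance two-sample t statistic."""
        man = pd.DataFrame(
            {"group": ["NC"] * 12 + ["AD"] * 15}
        )
        y = rng.standard_normal((27, 3))
        res = voxelwise_anova(y, man, covariates=())
        for v in range(3):
            t, _ = sps.ttest_ind(y[:12, v], y[12:, v])
            assert res.f[v] == pytest.approx(t**2, rel=1e-10)
        assert (res.df1, res.df2) == (1, 25)

    def test_matches_statsmodels_partial_f(self, rng):
        """Independent cross-check of the linear-algebra path against
        statsmodels' OLS compare_f_test on a handful of voxels."""
        import statsmodels.api as sm

        man = make_manifest(rng, sizes=(10, 11, 12, 9))
        Y = rng.standard_normal((len(man), 5))
        full, reduced = anova_designs(man)
        res = voxelwise_anova(Y, man)
        for v in range(5):
            fit_full = sm.OLS(Y[:, v], full).fit()
            fit_red = sm.OLS(Y[:, v], reduced).fit()
            f_sm, p_sm, df_sm = fit_full.compare_f_test(fit_red)
            assert res.f[v] == pytest.approx(f_sm, rel=1e-8)
            assert res.p[v] == pytest.approx(p_sm, rel=1e-6)
            assert df_sm == res.df1

    def test_null_p_values_uniform(self, rng):
        """Kolmogorov-Smirnov calibration on pure-noise maps."""
        man = make_manifest(rng, sizes=(12, 12, 12, 12))
        Y = rng.standard_normal((48, 2000))
        res = voxelwise_anova(Y, man)
        stat = sps.kstest(res.p, "uniform")
        assert stat.pvalue > 0.01

    def test_zero_group_effect_gives_zero_f(self, rng):
        """A voxel whose group-term numerator is exactly annihilated."""
        man = make_manifest(rng, sizes=(8, 8, 8, 8))
        full, _ = anova_designs(man)
        noise = rng.standard_normal(32)
        # residualize the noise against the FULL design: group term adds
        # nothing on top of the covariates
        resid = noise - full @ np.linalg.lstsq(full, noise, rcond=None)[0]
        y = 3.0 * man["age"].to_numpy() + resid
        res = voxelwise_anova(y[:, None], man)
        assert res.f[0] == pytest.approx(0.0, abs=1e-8)

    def test_f_nonnegative_and_missing_propagates(self, rng):
        man = make_manifest(rng, sizes=(6, 6, 6, 6))
        Y = rng.standard_normal((24, 50))
        Y[3, 7] = np.nan
        res = voxelwise_anova(Y, man)
        assert np.isnan(res.f[7])
        good = np.isfinite(res.f)
        assert good.sum() == 49
        assert np.all(res.f[good] >= 0)

    def test_too_small_groups_rejected(self, rng):
        man = pd.DataFrame({"group": ["NC", "NC", "AD"],
                            "age": [70.0, 71, 72], "sex": [0, 1, 0],
                            "education": [16.0, 15, 14]})
        with pytest.raises(ValueError):
            voxelwise_anova(rng.standard_normal((3, 2)), man)


class TestClusterCorrect:
    shape = (8, 8, 8)

    def _planted_data(self, rng, effect=2.0):
        man = make_manifest(rng, sizes=(10, 10, 10, 10))
        Y = rng.standard_normal((40, int(np.prod(self.shape))))
        block = np.zeros(self.shape, bool)
        block[2:5, 2:5, 2:5] = True
        shift = {"NC": 1.5, "EMCI": 0.5, "LMCI": -0.5, "AD": -1.5}
        for g, s in shift.items():
            Y[np.ix_(man["group"] == g, block.ravel())] += effect * s
        return man, Y, block

    def test_planted_block_survives_null_does_not(self, rng):
        man, Y, block = self._planted_data(rng)
        clusters = cluster_correct(
            Y, man, self.shape, np.eye(4), n_perm=200, seed=5
        )
        assert clusters
        found = np.zeros(int(np.prod(self.shape)), bool)
        for cl in clusters:
            found[cl.voxels] = True
        overlap = (found & block.ravel()).sum() / block.sum()
        assert overlap > 0.8
        assert all(cl.p_corrected < 0.05 for cl in clusters)
        # same data, labels shuffled: a null cohort
        man_null = man.copy()
        man_null["group"] = rng.permutation(man["group"].to_numpy())
        null_clusters = cluster_correct(
            Y * 0 + rng.standard_normal(Y.shape), man_null, self.shape,
            np.eye(4), n_perm=200, seed=6,
        )
        assert len(null_clusters) <= 1

    def test_seed_reproducibility(self, rng):
        man, Y, _ = self._planted_data(rng)
        a = cluster_correct(Y, man, self.shape, np.eye(4), n_perm=150, seed=9)
        b = cluster_correct(Y, man, self.shape, np.eye(4), n_perm=150, seed=9)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.voxels, cb.voxels)
            assert ca.p_corrected == cb.p_corrected

    def test_peak_reported_in_mm_space(self, rng):
        man, Y, block = self._planted_data(rng)
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = (-12.0, -12.0, -12.0)
        clusters = cluster_correct(
            Y, man, self.shape, affine, n_perm=150, seed=2
        )
        cl = clusters[0]
        expected = affine @ np.array([*cl.peak_index, 1.0])
        assert cl.peak_mm == tuple(expected[:3])

    def test_min_permutations_enforced(self, rng):
        man, Y, _ = self._planted_data(rng)
        with pytest.raises(ValueError):
            cluster_correct(Y, man, self.shape, np.eye(4), n_perm=50)


class TestStratifiedFolds:
    def test_124_subjects_fold_sizes_and_coverage(self, rng):
        man = make_manifest(rng)  # 30/33/32/29
        folds = stratified_folds(man["group"], 5, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {24, 25}
        assert sum(sizes) == 124
        for f in folds:
            assert set(man["group"].iloc[f]) == {"NC", "EMCI", "LMCI", "AD"}
        # partition: disjoint and exhaustive
        allidx = np.concatenate(folds)
        assert len(np.unique(allidx)) == 124

    def test_deterministic_under_seed(self, rng):
        man = make_manifest(rng)
        a = stratified_folds(man["group"], 5, seed=7)
        b = stratified_folds(man["group"], 5, seed=7)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa, fb)
        c = stratified_folds(man["group"], 5, seed=8)
        assert any(not np.array_equal(fa, fc) for fa, fc in zip(a, c))

    def test_small_group_warns_and_rebalances(self, rng, caplog):
        man = make_manifest(rng, sizes=(3, 6, 6, 6))
        with caplog.at_level("WARNING", logger="boldmse.stats"):
            folds = stratified_folds(man["group"], 5, seed=1)
        assert any("rebalancing" in r.message for r in caplog.records)
        assert sum(len(f) for f in folds) == 21


class TestFivefoldRoiSelection:
    def test_planted_effect_rois_recovered_per_fold(self, rng):
        shape = (8, 8, 8)
        man = make_manifest(rng, sizes=(10, 10, 10, 10))
        Y = rng.standard_normal((40, int(np.prod(shape))))
        block = np.zeros(shape, bool)
        block[2:5, 2:5, 2:5] = True
        shift = {"NC": 2.0, "EMCI": 0.7, "LMCI": -0.7, "AD": -2.0}
        for g, s in shift.items():
            Y[np.ix_(man["group"] == g, block.ravel())] += s
        res = fivefold_roi_selection(
            Y, man, shape, np.eye(4), n_perm=120, seed=3
        )
        assert len(res) == 5
        n_with_roi = sum(bool(fr.rois) for fr in res)
        assert n_with_roi >= 4
        for fr in res:
            assert np.intersect1d(fr.train_index, fr.test_index).size == 0

    def test_determinism(self, rng):
        shape = (6, 6, 6)
        man = make_manifest(rng, sizes=(8, 8, 8, 8))
        Y = rng.standard_normal((32, int(np.prod(shape))))
        a = fivefold_roi_selection(Y, man, shape, np.eye(4), n_perm=100, seed=4)
        b = fivefold_roi_selection(Y, man, shape, np.eye(4), n_perm=100, seed=4)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.test_index, fb.test_index)
            assert [r.center_mm for r in fa.rois] == [
                r.center_mm for r in fb.rois
            ]


class TestPosthocPairwise:
    def test_identical_distributions_all_p_one(self, rng):
        base = rng.standard_normal(20)
        man = make_manifest(rng, sizes=(20, 20, 20, 20))
        values = np.tile(base, 4)
        # disable adjustment so the duplication is exact
        table = posthoc_pairwise(values, man, adjust_covariates=False)
        assert len(table) == 6
        assert np.allclose(table["p_bonferroni"], 1.0)

    def test_bonferroni_at_least_raw(self, rng):
        man = make_manifest(rng, sizes=(10, 10, 10, 10))
        values = rng.standard_normal(40)
        table = posthoc_pairwise(values, man)
        assert np.all(table["p_bonferroni"] >= table["p_raw"] - 1e-15)
        assert np.all(table["p_bonferroni"] <= 1.0)

    def test_planted_monotone_effect_detected(self, rng):
        man = make_manifest(rng, sizes=(25, 25, 25, 25))
        effect = {"NC": 3.0, "EMCI": 2.0, "LMCI": 1.0, "AD": 0.0}
        values = np.array([effect[g] for g in man["group"]])
        values = values + 0.5 * rng.standard_normal(100)
        table = posthoc_pairwise(values, man).set_index(
            ["group_a", "group_b"]
        )
        assert table.loc[("NC", "AD"), "p_bonferroni"] < 1e-6
        assert table.loc[("NC", "AD"), "mean_a"] > table.loc[
            ("NC", "AD"), "mean_b"
        ]

    def test_small_group_skipped(self, rng):
        man = pd.DataFrame({
            "group": ["NC"] * 5 + ["AD"] * 1 + ["EMCI"] * 5 + ["LMCI"] * 5,
            "age": rng.normal(73, 6, 16), "sex": rng.integers(0, 2, 16),
            "education": rng.normal(16, 2, 16),
        })
        table = posthoc_pairwise(rng.standard_normal(16), man)
        skipped = table[table["skipped"]]
        assert set(
            tuple(sorted(p)) for p in
            zip(skipped["group_a"], skipped["group_b"])
        ) == {("AD", "EMCI"), ("AD", "LMCI"), ("AD", "NC")}


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_clinical([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # ranks differ by d = (0,0,0,1,-1): rho = 1 - 6*2/(5*24) = 0.9
        rho, _ = spearman_clinical([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert rho == pytest.approx(0.9)

    def test_noisy_decreasing_coupling_negative(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 1, 60)
            y = 10 - 8 * x + rng.normal(0, 2.0, 60)
            rho, _ = spearman_clinical(x, y)
            hits += rho < 0
        assert hits >= 19

    def test_constant_vector_undefined(self):
        rho, p = spearman_clinical([1, 2, 3, 4, 5], [7, 7, 7, 7, 7])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_clinical([1, 2, 3], [1, 2, 3])

    def test_adjusted_p_monotone_within_family(self, rng):
        vals = pd.DataFrame(rng.standard_normal((40, 6)),
                            columns=[f"roi{i}" for i in range(6)])
        scores = pd.DataFrame({"MMSE": rng.normal(25, 3, 40)})
        table = correlation_table(vals, scores)
        fam = table[table["score"] == "MMSE"].sort_values("p_raw")
        assert np.all(np.diff(fam["p_adjusted"]) >= -1e-12)
        assert np.all(table["p_adjusted"] >= table["p_raw"] - 1e-12)

    def test_bonferroni_scope_stricter(self, rng):
        vals = pd.DataFrame(rng.standard_normal((30, 4)),
                            columns=list("abcd"))
        scores = pd.DataFrame({"CDR": rng.normal(1, 0.5, 30)})
        bh = correlation_table(vals, scores, method="fdr_bh")
        bf = correlation_table(vals, scores, method="bonferroni")
        assert np.all(
            bf["p_adjusted"].to_numpy() >= bh["p_adjusted"].to_numpy() - 1e-12
        )
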