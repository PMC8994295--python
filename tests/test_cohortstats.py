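"""Cohort statistics: regressions, correlation choice, rank tests, clustering."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repeatmosaic import pipeline, simcore
from repeatmosaic.cohortstats import (
    correlate,
    cross_locus_correlation,
    fit_length_phenotype,
    heatmap_cluster,
    index_length_regression_per_tissue,
    pairwise_tissue_tests,
    validate_cohort,
)


def cohort_frame(repeat, aao, aad=None, ei=None, tissue="blood", ids=None):
    n = len(repeat)
    return pd.DataFrame(
        {
            "individual_id": ids if ids is not None else [f"i{k}" for k in range(n)],
            "tissue": tissue,
            "locus": "XDP",
            "repeat_length": repeat,
            "expansion_index": ei if ei is not None else np.nan,
            "aao": aao,
            "aad": aad if aad is not None else np.nan,
        }
    )


class TestValidate:
    def test_duration_derived(self):
        df = validate_cohort(cohort_frame([40, 41, 42], [40, 39, 38], [50, 49, 48]))
        assert (df["duration"] == 10).all()

    def test_death_before_onset_rejected(self):
        with pytest.raises(ValueError, match="death"):
            validate_cohort(cohort_frame([40, 41], [40, 39], [30, 49]))

    def test_duplicate_rows_rejected(self):
        df = cohort_frame([40, 41], [40, 39], ids=["i0", "i0"])
        with pytest.raises(ValueError, match="duplicate"):
            validate_cohort(df)


class TestFitLengthPhenotype:
    def test_zero_noise_exact_fit(self):
        reps = np.arange(34, 54)
        aao = 100.0 - 1.4 * reps
        res = fit_length_phenotype(cohort_frame(reps, aao), "aao")
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(-1.4, abs=1e-12)

    def test_recovers_generator_slope_within_two_se(self):
        rng = np.random.default_rng(0)
        reps = np.round(rng.normal(41.6, 3.9, 266))
        aao = 100 - 1.4 * reps + rng.normal(0, 6.0, 266)
        res = fit_length_phenotype(cohort_frame(reps, aao), "aao")
        assert abs(res.slope + 1.4) <= 2 * res.slope_se

    def test_permuted_response_kills_fit(self):
        r2 = []
        for s in range(20):
            rng = np.random.default_rng(s)
            reps = np.round(rng.normal(41.6, 3.9, 200))
            aao = 100 - 1.4 * reps + rng.normal(0, 6.0, 200)
            res = fit_length_phenotype(cohort_frame(reps, rng.permutation(aao)), "aao")
            r2.append(res.r_squared)
        assert np.mean(r2) < 0.05

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_length_phenotype(cohort_frame([40, 40, 40], [35, 36, 37]), "aao")

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_length_phenotype(cohort_frame([40, 41], [35, 36]), "aao")

    def test_missing_rows_dropped(self):
        reps = [40, 41, 42, 43, np.nan]
        aao = [44, 42.6, 41.2, 39.8, 38.4]
        res = fit_length_phenotype(cohort_frame(reps, aao), "aao")
        assert res.n == 4 and res.n_dropped == 1


class TestCorrelate:
    def test_linear_gaussian_uses_pearson(self, rng):
        x = rng.normal(size=60)
        res = correlate(x, 2 * x)
        assert res.method == "pearson"
        assert res.coefficient == pytest.approx(1.0)

    def test_monotone_heavy_tail_uses_spearman(self, rng):
        x = rng.standard_cauchy(size=60)
        res = correlate(x, np.exp(np.clip(x, -20, 20)))
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0)

    def test_null_coefficient_small(self):
        hits = 0
        for s in range(100):
            r = np.random.default_rng(s)
            res = correlate(r.normal(size=100), r.normal(size=100))
            hits += abs(res.coefficient) < 0.3
        assert hits >= 95

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [1, 2, 3])


class TestPairwiseTissueTests:
    def _cohort(self, groups):
        rows = []
        for tissue, values in groups.items():
            for k, v in enumerate(values):
                rows.append({"individual_id": f"{tissue}{k}", "tissue": tissue,
                             "expansion_index": v})
        return pd.DataFrame(rows)

    def test_identical_groups_adjusted_p_one(self):
        vals = list(np.linspace(0.1, 1.0, 10))
        mat = pairwise_tissue_tests(self._cohort({"a": vals, "b": vals}))
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.2, 20)
        b = rng.normal(1.0, 0.2, 20)
        mat = pairwise_tissue_tests(self._cohort({"a": a, "b": b}))
        assert mat.loc["a", "b"] < 0.05

    def test_matrix_shape_and_symmetry(self):
        rng = np.random.default_rng(2)
        groups = {t: rng.normal(size=8) for t in "abcd"}
        mat = pairwise_tissue_tests(self._cohort(groups))
        off_diag = mat.values[~np.eye(4, dtype=bool)]
        assert np.isfinite(off_diag).sum() == 12  # 6 informative pairs, mirrored
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)

    def test_adjustment_never_below_raw_and_capped(self):
        rng = np.random.default_rng(3)
        groups = {t: rng.normal(size=10) for t in "abc"}
        mat = pairwise_tissue_tests(self._cohort(groups))
        for a, b in [("a", "b"), ("a", "c"), ("b", "c")]:
            raw = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
            assert mat.loc[a, b] >= raw - 1e-12
            assert mat.loc[a, b] <= 1.0

    def test_small_tissue_skipped_with_warning(self):
        groups = {"a": [1, 2, 3, 4], "b": [2, 3, 4, 5], "c": [1.0]}
        with pytest.warns(UserWarning, match="skipped"):
            mat = pairwise_tissue_tests(self._cohort(groups))
        assert "c" not in mat.index


class TestPerTissueRegression:
    def test_length_dependence_detected(self):
        """With length-dependent expansion on, per-tissue slopes are positive
        in nearly all seeded cohorts."""
        prof = simcore.TissueProfile("cereb", 0.035, 0.10, 0.6, 0.4, 0.0, block="s")
        positives = 0
        for s in range(20):
            cfg = simcore.CohortConfig(n_individuals=20, seed=s)
            cohort = pipeline.measure_cohort(simcore.simulate_cohort(cfg, [prof]),
                                             seed=900 + s)
            res = index_length_regression_per_tissue(cohort)["cereb"]
            positives += res.slope > 0
        assert positives >= 18

    def test_no_length_dependence_ci_covers_zero(self):
        """With expansion off, only stutter shapes the trace and the slope CI
        covers zero in nearly all seeds."""
        prof = simcore.TissueProfile("t", 0.0, 0.0, 0.5, 0.4, 0.0, block="s")
        stutter = simcore.StutterModel(0.12, 0.05, 1.0)
        covered = 0
        for s in range(20):
            cfg = simcore.CohortConfig(n_individuals=20, seed=s)
            cohort = pipeline.measure_cohort(
                simcore.simulate_cohort(cfg, [prof]), stutter=stutter, seed=900 + s
            )
            res = index_length_regression_per_tissue(cohort)["t"]
            covered += res.ci_covers(0.0)
        assert covered >= 18

    def test_single_individual_tissue_skipped(self):
        df = pd.DataFrame(
            {
                "individual_id": ["i1", "i1", "i2", "i3"],
                "tissue": ["solo", "both", "both", "both"],
                "locus": "XDP",
                "repeat_length": [40, 40, 45, 50],
                "expansion_index": [0.5, 0.4, 0.8, 1.2],
                "aao": np.nan,
                "aad": np.nan,
            }
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = index_length_regression_per_tissue(df)
        assert "solo" not in out and "both" in out


class TestCrossLocus:
    def test_identical_means_r_one(self):
        means = {"a": 0.1, "b": 0.5, "c": 0.9, "d": 1.3}
        res = cross_locus_correlation(means, dict(means))
        assert res.coefficient == pytest.approx(1.0)

    def test_shared_profiles_correlate(self):
        """Two loci driven by the same tissue propensities give high r."""
        profiles = simcore.default_tissue_profiles()
        rs = []
        for s in range(6):
            means = {}
            for locus, seed in (("A", s), ("B", 1000 + s)):
                cfg = simcore.CohortConfig(n_individuals=8, seed=seed)
                co = pipeline.measure_cohort(simcore.simulate_cohort(cfg, profiles),
                                             seed=2000 + seed)
                means[locus] = co.groupby("tissue")["expansion_index"].mean().to_dict()
            rs.append(cross_locus_correlation(means["A"], means["B"]).coefficient)
        assert np.median(rs) > 0.8

    def test_shuffled_profiles_decorrelate(self):
        profiles = simcore.default_tissue_profiles()
        names = [p.tissue_name for p in profiles]
        rs = []
        for s in range(8):
            cfg = simcore.CohortConfig(n_individuals=8, seed=s)
            co = pipeline.measure_cohort(simcore.simulate_cohort(cfg, profiles),
                                         seed=3000 + s)
            means_a = co.groupby("tissue")["expansion_index"].mean().to_dict()
            perm = np.random.default_rng(s).permutation(names)
            means_b = {t: means_a[p] for t, p in zip(names, perm)}
            rs.append(cross_locus_correlation(means_a, means_b).coefficient)
        assert abs(np.mean(rs)) < 0.4

    def test_too_few_shared_tissues(self):
        with pytest.raises(ValueError, match="shared"):
            cross_locus_correlation({"a": 1, "b": 2, "c": 3}, {"a": 1, "b": 2, "c": 3})


class TestHeatmapCluster:
    def _cohort(self, mat: pd.DataFrame):
        rows = []
        for ind in mat.index:
            for tissue in mat.columns:
                v = mat.loc[ind, tissue]
                if not np.isnan(v):
                    rows.append({"individual_id": ind, "tissue": tissue,
                                 "expansion_index": v})
        return pd.DataFrame(rows)

    def _random_matrix(self, seed=0, n=15, tissues=6):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(1.0, 0.3, size=(n, tissues)),
            index=[f"i{k}" for k in range(n)],
            columns=[f"t{k}" for k in range(tissues)],
        )

    def test_scaled_columns_standardized(self):
        res = heatmap_cluster(self._cohort(self._random_matrix()),
                              min_measures_per_tissue=5, min_tissues_per_individual=3)
        assert np.allclose(res.matrix.mean(), 0.0, atol=1e-9)
        assert np.allclose(res.matrix.std(ddof=1), 1.0, atol=1e-9)

    def test_scaling_idempotent(self):
        mat = self._random_matrix(1)
        scaled = (mat - mat.mean()) / mat.std(ddof=1)
        res = heatmap_cluster(self._cohort(scaled),
                              min_measures_per_tissue=5, min_tissues_per_individual=3)
        aligned = scaled.loc[res.matrix.index, res.matrix.columns]
        np.testing.assert_allclose(res.matrix.to_numpy(), aligned.to_numpy(), atol=1e-12)

    def test_constant_column_dropped(self):
        mat = self._random_matrix(2)
        mat["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = heatmap_cluster(self._cohort(mat),
                                  min_measures_per_tissue=5, min_tissues_per_individual=3)
        assert "flat" in res.dropped_tissues

    def test_exclusion_rules(self):
        mat = self._random_matrix(3, n=20, tissues=7)
        mat.iloc[5:, 6] = np.nan      # tissue t6: only 5 measures
        mat.iloc[0, 1:] = np.nan      # individual i0: only 1 tissue
        res = heatmap_cluster(self._cohort(mat),
                              min_measures_per_tissue=12, min_tissues_per_individual=6)
        assert "t6" in res.dropped_tissues
        assert "i0" in res.dropped_individuals

    def test_missing_cells_preserved(self):
        mat = self._random_matrix(4)
        mat.loc["i2", "t3"] = np.nan
        res = heatmap_cluster(self._cohort(mat),
                              min_measures_per_tissue=5, min_tissues_per_individual=3)
        assert np.isnan(res.matrix.loc["i2", "t3"])

    def test_planted_blocks_recovered_single_seed(self):
        profiles = [p for p in simcore.default_tissue_profiles() if p.block != "blood"]
        blocks = {p.tissue_name: p.block for p in profiles}
        cfg = simcore.CohortConfig(n_individuals=23, seed=42)
        cohort = pipeline.measure_cohort(simcore.simulate_cohort(cfg, profiles), seed=43)
        res = heatmap_cluster(cohort)
        labels = {}
        for tissue, cl in res.column_clusters.items():
            labels.setdefault(blocks[tissue], set()).add(cl)
        assert labels["cortical"].isdisjoint(labels["subcortical"])
        assert len(labels["cortical"]) == 1 and len(labels["subcortical"]) == 1

    def test_degenerate_matrix_rejected(self):
        mat = self._random_matrix(5, n=3, tissues=2)
        with pytest.raises(ValueError, match="degenerate"):
            heatmap_cluster(self._cohort(mat),
                            min_measures_per_tissue=12, min_tissues_per_individual=6)
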