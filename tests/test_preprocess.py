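"""QC filters, the beta/M transform, deconvolution and control matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

import episig as es
from episig.preprocess import beta_to_m, m_to_beta
from episig.synthetic import CohortDesign, simulate_null_cohort

from conftest import toy_cohort


class TestFilterProbes:
    def test_sex_chromosome_removal(self, manifest_small):
        mani = manifest_small.copy()
        mani["sex_chromosome"] = False
        mani.iloc[:2, mani.columns.get_loc("sex_chromosome")] = True
        mani["snp_overlap"] = False
        mani["cross_reactive"] = False
        cohort = toy_cohort(np.full((len(mani), 4), 0.5), mani)
        out, report = es.filter_probes(cohort, drop_sex=True)
        assert out.n_probes == len(mani) - 2
        assert sorted(report.removed_probes.values()) == ["sex_chromosome"] * 2

    def test_no_removal_when_clean(self, manifest_small):
        mani = manifest_small.copy()
        for f in ["sex_chromosome", "snp_overlap", "cross_reactive"]:
            mani[f] = False
        cohort = toy_cohort(np.full((len(mani), 3), 0.5), mani,
                            detection_p=np.zeros((len(mani), 3)))
        out, report = es.filter_probes(cohort, drop_sex=False, blacklist={})
        assert out.n_probes == cohort.n_probes
        assert not report.removed_probes

    def test_detection_p_any_sample_triggers(self, manifest_small):
        """A single detection failure (p = 0.02 > 0.01) removes the probe."""
        mani = manifest_small.copy()
        dp = np.zeros((len(mani), 5))
        dp[7, 2] = 0.02
        cohort = toy_cohort(np.full((len(mani), 5), 0.5), mani, detection_p=dp)
        out, report = es.filter_probes(cohort, drop_sex=False, blacklist={})
        bad = mani.index[7]
        assert report.removed_probes == {bad: "detection_p"}
        assert bad not in out.betas.index

    def test_idempotent(self, null_cohort):
        once, _ = es.filter_probes(null_cohort[0])
        twice, report = es.filter_probes(once)
        assert twice.betas.equals(once.betas)
        assert not report.removed_probes


class TestFilterSamples:
    def test_failed_probe_rate(self, manifest_small):
        dp = np.zeros((len(manifest_small), 5))
        dp[: int(0.06 * len(manifest_small)), 0] = 0.5     # 6% failed in sample 0
        cohort = toy_cohort(
            np.clip(np.tile(np.random.default_rng(0).beta(0.3, 0.3, len(manifest_small)),
                            (5, 1)).T, 0.01, 0.99),
            manifest_small, detection_p=dp)
        _, report = es.filter_samples(cohort, pca_outlier_sd=0.0)
        assert report.removed_samples.get("t00") == "failed_probe_rate"

    def test_unimodal_sample_flagged(self, null_cohort):
        cohort = null_cohort[0]
        b = cohort.betas.copy()
        rng = np.random.default_rng(4)
        b.iloc[:, 0] = rng.uniform(0.45, 0.55, size=len(b))
        modified = es.MethylationCohort(b, cohort.samples, cohort.manifest)
        _, report = es.filter_samples(modified, pca_outlier_sd=0.0)
        first = cohort.betas.columns[0]
        assert report.removed_samples.get(first) == "density_not_bimodal"

    def test_clean_cohort_untouched(self, null_cohort):
        """Deterministic screens pass every clean sample (the 3-sd PCA rule
        flags a small tail by construction, so it is exercised separately)."""
        out, report = es.filter_samples(null_cohort[0], pca_outlier_sd=0.0)
        assert not report.removed_samples
        assert out.n_samples == null_cohort[0].n_samples

    def test_pca_outlier_flagged(self, null_cohort):
        cohort = null_cohort[0]
        b = cohort.betas.copy()
        rng = np.random.default_rng(6)
        # a sample with a large coherent shift dominates a leading component
        shifted = np.clip(b.iloc[:, 0] + rng.choice([-0.25, 0.25], len(b)),
                          0.01, 0.99)
        b.iloc[:, 0] = 0.5 * b.iloc[:, 0] + 0.5 * shifted
        modified = es.MethylationCohort(b, cohort.samples, cohort.manifest)
        _, report = es.filter_samples(modified, bimodality_check=False)
        assert report.removed_samples.get(cohort.betas.columns[0]) == "pca_outlier"


class TestBetaMTransform:
    @pytest.mark.parametrize("beta,expected", [(0.5, 0.0), (0.8, 2.0),
                                               (0.2, -2.0)])
    def test_known_values(self, beta, expected):
        assert beta_to_m(beta) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(deadline=None)
    def test_round_trip_identity(self, x):
        assert m_to_beta(beta_to_m(x)) == pytest.approx(x, abs=1e-12)

    @given(st.lists(st.integers(min_value=2, max_value=998),
                    min_size=2, max_size=20))
    @settings(deadline=None)
    def test_strictly_increasing_inside_clamp(self, xs):
        xs = np.array(sorted(set(xs))) / 1000.0
        ms = beta_to_m(xs)
        assert (np.diff(ms) > 0).all()

    def test_clamp_makes_transform_total(self):
        assert np.isfinite(beta_to_m(np.array([0.0, 1.0]))).all()


class TestCellComposition:
    def test_noiseless_exact_recovery(self, manifest_small, panel_small):
        rng = np.random.default_rng(8)
        props = rng.dirichlet(np.full(7, 5.0), size=4)
        mix = panel_small.reference_betas.to_numpy() @ props.T
        cohort = toy_cohort(mix, manifest_small)
        est = es.estimate_cell_composition(cohort, panel_small)
        assert np.abs(est.proportions.to_numpy() - props).max() <= 1e-6

    def test_pure_reference_column_is_unit_vector(self, manifest_small,
                                                  panel_small):
        col = panel_small.reference_betas.iloc[:, 2].to_numpy()[:, None]
        cohort = toy_cohort(col, manifest_small)
        est = es.estimate_cell_composition(cohort, panel_small)
        expected = np.zeros(7)
        expected[2] = 1.0
        assert np.abs(est.proportions.to_numpy()[0] - expected).max() <= 1e-6

    def test_simplex_sums_to_one(self, null_cohort, panel_small):
        est = es.estimate_cell_composition(null_cohort[0], panel_small)
        assert np.abs(est.proportions.sum(axis=1) - 1.0).max() <= 1e-6

    def test_noisy_recovery_rmse(self, manifest_small, panel_small):
        """At logit noise sd 0.05, proportion RMSE over 50 samples ≤ 0.05."""
        rng = np.random.default_rng(9)
        props = rng.dirichlet(np.full(7, 5.0), size=50)
        mix = panel_small.reference_betas.to_numpy() @ props.T
        noisy = expit(logit(np.clip(mix, 1e-9, 1 - 1e-9))
                      + rng.normal(0, 0.05, mix.shape))
        cohort = toy_cohort(noisy, manifest_small)
        est = es.estimate_cell_composition(cohort, panel_small)
        rmse = np.sqrt(np.mean((est.proportions.to_numpy() - props) ** 2))
        assert rmse <= 0.05


def _pool(n, rng, array_types=("450k", "EPIC")):
    return pd.DataFrame({
        "group": "control",
        "age": rng.uniform(1, 30, n).round(1),
        "sex": rng.choice(["F", "M"], n),
        "batch": "b1",
        "array_type": rng.choice(array_types, n),
    }, index=[f"c{i:03d}" for i in range(n)])


def _cases(n, rng, array_type="450k"):
    return pd.DataFrame({
        "group": "A", "age": rng.uniform(2, 25, n).round(1),
        "sex": rng.choice(["F", "M"], n), "batch": "b1",
        "array_type": array_type,
    }, index=[f"p{i:02d}" for i in range(n)])


class TestMatchControls:
    @pytest.mark.parametrize("n_cases,expected", [(14, 84), (5, 30), (7, 42)])
    def test_six_to_one_ratio(self, n_cases, expected):
        rng = np.random.default_rng(1)
        design = es.match_controls(_cases(n_cases, rng), _pool(200, rng),
                                   ratio=6, seed=0)
        assert len(design.control_ids) == expected
        assert len(set(design.control_ids)) == expected    # without replacement

    def test_capacity_error_names_stratum(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="450k"):
            es.match_controls(_cases(14, rng), _pool(50, rng), ratio=6, seed=0)

    def test_exact_array_type_respected(self):
        rng = np.random.default_rng(3)
        cases = _cases(4, rng, array_type="EPIC")
        pool = _pool(100, rng)
        design = es.match_controls(cases, pool, ratio=6, seed=0)
        assert (pool.loc[design.control_ids, "array_type"] == "EPIC").all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        cases, pool = _cases(5, rng), _pool(120, rng)
        d1 = es.match_controls(cases, pool, seed=7)
        d2 = es.match_controls(cases, pool, seed=7)
        assert d1.control_ids == d2.control_ids

    def test_age_gaps_small_on_dense_pool(self):
        rng = np.random.default_rng(5)
        cases, pool = _cases(5, rng), _pool(300, rng)
        design = es.match_controls(cases, pool, seed=1)
        # ~10 controls per year of age in the pool; six nearest stay close
        assert design.age_gaps.abs().mean() <= 2.0
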