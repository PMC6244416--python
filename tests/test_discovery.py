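"""Moderated regression, BH, clustering, Stouffer and the DMR caller."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import episig as es
from episig.discovery import (adjust_bh, detect_dmrs, fit_moderated_model,
                              hierarchical_cluster, select_signature_probes,
                              stouffer_combine)


def _random_fit_inputs(n_probes=200, n_samples=30, seed=42):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame({
        "intercept": np.ones(n_samples),
        "case": rng.integers(0, 2, n_samples).astype(float),
        "z": rng.normal(size=n_samples),
    }, index=[f"s{i}" for i in range(n_samples)])
    y = rng.normal(size=(n_probes, n_samples)) \
        * rng.uniform(0.5, 2.0, size=(n_probes, 1))
    y[: n_probes // 4] += 1.5 * x["case"].to_numpy()
    m = pd.DataFrame(y, index=[f"p{i}" for i in range(n_probes)],
                     columns=x.index)
    return m, x


class TestModeratedModel:
    def test_coefficients_match_normal_equations_oracle(self):
        m, x = _random_fit_inputs()
        st_tab = fit_moderated_model(m, x)
        xm = x.to_numpy()
        for i in range(0, len(m), 17):
            beta = np.linalg.solve(xm.T @ xm, xm.T @ m.iloc[i].to_numpy())
            assert st_tab["coefficient"].iloc[i] == pytest.approx(
                beta[1], abs=1e-8)

    def test_zero_prior_df_recovers_ols_t(self):
        m, x = _random_fit_inputs()
        st_tab = fit_moderated_model(m, x, prior_df=0.0)
        xm = x.to_numpy()
        xtx_inv = np.linalg.inv(xm.T @ xm)
        for i in range(0, len(m), 31):
            y = m.iloc[i].to_numpy()
            beta = xtx_inv @ xm.T @ y
            resid = y - xm @ beta
            s2 = (resid ** 2).sum() / (len(y) - 3)
            t_ols = beta[1] / np.sqrt(s2 * xtx_inv[1, 1])
            assert st_tab["t"].iloc[i] == pytest.approx(t_ols, abs=1e-10)

    def test_infinite_prior_df_gives_common_variance(self):
        m, x = _random_fit_inputs()
        st_tab = fit_moderated_model(m, x, prior_df=np.inf)
        # all probes share the prior variance -> t proportional to coefficient
        ratio = st_tab["t"] / st_tab["coefficient"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_moderation_shrinks_variance_spread(self):
        m, x = _random_fit_inputs()
        plain = fit_moderated_model(m, x, prior_df=0.0)
        moderated = fit_moderated_model(m, x)
        assert moderated.attrs["d0"] > 0
        # posterior t statistics less dispersed than raw OLS t under the null
        null = slice(len(m) // 4, None)
        assert moderated["t"].iloc[null].std() <= plain["t"].iloc[null].std() * 1.05

    def test_rank_deficient_design_rejected(self):
        m, x = _random_fit_inputs()
        x2 = x.copy()
        x2["dup"] = x2["case"]
        with pytest.raises(ValueError):
            fit_moderated_model(m, x2)


class TestBenjaminiHochberg:
    def test_closed_form_triple(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2]) == pytest.approx([0.2])

    def test_matches_literal_step_up_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=1000)
        q = adjust_bh(p)
        # literal step-up definition, applied without vector tricks
        order = np.argsort(p)
        expected = np.empty_like(p)
        for i, pi in enumerate(p):
            candidates = [len(p) * pj / (np.searchsorted(p[order], pj,
                                                         side="right"))
                          for pj in p if pj >= pi]
            expected[i] = min(1.0, min(candidates))
        assert np.abs(q - expected).max() <= 1e-12

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        q = adjust_bh(p)
        _, q_sm, _, _ = statsmodels.multipletests(p, method="fdr_bh")
        assert np.abs(q - q_sm).max() <= 1e-12

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2,
                    max_size=60), st.randoms(use_true_random=False))
    @settings(deadline=None, max_examples=50)
    def test_permutation_invariant_and_monotone(self, ps, rnd):
        p = np.array(ps)
        q = adjust_bh(p)
        perm = np.array(rnd.sample(range(len(p)), len(p)))
        assert np.allclose(adjust_bh(p[perm]), q[perm])
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])


class TestSelectSignatureProbes:
    def test_effect_and_q_filters(self):
        tab = pd.DataFrame({
            "p": [1e-4, 2e-4, 0.5], "q": [0.04, 0.04, 0.9],
            "t": [5, 5, 0.1], "delta_beta": [0.09, 0.12, 0.3],
        }, index=["a", "b", "c"])
        assert select_signature_probes(tab) == ["b"]

    def test_sorted_by_p_with_id_tiebreak(self):
        tab = pd.DataFrame({
            "p": [1e-4, 1e-4, 1e-5], "q": [0.01] * 3,
            "t": [5] * 3, "delta_beta": [0.2] * 3,
        }, index=["z", "a", "m"])
        assert select_signature_probes(tab) == ["m", "a", "z"]


class TestHierarchicalCluster:
    def test_duplicate_samples_merge_first(self):
        rng = np.random.default_rng(2)
        b = rng.uniform(0.1, 0.9, size=(50, 5))
        b[:, 1] = b[:, 0]
        betas = pd.DataFrame(b, columns=[f"s{i}" for i in range(5)])
        z, _ = hierarchical_cluster(betas)
        assert z[0, 2] == pytest.approx(0.0)
        assert set(z[0, :2]) == {0.0, 1.0}

    def test_sample_order_invariance(self, study):
        sig = study.truth.planted_probe_ids["shared"]
        ids = list(study.cohort.betas.columns[:40])
        b = study.cohort.betas.loc[sig, ids]
        _, lab1 = hierarchical_cluster(b)
        perm = list(reversed(ids))
        _, lab2 = hierarchical_cluster(b[perm])
        tab = pd.crosstab(lab1.loc[ids], lab2.loc[ids])
        assert (tab.gt(0).sum(axis=1) == 1).all()         # identical partition

    def test_fewer_than_two_samples_rejected(self):
        betas = pd.DataFrame(np.ones((10, 1)), columns=["only"])
        with pytest.raises(ValueError):
            hierarchical_cluster(betas)


class TestStouffer:
    @pytest.mark.parametrize("z,expected", [
        ([0.0, 0.0, 0.0], 0.0),
        ([1.96, 1.96], 2 * 1.96 / np.sqrt(2)),
        ([1.3], 1.3),
    ])
    def test_known_values(self, z, expected):
        assert stouffer_combine(z) == pytest.approx(expected, abs=1e-4)

    def test_weighted_form(self):
        z = np.array([1.0, 2.0])
        w = np.array([2.0, 1.0])
        assert stouffer_combine(z, w) == pytest.approx(4.0 / np.sqrt(5.0))

    def test_empty_and_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            stouffer_combine([])
        with pytest.raises(ValueError):
            stouffer_combine([1.0], weights=[0.0])


def _stats_table(pos, chrom, p, delta, q=None):
    idx = [f"cg{i}" for i in range(len(pos))]
    tab = pd.DataFrame({
        "p": p, "t": np.sign(delta) * sps.norm.isf(np.array(p) / 2),
        "delta_beta": delta,
        "q": q if q is not None else adjust_bh(np.asarray(p)),
    }, index=idx)
    mani = pd.DataFrame({"chrom": chrom, "pos": pos, "gene": "",
                         "island_relation": "OpenSea",
                         "sex_chromosome": False, "snp_overlap": False,
                         "cross_reactive": False}, index=idx)
    return tab, mani


class TestDetectDmrs:
    def test_gap_breaks_run(self):
        """Probes at 100/600/1100/3000, first three significant: one 3-probe
        region ending at 1100; the 1900 bp gap excludes the fourth."""
        tab, mani = _stats_table(
            [100, 600, 1100, 3000], ["chr1"] * 4,
            p=[1e-8, 1e-8, 1e-8, 0.9], delta=[0.15, 0.15, 0.15, 0.0],
            q=[1e-7, 1e-7, 1e-7, 0.9])
        out = detect_dmrs(tab, mani)
        assert len(out) == 1
        assert out.loc[0, ["start", "end", "n_probes"]].tolist() == [100, 1100, 3]

    def test_two_probe_run_rejected(self):
        tab, mani = _stats_table([100, 600, 5000], ["chr1"] * 3,
                                 p=[1e-8, 1e-8, 0.9], delta=[0.15, 0.15, 0.0],
                                 q=[1e-7, 1e-7, 0.9])
        assert detect_dmrs(tab, mani).empty

    def test_weak_mean_delta_rejected(self):
        tab, mani = _stats_table([100, 600, 1100], ["chr1"] * 3,
                                 p=[1e-8] * 3, delta=[0.08, 0.08, 0.08],
                                 q=[1e-7] * 3)
        assert detect_dmrs(tab, mani).empty

    def test_unsorted_manifest_rejected(self):
        tab, mani = _stats_table([600, 100, 1100], ["chr1"] * 3,
                                 p=[1e-8] * 3, delta=[0.15] * 3)
        with pytest.raises(ValueError):
            detect_dmrs(tab, mani)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_enumeration(self, seed):
        """On small random inputs the caller equals a from-scratch oracle
        that enumerates maximal significant runs and applies each rule."""
        rng = np.random.default_rng(seed)
        n = 120
        pos = np.cumsum(rng.integers(50, 2000, size=n))
        p = np.where(rng.random(n) < 0.4, rng.uniform(1e-10, 1e-4, n),
                     rng.uniform(0.05, 1.0, n))
        delta = rng.uniform(-0.25, 0.25, size=n)
        tab, mani = _stats_table(pos, ["chr1"] * n, p=p, delta=delta)
        out = detect_dmrs(tab, mani)

        q = tab["q"].to_numpy()
        sig = np.flatnonzero(q < 0.05)
        oracle_regions = []
        i = 0
        while i < len(sig):
            j = i
            while j + 1 < len(sig) and pos[sig[j + 1]] - pos[sig[j]] <= 1000:
                j += 1
            run = sig[i:j + 1]
            if len(run) >= 3 and abs(delta[run].mean()) > 0.10:
                zs = np.sign(delta[run]) * sps.norm.isf(p[run] / 2)
                zc = zs.sum() / np.sqrt(len(zs))
                oracle_regions.append((int(pos[run[0]]), int(pos[run[-1]]),
                                       len(run), 2 * sps.norm.sf(abs(zc))))
            i = j + 1
        if oracle_regions:
            fdr = adjust_bh(np.array([r[3] for r in oracle_regions]))
            oracle_regions = [r for r, f in zip(oracle_regions, fdr) if f < 0.05]
        expected = [(s, e, k) for s, e, k, _ in oracle_regions]
        got = list(out[["start", "end", "n_probes"]].itertuples(index=False,
                                                                name=None))
        assert got == expected
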