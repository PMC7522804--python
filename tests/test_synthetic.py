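import numpy as np
import pytest
from scipy import stats as sps

from connpredict.synthetic import (CohortConfig, SyntheticCohort,
                                   evenly_spaced_regions,
                                   make_region_table, nearest_correlation,
                                   simulate_cohort, simulate_timeseries,
                                   write_cohort)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_regions": 2}, {"n_subjects": 4},
        {"planted_regions": (0, 50), "n_regions": 40},
        {"planted_regions": (1, 1)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)


class TestScores:
    def test_moments_match_rounded_truncated_normal_oracle(self):
        mean, sd = 18.4, 2.3
        cfg = CohortConfig(n_subjects=10_000, n_regions=6, effect_size=0.0,
                           score_mean=mean, score_sd=sd, seed=3)
        y = simulate_cohort(cfg).phenotypes["psqi"].to_numpy()
        # oracle: exact moments of the normal after integer rounding and
        # clipping to [0, 21], by numerical integration over the 22 bins
        ks = np.arange(0, 22)
        lo = np.where(ks == 0, -np.inf, ks - 0.5)
        hi = np.where(ks == 21, np.inf, ks + 0.5)
        p = sps.norm.cdf(hi, mean, sd) - sps.norm.cdf(lo, mean, sd)
        m_oracle = float((ks * p).sum())
        sd_oracle = float(np.sqrt(((ks - m_oracle) ** 2 * p).sum()))
        assert y.mean() == pytest.approx(m_oracle, rel=0.02)
        assert y.std() == pytest.approx(sd_oracle, rel=0.02)
        assert y.min() >= 0 and y.max() <= 21

    def test_scores_are_integers_in_instrument_range(self, planted_cohort):
        y = planted_cohort.phenotypes["psqi"]
        assert (y == y.astype(int)).all()
        assert y.between(0, 21).all()


class TestPlantedSignal:
    def test_null_cohort_edges_independent_of_score(self):
        cfg = CohortConfig(n_subjects=200, n_regions=20, effect_size=0.0, seed=21)
        cohort = simulate_cohort(cfg)
        y = cohort.phenotypes["psqi"].to_numpy(float)
        stack = np.stack([c.values for c in cohort.connectomes])
        iu = np.triu_indices(20, k=1)
        pvals = np.array([sps.pearsonr(stack[:, i, j], y).pvalue
                          for i, j in zip(*iu)])
        # null: ~5% of edges nominally significant
        assert 0.01 < np.mean(pvals < 0.05) < 0.10

    def test_planted_edge_correlation_matches_brute_force_oracle(self):
        cfg = CohortConfig(n_subjects=200, n_regions=40,
                           planted_regions=(0, 8, 16, 24, 32),
                           effect_size=0.5, noise_sd=0.05, seed=1)
        cohort = simulate_cohort(cfg)
        y = cohort.phenotypes["psqi"].to_numpy(float)
        cors = []
        for i, j in cohort.truth["planted_edges"]:
            vals = np.array([c.values[i, j] for c in cohort.connectomes])
            cors.append(np.corrcoef(vals, y)[0, 1])
        observed = float(np.mean(cors))
        oracle = self._oracle_mean_corr(n=20_000, seed=99, cfg=cfg)
        assert observed == pytest.approx(oracle, abs=0.05)

    @staticmethod
    def _oracle_mean_corr(n, seed, cfg):
        """Independent large-n simulation with the same generative
        equations (straight-line code, including the clipped-eigenvalue
        repair applied per subject)."""
        from statsmodels.stats.correlation_tools import corr_clipped

        g = np.random.default_rng(seed)
        R = cfg.n_regions
        systems = make_region_table(R)["system"].to_numpy()
        base = np.where(systems[:, None] == systems[None, :], 0.3, 0.05)
        np.fill_diagonal(base, 1.0)
        planted = np.array(cfg.planted_regions)
        y = np.clip(np.rint(g.normal(cfg.score_mean, cfg.score_sd, n)), 0, 21)
        z = (y - y.mean()) / y.std()
        iu = np.triu_indices(R, k=1)
        pe = [(i, j) for a, i in enumerate(planted) for j in planted[a + 1:]]
        acc = np.zeros((len(pe), n))
        for s in range(n):
            noise = np.zeros((R, R))
            noise[iu] = g.normal(0, cfg.noise_sd, iu[0].size)
            noise += noise.T
            C = base + noise
            for i, j in pe:
                C[i, j] += cfg.effect_size * z[s]
                C[j, i] = C[i, j]
            np.fill_diagonal(C, 1.0)
            C = np.clip(C, -1, 1)
            if np.linalg.eigvalsh(C)[0] < -1e-10:
                C = corr_clipped(C, threshold=1e-12)
            for k, (i, j) in enumerate(pe):
                acc[k, s] = C[i, j]
        return float(np.mean([np.corrcoef(acc[k], y)[0, 1]
                              for k in range(len(pe))]))

    def test_ols_on_planted_edges_recovers_score(self):
        cfg = CohortConfig(n_subjects=100, n_regions=40,
                           planted_regions=(0, 8, 16, 24, 32),
                           effect_size=0.5, noise_sd=0.05, seed=5)
        cohort = simulate_cohort(cfg)
        y = cohort.phenotypes["psqi"].to_numpy(float)
        E = np.column_stack([[c.values[i, j] for c in cohort.connectomes]
                             for i, j in cohort.truth["planted_edges"]])
        D = np.column_stack([np.ones(len(y)), E])
        pred = D @ np.linalg.lstsq(D, y, rcond=None)[0]
        assert np.corrcoef(pred, y)[0, 1] > 0.9


class TestCohortStructure:
    def test_reproducible_bit_identical(self):
        cfg = CohortConfig(n_subjects=8, n_regions=15,
                           planted_regions=(0, 5), seed=42)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        for ca, cb in zip(a.connectomes, b.connectomes):
            np.testing.assert_array_equal(ca.values, cb.values)
        assert a.phenotypes.equals(b.phenotypes)

    def test_one_connectome_per_phenotype_row(self, planted_cohort):
        assert len(planted_cohort.connectomes) == len(planted_cohort.phenotypes)
        ids = [c.subject_id for c in planted_cohort.connectomes]
        assert ids == planted_cohort.phenotypes["subject"].tolist()

    def test_connectomes_are_valid_correlation_matrices(self, planted_cohort):
        for c in planted_cohort.connectomes:
            v = c.values
            assert np.array_equal(v, v.T)
            assert np.all(np.diag(v) == 1.0)
            assert np.all(np.abs(v) <= 1.0)
            assert np.linalg.eigvalsh(v)[0] >= -1e-8

    def test_covariates_independent_of_score(self):
        cfg = CohortConfig(n_subjects=500, n_regions=6, effect_size=0.0, seed=8)
        ph = simulate_cohort(cfg).phenotypes
        y = ph["psqi"].to_numpy(float)
        for col in ("age", "education", "ess", "motion"):
            assert abs(np.corrcoef(ph[col], y)[0, 1]) < 0.12

    def test_region_table_systems_and_planted_helper(self):
        tab = make_region_table(246)
        assert len(tab) == 246
        assert set(tab["system"]) == {"VS", "MT", "DA", "LM", "FP", "DM", "SC"}
        planted = evenly_spaced_regions(246, 10)
        assert len(planted) == 10 and len(set(planted)) == 10

    def test_write_cohort_roundtrip(self, planted_cohort, tmp_path):
        from connpredict import io
        out = write_cohort(planted_cohort, tmp_path / "cohort")
        ph = io.read_phenotypes(out / "phenotypes.csv")
        conns = io.read_connectomes(out, ph["subject"].tolist())
        np.testing.assert_allclose(conns[0].values,
                                   planted_cohort.connectomes[0].values,
                                   atol=1e-9)


class TestNearestCorrelation:
    @pytest.mark.filterwarnings("ignore")
    def test_agrees_with_statsmodels_reference(self, rng):
        from statsmodels.stats.correlation_tools import corr_nearest
        A = np.clip(rng.uniform(-1, 1, (8, 8)), -1, 1)
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        ours, _ = nearest_correlation(A, tol=1e-10, max_iter=500)
        ref = corr_nearest(A, threshold=1e-10, n_fact=200)
        np.testing.assert_allclose(ours, ref, atol=1e-4)
        assert np.linalg.eigvalsh(ours)[0] >= -1e-8

    def test_already_valid_matrix_unchanged(self, rng):
        from conftest import random_correlation
        C = random_correlation(rng, 6)
        out, n_iter = nearest_correlation(C)
        np.testing.assert_allclose(out, C, atol=1e-7)


class TestTimeseries:
    def _single_subject(self, C):
        from connpredict.features import ConnectivityMatrix
        import pandas as pd
        cm = ConnectivityMatrix("sub-000", C)
        ph = pd.DataFrame({"subject": ["sub-000"], "psqi": [15]})
        return SyntheticCohort([cm], ph, make_region_table(C.shape[0]), {})

    def test_identity_target_gives_independent_series(self):
        cohort = self._single_subject(np.eye(6))
        simulate_timeseries(cohort, 100_000, seed=1)
        emp = np.corrcoef(cohort.timeseries[0], rowvar=False)
        off = emp[np.triu_indices(6, k=1)]
        assert np.all(np.abs(off) < 0.02)

    def test_forced_pair_correlation_recovered(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.8
        cohort = self._single_subject(C)
        simulate_timeseries(cohort, 50_000, seed=2)
        emp = np.corrcoef(cohort.timeseries[0], rowvar=False)
        assert emp[0, 1] == pytest.approx(0.8, abs=0.02)
        assert abs(emp[0, 2]) < 0.02 and abs(emp[1, 2]) < 0.02

    def test_fisher_z_sampling_variance(self, rng):
        """Across repeated draws at T=200, var(atanh r) ~ 1/(T-3)."""
        from conftest import random_correlation
        C = random_correlation(rng, 5)
        T = 200
        devs = []
        for rep in range(300):
            cohort = self._single_subject(C)
            simulate_timeseries(cohort, T, seed=rep)
            emp = np.corrcoef(cohort.timeseries[0], rowvar=False)
            devs.append(np.arctanh(emp[0, 1]) - np.arctanh(C[0, 1]))
        ratio = np.var(devs) * (T - 3)
        assert 0.7 < ratio < 1.35
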