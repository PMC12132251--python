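"""Synthetic-cohort generator: determinism, planted truth, oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lungmeth import methio, synthdata
from lungmeth.evaluation import ols_slope


class TestCohortConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_samples", 5),
            ("n_cpgs", 3),
            ("frac_causal", 1.5),
            ("noise_sd", 0.0),
            ("frac_sex_divergent", -0.1),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        cfg = synthdata.CohortConfig(cohort_id="X", n_samples=50, n_cpgs=100)
        bad = synthdata.CohortConfig(**{**cfg.__dict__, field: value})
        with pytest.raises(synthdata.ConfigError, match=field):
            bad.validate()


class TestGenerateCohort:
    def test_seeded_determinism(self):
        cfg = synthdata.CohortConfig(
            cohort_id="D", n_samples=50, n_cpgs=100, frac_causal=0.1, seed=7
        )
        b1, s1, t1 = synthdata.generate_cohort(cfg)
        b2, s2, t2 = synthdata.generate_cohort(cfg)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_beta_values_in_open_interval(self, small_cohort):
        beta, _, _ = small_cohort
        arr = beta.to_numpy()
        assert (arr > 0).all() and (arr < 1).all()

    def test_no_nan_in_emitted_tables(self, small_cohort):
        beta, samples, truth = small_cohort
        assert not beta.isna().any().any()
        assert not truth.isna().any().any()
        assert not samples.drop(columns="gestational_age").isna().any().any()

    def test_truth_conservation(self):
        for frac in (0.0, 0.05, 0.2):
            cfg = synthdata.CohortConfig(
                cohort_id="C", n_samples=30, n_cpgs=200, frac_causal=frac, seed=3
            )
            _, _, truth = synthdata.generate_cohort(cfg)
            assert truth["is_causal"].sum() == round(frac * 200)

    def test_null_cohort_has_zero_effects(self):
        cfg = synthdata.CohortConfig(
            cohort_id="N", n_samples=40, n_cpgs=50, frac_causal=0.0, seed=5
        )
        beta, samples, truth = synthdata.generate_cohort(cfg)
        assert (truth[["effect_all", "effect_female", "effect_male"]] == 0).all().all()
        # outcome independent of methylation: per-CpG correlations small
        m = methio.beta_to_m(beta).to_numpy()
        y = samples["FEV1"].to_numpy()
        r = np.array([np.corrcoef(m[i], y)[0, 1] for i in range(m.shape[0])])
        assert np.abs(r).max() < 0.6  # no planted structure at n=40

    def test_causal_slopes_match_planted_mean(self):
        """Brute-force OLS refit oracle: causal slopes average to effect_mean."""
        cfg = synthdata.CohortConfig(
            cohort_id="O", n_samples=2000, n_cpgs=150, frac_causal=0.1,
            effect_mean=0.5, effect_sd=0.05, noise_sd=0.5, seed=13,
        )
        beta, samples, truth = synthdata.generate_cohort(cfg)
        m = methio.beta_to_m(beta)
        y = samples["FEV1"].to_numpy()
        causal = truth.loc[truth["is_causal"] & (truth["outcome"] == "FEV1"), "cpg_id"]
        slopes = [ols_slope(y, m.loc[c].to_numpy())[0] for c in causal]
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.06)

    def test_divergent_flip_is_exact(self):
        cfg = synthdata.CohortConfig(
            cohort_id="V", n_samples=30, n_cpgs=100, frac_causal=0.2,
            frac_sex_divergent=0.5, seed=2,
        )
        _, _, truth = synthdata.generate_cohort(cfg)
        div = truth[truth["is_divergent"]]
        assert len(div) == round(0.5 * 20)
        assert (div["effect_male"] == -div["effect_female"]).all()
        assert (div["effect_female"] != 0).all()
        assert (div["effect_all"] == 0).all()

    def test_birth_cohort_uses_gestational_age(self):
        cfg = synthdata.CohortConfig(
            cohort_id="B", n_samples=30, n_cpgs=20, birth_cohort=True, seed=1
        )
        _, samples, _ = synthdata.generate_cohort(cfg)
        assert (samples["age"] == 0).all()
        assert samples["gestational_age"].between(30, 43).all()

    def test_cell_proportions_are_compositional(self, small_cohort):
        _, samples, _ = small_cohort
        cells = samples[[c for c in samples.columns if c.startswith("cell_")]]
        assert (cells >= 0).all().all()
        np.testing.assert_allclose(cells.sum(axis=1), 1.0, atol=1e-9)


class TestMultiCohort:
    def _configs(self, n=3, n_cpgs=1000, frac=0.1):
        return [
            synthdata.CohortConfig(
                cohort_id=f"C{i}", n_samples=40, n_cpgs=n_cpgs, frac_causal=frac, seed=i + 1
            )
            for i in range(n)
        ]

    def test_full_sharing_aligns_signs_everywhere(self):
        res = synthdata.generate_multi_cohort(self._configs(), shared_truth_frac=1.0)
        truths = [t.set_index("cpg_id") for _, _, t in res]
        causal = truths[0][truths[0]["is_causal"]].index
        for c in causal:
            signs = {np.sign(t.at[c, "effect_all"]) or np.sign(t.at[c, "effect_female"]) for t in truths}
            assert len(signs) == 1

    def test_zero_sharing_gives_disjoint_causal_sets(self):
        res = synthdata.generate_multi_cohort(self._configs(), shared_truth_frac=0.0)
        sets = [set(t.loc[t["is_causal"], "cpg_id"]) for _, _, t in res]
        assert sets[0] & sets[1] == set()
        assert sets[0] & sets[2] == set()
        assert sets[1] & sets[2] == set()

    def test_half_sharing_counts(self):
        res = synthdata.generate_multi_cohort(self._configs(frac=0.1), shared_truth_frac=0.5)
        sets = [set(t.loc[t["is_causal"], "cpg_id"]) for _, _, t in res]
        shared = sets[0] & sets[1] & sets[2]
        assert len(shared) == 50  # 0.5 x 100 causal
        for s in sets:
            assert len(s) == 100

    def test_mismatched_n_cpgs_rejected(self):
        configs = self._configs()
        configs[1] = synthdata.CohortConfig(cohort_id="C1", n_samples=40, n_cpgs=999, seed=2)
        with pytest.raises(synthdata.ConfigError, match="n_cpgs"):
            synthdata.generate_multi_cohort(configs)

    def test_planted_region_runs_stay_within_clusters(self):
        res = synthdata.generate_multi_cohort(self._configs(n_cpgs=2000), shared_truth_frac=1.0)
        truth = res[0][2]
        idx = sorted(int(c[2:]) for c in truth.loc[truth["is_causal"], "cpg_id"])
        runs, cur = [], [idx[0]]
        for a, b in zip(idx, idx[1:]):
            if b == a + 1:
                cur.append(b)
            else:
                runs.append(cur)
                cur = [b]
        runs.append(cur)
        long_runs = [r for r in runs if len(r) >= 4]
        assert long_runs, "expected at least one planted contiguous causal run"
        # at least one long run sits wholly inside a spacing cluster (no member
        # after the first opens a new cluster); scattered picks can also land
        # adjacent by chance, so not every long run needs to qualify
        assert any(
            all(j % synthdata.CLUSTER_PERIOD != 0 for j in run[1:]) for run in long_runs
        )


class TestGgmData:
    def test_truth_adjacency_matches_structure(self):
        f = synthdata.PrecisionSpec(6, "star", 0.3, "female")
        m = synthdata.PrecisionSpec(6, "chain", 0.3, "male")
        _, _, truth = synthdata.generate_ggm_data(f, m, 10, seed=0)
        star = truth["female"].to_numpy()
        chain = truth["male"].to_numpy()
        assert star[0].sum() == 5 and star[1:, 1:].sum() == 0
        assert (np.diag(chain, 1) == 1).all() and chain.sum() == 2 * 5

    def test_empirical_partial_correlations(self):
        """Matrix-inversion oracle: invert the empirical covariance."""
        f = synthdata.PrecisionSpec(10, "chain", 0.4, "female")
        m = synthdata.PrecisionSpec(10, "chain", 0.4, "male")
        data, _, _ = synthdata.generate_ggm_data(f, m, 5000, seed=4)
        prec = np.linalg.inv(np.cov(data.to_numpy().T))
        d = np.sqrt(np.diag(prec))
        pc = -prec / np.outer(d, d)
        off = np.array([pc[i, i + 1] for i in range(9)])
        assert np.abs(off - 0.4).max() < 0.05

    def test_identical_specs_give_identical_strata(self):
        f = synthdata.PrecisionSpec(8, "chain", 0.3, "female")
        m = synthdata.PrecisionSpec(8, "chain", 0.3, "male")
        data_f, data_m, _ = synthdata.generate_ggm_data(f, m, 50, seed=9)
        np.testing.assert_array_equal(data_f.to_numpy(), data_m.to_numpy())

    def test_non_positive_definite_rejected(self):
        # star with rho > 1/sqrt(p-1) is indefinite
        f = synthdata.PrecisionSpec(20, "star", 0.5, "female")
        m = synthdata.PrecisionSpec(20, "chain", 0.3, "male")
        with pytest.raises(synthdata.ConfigError, match="positive definite"):
            synthdata.generate_ggm_data(f, m, 10, seed=0)


class TestPrs:
    def test_requested_correlation_attained(self, ):
        cfg = synthdata.CohortConfig(cohort_id="P", n_samples=5000, n_cpgs=10, seed=21)
        _, samples, _ = synthdata.generate_cohort(cfg)
        prs = synthdata.generate_prs(samples, 0.3, seed=8)
        r = np.corrcoef(prs["prs_asthma"], samples["FEV1"])[0, 1]
        assert 0.25 <= r <= 0.35

    def test_zero_correlation_near_zero(self):
        cfg = synthdata.CohortConfig(cohort_id="P0", n_samples=1000, n_cpgs=10, seed=22)
        _, samples, _ = synthdata.generate_cohort(cfg)
        prs = synthdata.generate_prs(samples, 0.0, seed=9)
        assert abs(np.corrcoef(prs["prs_asthma"], samples["FEV1"])[0, 1]) < 0.1

    def test_seeded_determinism(self, small_cohort):
        _, samples, _ = small_cohort
        p1 = synthdata.generate_prs(samples, 0.2, seed=3)
        p2 = synthdata.generate_prs(samples, 0.2, seed=3)
        pd.testing.assert_frame_equal(p1, p2)

    def test_unit_correlation_rejected(self, small_cohort):
        _, samples, _ = small_cohort
        with pytest.raises(ValueError, match="correlation"):
            synthdata.generate_prs(samples, 1.0, seed=0)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            synthdata.generate_prs(pd.DataFrame({"sample_id": [], "FEV1": []}), 0.1)


def test_null_cohort_pvalues_uniform():
    """Null calibration: EWAS p-values on a causal-free cohort are Uniform(0,1)."""
    from lungmeth import ewas

    cfg = synthdata.CohortConfig(
        cohort_id="U", n_samples=300, n_cpgs=4000, frac_causal=0.0, seed=31
    )
    beta, samples, _ = synthdata.generate_cohort(cfg)
    scan = ewas.run_ewas(methio.beta_to_m(beta), samples, "FEV1", covariates=["sex", "age"])
    ks = stats.kstest(scan["p"], "uniform")
    assert ks.pvalue > 0.01
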