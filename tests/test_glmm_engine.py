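"""Gibbs engine: oracle equivalence, link inverses, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from transplantqg import glmm_engine as ge


def halfsib_gaussian(n_sires, n_off, v_sire, v_res, seed):
    rng = np.random.default_rng(seed)
    fx = rng.normal(0, np.sqrt(v_sire), n_sires)
    sire = np.repeat(np.arange(n_sires), n_off)
    y = fx[sire] + rng.normal(0, np.sqrt(v_res), n_sires * n_off)
    return pd.DataFrame({"y": y, "sire": [f"s{i}" for i in sire]})


def anova_sire_variance(df, n_off):
    """Expected-mean-squares estimator (MS_sire - MS_within) / n_off."""
    g = df.groupby("sire")["y"]
    means = g.mean()
    ms_sire = n_off * means.var(ddof=1)
    ms_within = ((df["y"] - df["sire"].map(means)) ** 2).sum() / (
        df["sire"].nunique() * (n_off - 1))
    return (ms_sire - ms_within) / n_off


class TestGaussian:
    def test_exact_interpolation_fixed_only(self):
        # response [0, 1] on covariate [0, 1]: slope -> 1, intercept -> 0
        reps = 50
        y = np.tile([0.0, 1.0], reps)
        X = np.column_stack([np.ones(2 * reps), np.tile([0.0, 1.0], reps)])
        post = ge.fit_mixed(
            y, np.zeros_like(y, int), ["gaussian"], ["y"], X,
            ["intercept", "slope"], [], ge.MCMCConfig(200, 1, 300, rng_seed=0),
        )
        assert abs(post.fixed[:, 1].mean() - 1.0) < 0.05
        assert abs(post.fixed[:, 0].mean() - 0.0) < 0.05

    def test_halfsib_matches_anova_oracle(self, fast_cfg):
        df = halfsib_gaussian(100, 30, 0.25, 1.0, seed=12)
        spec = ge.ModelSpec("y", "gaussian",
                            random_terms=[ge.RandomTerm("sire")])
        post = ge.fit_gaussian_mixed(df, spec, fast_cfg.with_(n_burnin=400,
                                                              n_saved=400))
        anova = anova_sire_variance(df, 30)
        post_mean = post.random_cov["sire"].mean()
        # the ANOVA estimator's own sampling SD at this design
        mc_sd = np.sqrt(2 / 100) * (0.25 + 1.0 / 30)
        assert abs(post_mean - anova) < 3 * mc_sd

    def test_permuted_labels_collapse_sire_variance(self, fast_cfg):
        df = halfsib_gaussian(80, 20, 0.5, 1.0, seed=5)
        spec = ge.ModelSpec("y", "gaussian",
                            random_terms=[ge.RandomTerm("sire")])
        post = ge.fit_gaussian_mixed(df, spec, fast_cfg)
        rng = np.random.default_rng(0)
        shuffled = df.copy()
        shuffled["sire"] = rng.permutation(shuffled["sire"].to_numpy())
        post_null = ge.fit_gaussian_mixed(shuffled, spec, fast_cfg)
        q05 = np.quantile(post.random_cov["sire"], 0.05)
        assert post_null.random_cov["sire"].mean() < q05

    def test_rank_deficient_design_names_aliased(self):
        y = np.arange(6, dtype=float)
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="aliased.*x2"):
            ge.fit_mixed(y, np.zeros(6, int), ["gaussian"], ["y"], X,
                         ["int", "x1", "x2"], [], ge.MCMCConfig(10, 1, 10))


class TestProbit:
    def test_intercept_recovers_link_inverse(self):
        rng = np.random.default_rng(3)
        for p in (0.5, 0.8):
            y = (rng.random(5000) < p).astype(float)
            df = pd.DataFrame({"y": y})
            post = ge.fit_probit_mixed(
                df, ge.ModelSpec("y", "binary_probit"),
                ge.MCMCConfig(200, 1, 300, rng_seed=1))
            target = norm.ppf(y.mean())
            assert abs(post.fixed.mean() - target) < 0.08

    def test_sire_liability_variance_recovery(self):
        # 200 sires x 40 obs, liability sire variance 0.5; posterior mean
        # within +/-30% of truth averaged over 5 seeds
        estimates = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            fx = rng.normal(0, np.sqrt(0.5), 200)
            sire = np.repeat(np.arange(200), 40)
            liab = fx[sire] + rng.standard_normal(200 * 40)
            df = pd.DataFrame({"y": (liab > 0).astype(float),
                               "sire": [f"s{i}" for i in sire]})
            post = ge.fit_probit_mixed(
                df, ge.ModelSpec("y", "binary_probit",
                                 random_terms=[ge.RandomTerm("sire")]),
                ge.MCMCConfig(400, 2, 300, rng_seed=seed))
            estimates.append(post.random_cov["sire"].mean())
        assert abs(np.mean(estimates) - 0.5) < 0.15

    def test_single_class_response_rejected(self):
        df = pd.DataFrame({"y": np.ones(50)})
        with pytest.raises(ValueError, match="single observed class"):
            ge.fit_probit_mixed(df, ge.ModelSpec("y", "binary_probit"),
                                ge.MCMCConfig(10, 1, 10))

    def test_augmentation_consistency_with_latent_gaussian(self):
        # the probit fit of thresholded liabilities agrees with the
        # gaussian fit of the liabilities themselves on the variance ratio
        rng = np.random.default_rng(8)
        fx = rng.normal(0, np.sqrt(0.6), 150)
        sire = np.repeat(np.arange(150), 30)
        liab = fx[sire] + rng.standard_normal(150 * 30)
        df = pd.DataFrame({"liab": liab, "y": (liab > 0).astype(float),
                           "sire": [f"s{i}" for i in sire]})
        cfg = ge.MCMCConfig(300, 1, 300, rng_seed=2)
        g = ge.fit_gaussian_mixed(
            df, ge.ModelSpec("liab", "gaussian",
                             random_terms=[ge.RandomTerm("sire")]), cfg)
        p = ge.fit_probit_mixed(
            df, ge.ModelSpec("y", "binary_probit",
                             random_terms=[ge.RandomTerm("sire")]), cfg)
        v_g = g.random_cov["sire"].mean() / g.resid_var.mean()
        v_p = p.random_cov["sire"].mean()
        assert abs(v_g - v_p) < 0.15


class TestBivariate:
    @staticmethod
    def simulate(corr, seed, n_sires=80, n_off=12):
        rng = np.random.default_rng(seed)
        cov = np.array([[4.0, corr * np.sqrt(4.0 * 0.5)],
                        [corr * np.sqrt(4.0 * 0.5), 0.5]])
        fx = rng.multivariate_normal([0, 0], cov, n_sires)
        sire = np.repeat(np.arange(n_sires), n_off)
        dev = 40 + fx[sire, 0] + rng.normal(0, 2, sire.size)
        liab = fx[sire, 1] + rng.standard_normal(sire.size)
        df = pd.DataFrame({"dev_time": dev, "survived": (liab > 0).astype(float),
                           "sire": [f"s{i}" for i in sire],
                           "family": [f"s{i}" for i in sire]})
        # a third of individuals lack the gaussian trait
        df.loc[df.index % 3 == 0, "dev_time"] = np.nan
        return df

    def test_negative_sire_correlation_sign_recovered(self, fast_cfg):
        signs = []
        for seed in range(5):
            df = self.simulate(-0.9, seed)
            post = ge.fit_bivariate_mixed(
                df, "dev_time", "survived",
                [ge.RandomTerm("sire", "unstructured")],
                fast_cfg.with_(n_burnin=300, rng_seed=seed))
            S = post.random_cov["sire"]
            r = S[:, 0, 1] / np.sqrt(S[:, 0, 0] * S[:, 1, 1])
            signs.append(r.mean() < 0)
        assert sum(signs) >= 4

    def test_cov2cor_identity(self):
        c = ge.cov2cor(np.array([[4.0, 2.0], [2.0, 4.0]]))
        assert np.allclose(c, [[1.0, 0.5], [0.5, 1.0]])

    def test_no_joint_observation_rejected(self):
        df = self.simulate(0.0, 0)
        df.loc[df["dev_time"].notna(), "survived"] = np.nan
        df = df.dropna(subset=["dev_time", "survived"], how="all")
        with pytest.raises(ValueError, match="both responses"):
            ge.fit_bivariate_mixed(df, "dev_time", "survived",
                                   [ge.RandomTerm("sire", "unstructured")],
                                   ge.MCMCConfig(10, 1, 10))


class TestInvariants:
    def test_covariance_draws_psd_and_correlations_bounded(self, small_dataset,
                                                           fast_cfg):
        df = small_dataset[small_dataset["established"] == 1]
        spec = ge.ModelSpec("dev_time", "gaussian", fixed_terms=["elevation"],
                            random_terms=[ge.RandomTerm("sire", "unstructured"),
                                          ge.RandomTerm("family", "diagonal")],
                            environment_factor="elevation")
        post = ge.fit_gaussian_mixed(df, spec, fast_cfg)
        for S in post.random_cov["sire"]:
            w = np.linalg.eigvalsh(S)
            assert w.min() > -1e-9
            corr = ge.cov2cor(S)
            assert np.allclose(np.diag(corr), 1.0)
            off = corr[~np.eye(4, dtype=bool)]
            assert (np.abs(off) <= 1.0 + 1e-9).all()
        assert (post.random_cov["family"] >= 0).all()

    def test_chain_reproducibility_and_seed_independence(self, fast_cfg):
        df = halfsib_gaussian(60, 20, 0.4, 1.0, seed=2)
        spec = ge.ModelSpec("y", "gaussian",
                            random_terms=[ge.RandomTerm("sire")])
        a = ge.fit_gaussian_mixed(df, spec, fast_cfg.with_(rng_seed=5))
        b = ge.fit_gaussian_mixed(df, spec, fast_cfg.with_(rng_seed=5))
        c = ge.fit_gaussian_mixed(df, spec, fast_cfg.with_(rng_seed=6,
                                                            n_saved=400))
        assert np.array_equal(a.random_cov["sire"], b.random_cov["sire"])
        assert not np.array_equal(a.random_cov["sire"][:10],
                                  c.random_cov["sire"][:10])
        assert abs(a.random_cov["sire"].mean()
                   - c.random_cov["sire"].mean()) < 0.12

    def test_parameter_expansion_gives_consistent_posterior(self, fast_cfg):
        df = halfsib_gaussian(80, 20, 0.4, 1.0, seed=3)
        spec = ge.ModelSpec("y", "gaussian",
                            random_terms=[ge.RandomTerm("sire")])
        plain = ge.fit_gaussian_mixed(df, spec, fast_cfg.with_(n_saved=400))
        px = ge.fit_gaussian_mixed(
            df, spec, fast_cfg.with_(n_saved=400, parameter_expansion=True))
        assert abs(plain.random_cov["sire"].mean()
                   - px.random_cov["sire"].mean()) < 0.12
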