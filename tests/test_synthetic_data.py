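"""Breeding-design generator: pedigree structure, seed allocation, traits."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from transplantqg import synthetic_data as sd


class TestGeneratePedigree:
    def test_minimal_design_single_family(self):
        d = sd.DesignSpec(n_sires=1, n_dams=1, mating_block_size=1,
                          elevations=("500",), n_field_blocks=1)
        ped = sd.generate_pedigree(d, seed=0)
        assert len(ped) == 1
        assert ped.loc[0, "sire"] != ped.loc[0, "dam"]

    def test_factorial_block_structure(self):
        d = sd.DesignSpec(n_sires=9, n_dams=9)
        ped = sd.generate_pedigree(d, seed=0)
        assert len(ped) == 27  # 3 blocks x 3x3 crosses
        for _, blk in ped.groupby("mating_block"):
            assert blk["sire"].nunique() == 3
            assert blk["dam"].nunique() == 3
            assert len(blk) == 9  # every sire crossed to every dam
        # a (sire, dam) pair appears at most once
        assert not ped.duplicated(["sire", "dam"]).any()
        # each family pairs one sire and one dam
        assert ped["family"].is_unique

    def test_partial_last_block_and_subset_retention(self):
        # 36 sires -> 12 blocks of 3; 35 dams -> last block has 2 dams;
        # retaining 94 of the candidate crosses gives the smaller species'
        # family count
        d = sd.DesignSpec(n_sires=36, n_dams=35, n_families=94)
        ped = sd.generate_pedigree(d, seed=3)
        assert len(ped) == 94
        assert ped["sire"].nunique() <= 36
        assert ped["dam"].nunique() <= 35

    def test_36_sires_three_dams_each_candidate_count(self):
        d = sd.DesignSpec(n_sires=36, n_dams=36)
        ped = sd.generate_pedigree(d, seed=0)
        assert len(ped) == 108
        assert (ped.groupby("sire").size() == 3).all()

    def test_impossible_partition_raises(self):
        d = sd.DesignSpec(n_sires=6, n_dams=12)
        with pytest.raises(ValueError, match="mating blocks"):
            sd.generate_pedigree(d, seed=0)

    def test_requesting_too_many_families_raises(self):
        d = sd.DesignSpec(n_sires=3, n_dams=3, n_families=10)
        with pytest.raises(ValueError, match="candidate crosses"):
            sd.generate_pedigree(d, seed=0)


class TestAllocateSeeds:
    def test_full_design_per_site_and_block_counts(self):
        d = sd.DesignSpec(n_sires=36, n_dams=36)  # 108 families
        tab = sd.allocate_seeds(sd.generate_pedigree(d, 1), d, seed=2)
        per_site = tab.groupby("elevation").size()
        assert (per_site == 2700).all()
        per_block = tab.groupby(["elevation", "block"]).size()
        assert (per_block == 540).all()

    def test_shortfall_design_per_site_count(self):
        d = sd.DesignSpec(n_sires=36, n_dams=35, n_families=94,
                          family_shortfalls=((4, 10), (8, 15), (10, 20)))
        tab = sd.allocate_seeds(sd.generate_pedigree(d, 1), d, seed=2)
        assert (tab.groupby("elevation").size() == 2160).all()
        # shortfall overrides hit disjoint subsets: counts per family are
        # one of the stated values
        per_fam = tab.groupby(["family", "elevation"]).size()
        assert set(per_fam.unique()) == {10, 15, 20, 25}

    def test_even_split_single_family(self):
        d = sd.DesignSpec(n_sires=1, n_dams=1, mating_block_size=1,
                          seeds_per_family_per_elevation=5, n_field_blocks=5,
                          elevations=("500",))
        tab = sd.allocate_seeds(sd.generate_pedigree(d, 0), d, seed=0)
        assert (tab.groupby("block").size() == 1).all()

    def test_shortfall_exceeding_default_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            sd.DesignSpec(family_shortfalls=((2, 30),))

    def test_conservation_total_seeds(self, small_design):
        ped = sd.generate_pedigree(small_design, 5)
        tab = sd.allocate_seeds(ped, small_design, 5)
        expect = len(ped) * small_design.seeds_per_family_per_elevation * len(
            small_design.elevations)
        assert len(tab) == expect

    def test_reproducible_byte_for_byte(self, small_design):
        ped = sd.generate_pedigree(small_design, 5)
        bufs = []
        for _ in range(2):
            tab = sd.allocate_seeds(ped, small_design, seed=11)
            buf = io.StringIO()
            tab.to_csv(buf, index=False)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]


class TestSimulateTraits:
    def test_degenerate_parameters_exact_means(self):
        d = sd.DesignSpec(n_sires=3, n_dams=3, elevations=("500",),
                          seeds_per_family_per_elevation=400, n_field_blocks=2)
        params = sd.GroundTruthParams(
            elevations=("500",), elevation_means_devtime=(40.0,),
            devtime_sd_residual=0.0, emergence_prob=(1.0,),
            establishment_prob=(1.0,), survival_liability_intercepts=(0.0,),
            sire_cov=np.zeros((2, 2)), dam_var_devtime=0.0,
            dam_var_survival=0.0, block_var_devtime=0.0,
            block_var_survival=0.0)
        df = sd.simulate_dataset(d, params, seed=0)
        assert np.allclose(df["dev_time"], 40.0)
        # survival frequency ~ Phi(0) = 0.5, binomial error at n=3600
        p = df["survived"].mean()
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / len(df))

    def test_probit_integral_closed_form(self):
        # liability intercept mu with sire+dam+block variance V+W:
        # P(survive) = Phi(mu / sqrt(1 + V + W))
        mu, V, W = 0.8, 0.5, 0.3
        d = sd.DesignSpec(n_sires=60, n_dams=60, elevations=("500",),
                          seeds_per_family_per_elevation=112, n_field_blocks=4)
        params = sd.GroundTruthParams(
            elevations=("500",), elevation_means_devtime=(40.0,),
            emergence_prob=(1.0,), establishment_prob=(1.0,),
            survival_liability_intercepts=(mu,),
            sire_cov=np.diag([0.0, V]), dam_genetic=False,
            dam_var_survival=W / 2, block_var_survival=W / 2,
            dam_var_devtime=0.0, block_var_devtime=0.0)
        df = sd.simulate_dataset(d, params, seed=1)
        assert len(df) >= 20_000
        expect = ndtr(mu / np.sqrt(1 + V + W))
        se = np.sqrt(expect * (1 - expect) / len(df))
        # group structure inflates the error beyond binomial; allow for the
        # design effect of 180 sire and 180 dam groups
        assert abs(df["survived"].mean() - expect) < 10 * se

    def test_sire_effect_covariance_recovery(self):
        # with zero dam/block/residual variance and guaranteed
        # establishment, dev_time - elevation mean IS the sire effect, so
        # the sample covariance of the realized per-sire effect vectors
        # must match the dev-time block of sire_cov within sampling error
        dev_cov = sd.exchangeable_cov(4.0, 0.5, 4)
        cov = sd.sire_cov_from_blocks(dev_cov, sd.exchangeable_cov(0.4, 0.3, 4))
        params = sd.GroundTruthParams(
            sire_cov=cov, devtime_sd_residual=0.0, dam_genetic=False,
            emergence_prob=(1.0,) * 4, establishment_prob=(1.0,) * 4,
            dam_var_devtime=0.0, block_var_devtime=0.0)
        d = sd.DesignSpec(n_sires=501, n_dams=501,
                          seeds_per_family_per_elevation=1, n_field_blocks=1)
        df = sd.simulate_dataset(d, params, seed=2)
        means = {e: m for e, m in zip(params.elevations,
                                      params.elevation_means_devtime)}
        df["fx"] = df["dev_time"] - df["elevation"].map(means)
        wide = df.pivot_table(index="sire", columns="elevation", values="fx")
        wide = wide[list(params.elevations)]
        est = np.cov(wide.to_numpy().T)
        # element-wise Monte-Carlo tolerance ~ Var/sqrt(n_sires)
        assert np.max(np.abs(est - dev_cov)) < 4 * 4.0 / np.sqrt(501) + 0.3

    def test_nonpsd_sire_cov_rejected_at_construction(self):
        bad = np.eye(8)
        bad[0, 1] = bad[1, 0] = 2.0
        with pytest.raises(ValueError, match="positive semi-definite"):
            sd.GroundTruthParams(sire_cov=bad)

    def test_conditioning_invariants(self, small_dataset):
        df = small_dataset
        est = df[df["established"] == 1]
        assert est["dev_time"].notna().all()
        assert (est["emerged"] == 1).all()
        assert df.loc[df["established"] == 0, "dev_time"].isna().all()
        assert df.loc[df["emerged"] == 0, "survived"].isna().all()
        assert df.loc[df["emerged"] == 1, "survived"].notna().all()

    def test_reproducibility_and_seed_sensitivity(self, small_design, gxe_params):
        a = sd.simulate_dataset(small_design, gxe_params, seed=9)
        b = sd.simulate_dataset(small_design, gxe_params, seed=9)
        c = sd.simulate_dataset(small_design, gxe_params, seed=10)
        pd.testing.assert_frame_equal(a, b)
        assert not a["emerged"].equals(c["emerged"])


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1),
       n_parents=st.integers(3, 9),
       seeds_per_family=st.integers(1, 6))
def test_simulation_invariants_property(seed, n_parents, seeds_per_family):
    """Conservation and conditioning hold for any seed and small design."""
    d = sd.DesignSpec(n_sires=n_parents, n_dams=n_parents,
                      seeds_per_family_per_elevation=seeds_per_family,
                      elevations=("500", "2000"), n_field_blocks=2)
    params = sd.GroundTruthParams(
        elevations=("500", "2000"), elevation_means_devtime=(30.0, 50.0),
        emergence_prob=(0.7, 0.7), establishment_prob=(0.8, 0.8),
        survival_liability_intercepts=(0.0, 0.0), sire_cov=np.eye(4) * 0.2)
    df = sd.simulate_dataset(d, params, seed)
    ped = sd.generate_pedigree(d, seed)
    assert len(df) % len(params.elevations) == 0
    assert df["family"].nunique() == len(ped)
    assert (df["dev_time"].notna() == (df["established"] == 1)).all()


def test_csv_roundtrip(tmp_path, small_dataset):
    path = tmp_path / "trials.csv"
    sd.write_trials_csv(small_dataset, path)
    header = path.read_text().splitlines()[0]
    assert header == ",".join(sd.CSV_COLUMNS)
    back = sd.read_trials_csv(path)
    assert len(back) == len(small_dataset)
    assert back["dev_time"].isna().sum() == small_dataset["dev_time"].isna().sum()


def test_devtime_means_converge_per_elevation(small_design):
    params = sd.GroundTruthParams()  # all genetic variances zero
    big = sd.DesignSpec(n_sires=30, n_dams=30,
                        seeds_per_family_per_elevation=15)
    df = sd.simulate_dataset(big, params, seed=4)
    got = df.groupby("elevation", sort=False)["dev_time"].mean()
    for elev, mean in zip(params.elevations, params.elevation_means_devtime):
        n = df[(df["elevation"] == elev) & df["dev_time"].notna()].shape[0]
        tol = 4 * np.sqrt((params.devtime_sd_residual**2
                           + params.dam_var_devtime
                           + params.block_var_devtime) / n) + 1.0
        assert abs(got[elev] - mean) < tol
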