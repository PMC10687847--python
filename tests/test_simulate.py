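"""Synthetic-data generator: structure, reproducibility, statistical fidelity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import duelfit as dfit
from duelfit.simulate import constrained_block


class TestScsTransform:
    def test_reference_count_maps_to_three(self):
        assert dfit.scs_transform(100_000) == pytest.approx(3.0)

    @given(st.floats(min_value=1e3, max_value=1e8))
    @settings(deadline=None)
    def test_doubling_adds_one_point(self, scc):
        assert dfit.scs_transform(2 * scc) - dfit.scs_transform(scc) == (
            pytest.approx(1.0)
        )

    def test_halving_subtracts_one(self):
        assert dfit.scs_transform(50_000) == pytest.approx(2.0)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            dfit.scs_transform(0.0)


class TestPedigreeSimulation:
    def test_zero_generations_gives_founders(self):
        ped = dfit.simulate_pedigree(10, 0, seed=1)
        assert len(ped) == 10 and ped.is_founder.all()

    def test_one_generation_full_sibs(self):
        ped = dfit.simulate_pedigree(2, 1, offspring_per_pair=3, seed=4)
        kids = ~ped.is_founder
        assert kids.sum() >= 1
        sires = set(ped.sire[kids])
        dams = set(ped.dam[kids])
        assert len(sires) == 1 and len(dams) == 1  # all full sibs

    def test_parents_born_before_offspring(self):
        ped = dfit.simulate_pedigree(100, 5, seed=7)
        for i in range(len(ped)):
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0:
                    assert ped.birth_year[p] < ped.birth_year[i]

    def test_too_few_founders_rejected(self):
        with pytest.raises(ValueError):
            dfit.simulate_pedigree(1, 1, seed=0)


class TestBreedingValues:
    def test_zero_g_gives_zero_bv(self, random_pedigree):
        bv = dfit.simulate_breeding_values(random_pedigree, np.zeros((3, 3)), seed=0)
        assert (bv.to_numpy() == 0).all()

    def test_founder_covariance_approaches_g(self):
        ped = dfit.simulate_pedigree(4000, 0, seed=2)
        bv = dfit.simulate_breeding_values(ped, np.eye(3), seed=3)
        cov = np.cov(bv.to_numpy().T)
        assert np.allclose(cov, np.eye(3), atol=0.12)

    def test_stacked_covariance_matches_kronecker_oracle(self):
        """Empirical cov over replicate gene-drops equals G (x) A, the direct
        MVN covariance, on a small pedigree."""
        ped = dfit.simulate_pedigree(4, 2, offspring_per_pair=2.0, seed=9)
        n = len(ped)
        G = np.array([[0.4, -0.3], [-0.3, 0.5]])
        reps = 4000
        draws = np.empty((reps, 2 * n))
        for r in range(reps):
            bv = dfit.simulate_breeding_values(ped, G, seed=100 + r)
            draws[r] = bv.to_numpy().T.ravel()  # stacked (comp0 all, comp1 all)
        emp = np.cov(draws.T)
        target = np.kron(G, ped.relationship_matrix())
        # MC standard error of a covariance at 4000 reps is about 0.01-0.015
        assert np.max(np.abs(emp - target)) < 0.06

    def test_non_psd_rejected(self, random_pedigree):
        with pytest.raises(ValueError):
            dfit.simulate_breeding_values(
                random_pedigree, np.array([[1.0, 2.0], [2.0, 1.0]]), seed=0
            )


def _tiny_params(**kw):
    base = dict(
        n_founders=80, n_generations=4, n_herds=10, n_duels=3000,
        n_contestants=120, n_trait_animals=80, records_per_animal=2,
    )
    base.update(kw)
    return dfit.TrueParameters(**base)


class TestContests:
    def test_seed_reproducibility(self):
        a = dfit.simulate_study(_tiny_params(), seed=5)
        b = dfit.simulate_study(_tiny_params(), seed=5)
        pd.testing.assert_frame_equal(a.contests, b.contests)
        pd.testing.assert_frame_equal(a.trait_records, b.trait_records)
        pd.testing.assert_frame_equal(a.true_bv, b.true_bv)

    def test_both_roles_by_construction(self):
        ds = dfit.simulate_study(_tiny_params(), seed=6)
        focal = set(ds.contests["focal"])
        opp = set(ds.contests["opponent"])
        assert focal == opp
        assert (ds.contests["focal"] != ds.contests["opponent"]).all()

    def test_marginal_win_rate_half(self):
        ds = dfit.simulate_study(_tiny_params(n_duels=12000, n_contestants=200), seed=8)
        rate = ds.contests["outcome"].mean()
        assert abs(rate - 0.5) < 3 / np.sqrt(len(ds.contests))  # 3 binomial SDs

    def test_huge_direct_effect_always_wins(self):
        params = _tiny_params(G=np.zeros((3, 3)), pe_cov=np.zeros((3, 3)),
                              herd_cov=np.zeros((3, 3)))
        ds = dfit.simulate_study(params, seed=9)
        ped, bv = ds.pedigree, ds.true_bv.copy()
        champion = ds.contests["focal"].iloc[0]
        bv.loc[champion, "a_D"] = 10.0
        bv.loc[champion, "a_C"] = -10.0
        contests = dfit.simulate_contests(ped, bv, params, seed=10)
        mine = contests[contests["focal"] == champion]
        theirs = contests[contests["opponent"] == champion]
        won = mine["outcome"].sum() + (1 - theirs["outcome"]).sum()
        assert won == len(mine) + len(theirs)

    def test_outcomes_calibrated_to_probit_of_true_liability(self):
        """Recomputing each duel's systematic liability from the stored true
        effects, the realized win frequencies must match the probit
        probabilities Phi(liability) — the generator's closed-form oracle."""
        from scipy.special import ndtr

        ds = dfit.simulate_study(_tiny_params(n_duels=20000, n_contestants=150),
                                 seed=15)
        con = ds.contests
        a = ds.true_bv
        pe = ds.true_pe
        herd = ds.true_herd.to_numpy()
        m = (
            a.loc[con["focal"], "a_D"].to_numpy()
            + a.loc[con["opponent"], "a_C"].to_numpy()
            + pe.loc[con["focal"], "pe_D"].to_numpy()
            + pe.loc[con["opponent"], "pe_C"].to_numpy()
            + herd[con["herd_focal"], 0]
            + herd[con["herd_opponent"], 1]
        )
        p = ndtr(m)
        y = con["outcome"].to_numpy()
        for lo, hi in [(0.0, 0.35), (0.35, 0.65), (0.65, 1.0)]:
            sel = (p >= lo) & (p < hi)
            assert sel.sum() > 200
            se = np.sqrt(p[sel].mean() * (1 - p[sel].mean()) / sel.sum())
            assert abs(y[sel].mean() - p[sel].mean()) < 4 * se + 1e-3


class TestLinearTrait:
    def test_all_variances_zero_gives_fixed_part(self):
        params = _tiny_params(
            G=np.zeros((3, 3)), pe_cov=np.zeros((3, 3)), herd_cov=np.zeros((3, 3)),
            residual_linear=0.0, htd_var=0.0, mu_linear=7.5,
        )
        ds = dfit.simulate_study(params, seed=12)
        assert np.allclose(ds.trait_records["value"], 7.5)

    def test_residual_only_variance(self):
        params = _tiny_params(
            G=np.zeros((3, 3)), pe_cov=np.zeros((3, 3)), herd_cov=np.zeros((3, 3)),
            residual_linear=1.0, htd_var=0.0, n_trait_animals=80,
            records_per_animal=30,
        )
        ds = dfit.simulate_study(params, seed=13)
        assert abs(ds.trait_records["value"].var() - 1.0) < 0.1

    def test_repeated_records_share_animal_effects(self):
        params = _tiny_params(residual_linear=0.0, htd_var=0.0,
                              herd_cov=np.zeros((3, 3)))
        ds = dfit.simulate_study(params, seed=14)
        merged = ds.trait_records.merge(ds.true_bv, left_on="animal", right_index=True)
        # within an animal x herd cell, records differ only through the HTD
        # effect and the residual, both switched off here up to test-day cells
        for _, grp in merged.groupby(["animal", "htd"]):
            assert grp["value"].std(ddof=0) == pytest.approx(0.0, abs=1e-9)


class TestWriters:
    def test_dataset_write_round_trip(self, tmp_path):
        ds = dfit.simulate_study(_tiny_params(), seed=20)
        ds.write(tmp_path)
        again = pd.read_csv(tmp_path / "contests.csv")
        assert list(again.columns) == list(ds.contests.columns)
        assert len(again) == len(ds.contests)
        ped = dfit.read_pedigree_csv(tmp_path / "pedigree.csv")
        assert len(ped) == len(ds.pedigree)
        import json

        sidecar = json.loads((tmp_path / "parameters.json").read_text())
        assert sidecar["seed"] == 20
        assert np.allclose(sidecar["G"], ds.params.G)


class TestConstrainedBlock:
    @given(st.floats(min_value=1e-4, max_value=5.0),
           st.floats(min_value=0.0, max_value=5.0),
           st.floats(min_value=-0.99, max_value=0.99))
    @settings(deadline=None, max_examples=50)
    def test_always_psd_with_mirror_structure(self, v, vt, r):
        m = constrained_block(v, vt, r)
        assert np.allclose(m, m.T)
        assert np.linalg.eigvalsh(m).min() >= -1e-10
        assert m[0, 1] == pytest.approx(-v)
        if vt > 0:
            assert m[0, 2] == pytest.approx(-m[1, 2])
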