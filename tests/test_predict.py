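"""Expected-taxa predictor, Spearman validation, recovery experiment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import raftkit as rk
from raftkit.records import FouledItem
from raftkit.vocab import Material, Taxon

TAXA = [t.value for t in Taxon]
MATS = [m.value for m in Material]


def _item(iid, beach="b", material=Material.HPL, **attach):
    return FouledItem(iid, beach, "Buoys", material,
                      {Taxon(k): v for k, v in attach.items()})


def _normalized_profile(rng):
    raw = rng.uniform(0.1, 1.0, size=(4, 6))
    raw /= raw.sum(axis=1, keepdims=True)
    return pd.DataFrame(raw, index=MATS, columns=TAXA)


class TestExpectedTaxa:
    def test_degenerate_composition_concentrates_on_one_row(self):
        profile = pd.DataFrame(0.0, index=MATS, columns=TAXA)
        profile.loc["HPl", "polychaetes"] = 1.0
        exp = rk.expected_taxa({"HPl": 1.0, "OPl": 0.0, "Foam": 0.0,
                                "NPl": 0.0}, profile, 50)
        assert exp["polychaetes"] == pytest.approx(50)
        assert exp.drop("polychaetes").eq(0).all()

    def test_hand_arithmetic_on_published_inputs(self):
        """Goose-barnacle expectation for a beach with material mix
        (.18, .74, .08, 0) and the published per-material goose shares
        (.07, .23, .99, .97), 100 individuals:
        (0.18*0.07 + 0.74*0.23 + 0.08*0.99)*100 = 26.20."""
        goose = pd.DataFrame({"goose_barnacles": [0.07, 0.23, 0.99, 0.97]},
                             index=MATS)
        exp = rk.expected_taxa({"HPl": 0.18, "OPl": 0.74, "Foam": 0.08,
                                "NPl": 0.0}, goose, 100)
        assert exp["goose_barnacles"] == pytest.approx(26.20)

    def test_zero_total_gives_zero_everywhere(self, taxon_profiles):
        exp = rk.expected_taxa({"HPl": 0.25, "OPl": 0.25, "Foam": 0.25,
                                "NPl": 0.25}, taxon_profiles, 0)
        assert exp.eq(0).all()

    def test_conservation_of_total(self, taxon_profiles):
        """With normalized profile rows and fM, expected counts sum to
        the beach total."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            fm = rng.dirichlet(np.ones(4))
            nt = float(rng.integers(1, 500))
            exp = rk.expected_taxa(dict(zip(MATS, fm)), taxon_profiles, nt)
            assert exp.sum() == pytest.approx(nt, rel=1e-9)

    def test_linear_in_total_and_taxon_order_invariant(self):
        rng = np.random.default_rng(9)
        profile = _normalized_profile(rng)
        fm = dict(zip(MATS, rng.dirichlet(np.ones(4))))
        e1 = rk.expected_taxa(fm, profile, 10)
        e3 = rk.expected_taxa(fm, profile, 30)
        assert np.allclose(3 * e1.to_numpy(), e3.to_numpy())
        shuffled = profile[list(reversed(TAXA))]
        e_shuf = rk.expected_taxa(fm, shuffled, 10)
        assert np.allclose(e1[TAXA].to_numpy(),
                           e_shuf[TAXA].to_numpy())

    def test_input_validation(self, taxon_profiles):
        with pytest.raises(ValueError, match="sum"):
            rk.expected_taxa({"HPl": 0.6, "OPl": 0.6, "Foam": 0.0,
                              "NPl": 0.0}, taxon_profiles, 10)
        with pytest.raises(ValueError, match="negative"):
            rk.expected_taxa({"HPl": 1.5, "OPl": -0.5, "Foam": 0.0,
                              "NPl": 0.0}, taxon_profiles, 10)

    def test_missing_profile_row_contributes_zero(self, taxon_profiles):
        partial = taxon_profiles.drop(index="Foam")
        exp = rk.expected_taxa({"HPl": 0.5, "OPl": 0.0, "Foam": 0.5,
                                "NPl": 0.0}, partial, 100)
        assert exp.sum() == pytest.approx(50, rel=1e-9)


class TestProfileEstimation:
    def test_fixture_opl_row_matches_published_shares(self, fixture_dataset):
        prof = rk.estimate_taxon_material_profile(fixture_dataset.fouled_items)
        assert prof.loc["OPl", "polychaetes"] == pytest.approx(0.66, abs=0.01)
        assert prof.loc["OPl", "goose_barnacles"] == \
            pytest.approx(0.23, abs=0.01)

    def test_single_material_single_taxon(self):
        prof = rk.estimate_taxon_material_profile(
            [_item("a", material=Material.FOAM, goose_barnacles=3)])
        assert prof.loc["Foam", "goose_barnacles"] == 1.0

    def test_leave_one_beach_out_drops_exclusive_material(self):
        items = [_item("a", beach="x", material=Material.FOAM,
                       goose_barnacles=5),
                 _item("b", beach="y", material=Material.HPL, molluscs=2)]
        prof = rk.estimate_taxon_material_profile(items, exclude_beach="x")
        assert "Foam" not in prof.index
        assert "HPl" in prof.index

    def test_estimator_class_fit_predict(self, fixture_dataset):
        model = rk.RaftCommunityPredictor().fit(fixture_dataset.fouled_items)
        assert model.n_items_ == 94
        fM = pd.DataFrame([[1.0, 0, 0, 0]], index=["navia"], columns=MATS)
        pred = model.predict(fM, pd.Series({"navia": 10.0}))
        assert pred.loc["navia"].sum() == pytest.approx(10, rel=1e-9)
        # sklearn parameter plumbing
        assert rk.RaftCommunityPredictor(exclude_beach="navia") \
            .get_params()["exclude_beach"] == "navia"


class TestSpearman:
    def test_perfect_monotone(self):
        assert rk.spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert rk.spearman([1, 2, 3], [30, 20, 10]).rho == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.integers(0, 5, size=20).astype(float)
            y = rng.integers(0, 5, size=20).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = rk.spearman(x, y)
            oracle = stats.pearsonr(stats.rankdata(x),
                                    stats.rankdata(y)).statistic
            assert res.rho == pytest.approx(oracle, abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=15,
                    unique=True),
           st.lists(st.integers(-1000, 1000), min_size=15, max_size=15,
                    unique=True))
    def test_invariant_under_strictly_monotone_transform(self, x, y):
        x = [v / 10 for v in x]
        y = [v / 10 for v in y[:len(x)]]
        r0 = rk.spearman(x, y).rho
        r1 = rk.spearman(np.exp(np.asarray(x) / 50), y).rho
        r2 = rk.spearman(x, 3 * np.asarray(y) + 7).rho
        assert r0 == pytest.approx(r1, abs=1e-9)
        assert r0 == pytest.approx(r2, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rk.spearman([1, 1, 1], [1, 2, 3])

    def test_permutation_p_deterministic_and_consistent(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        a = rk.spearman(x, y, method="permutation", n_permutations=499,
                        seed=5)
        b = rk.spearman(x, y, method="permutation", n_permutations=499,
                        seed=5)
        assert a.p_value == b.p_value
        asym = rk.spearman(x, y).p_value
        assert a.p_value == pytest.approx(asym, abs=0.05)


class TestEvaluatePrediction:
    def test_fixture_scopes_run_and_conserve(self, fixture_dataset):
        scopes = rk.scopes_by_longitude(
            fixture_dataset, fixture_dataset.quadrat_beaches())
        assert len(scopes["west"]) == 6 and len(scopes["east"]) == 6
        results, table = rk.evaluate_prediction(fixture_dataset,
                                                scopes=scopes)
        assert {r.scope for r in results} == {"all", "west", "east"}
        assert all(-1 <= r.rho <= 1 for r in results)
        # per-beach conservation of expected totals
        census = rk.census_by_beach(fixture_dataset.fouled_items)
        for bid, sub in table.groupby("beach_id"):
            assert sub.expected.sum() == \
                pytest.approx(census[bid].n_total, rel=1e-9)

    def test_shares_mode_normalizes_within_beach(self, fixture_dataset):
        _, table = rk.evaluate_prediction(fixture_dataset,
                                          value_mode="shares")
        for _, sub in table.groupby("beach_id"):
            assert sub.expected.sum() == pytest.approx(1, rel=1e-6)
            assert sub.observed.sum() == pytest.approx(1, rel=1e-6)

    def test_scope_errors(self, fixture_dataset):
        with pytest.raises(ValueError, match="lack"):
            rk.evaluate_prediction(fixture_dataset,
                                   scopes={"bad": ["silencio"]})

    def test_reference_profile_mode(self, fixture_dataset, taxon_profiles):
        results, _ = rk.evaluate_prediction(
            fixture_dataset, reference_profile=taxon_profiles)
        assert -1 <= results[0].rho <= 1


class TestRecoveryExperiment:
    def test_deterministic_given_seed(self):
        config = rk.SyntheticConfig(n_beaches=6, n_fouled_items_per_beach=6,
                                    mean_items_per_quadrat=5.0)
        a = rk.recovery_experiment(config, n_replicates=3, seed=21)
        b = rk.recovery_experiment(config, n_replicates=3, seed=21)
        pd.testing.assert_frame_equal(a, b)
        assert set(a.columns) >= {"rho", "p_value", "profile_max_abs_error"}

    def test_rho_increases_with_fouled_sample_size(self):
        small = rk.SyntheticConfig(n_fouled_items_per_beach=3)
        large = rk.SyntheticConfig(n_fouled_items_per_beach=60)
        rho_small = rk.recovery_experiment(small, 8, seed=2).rho.median()
        rho_large = rk.recovery_experiment(large, 8, seed=2).rho.median()
        assert rho_large > rho_small

    def test_identical_profiles_give_unbiased_rho(self, taxon_profiles):
        """Material-independent attachment with a fixed reference
        profile: rho scatters around zero."""
        uniform = pd.DataFrame(np.full((4, 6), 1 / 6), index=MATS,
                               columns=TAXA)
        config = rk.SyntheticConfig(taxon_profiles=uniform,
                                    fixed_individuals_per_item=True)
        df = rk.recovery_experiment(config, n_replicates=60, seed=17,
                                    reference_profile=taxon_profiles)
        assert abs(df.rho.mean()) < 0.1
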