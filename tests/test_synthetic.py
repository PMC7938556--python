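import numpy as np
import pandas as pd
import pytest

from phenokit import FLAG_COLUMNS, evaluate_all, match_text
from phenokit.emr_tables import TABLE_SCHEMAS
from phenokit.synthetic import (
    CalibrationProfile,
    Stratum,
    TextPool,
    default_profile,
    default_text_pool,
    generate,
    phi_bounds,
    render_tables,
    sample_cohort_flags,
    sample_flag_matrix,
    solve_pair_rho,
)


def _profile(marginals, dependence=(), n=1000, ineligible=0.0):
    st = Stratum(2017, "LHD1", n, marginals)
    return CalibrationProfile(strata=[st], dependence=list(dependence),
                              ineligible_fraction=ineligible), st


class TestProfileValidation:
    def test_marginal_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="marginals"):
            _profile({"c1": 1.2})

    def test_infeasible_dependence_rejected_with_frechet_diagnostic(self):
        """The published r=0.9 at 3.1%/1.2% marginals violates the Fréchet bound."""
        with pytest.raises(ValueError, match="Fréchet"):
            _profile({"c6": 0.031, "c5": 0.012}, [("c6", "c5", 0.9)])

    def test_feasible_dependence_accepted(self):
        profile, _ = _profile({"c6": 0.031, "c5": 0.012}, [("c6", "c5", 0.55)])
        assert profile.dependence == [("c6", "c5", 0.55)]

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _profile({"c5": 0.5, "c6": 0.5}, [("c6", "c5", 0.1), ("c5", "c6", 0.2)])

    def test_default_profile_is_feasible_and_stratified(self):
        profile = default_profile()
        years = {s.year for s in profile.strata}
        lhds = {s.lhd for s in profile.strata}
        assert years == {2013, 2014, 2015, 2016, 2017} and lhds == {"LHD1", "LHD2"}

    def test_yaml_round_trip(self, tmp_path):
        profile = default_profile(n_per_stratum=100)
        profile.to_yaml(tmp_path / "p.yaml")
        back = CalibrationProfile.from_yaml(tmp_path / "p.yaml")
        assert back.to_dict() == profile.to_dict()


class TestPhiBounds:
    def test_symmetric_marginals_allow_full_range(self):
        lo, hi = phi_bounds(0.5, 0.5)
        assert lo == pytest.approx(-1.0) and hi == pytest.approx(1.0)

    def test_rare_marginals_cap_positive_phi(self):
        _, hi = phi_bounds(0.031, 0.012)
        assert hi < 0.65


class TestSampleFlagMatrix:
    def test_all_zero_marginals_give_all_false(self):
        profile, st = _profile({})
        assert not sample_flag_matrix(profile, st, 500, seed=1).any()

    def test_all_one_marginals_give_all_true(self):
        profile, st = _profile({c: 1.0 for c in FLAG_COLUMNS})
        assert sample_flag_matrix(profile, st, 500, seed=1).all()

    def test_marginals_within_three_binomial_se(self):
        marginals = {"c1": 0.4, "c2": 0.6, "c3": 0.25, "c5": 0.02, "c6": 0.05, "c7": 0.7}
        profile, st = _profile(marginals)
        n = 20_000
        mat = sample_flag_matrix(profile, st, n, seed=2)
        for i, c in enumerate(FLAG_COLUMNS):
            p = marginals.get(c, 0.0)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(mat[:, i].mean() - p) <= max(3 * se, 1e-12), c

    def test_dependence_pair_phi_recovery(self):
        profile, st = _profile({"c5": 0.5, "c6": 0.5}, [("c6", "c5", 0.9)])
        mat = sample_flag_matrix(profile, st, 50_000, seed=3)
        phi = np.corrcoef(mat[:, 4].astype(float), mat[:, 5].astype(float))[0, 1]
        assert phi == pytest.approx(0.9, abs=0.05)

    def test_deterministic_given_seed(self):
        profile, st = _profile({"c1": 0.3, "c7": 0.7}, [("c1", "c7", 0.2)])
        a = sample_flag_matrix(profile, st, 2_000, seed=5)
        b = sample_flag_matrix(profile, st, 2_000, seed=5)
        assert np.array_equal(a, b)

    def test_solve_pair_rho_matches_monte_carlo(self):
        """The solved latent correlation reproduces the target phi in simulation."""
        rho = solve_pair_rho(0.3, 0.6, 0.4)
        rng = np.random.default_rng(8)
        z = rng.standard_normal((200_000, 2))
        z[:, 1] = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        from scipy.stats import norm
        flags = z < norm.ppf([0.3, 0.6])
        phi = np.corrcoef(flags[:, 0].astype(float), flags[:, 1].astype(float))[0, 1]
        assert phi == pytest.approx(0.4, abs=0.01)


class TestSampleCohortFlags:
    def test_ineligible_fraction_one_gives_no_eligible_rows(self):
        profile, st = _profile({"c1": 0.5}, ineligible=1.0)
        assert not sample_cohort_flags(profile, st, 300, seed=1).any()

    def test_eligible_rows_have_score_at_least_one(self):
        profile, st = _profile({"c1": 0.3, "c7": 0.6}, ineligible=0.25)
        mat = sample_cohort_flags(profile, st, 2_000, seed=4)
        n_elig = mat.any(axis=1).sum()
        assert n_elig == 1_500  # exactly (1 - 0.25) * n rows eligible

    def test_conditional_marginals_match_targets(self):
        """Among eligible rows the prevalences hit the stratum targets."""
        marginals = {"c1": 0.382, "c2": 0.6, "c3": 0.257, "c5": 0.012, "c6": 0.031, "c7": 0.72}
        profile, st = _profile(marginals, [("c6", "c5", 0.55)], ineligible=0.2)
        n = 25_000
        mat = sample_cohort_flags(profile, st, n, seed=6)
        elig = mat[mat.any(axis=1)]
        for i, c in enumerate(FLAG_COLUMNS):
            p = marginals.get(c, 0.0)
            se = np.sqrt(p * (1 - p) / len(elig)) if p else 0.0
            assert abs(elig[:, i].mean() - p) <= max(3.5 * se, 1e-12), c


class TestTextPool:
    def test_leakage_detected_at_build(self, lexicon):
        with pytest.raises(ValueError, match="leakage"):
            TextPool(positive_templates=["{TERM} now"],
                     negative_texts=["ongoing chest pain"]).validate_against(lexicon)

    def test_template_without_slot_rejected(self, lexicon):
        with pytest.raises(ValueError, match="slot"):
            TextPool(positive_templates=["no slot here"],
                     negative_texts=[]).validate_against(lexicon)

    def test_default_pool_is_clean(self, lexicon):
        pool = default_text_pool(lexicon)
        for text in pool.negative_texts:
            assert match_text(text, lexicon) == set()


class TestRenderRoundTrip:
    def test_single_row_single_criterion(self, lexicon):
        st = Stratum(2017, "LHD1", 1, {})
        for i in range(7):
            mat = np.zeros((1, 7), dtype=bool)
            mat[0, i] = True
            bundle = render_tables(mat, lexicon, default_text_pool(lexicon), st, seed=i)
            flags = evaluate_all(bundle, lexicon)
            assert flags.loc[0, FLAG_COLUMNS].to_numpy(dtype=bool).tolist() == mat[0].tolist()

    def test_all_false_row_scores_zero(self, lexicon):
        st = Stratum(2016, "LHD2", 1, {})
        bundle = render_tables(np.zeros((3, 7), dtype=bool), lexicon,
                               default_text_pool(lexicon), st, seed=0)
        flags = evaluate_all(bundle, lexicon)
        assert (flags["score"] == 0).all()

    def test_round_trip_at_scale(self, lexicon):
        rng = np.random.default_rng(12)
        mat = rng.random((1_000, 7)) < rng.uniform(0.05, 0.8, size=7)
        st = Stratum(2015, "LHD1", len(mat), {})
        bundle = render_tables(mat, lexicon, default_text_pool(lexicon), st, seed=1)
        flags = evaluate_all(bundle, lexicon)
        recovered = flags[FLAG_COLUMNS].to_numpy(dtype=bool)
        assert np.array_equal(recovered, mat)

    def test_no_lexicon_variant_attached_to_false_flags(self, lexicon):
        """Leakage scan: text of c1/c2-false encounters matches nothing."""
        rng = np.random.default_rng(13)
        mat = rng.random((300, 7)) < 0.4
        st = Stratum(2014, "LHD2", len(mat), {})
        bundle = render_tables(mat, lexicon, default_text_pool(lexicon), st, seed=2)
        keys = bundle.encounters["encounter_key"].to_numpy()
        c1_false = set(keys[~mat[:, 0]])
        rfv = bundle.reason_for_visit
        for _, row in rfv[rfv["encounter_key"].isin(c1_false)].iterrows():
            assert match_text(row["free_text"], lexicon) == set()


class TestGenerate:
    def test_deterministic_given_seed(self, tmp_path):
        profile = default_profile(years=(2017,), n_per_stratum=400)
        a = generate(profile, tmp_path / "a", seed=7)
        b = generate(profile, tmp_path / "b", seed=7)
        for name in TABLE_SCHEMAS:
            pd.testing.assert_frame_equal(a.table(name), b.table(name))
        assert (tmp_path / "a" / "provenance.json").read_text() == \
               (tmp_path / "b" / "provenance.json").read_text()

    def test_different_seeds_differ(self):
        profile = default_profile(years=(2017,), n_per_stratum=400)
        a = generate(profile, None, seed=7)
        b = generate(profile, None, seed=8)
        assert not a.encounters["person_key"].equals(b.encounters["person_key"]) or \
               not a.reason_for_visit.equals(b.reason_for_visit)

    def test_every_encounter_has_person_key(self):
        profile = default_profile(years=(2016, 2017), n_per_stratum=200)
        bundle = generate(profile, None, seed=9)
        assert (bundle.encounters["person_key"] != "").all()

    def test_per_year_prevalence_ordering_follows_profile(self, lexicon):
        """c7 prevalence among eligible rises across well-separated years as calibrated."""
        profile = default_profile(years=(2013, 2015, 2017), n_per_stratum=2_000,
                                  lhds=("LHD1",))
        bundle = generate(profile, None, seed=10, lexicon=lexicon)
        flags = evaluate_all(bundle, lexicon)
        joined = flags.merge(bundle.encounters[["encounter_key", "year"]], on="encounter_key")
        elig = joined[joined["eligible"]]
        prev = elig.groupby("year")["c7"].mean()
        assert list(prev.index) == sorted(prev.index)
        assert prev.is_monotonic_increasing
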