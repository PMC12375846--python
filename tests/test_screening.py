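"""Screening strategies: presets, invitation scheduling, the test cascade,
detection, participation, and active surveillance."""

import numpy as np
import pytest

from prostasim.natural_history import simulate_cohort
from prostasim.screening import (
    DX_CLINICAL,
    DX_SCREEN,
    ConfigurationError,
    PRESET_NAMES,
    StrategyDefinition,
    TestProfile,
    active_surveillance_schedule,
    as_event_counts,
    next_invitation,
    run_cohort_screening,
    run_screening,
    strategy_preset,
)
from prostasim.natural_history import cohort_life_history


class TestPresets:
    def test_ten_strategies_shipped(self):
        assert len(PRESET_NAMES) == 10

    def test_psa_ras_50_60_nomri_definition(self):
        s = strategy_preset("psa_ras_50_60_nomri")
        assert (s.start_age, s.stop_age) == (50, 60)
        assert s.risk_bands == ((1.5, 5.0), (3.0, 2.0))
        assert s.workup_threshold == 3.0
        assert not s.mri_triage
        assert s.biopsy_type_on_workup == "systematic-only"
        assert s.participation == {"first_screen": 0.75, "rescreen": 0.95, "biopsy": 0.65}

    def test_dre_45_75_definition(self):
        s = strategy_preset("dre_45_75")
        assert (s.start_age, s.stop_age) == (45, 75)
        assert s.primary_test == "DRE"
        assert s.dre_interval == 1.0

    def test_no_screening_uses_mri_workup_for_symptomatic(self):
        s = strategy_preset("no_screening")
        assert s.primary_test == "none"
        assert s.mri_triage  # symptomatic cases costed as MRI + combined biopsy

    def test_unknown_name_lists_valid(self):
        with pytest.raises(KeyError) as exc:
            strategy_preset("psa_every_year")
        assert "psa_ras_50_60_nomri" in str(exc.value)

    def test_presets_immutable_between_calls(self):
        a = strategy_preset("dre_45_75")
        a.participation["biopsy"] = 0.0
        assert strategy_preset("dre_45_75").participation["biopsy"] == 0.65

    def test_invalid_definitions_rejected(self):
        with pytest.raises(ConfigurationError):
            StrategyDefinition(name="x", start_age=60, stop_age=50, primary_test="PSA")
        with pytest.raises(ConfigurationError):
            StrategyDefinition(
                name="x", start_age=50, stop_age=60, primary_test="PSA",
                risk_bands=((3.0, 2.0), (1.5, 5.0)),
            )


class TestNextInvitation:
    @pytest.mark.parametrize(
        "last_age,last_psa,expected",
        [
            (50.0, 1.0, 55.0),  # low risk: 5-year interval
            (50.0, 2.0, 52.0),  # moderate risk: 2-year interval
            (58.0, 1.0, None),  # 5-year interval overshoots stop age 60
            (None, None, 50.0),  # first invitation at start age
            (59.0, 2.0, None),  # 2-year interval overshoots
        ],
    )
    def test_band_intervals(self, last_age, last_psa, expected):
        s = strategy_preset("psa_ras_50_60_nomri")
        assert next_invitation(s, last_age, last_psa) == expected

    def test_negative_psa_rejected(self):
        s = strategy_preset("psa_ras_50_60_nomri")
        with pytest.raises(ConfigurationError):
            next_invitation(s, 52.0, -1.0)

    def test_dre_annual(self):
        s = strategy_preset("dre_45_75")
        assert next_invitation(s, 74.0, None) == 75.0
        assert next_invitation(s, 75.0, None) is None


def _participation(first, re_, bx):
    return {"first_screen": first, "rescreen": re_, "biopsy": bx}


class TestRunScreening:
    def test_zero_participation_equals_no_screening(self, small_cohort, test_profiles):
        s = strategy_preset("psa_ras_50_70_nomri")
        s.participation = _participation(0.0, 0.0, 0.0)
        res = run_cohort_screening(small_cohort, s, test_profiles, seed=42)
        assert res.n_psa.sum() == 0
        assert res.n_biopsy_screen.sum() == 0
        assert (res.dx_mode != DX_SCREEN).all()
        none = run_cohort_screening(
            small_cohort, strategy_preset("no_screening"), test_profiles, seed=42
        )
        assert np.array_equal(res.dx_age, none.dx_age, equal_nan=True)
        assert np.array_equal(res.death_age, none.death_age)

    def test_psa_below_threshold_no_biopsies(self, params, life_table, test_profiles):
        import copy
        from prostasim.natural_history import NaturalHistoryParams

        d = copy.deepcopy(params.to_dict())
        d["psa_baseline_level"] = 1e-6  # PSA can never reach 3 ng/mL
        d["psa_person_sd"] = {"intercept": 0.0, "slope": 0.0}
        tiny = NaturalHistoryParams.from_dict(d)
        cohort = simulate_cohort(tiny, life_table, n=2_000, seed=5)
        s = strategy_preset("psa_ras_45_70_nomri")
        res = run_cohort_screening(cohort, s, test_profiles, seed=5)
        assert res.n_biopsy_screen.sum() == 0
        assert (res.dx_mode != DX_SCREEN).all()
        assert res.n_psa.sum() > 0

    def test_perfect_tests_detect_first_qualifying_screen(self, params, life_table):
        """With sensitivity 1, specificity 1 and full participation, every
        man with preclinical cancer and measured PSA >= 3 at a screen is
        detected at his first qualifying screen."""
        import copy
        from prostasim.natural_history import NaturalHistoryParams

        d = copy.deepcopy(params.to_dict())
        d["noise_sd"] = 0.0
        p = NaturalHistoryParams.from_dict(d)
        cohort = simulate_cohort(p, life_table, n=4_000, seed=6)
        perfect = {
            "systematic_biopsy": TestProfile(
                "systematic_biopsy", {"by_grade": [1.0, 1.0, 1.0]}, 1.0
            ),
        }
        s = strategy_preset("psa_ras_45_70_nomri")
        s.participation = _participation(1.0, 1.0, 1.0)
        res = run_cohort_screening(cohort, s, perfect, seed=6)
        screened = res.dx_mode == DX_SCREEN
        assert screened.any()
        # every screen-detected man's detection age is his first round where
        # he is a case with true PSA >= 3
        for i in np.flatnonzero(screened)[:200]:
            ages = res.age_r[i][res.psa_r[i]]
            case = (ages >= np.nan_to_num(cohort.onset_age[i], nan=np.inf)) & (
                ages < np.nan_to_num(cohort.clin_dx_age[i], nan=np.inf)
            )
            psa = np.exp(
                np.asarray([cohort.true_log_psa(float(a))[i] for a in ages])
            )
            qualifying = ages[case & (psa >= 3.0)]
            assert qualifying.size > 0
            assert res.screen_dx_age[i] == pytest.approx(qualifying[0], abs=1e-5)

    def test_mri_triage_gates_biopsies(self, small_cohort):
        """A negative MRI never proceeds to biopsy: with an MRI that is
        always negative there are no screen biopsies at all."""
        never_positive = {
            "mri": TestProfile("mri", {"by_grade": [0.0, 0.0, 0.0]}, 1.0),
            "combined_biopsy": TestProfile(
                "combined_biopsy", {"by_grade": [1.0, 1.0, 1.0]}, 1.0
            ),
        }
        s = strategy_preset("psa_ras_45_70_mri")
        res = run_cohort_screening(small_cohort, s, never_positive, seed=42)
        assert res.n_mri.sum() > 0
        assert res.n_biopsy_screen.sum() == 0

    def test_missing_profile_raises(self, small_cohort):
        s = strategy_preset("psa_ras_45_70_mri")
        with pytest.raises(ConfigurationError):
            run_cohort_screening(small_cohort, s, {}, seed=42)

    def test_no_events_after_stop_or_death(self, small_cohort, test_profiles):
        for name in ("dre_45_75", "psa_ras_50_70_mri"):
            s = strategy_preset(name)
            res = run_cohort_screening(small_cohort, s, test_profiles, seed=42)
            ages = res.age_r
            ok = np.isfinite(ages)
            assert (ages[ok] <= s.stop_age + 1e-6).all()
            death = np.broadcast_to(res.death_age[:, None], ages.shape)
            assert (ages[ok] <= death[ok] + 1e-6).all()

    def test_detection_conservation(self, small_cohort, test_profiles):
        res = run_cohort_screening(
            small_cohort, strategy_preset("dre_45_75"), test_profiles, seed=42
        )
        n_dx = (res.dx_mode > 0).sum()
        assert n_dx == (res.dx_mode == DX_SCREEN).sum() + (res.dx_mode == DX_CLINICAL).sum()
        assert (np.isfinite(res.screen_dx_age) == (res.dx_mode == DX_SCREEN)).all()

    def test_lead_time_nonnegative(self, small_cohort, test_profiles):
        res = run_cohort_screening(
            small_cohort, strategy_preset("dre_45_75"), test_profiles, seed=42
        )
        screen = res.dx_mode == DX_SCREEN
        cf = small_cohort.clin_dx_age[screen]
        lead = np.nan_to_num(cf, nan=np.inf) - res.dx_age[screen]
        assert (lead >= -1e-9).all()

    def test_overdiagnosis_definition(self, small_cohort, test_profiles):
        res = run_cohort_screening(
            small_cohort, strategy_preset("dre_45_75"), test_profiles, seed=42
        )
        od = res.overdiagnosed
        screen = res.dx_mode == DX_SCREEN
        assert (od <= screen).all()
        assert np.array_equal(od, screen & ~np.isfinite(small_cohort.clin_dx_age))

    def test_screens_per_attender_matches_cascade_calculator(
        self, params, life_table
    ):
        """The engine's PSA-test counts must equal an independent
        per-person walk over the scalar cascade API on the same (noise-free)
        PSA trajectories."""
        import copy
        from prostasim.natural_history import NaturalHistoryParams, psa_at_age

        d = copy.deepcopy(params.to_dict())
        d["noise_sd"] = 0.0
        p = NaturalHistoryParams.from_dict(d)
        cohort = simulate_cohort(p, life_table, n=1_000, seed=13)
        blind_biopsy = {
            "systematic_biopsy": TestProfile(
                "systematic_biopsy", {"by_grade": [0.0, 0.0, 0.0]}, 1.0
            ),
        }
        s = strategy_preset("psa_ras_50_70_nomri")
        s.participation = _participation(1.0, 1.0, 1.0)
        res = run_cohort_screening(cohort, s, blind_biopsy, seed=13)

        for i in range(cohort.n):
            h = cohort_life_history(cohort, i)
            censor = min(
                h.death_age,
                h.counterfactual_clinical_dx_age or np.inf,
            )
            expected = 0
            age, psa = None, None
            while True:
                nxt = next_invitation(s, age, psa)
                if nxt is None or nxt >= censor:
                    break
                age = nxt
                psa = psa_at_age(
                    p, h.psa_person_effects, h.onset_age, h.grade_category, age
                )
                expected += 1
            assert res.n_psa[i] == expected


class TestEventLog:
    def test_biopsy_preceded_by_trigger_at_same_age(self, params, life_table, test_profiles, small_cohort):
        n_checked = 0
        for i in range(400):
            h = cohort_life_history(small_cohort, i)
            rec = run_screening(
                h, strategy_preset("dre_45_75"), test_profiles, seed=42,
                cohort=small_cohort,
            )
            kinds_at = {}
            for age, kind, _ in rec.events:
                kinds_at.setdefault(round(age * 4), []).append(kind)
            for age_key, kinds in kinds_at.items():
                if "biopsy" in kinds:
                    assert "dre_test" in kinds
                    n_checked += 1
        assert n_checked > 0

    def test_events_sorted_and_within_life(self, small_cohort, test_profiles):
        h = cohort_life_history(small_cohort, 3)
        rec = run_screening(
            h, strategy_preset("psa_ras_45_70_mri"), test_profiles, seed=42,
            cohort=small_cohort,
        )
        ages = [a for a, _, _ in rec.events]
        assert ages == sorted(ages)
        assert all(35.0 <= a <= h.death_age + 1e-6 for a in ages)

    def test_tidy_export_schema(self, small_cohort, test_profiles):
        h = cohort_life_history(small_cohort, 3)
        rec = run_screening(
            h, strategy_preset("dre_45_75"), test_profiles, seed=42,
            cohort=small_cohort,
        )
        frame = rec.to_frame()
        assert list(frame.columns) == ["person_id", "age", "event_kind", "result"]
        assert len(frame) == len(rec.events)

    def test_profile_round_trip(self, test_profiles):
        from prostasim.screening import TestProfile

        for p in test_profiles.values():
            again = TestProfile.from_dict(p.to_dict())
            assert again == p


class TestActiveSurveillance:
    def test_truncation_short_course(self):
        events = active_surveillance_schedule(60.0, 60.5)
        assert [(round(a, 2), k) for a, k in events] == [
            (60.0, "as_visit"), (60.25, "as_visit"),
        ]

    def test_quarterly_then_biannual(self):
        events = active_surveillance_schedule(60.0, 63.0)
        visits = [round(a - 60.0, 2) for a, k in events if k == "as_visit"]
        assert visits[:8] == [0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75]
        assert visits[8:] == [2.0, 2.5]

    def test_biopsy_count_matches_closed_form(self):
        for dur in (1.0, 2.0, 5.0, 10.0, 17.3):
            events = active_surveillance_schedule(60.0, 60.0 + dur)
            n_bx = sum(1 for _, k in events if k == "as_mri_biopsy")
            n_visits = sum(1 for _, k in events if k == "as_visit")
            v, b = as_event_counts(np.array([dur]))
            assert n_visits == v[0]
            assert n_bx == b[0]

    def test_invalid_order_raises(self):
        with pytest.raises(ConfigurationError):
            active_surveillance_schedule(60.0, 60.0)
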