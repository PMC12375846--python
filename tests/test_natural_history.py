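"""Natural-history model: PSA growth, competing hazards, life-table
reproduction, stage-shift survival."""

import copy

import numpy as np
import pytest
from scipy import stats

from prostasim.natural_history import (
    AGE_ENTRY,
    DiseaseState,
    NaturalHistoryParams,
    ParameterError,
    InputError,
    cohort_life_history,
    load_life_table,
    log_psa_mean,
    psa_at_age,
    sample_survival_time,
    simulate_cohort,
    simulate_natural_course,
    stage_shift_survival,
    survival_probability,
)


def _override(params, **groups):
    d = copy.deepcopy(params.to_dict())
    for key, sub in groups.items():
        if isinstance(sub, dict):
            d[key].update(sub)
        else:
            d[key] = sub
    return NaturalHistoryParams.from_dict(d)


# ---------------------------------------------------------------------------
# PSA growth
# ---------------------------------------------------------------------------


class TestPsaAtAge:
    def test_continuous_at_onset(self, params):
        at_onset = psa_at_age(params, (0.1, 0.001), 55.0, 2, 55.0)
        no_onset = psa_at_age(params, (0.1, 0.001), None, None, 55.0)
        assert at_onset == pytest.approx(no_onset, rel=1e-12)

    def test_pre_onset_log_slope_closed_form(self, params):
        lo = psa_at_age(params, (0.0, 0.0), None, None, 50.0)
        hi = psa_at_age(params, (0.0, 0.0), None, None, 60.0)
        assert np.log(hi) - np.log(lo) == pytest.approx(
            10 * params.psa_pre_onset_slope, abs=1e-12
        )

    def test_value_matches_independent_formula(self, params):
        # onset at 55, GS>7, evaluated at 60 with zero person effects:
        # exp(log(baseline) + pre*(60-35) + (post_gt7 - pre)*(60-55))
        expected = np.exp(
            np.log(params.psa_baseline_level)
            + params.psa_pre_onset_slope * 25.0
            + (params.psa_post_onset_slope_by_grade[2] - params.psa_pre_onset_slope)
            * 5.0
        )
        got = psa_at_age(params, (0.0, 0.0), 55.0, 2, 60.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_noise_multiplicative_on_log_scale(self, params):
        clean = psa_at_age(params, (0.0, 0.0), None, None, 50.0)
        noisy = psa_at_age(params, (0.0, 0.0), None, None, 50.0, with_noise=True, noise_z=1.0)
        assert np.log(noisy) - np.log(clean) == pytest.approx(params.noise_sd)

    def test_invalid_inputs_raise(self, params):
        with pytest.raises(ParameterError):
            psa_at_age(params, (0.0, 0.0), None, None, 20.0)
        with pytest.raises(ParameterError):
            psa_at_age(params, (0.0, 0.0), 30.0, 1, 50.0)
        with pytest.raises(ParameterError):
            NaturalHistoryParams(psa_pre_onset_slope=0.5)  # post < pre


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


class TestParams:
    def test_grade_probabilities_sum_to_one(self, params):
        p = params.grade_probabilities(np.linspace(40, 100, 20))
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_roundtrip_yaml(self, params, tmp_path):
        path = tmp_path / "nh.yaml"
        params.save(path)
        again = NaturalHistoryParams.load(path)
        assert again.to_dict() == params.to_dict()

    def test_negative_rates_rejected(self):
        with pytest.raises(ParameterError):
            NaturalHistoryParams(noise_sd=-0.1)
        with pytest.raises(ParameterError):
            NaturalHistoryParams(
                progression_rate_params={
                    "t1_t2": [-0.1, 0.1, 0.1],
                    "t2_t3": [0.1, 0.1, 0.1],
                    "met_base": [0.01, 0.01, 0.01],
                    "met_tcat_mult": [1, 1, 1],
                }
            )

    def test_18_states_enumerable(self):
        states = DiseaseState.all_states()
        assert len(states) == 18
        assert sorted(s.index for s in states) == list(range(18))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


class TestSimulateNaturalCourse:
    def test_determinism_bitwise(self, params, life_table):
        h1 = simulate_natural_course(params, life_table, person_id=17, seed=5)
        h2 = simulate_natural_course(params, life_table, person_id=17, seed=5)
        assert h1 == h2

    def test_person_in_cohort_matches_single_simulation(self, params, life_table, small_cohort):
        i = 1234
        single = simulate_natural_course(params, life_table, person_id=i, seed=42)
        from_cohort = cohort_life_history(small_cohort, i)
        assert single == from_cohort

    def test_zero_onset_hazard_degenerates_to_life_table(self, params, life_table):
        p0 = _override(params, onset_hazard_params={"susceptible": 0.0})
        c = simulate_cohort(p0, life_table, n=2_000, seed=9)
        assert not np.isfinite(c.onset_age).any()
        assert not np.isfinite(c.clin_dx_age).any()
        assert np.array_equal(c.death_age_ns, c.oc_death_age)

    def test_death_age_is_min_of_causes(self, small_cohort):
        cd = np.nan_to_num(small_cohort.cancer_death_age_ns, nan=np.inf)
        expected = np.minimum(small_cohort.oc_death_age, cd)
        assert np.allclose(small_cohort.death_age_ns, expected)

    def test_trajectory_ages_strictly_increasing(self, params, life_table):
        for pid in range(300):
            h = simulate_natural_course(params, life_table, pid, seed=3)
            ages = [a for a, _ in h.state_trajectory]
            assert all(b > a for a, b in zip(ages, ages[1:]))
            if h.counterfactual_clinical_dx_age is not None:
                assert h.counterfactual_clinical_dx_age <= h.death_age

    def test_incomplete_life_table_rejected(self, params, life_table):
        import pandas as pd

        short = life_table[life_table["age"] < 80]
        with pytest.raises(InputError):
            simulate_cohort(params, short, n=10, seed=0)


class TestDistributionalProperties:
    def test_all_cause_mortality_reproduces_life_table(self, params, life_table):
        """With cancer switched off, death ages follow the life table
        (Kolmogorov-Smirnov at n = 50,000, alpha = 0.01)."""
        p0 = _override(params, onset_hazard_params={"susceptible": 0.0})
        c = simulate_cohort(p0, life_table, n=50_000, seed=77)
        haz, cum = load_life_table(life_table)

        def cdf(age):
            age = np.asarray(age, dtype=float)
            idx = np.clip((age - AGE_ENTRY).astype(int), 0, len(haz) - 1)
            frac = age - AGE_ENTRY - idx
            return 1.0 - np.exp(-(cum[idx] + haz[idx] * frac))

        res = stats.kstest(c.death_age_ns[c.death_age_ns < 105.0], cdf)
        assert res.pvalue > 0.01

    def test_grade_mixture_marginal_matches_configured(self, params, mid_cohort):
        onset = np.isfinite(mid_cohort.onset_age)
        expected = params.grade_probabilities(mid_cohort.onset_age[onset]).mean(axis=0)
        n = onset.sum()
        for g in range(3):
            observed = (mid_cohort.grade[onset] == g).mean()
            se = np.sqrt(expected[g] * (1 - expected[g]) / n)
            assert abs(observed - expected[g]) < 3 * se

    def test_clinical_incidence_matches_numerical_integration(self, life_table):
        """Restricted model (no progression, no metastasis, no person
        effects): the empirical diagnosis hazard among alive undiagnosed men
        must match quadrature over the same onset and diagnosis hazards."""
        base = NaturalHistoryParams()
        p = _override(
            base,
            onset_hazard_params={"shape": 3.0, "scale": 31.0, "susceptible": 0.4},
            progression_rate_params={
                "t1_t2": [0.0] * 3, "t2_t3": [0.0] * 3,
                "met_base": [0.0] * 3, "met_tcat_mult": [1.0] * 3,
            },
            psa_person_sd={"intercept": 0.0, "slope": 0.0},
        )
        c = simulate_cohort(p, life_table, n=50_000, seed=31)

        k = p.onset_hazard_params["shape"]
        lam = p.onset_hazard_params["scale"]
        fsus = p.onset_hazard_params["susceptible"]
        xi = p.clinical_dx_params["xi_by_tcat"][0]
        s_pre = p.psa_pre_onset_slope
        lp0 = np.log(p.psa_baseline_level)

        def onset_density(o):
            z = (o - AGE_ENTRY) / lam
            return fsus * (k / lam) * z ** (k - 1) * np.exp(-(z**k))

        def onset_survival(a):
            return 1 - fsus + fsus * np.exp(-(((a - AGE_ENTRY) / lam) ** k))

        post = p.psa_post_onset_slope_by_grade
        probs_by_onset = lambda o: p.grade_probabilities(o)

        def dx_hazard_and_surv(o, a):
            """hazard at age a and P(not dx by a) given onset at o, averaged
            over the grade mixture at onset."""
            pg = probs_by_onset(o)
            h = np.zeros_like(np.broadcast_arrays(o, a)[0], dtype=float)
            s = np.zeros_like(h)
            for g in range(3):
                sg = post[g]
                psa = np.exp(lp0 + s_pre * (o - AGE_ENTRY) + sg * (a - o))
                psa_on = np.exp(lp0 + s_pre * (o - AGE_ENTRY))
                cumh = xi * (psa - psa_on) / sg
                h += pg[..., g] * xi * psa * np.exp(-cumh)
                s += pg[..., g] * np.exp(-cumh)
            return h, s

        ogrid = np.linspace(AGE_ENTRY + 1e-3, 100, 400)

        def incidence_rate(a):
            mask = ogrid < a
            o = ogrid[mask]
            dens, surv_terms = dx_hazard_and_surv(o, np.full(o.shape, a))
            num = np.trapezoid(onset_density(o) * dens, o)
            den = onset_survival(a) + np.trapezoid(onset_density(o) * surv_terms, o)
            return num / den

        dx = c.clin_dx_age
        alive = c.oc_death_age  # no cancer deaths matter for at-risk time
        for lo in (55.0, 65.0, 75.0):
            hi = lo + 5.0
            at_risk = (
                np.minimum(np.nan_to_num(dx, nan=np.inf), np.minimum(alive, hi))
                - np.minimum(np.nan_to_num(dx, nan=np.inf), np.minimum(alive, lo))
            )
            py = at_risk.clip(0).sum()
            cases = ((dx >= lo) & (dx < hi) & (dx < alive)).sum()
            rate = cases / py
            expected = np.mean([incidence_rate(a) for a in np.linspace(lo, hi, 6)])
            se = np.sqrt(cases) / py
            assert abs(rate - expected) < 3 * se + 0.05 * expected


# ---------------------------------------------------------------------------
# stage-shift survival
# ---------------------------------------------------------------------------


class TestStageShift:
    def test_survival_curve_shape(self, params):
        s0 = survival_probability(params, DiseaseState(0, False, 0), 0.0)
        assert s0 == pytest.approx(1.0)
        s = [survival_probability(params, DiseaseState(0, False, 0), t) for t in (5, 10, 15)]
        assert s[0] > s[1] > s[2]

    def test_same_state_same_seed_identical(self, params, life_table):
        for pid in range(2000):
            h = simulate_natural_course(params, life_table, pid, seed=8)
            if h.dx_mode != "clinical":
                continue
            cd = stage_shift_survival(
                params, h, h.counterfactual_clinical_dx_age, h.stage_at_dx, seed=8
            )
            assert (cd is None) == (h.cancer_death_age is None)
            if cd is not None:
                assert cd == pytest.approx(h.cancer_death_age, rel=1e-12)
            break

    def test_earlier_stage_paired_draws_dominate(self, params):
        u = np.random.default_rng(0).random(100_000)
        early = sample_survival_time(params, np.zeros(u.shape, int), np.zeros(u.shape, bool), np.full(u.shape, 1), u)
        late = sample_survival_time(params, np.full(u.shape, 2), np.ones(u.shape, bool), np.full(u.shape, 1), u)
        assert np.all(early >= late)
        finite = np.isfinite(early) & np.isfinite(late)
        assert early[finite].mean() > late[finite].mean()

    def test_contract_violation_raises(self, params, life_table):
        h = simulate_natural_course(params, life_table, 0, seed=1)
        if h.counterfactual_clinical_dx_age is None:
            h.counterfactual_clinical_dx_age = 70.0
        with pytest.raises(ParameterError):
            stage_shift_survival(
                params, h, h.counterfactual_clinical_dx_age + 5.0,
                DiseaseState(0, False, 0), seed=1,
            )
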