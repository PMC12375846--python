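"""Costs and quality-of-life: attach euros and utilities to event logs and
life courses, discounted to present value.

Conventions
-----------
* Discounting is annual-equivalent continuous: a payment at time ``t`` years
  after age 45 is worth ``(1+r)^-t``; ongoing per-year costs over an
  interval integrate that factor in closed form.  Events before age 45
  clamp to ``t = 0``.
* Quality adjustment uses the multiplicative model: the utility at an age
  is the age-specific background utility times the product of active
  health-state utilities.  Accumulation applies each state as a
  disutility rectangle of its configured duration (the first-order
  expansion of the product; states rarely overlap).
* Life-years and QALYs integrate from age 45 to death; QALYs use annual
  midpoint discounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .screening import (
    DX_CLINICAL,
    DX_SCREEN,
    ScreenResult,
    ScreeningRecord,
    active_surveillance_schedule,
    strategy_preset,
)
from .natural_history import Cohort, LifeHistory


class ConfigurationError(ValueError):
    pass


@dataclass
class CostSchedule:
    """Per-event and per-year costs in 2023 euros."""

    values: dict

    def __post_init__(self):
        for k, v in self.values.items():
            if v < 0:
                raise ConfigurationError(f"cost '{k}' must be >= 0")

    def __getitem__(self, key: str) -> float:
        if key not in self.values:
            raise ConfigurationError(f"no cost entry for event kind '{key}'")
        return float(self.values[key])


@dataclass
class UtilityInputs:
    """Background utility curve plus per-state utilities and durations."""

    background_ages: list
    background_values: list
    state_utility: dict
    state_duration_years: dict
    utility_set_name: str = "PORPUS-U"

    def __post_init__(self):
        bg = np.asarray(self.background_values, dtype=float)
        if np.any((bg < 0) | (bg > 1)):
            raise ConfigurationError("background utilities must lie in [0, 1]")
        for k, v in self.state_utility.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"state utility '{k}' must lie in [0, 1]")
        for k, v in self.state_duration_years.items():
            if v is not None and v <= 0:
                raise ConfigurationError(f"state duration '{k}' must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "UtilityInputs":
        return cls(
            background_ages=d["background_ages"],
            background_values=d["background_values"],
            state_utility=d["state_utility"],
            state_duration_years=d["state_duration_years"],
            utility_set_name=d.get("utility_set_name", "PORPUS-U"),
        )

    def background(self, age):
        return np.interp(age, self.background_ages, self.background_values)

    def state(self, name: str) -> float:
        if name not in self.state_utility:
            raise ConfigurationError(f"unknown health state '{name}'")
        return float(self.state_utility[name])

    def duration(self, name: str) -> Optional[float]:
        return self.state_duration_years.get(name)


# ---------------------------------------------------------------------------
# discounting
# ---------------------------------------------------------------------------

REF_AGE = 45.0


def discount_value(amount, event_time_years_from_age_45, annual_rate) -> float:
    """Present value of ``amount`` paid ``t`` years after age 45."""
    if annual_rate < 0:
        raise ConfigurationError("discount rate must be >= 0")
    t = max(0.0, float(event_time_years_from_age_45))
    return float(amount) / (1.0 + annual_rate) ** t


def _disc_at_age(age, rate):
    t = np.maximum(np.asarray(age, dtype=float) - REF_AGE, 0.0)
    return (1.0 + rate) ** (-t)


def _disc_interval(start_age, end_age, rate):
    """Integral of the discount factor over an age interval.  Time before
    the reference age discounts at factor 1 (t clamped to 0); equals the
    interval length when rate = 0."""
    s_raw = np.asarray(start_age, dtype=float)
    e_raw = np.maximum(np.asarray(end_age, dtype=float), s_raw)
    pre = np.clip(np.minimum(e_raw, REF_AGE) - s_raw, 0.0, None)
    s = np.maximum(s_raw - REF_AGE, 0.0)
    e = np.maximum(e_raw - REF_AGE, 0.0)
    if rate == 0.0:
        return e_raw - s_raw
    lr = np.log1p(rate)
    return pre + ((1.0 + rate) ** (-s) - (1.0 + rate) ** (-e)) / lr


def utility_at_age(inputs: UtilityInputs, age: float, active_states) -> float:
    """Instantaneous utility: background(age) x product of active states."""
    u = float(inputs.background(age))
    for s in active_states:
        u *= inputs.state(s)
    return u


# ---------------------------------------------------------------------------
# treatment plan shared by the per-person and cohort routes
# ---------------------------------------------------------------------------


def treatment_plan(
    dx_age: Optional[float],
    met_at_dx: bool,
    grade: int,
    cancer_death_age: Optional[float],
    death_age: float,
    econ: dict,
) -> dict:
    """Treatment modality and dated phases for one diagnosed man.

    Modality by grade/stage/age (config ``treatment_rules``): metastatic
    disease -> ADT/chemo; localized GS<7 within the age limit -> active
    surveillance; other localized within the radical age limit -> radical
    treatment; beyond it -> ADT.  Cancer deaths are preceded by an ADT/chemo
    phase and a terminal palliative phase.
    """
    if dx_age is None:
        return {"mode": None, "phases": [], "as_end": None}
    rules = econ["treatment_rules"]
    adty = econ["adt_years_before_death"]
    term = econ["terminal_years"]
    cd = cancer_death_age
    if met_at_dx:
        mode = "adt"
    elif grade <= rules["as_grade_max"] and dx_age <= rules["as_age_max"]:
        mode = "as"
    elif dx_age <= rules["radical_age_max"]:
        mode = "radical"
    else:
        mode = "adt"

    if cd is not None:
        t_term = max(dx_age, cd - term)
        t_adt = max(dx_age, cd - term - adty)
    else:
        t_term = t_adt = death_age

    phases = []
    as_end = None
    if mode == "as":
        as_end = min(death_age, t_adt)
        phases.append(("active_surveillance", dx_age, as_end))
        if cd is not None:
            phases.append(("adt_chemo", t_adt, t_term))
            phases.append(("palliative_terminal", t_term, min(cd, death_age)))
    elif mode == "radical":
        if cd is not None:
            phases.append(("adt_chemo", t_adt, t_term))
            phases.append(("palliative_terminal", t_term, min(cd, death_age)))
    else:  # adt from diagnosis
        phases.append(("adt_chemo", dx_age, t_term if cd is not None else death_age))
        if cd is not None:
            phases.append(("palliative_terminal", t_term, min(cd, death_age)))
    phases = [(k, s, min(e, death_age)) for k, s, e in phases if e > s]
    return {"mode": mode, "phases": phases, "as_end": as_end}


_PHASE_COST = {"adt_chemo": "adt_chemo_per_year", "palliative_terminal": "palliative_per_year"}


# ---------------------------------------------------------------------------
# per-person accumulation (reference route)
# ---------------------------------------------------------------------------


_HISTORY_CD = object()  # sentinel: take cancer death from the history


def _person_plan(record, history, econ, death_age, cancer_death_age=_HISTORY_CD):
    dx_age = dx_met = None
    grade = history.grade_category if history.grade_category is not None else -1
    for age, kind, payload in record.events:
        if kind in ("screen_dx", "clinical_dx"):
            dx_age = age
            dx_met = bool(payload.metastasis) if payload is not None else False
    if grade < 0:
        # no underlying cancer: diagnosis event carries no treatment pathway
        return {"mode": None, "phases": [], "as_end": None}, dx_age
    if cancer_death_age is _HISTORY_CD:
        cancer_death_age = history.cancer_death_age
    cd = cancer_death_age if dx_age is not None else None
    return treatment_plan(dx_age, bool(dx_met), grade, cd, death_age, econ), dx_age


def accumulate_costs(
    record: ScreeningRecord,
    history: LifeHistory,
    costs: CostSchedule,
    rate: float,
    strategy=None,
    econ: Optional[dict] = None,
    death_age: Optional[float] = None,
    cancer_death_age=_HISTORY_CD,
) -> tuple[float, float]:
    """Event-by-event cost accumulation for one man: (undiscounted,
    discounted) 2023 euros.  ``death_age`` and ``cancer_death_age`` default
    to the history's natural-course values; pass the strategy-level values
    for screen-detected (stage-shifted) cases."""
    from .defaults import default_economic_config

    econ = econ or default_economic_config()
    if strategy is None:
        strategy = strategy_preset(record.strategy)
    death_age = death_age if death_age is not None else history.death_age
    bx_cost = (
        costs["combined_biopsy"]
        if strategy.biopsy_type_on_workup == "combined-targeted-systematic"
        else costs["systematic_biopsy"]
    )
    event_cost = {
        "invitation": costs["invitation"],
        "psa_test": costs["psa_test"],
        "dre_test": costs["dre_test"],
        "mri": costs["mri"],
        "biopsy": bx_cost,
        "clinical_dx": (
            costs["clinical_workup_mri"] if strategy.mri_triage
            else costs["clinical_workup_sbx"]
        ),
        "screen_dx": 0.0,
        "as_visit": costs["as_visit"],
        "as_mri_biopsy": costs["as_mri_biopsy"],
        "treatment_start": 0.0,
    }
    undisc = disc = 0.0
    for age, kind, payload in record.events:
        if age > death_age:
            continue
        c = event_cost.get(kind)
        if c is None:
            raise ConfigurationError(f"no cost entry for event kind '{kind}'")
        undisc += c
        disc += c * float(_disc_at_age(age, rate))
        if kind == "dre_test" and payload == "positive":
            undisc += costs["psa_test"]
            disc += costs["psa_test"] * float(_disc_at_age(age, rate))

    plan, dx_age = _person_plan(record, history, econ, death_age, cancer_death_age)
    if plan["mode"] == "radical":
        undisc += costs["radical_treatment"]
        disc += costs["radical_treatment"] * float(_disc_at_age(dx_age, rate))
        k = 1
        while dx_age + k <= min(death_age, dx_age + costs["followup_years"]):
            undisc += costs["followup_visit_per_year"]
            disc += costs["followup_visit_per_year"] * float(
                _disc_at_age(dx_age + k, rate)
            )
            k += 1
    if plan["mode"] == "as" and plan["as_end"] is not None and dx_age < plan["as_end"]:
        for age, kind in active_surveillance_schedule(dx_age, plan["as_end"]):
            undisc += costs[kind]
            disc += costs[kind] * float(_disc_at_age(age, rate))
    for kind, s, e in plan["phases"]:
        if kind in _PHASE_COST:
            c = costs[_PHASE_COST[kind]]
            undisc += c * (e - s)
            disc += c * float(_disc_interval(s, e, rate))
    return float(undisc), float(disc)


def accumulate_qalys(
    record: ScreeningRecord,
    history: LifeHistory,
    inputs: UtilityInputs,
    rate: float,
    econ: Optional[dict] = None,
    death_age: Optional[float] = None,
    cancer_death_age=_HISTORY_CD,
) -> tuple[float, float, float, float]:
    """(LY undiscounted, LY discounted, QALY undiscounted, QALY discounted)
    from age 45 for one man."""
    from .defaults import default_economic_config

    econ = econ or default_economic_config()
    death_age = death_age if death_age is not None else history.death_age
    T = max(0.0, death_age - REF_AGE)
    ly_undisc = T
    ly_disc = float(_disc_interval(REF_AGE, death_age, rate))

    qaly_undisc = _base_qaly_scalar(death_age, inputs, 0.0)
    qaly_disc = _base_qaly_scalar(death_age, inputs, rate)

    rects = []  # (state, start)
    for age, kind, payload in record.events:
        if age > death_age:
            continue
        if kind in ("psa_test", "dre_test"):
            rects.append(("screen_attendance", age))
        elif kind in ("biopsy", "as_mri_biopsy"):
            rects.append(("biopsy", age))
        elif kind in ("screen_dx", "clinical_dx"):
            rects.append(("diagnosis", age))
    plan, dx_age = _person_plan(record, history, econ, death_age, cancer_death_age)
    if plan["mode"] == "radical":
        rects.append(("radical_treatment", dx_age))
        dur_rt = inputs.duration("radical_treatment") or 0.0
        rects.append(("post_treatment", dx_age + dur_rt))
    du = 0.0
    du0 = 0.0
    for state, start in rects:
        d = inputs.duration(state)
        if d is None:
            continue
        dq0, dq = _rect_disutility(start, d, inputs.state(state), inputs, rate, death_age)
        du0 += dq0
        du += dq
    for kind, s, e in plan["phases"]:
        if kind in inputs.state_utility:
            dq0, dq = _rect_disutility(s, e - s, inputs.state(kind), inputs, rate, death_age)
            du0 += dq0
            du += dq
    if plan["mode"] == "as" and plan["as_end"] is not None and dx_age < plan["as_end"]:
        # periodic AS biopsies carry the biopsy disutility
        for age, kind in active_surveillance_schedule(dx_age, plan["as_end"]):
            if kind == "as_mri_biopsy":
                dq0, dq = _rect_disutility(
                    age, inputs.duration("biopsy") or 0.0, inputs.state("biopsy"),
                    inputs, rate, death_age,
                )
                du0 += dq0
                du += dq
    return ly_undisc, ly_disc, max(qaly_undisc - du0, 0.0), max(qaly_disc - du, 0.0)


def _base_qaly_scalar(death_age, inputs, rate):
    q = 0.0
    a0 = REF_AGE
    while a0 < death_age - 1e-12:
        seg = min(1.0, death_age - a0)
        mid = a0 + seg / 2.0
        q += float(inputs.background(mid)) * float(_disc_at_age(mid, rate)) * seg
        a0 += 1.0
    return q


def _rect_disutility(start, duration, state_u, inputs, rate, death_age):
    s = max(start, REF_AGE)
    e = min(start + duration, death_age)
    if e <= s:
        return 0.0, 0.0
    mid = (s + e) / 2.0
    loss = float(inputs.background(mid)) * (1.0 - state_u) * (e - s)
    return loss, loss * float(_disc_at_age(mid, rate))


# ---------------------------------------------------------------------------
# vectorized cohort economics
# ---------------------------------------------------------------------------


def cohort_economics(
    cohort: Cohort, res: ScreenResult, econ: Optional[dict] = None
) -> pd.DataFrame:
    """Per-person counts, life-years, QALYs and costs for one strategy.

    Applies exactly the same event, phase and discounting rules as the
    per-person reference functions, vectorized over the cohort.
    """
    from .defaults import default_economic_config

    econ = econ or default_economic_config()
    costs = CostSchedule(econ["costs"]) if not isinstance(econ["costs"], CostSchedule) else econ["costs"]
    inputs = (
        UtilityInputs.from_dict(econ["utilities"])
        if not isinstance(econ["utilities"], UtilityInputs)
        else econ["utilities"]
    )
    rate = econ["discount_rate"]
    strategy = res.strategy
    n = cohort.n
    death = res.death_age

    bx_cost = (
        costs["combined_biopsy"]
        if strategy.biopsy_type_on_workup == "combined-targeted-systematic"
        else costs["systematic_biopsy"]
    )

    # ---- screening event costs (round matrices) -------------------------
    age_r = res.age_r.astype(np.float64)
    disc_r = np.where(np.isfinite(age_r), _disc_at_age(np.nan_to_num(age_r, nan=REF_AGE), rate), 0.0)
    ev_undisc = np.zeros(n)
    ev_disc = np.zeros(n)
    for flags, c in (
        (res.invited_r, costs["invitation"]),
        (res.psa_r, costs["psa_test"]),
        (res.dre_r, costs["dre_test"]),
        (res.reflex_psa_r, costs["psa_test"]),
        (res.mri_r, costs["mri"]),
        (res.biopsy_r, bx_cost),
    ):
        if c == 0.0:
            continue
        ev_undisc += c * flags.sum(axis=1)
        ev_disc += c * (flags * disc_r).sum(axis=1)

    # clinical diagnostic work-up
    clin = res.dx_mode == DX_CLINICAL
    c_workup = (
        costs["clinical_workup_mri"] if strategy.mri_triage
        else costs["clinical_workup_sbx"]
    )
    dx_age = np.nan_to_num(res.dx_age, nan=REF_AGE)
    ev_undisc += c_workup * clin
    ev_disc += c_workup * clin * _disc_at_age(dx_age, rate)

    # ---- treatment plan (vectorized version of treatment_plan) ----------
    rules = econ["treatment_rules"]
    diagnosed = res.dx_mode > 0
    grade = np.maximum(res.dx_grade, 0)
    cd = res.cancer_death_age  # NaN if none
    has_cd = np.isfinite(cd)
    adty, term = econ["adt_years_before_death"], econ["terminal_years"]

    mode = np.where(
        ~diagnosed,
        0,
        np.where(
            res.dx_met,
            3,
            np.where(
                (grade <= rules["as_grade_max"]) & (res.dx_age <= rules["as_age_max"]),
                1,
                np.where(res.dx_age <= rules["radical_age_max"], 2, 3),
            ),
        ),
    )  # 0 none, 1 AS, 2 radical, 3 ADT

    t_term = np.where(has_cd, np.maximum(dx_age, np.nan_to_num(cd) - term), death)
    t_adt = np.where(has_cd, np.maximum(dx_age, np.nan_to_num(cd) - term - adty), death)
    cd_end = np.where(has_cd, np.minimum(np.nan_to_num(cd), death), death)

    ph_undisc = np.zeros(n)
    ph_disc = np.zeros(n)
    du_undisc = np.zeros(n)
    du_disc = np.zeros(n)

    def add_phase(mask, s, e, cost_key, state_key):
        s = np.where(mask, s, REF_AGE)
        e = np.where(mask, np.minimum(e, death), REF_AGE)
        length = np.maximum(e - s, 0.0)
        if cost_key is not None:
            c = costs[cost_key]
            ph_undisc[mask] += c * length[mask]
            ph_disc[mask] += c * _disc_interval(s, e, rate)[mask]
        if state_key is not None and state_key in inputs.state_utility:
            mid = (np.maximum(s, REF_AGE) + e) / 2.0
            lo = np.maximum(s, REF_AGE)
            L = np.maximum(e - lo, 0.0)
            loss = inputs.background(mid) * (1.0 - inputs.state(state_key)) * L
            du_undisc[mask] += loss[mask]
            du_disc[mask] += (loss * _disc_at_age(mid, rate))[mask]

    is_as = mode == 1
    is_rad = mode == 2
    is_adt = mode == 3
    as_end = np.where(is_as, np.minimum(death, t_adt), REF_AGE)

    add_phase(is_as, dx_age, as_end, None, "active_surveillance")
    add_phase(is_as & has_cd, t_adt, t_term, "adt_chemo_per_year", "adt_chemo")
    add_phase(is_as & has_cd, t_term, cd_end, "palliative_per_year", "palliative_terminal")
    add_phase(is_rad & has_cd, t_adt, t_term, "adt_chemo_per_year", "adt_chemo")
    add_phase(is_rad & has_cd, t_term, cd_end, "palliative_per_year", "palliative_terminal")
    add_phase(is_adt, dx_age, np.where(has_cd, t_term, death), "adt_chemo_per_year", "adt_chemo")
    add_phase(is_adt & has_cd, t_term, cd_end, "palliative_per_year", "palliative_terminal")

    # radical treatment event + follow-up visits
    ph_undisc += np.where(is_rad, costs["radical_treatment"], 0.0)
    ph_disc += np.where(is_rad, costs["radical_treatment"] * _disc_at_age(dx_age, rate), 0.0)
    fu_limit = np.minimum(death, dx_age + costs["followup_years"])
    for k in range(1, int(costs["followup_years"]) + 1):
        visit_age = dx_age + k
        ok = is_rad & (visit_age <= fu_limit)
        ph_undisc += np.where(ok, costs["followup_visit_per_year"], 0.0)
        ph_disc += np.where(ok, costs["followup_visit_per_year"] * _disc_at_age(visit_age, rate), 0.0)

    # AS monitoring events (same grid as active_surveillance_schedule)
    as_idx = np.flatnonzero(is_as)
    n_as_visits = np.zeros(n)
    n_as_bx = np.zeros(n)
    if as_idx.size:
        d0 = dx_age[as_idx]
        horizon = as_end[as_idx] - d0
        t = 0.0
        while t < 60.0:
            live = t < horizon - 1e-9
            if not live.any():
                break
            ages = d0 + t
            n_as_visits[as_idx] += live
            ph_undisc[as_idx] += costs["as_visit"] * live
            ph_disc[as_idx] += costs["as_visit"] * _disc_at_age(ages, rate) * live
            t += 0.25 if t < 2.0 - 1e-9 else 0.5
        t_bx = [1.5, 3.0]
        while t_bx[-1] + 3.0 < 60.0:
            t_bx.append(t_bx[-1] + 3.0)
        for tb in t_bx:
            live = tb < horizon - 1e-9
            if not live.any():
                continue
            ages = d0 + tb
            n_as_bx[as_idx] += live
            ph_undisc[as_idx] += costs["as_mri_biopsy"] * live
            ph_disc[as_idx] += costs["as_mri_biopsy"] * _disc_at_age(ages, rate) * live
            # AS biopsies carry the biopsy disutility
            dur_bx = inputs.duration("biopsy") or 0.0
            s = np.maximum(ages, REF_AGE)
            e = np.minimum(ages + dur_bx, death[as_idx])
            L = np.maximum(e - s, 0.0)
            mid = (s + e) / 2.0
            loss = inputs.background(mid) * (1.0 - inputs.state("biopsy")) * L
            du_undisc[as_idx] += loss * live
            du_disc[as_idx] += loss * _disc_at_age(mid, rate) * live

    # ---- life-years and QALYs -------------------------------------------
    T = np.maximum(death - REF_AGE, 0.0)
    ly_undisc = T
    ly_disc = _disc_interval(REF_AGE, death, rate)
    qaly_undisc = _base_qaly_vector(death, inputs, 0.0)
    qaly_disc = _base_qaly_vector(death, inputs, rate)

    # screening attendance + biopsy disutilities from round matrices
    att_states = (
        (res.psa_r | res.dre_r, "screen_attendance"),
        (res.biopsy_r, "biopsy"),
    )
    for flags, state in att_states:
        dur = inputs.duration(state) or 0.0
        uloss = 1.0 - inputs.state(state)
        if dur == 0.0 or uloss == 0.0:
            continue
        start = np.where(np.isfinite(age_r), age_r, REF_AGE)
        s = np.maximum(start, REF_AGE)
        e = np.minimum(start + dur, death[:, None])
        L = np.maximum(e - s, 0.0)
        mid = (s + e) / 2.0
        loss = flags * inputs.background(mid) * uloss * L
        du_undisc += loss.sum(axis=1)
        du_disc += (loss * _disc_at_age(mid, rate)).sum(axis=1)

    # diagnosis disutility; radical treatment + post-treatment phases
    def add_rect(mask, start, dur, state):
        s = np.maximum(start, REF_AGE)
        e = np.minimum(start + dur, death)
        L = np.maximum(e - s, 0.0)
        mid = (s + e) / 2.0
        loss = inputs.background(mid) * (1.0 - inputs.state(state)) * L
        du_undisc[mask] += loss[mask]
        du_disc[mask] += (loss * _disc_at_age(mid, rate))[mask]

    add_rect(diagnosed, dx_age, inputs.duration("diagnosis") or 0.0, "diagnosis")
    rt_dur = inputs.duration("radical_treatment") or 0.0
    add_rect(is_rad, dx_age, rt_dur, "radical_treatment")
    add_rect(is_rad, dx_age + rt_dur, inputs.duration("post_treatment") or 0.0,
             "post_treatment")

    qaly_undisc = np.maximum(qaly_undisc - du_undisc, 0.0)
    qaly_disc = np.maximum(qaly_disc - du_disc, 0.0)

    out = pd.DataFrame(
        {
            "person_id": cohort.person_ids,
            "n_psa": res.n_psa,
            "n_dre": res.n_dre,
            "n_mri": res.n_mri,
            "n_biopsy_screen": res.n_biopsy_screen,
            "n_biopsy_clin": clin.astype(int),
            "dx_mode": res.dx_mode,
            "dx_age": res.dx_age,
            "dx_grade": res.dx_grade,
            "dx_met": res.dx_met,
            "dx_tcat": res.dx_tcat,
            "overdiagnosed": res.overdiagnosed,
            "pca_death": np.isfinite(res.cancer_death_age)
            & (res.cancer_death_age <= res.death_age + 1e-9),
            "death_age": death,
            "ly_undisc": ly_undisc,
            "ly_disc": ly_disc,
            "qaly_undisc": qaly_undisc,
            "qaly_disc": qaly_disc,
            "cost_undisc": ev_undisc + ph_undisc,
            "cost_disc": ev_disc + ph_disc,
        }
    )
    return out


def _base_qaly_vector(death_age, inputs, rate):
    death = np.asarray(death_age, dtype=float)
    q = np.zeros(death.shape)
    for y in range(61):
        a0 = REF_AGE + y
        seg = np.clip(death - a0, 0.0, 1.0)
        mid = a0 + seg / 2.0
        q += inputs.background(mid) * _disc_at_age(mid, rate) * seg
    return q
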