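"""Screening policies and their application to simulated life histories.

A :class:`StrategyDefinition` declares a policy (ages, PSA risk bands and
rescreen intervals, workup threshold, MRI triage, participation).  The
cohort engine applies the policy round by round:

    invitation -> participation draw -> primary test (PSA or DRE)
    -> [MRI triage] -> biopsy acceptance -> biopsy -> detection

Detection probabilities come from :class:`TestProfile` objects given the
man's true underlying state at the screen age.  Clinical presentations that
occur before any screen detection are realized with the arm-appropriate
diagnostic work-up.  Screen-detected cancers receive stage-shifted survival
(see :mod:`prostasim.natural_history`).

All test and participation draws are keyed by (person, age), so the same
man tested at the same age gets the same result under every strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import _rand
from .natural_history import (
    AGE_MAX,
    Cohort,
    DiseaseState,
    LifeHistory,
    sample_survival_time,
)

DX_NONE, DX_CLINICAL, DX_SCREEN = 0, 1, 2

_MAX_ROUNDS = 40


class ConfigurationError(ValueError):
    pass


class LookupError_(KeyError):
    pass


@dataclass
class TestProfile:
    """Detection characteristics of one test.

    ``sensitivity`` maps the true state to P(positive | cancer): either
    ``by_grade`` (three Gleason strata; used for MRI and biopsies, where
    the significant/insignificant split drives overdiagnosis) or
    ``by_tcat`` plus ``met`` (used for DRE, where palpability tracks local
    extent).  ``specificity`` is P(negative | no cancer).
    """

    __test__ = False  # not a test class despite the name

    test_name: str
    sensitivity: dict
    specificity: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.specificity <= 1.0):
            raise ConfigurationError("specificity must be in [0, 1]")
        for v in self.sensitivity.values():
            arr = np.atleast_1d(np.asarray(v, dtype=float))
            if np.any((arr < 0) | (arr > 1)):
                raise ConfigurationError("sensitivities must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TestProfile":
        return cls(**d)

    def p_positive(self, is_case, tcat, met, grade) -> np.ndarray:
        p = np.full(np.shape(is_case), 1.0 - self.specificity)
        if "by_grade" in self.sensitivity:
            sens = np.asarray(self.sensitivity["by_grade"], dtype=float)[
                np.maximum(grade, 0)
            ]
        else:
            sens = np.asarray(self.sensitivity["by_tcat"], dtype=float)[tcat]
            if "met" in self.sensitivity:
                sens = np.where(met, self.sensitivity["met"], sens)
        return np.where(is_case, sens, p)


@dataclass
class StrategyDefinition:
    """Declarative screening policy."""

    name: str
    start_age: float
    stop_age: float
    primary_test: str  # "PSA" | "DRE" | "none"
    risk_bands: tuple = ()  # ((psa_upper_cutoff, interval_years or None), ...)
    workup_threshold: Optional[float] = None  # ng/mL
    mri_triage: bool = False
    biopsy_type_on_workup: str = "systematic-only"
    dre_interval: float = 1.0
    workup_negative_interval: Optional[float] = 2.0
    reinvite_interval: float = 2.0
    participation: dict = field(
        default_factory=lambda: {"first_screen": 0.75, "rescreen": 0.95, "biopsy": 0.65}
    )

    def __post_init__(self):
        if self.primary_test != "none" and not self.start_age < self.stop_age:
            raise ConfigurationError("start_age must be < stop_age")
        cutoffs = [c for c, _ in self.risk_bands]
        if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ConfigurationError("risk-band cutoffs must be strictly increasing")
        for v in self.participation.values():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError("participation probabilities must be in [0,1]")

    def band_interval(self, psa: float) -> Optional[float]:
        """Rescreen interval (years) implied by a measured PSA value."""
        if psa < 0:
            raise ConfigurationError("PSA must be >= 0")
        for cutoff, interval in self.risk_bands:
            if psa < cutoff:
                return interval
        return self.workup_negative_interval

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StrategyDefinition":
        d = dict(d)
        d["risk_bands"] = tuple(tuple(b) for b in d.get("risk_bands", ()))
        return cls(**d)


_PRESET_PARTICIPATION = {"first_screen": 0.75, "rescreen": 0.95, "biopsy": 0.65}


def _psa_ras(start, stop, mri) -> StrategyDefinition:
    tag = "mri" if mri else "nomri"
    return StrategyDefinition(
        name=f"psa_ras_{start}_{stop}_{tag}",
        start_age=start,
        stop_age=stop,
        primary_test="PSA",
        risk_bands=((1.5, 5.0), (3.0, 2.0)),
        workup_threshold=3.0,
        mri_triage=mri,
        biopsy_type_on_workup=(
            "combined-targeted-systematic" if mri else "systematic-only"
        ),
        participation=dict(_PRESET_PARTICIPATION),
    )


def _presets() -> dict:
    presets = {
        "no_screening": StrategyDefinition(
            name="no_screening",
            start_age=0.0,
            stop_age=0.0,
            primary_test="none",
            mri_triage=True,  # symptomatic cases get MRI + combined biopsy
            biopsy_type_on_workup="combined-targeted-systematic",
            participation=dict(_PRESET_PARTICIPATION),
        ),
        "dre_45_75": StrategyDefinition(
            name="dre_45_75",
            start_age=45.0,
            stop_age=75.0,
            primary_test="DRE",
            dre_interval=1.0,
            reinvite_interval=1.0,
            participation=dict(_PRESET_PARTICIPATION),
        ),
    }
    for start in (45, 50):
        for stop in (60, 70):
            for mri in (False, True):
                s = _psa_ras(start, stop, mri)
                presets[s.name] = s
    return presets


PRESET_NAMES = tuple(sorted(_presets()))


def strategy_preset(name: str) -> StrategyDefinition:
    """Return one of the ten evaluated strategies by name."""
    presets = _presets()
    if name not in presets:
        raise LookupError_(
            f"unknown strategy '{name}'; valid names: {', '.join(sorted(presets))}"
        )
    return presets[name]


def next_invitation(
    strategy: StrategyDefinition,
    last_screen_age: Optional[float],
    last_psa: Optional[float],
) -> Optional[float]:
    """Age of the next screening invitation, or None when the policy stops.

    Invitations are issued while the invitation age is <= stop_age; an
    interval overshooting the stop age ends the programme for that man.
    """
    if last_screen_age is None:
        return float(strategy.start_age)
    if strategy.primary_test == "DRE":
        nxt = last_screen_age + strategy.dre_interval
    else:
        if last_psa is None:
            nxt = last_screen_age + strategy.reinvite_interval
        else:
            interval = strategy.band_interval(last_psa)
            if interval is None and last_psa < (strategy.workup_threshold or np.inf):
                return None  # band with no rescreen: exit programme
            nxt = last_screen_age + (interval or strategy.reinvite_interval)
    return float(nxt) if nxt <= strategy.stop_age + 1e-9 else None


# ---------------------------------------------------------------------------
# cohort engine
# ---------------------------------------------------------------------------


class ScreenResult:
    """Struct-of-arrays outcome of applying one strategy to a cohort.

    Round-level matrices (n x R) carry the event ages and flags needed by
    the economics layer; person-level vectors carry diagnosis, stage shift
    and death under the strategy.
    """

    def __init__(self, n: int, rounds: int, strategy: StrategyDefinition):
        self.strategy = strategy
        self.n = n
        self.rounds = rounds
        shape = (n, rounds)
        self.age_r = np.full(shape, np.nan, dtype=np.float32)
        self.invited_r = np.zeros(shape, dtype=bool)
        self.attended_r = np.zeros(shape, dtype=bool)
        self.psa_r = np.zeros(shape, dtype=bool)
        self.dre_r = np.zeros(shape, dtype=bool)
        self.reflex_psa_r = np.zeros(shape, dtype=bool)
        self.mri_r = np.zeros(shape, dtype=bool)
        self.biopsy_r = np.zeros(shape, dtype=bool)
        self.screen_dx_age = np.full(n, np.nan)
        self.screen_tcat = np.full(n, -1, dtype=np.int8)
        self.screen_met = np.zeros(n, dtype=bool)
        # realized diagnosis under the strategy
        self.dx_mode = np.zeros(n, dtype=np.int8)
        self.dx_age = np.full(n, np.nan)
        self.dx_tcat = np.full(n, -1, dtype=np.int8)
        self.dx_met = np.zeros(n, dtype=bool)
        self.dx_grade = np.full(n, -1, dtype=np.int8)
        self.overdiagnosed = np.zeros(n, dtype=bool)
        self.cancer_death_age = np.full(n, np.nan)
        self.death_age = np.full(n, np.nan)

    @property
    def n_psa(self):
        return self.psa_r.sum(axis=1)

    @property
    def n_dre(self):
        return self.dre_r.sum(axis=1)

    @property
    def n_mri(self):
        return self.mri_r.sum(axis=1)

    @property
    def n_biopsy_screen(self):
        return self.biopsy_r.sum(axis=1)

    @property
    def n_invitations(self):
        return self.invited_r.sum(axis=1)


def _age_slot(age) -> np.ndarray:
    # quarter-year key so draws align across strategies
    return np.round(np.asarray(age, dtype=float) * 4).astype(np.int64)


def run_cohort_screening(
    cohort: Cohort,
    strategy: StrategyDefinition,
    tests: dict,
    seed: int,
) -> ScreenResult:
    """Apply ``strategy`` to every man in ``cohort``.

    ``tests`` maps test names ('psa' noise is part of the natural-history
    model; 'dre', 'mri', 'systematic_biopsy', 'combined_biopsy') to
    :class:`TestProfile`.  Missing profiles required by the strategy raise
    :class:`ConfigurationError`.
    """
    n = cohort.n
    pid = cohort.person_ids
    res = ScreenResult(n, _MAX_ROUNDS, strategy)

    _require_tests(strategy, tests)

    censor = np.minimum(
        np.nan_to_num(cohort.clin_dx_age, nan=np.inf), cohort.death_age_ns
    )

    if strategy.primary_test != "none":
        u_first = _rand.uniform_slot(seed, pid, _rand.PURPOSE_PARTICIPATION, 0)
        ever = u_first < strategy.participation["first_screen"]

        next_age = np.full(n, float(strategy.start_age))
        active = np.ones(n, dtype=bool)
        first_round = np.ones(n, dtype=bool)
        detected = np.zeros(n, dtype=bool)

        bx_name = (
            "combined_biopsy"
            if strategy.biopsy_type_on_workup == "combined-targeted-systematic"
            else "systematic_biopsy"
        )

        for r in range(_MAX_ROUNDS):
            active &= next_age <= strategy.stop_age + 1e-9
            live = active & (next_age < censor)
            if not live.any():
                break
            idx = np.flatnonzero(live)
            a = next_age[idx]
            slot = _age_slot(a)
            res.age_r[idx, r] = a
            res.invited_r[idx, r] = True

            # participation
            u_att = _rand.uniform_slot(
                seed, pid[idx], _rand.PURPOSE_PARTICIPATION, slot * 8 + 1
            )
            attend = np.where(
                first_round[idx],
                ever[idx],
                ever[idx] & (u_att < strategy.participation["rescreen"]),
            )
            res.attended_r[idx, r] = attend
            # men who never attend exit after the first invitation
            never = first_round[idx] & ~ever[idx]
            active[idx[never]] = False
            first_round[idx] = False

            # non-attenders (still in the programme) are re-invited
            nonatt = idx[~attend]
            next_age[nonatt] = next_age[nonatt] + strategy.reinvite_interval
            att = idx[attend]
            if att.size == 0:
                continue
            a_att = next_age[att]
            slot_att = _age_slot(a_att)

            is_case = _subset_state(cohort, a_att, att, "case")
            tcat = _subset_state(cohort, a_att, att, "tcat")
            met = _subset_state(cohort, a_att, att, "met")
            grade = cohort.grade[att]

            if strategy.primary_test == "PSA":
                res.psa_r[att, r] = True
                z = _ndtri(
                    _rand.uniform_slot(seed, pid[att], _rand.PURPOSE_PSA_NOISE, slot_att)
                )
                lp = _true_lp(cohort, a_att, att)
                psa = np.exp(lp + cohort.params.noise_sd * z)
                workup = psa >= (strategy.workup_threshold or np.inf)

                # below-threshold: band interval or exit
                below = att[~workup]
                if below.size:
                    iv = _band_intervals(strategy, psa[~workup])
                    stays = np.isfinite(iv)
                    next_age[below] = np.where(stays, next_age[below] + iv, np.inf)
                    active[below[~stays]] = False

                cand = att[workup]
                if cand.size:
                    go_biopsy = np.ones(cand.size, dtype=bool)
                    if strategy.mri_triage:
                        res.mri_r[cand, r] = True
                        p_pos = tests["mri"].p_positive(
                            is_case[workup], tcat[workup], met[workup], grade[workup]
                        )
                        u_mri = _rand.uniform_slot(
                            seed, pid[cand], _rand.PURPOSE_SCREEN_TESTS,
                            _age_slot(next_age[cand]) * 8 + 2,
                        )
                        go_biopsy = u_mri < p_pos
                    _do_biopsy(
                        res, cohort, strategy, tests[bx_name], seed, pid, cand,
                        go_biopsy, r,
                        is_case[workup], tcat[workup], met[workup], grade[workup],
                        next_age, active, detected,
                    )
            else:  # DRE
                res.dre_r[att, r] = True
                p_pos = tests["dre"].p_positive(is_case, tcat, met, grade)
                u_dre = _rand.uniform_slot(
                    seed, pid[att], _rand.PURPOSE_SCREEN_TESTS, slot_att * 8 + 0
                )
                positive = u_dre < p_pos
                res.reflex_psa_r[att, r] = positive  # PSA cost on positive DRE
                neg = att[~positive]
                next_age[neg] = next_age[neg] + strategy.dre_interval
                cand = att[positive]
                if cand.size:
                    _do_biopsy(
                        res, cohort, strategy, tests["systematic_biopsy"], seed, pid,
                        cand, np.ones(cand.size, dtype=bool), r,
                        is_case[positive], tcat[positive], met[positive],
                        grade[positive], next_age, active, detected,
                        negative_interval=strategy.dre_interval,
                    )

    _finalize(res, cohort, seed)
    return res


def _true_lp(cohort, ages, idx):
    from .natural_history import log_psa_mean

    return log_psa_mean(
        cohort.params,
        cohort.psa_intercept_dev[idx],
        cohort.psa_slope_dev[idx],
        cohort.onset_age[idx],
        cohort.grade[idx],
        ages,
    )


def _subset_state(cohort, ages, idx, what):
    onset = np.nan_to_num(cohort.onset_age[idx], nan=np.inf)
    if what == "case":
        clin = np.nan_to_num(cohort.clin_dx_age[idx], nan=np.inf)
        return (ages >= onset) & (ages < clin)
    if what == "tcat":
        t = np.zeros(len(idx), dtype=np.int8)
        t += (ages >= np.nan_to_num(cohort.t2_age[idx], nan=np.inf)).astype(np.int8)
        t += (ages >= np.nan_to_num(cohort.t3_age[idx], nan=np.inf)).astype(np.int8)
        return t
    if what == "met":
        return ages >= np.nan_to_num(cohort.met_age[idx], nan=np.inf)
    raise ValueError(what)


def _band_intervals(strategy, psa_values):
    """Vectorized band -> rescreen interval lookup (inf = exit programme)."""
    psa = np.asarray(psa_values, dtype=float)
    default = strategy.workup_negative_interval
    iv = np.full(psa.shape, np.inf if default is None else float(default))
    for cutoff, interval in reversed(strategy.risk_bands):
        iv = np.where(psa < cutoff, np.inf if interval is None else interval, iv)
    return iv


def _do_biopsy(
    res, cohort, strategy, bx_profile, seed, pid, cand, go_biopsy, r,
    is_case, tcat, met, grade, next_age, active, detected,
    negative_interval=None,
):
    """Biopsy acceptance, the biopsy itself, and detection for candidates."""
    interval = (
        strategy.workup_negative_interval
        if negative_interval is None
        else negative_interval
    ) or strategy.reinvite_interval
    slot = _age_slot(next_age[cand])
    u_acc = _rand.uniform_slot(seed, pid[cand], _rand.PURPOSE_PARTICIPATION,
                               slot * 8 + 2)
    accept = go_biopsy & (u_acc < strategy.participation["biopsy"])
    res.biopsy_r[cand[accept], r] = True
    p_det = bx_profile.p_positive(is_case, tcat, met, grade)
    u_det = _rand.uniform_slot(seed, pid[cand], _rand.PURPOSE_SCREEN_TESTS,
                               slot * 8 + 3)
    hit = accept & (u_det < p_det) & is_case
    found = cand[hit]
    res.screen_dx_age[found] = next_age[found]
    res.screen_tcat[found] = tcat[hit]
    res.screen_met[found] = met[hit]
    detected[found] = True
    active[found] = False
    miss = cand[~hit]
    next_age[miss] = next_age[miss] + interval


def _ndtri(u):
    from scipy.special import ndtri

    return ndtri(u)


def _require_tests(strategy, tests):
    needed = []
    if strategy.primary_test == "DRE":
        needed += ["dre", "systematic_biopsy"]
    elif strategy.primary_test == "PSA":
        needed.append(
            "combined_biopsy"
            if strategy.biopsy_type_on_workup == "combined-targeted-systematic"
            else "systematic_biopsy"
        )
        if strategy.mri_triage:
            needed.append("mri")
    for name in needed:
        if name not in tests:
            raise ConfigurationError(
                f"strategy '{strategy.name}' requires a TestProfile for '{name}'"
            )


def _finalize(res: ScreenResult, cohort: Cohort, seed: int) -> None:
    """Realize diagnoses, stage shift, overdiagnosis and death."""
    n = cohort.n
    screen = np.isfinite(res.screen_dx_age)
    clin_cf = cohort.clin_dx_age  # realized counterfactual clinical dx (or NaN)
    clinical = ~screen & np.isfinite(clin_cf)

    res.dx_mode[screen] = DX_SCREEN
    res.dx_mode[clinical] = DX_CLINICAL
    res.dx_age = np.where(screen, res.screen_dx_age, clin_cf)
    res.dx_grade = np.where(screen | clinical, cohort.grade, -1).astype(np.int8)
    res.dx_tcat = np.where(
        screen, res.screen_tcat, cohort.stage_tcat_dx
    ).astype(np.int8)
    res.dx_met = np.where(screen, res.screen_met, cohort.stage_met_dx)

    # overdiagnosis: screen-detected but never clinically diagnosed in the
    # counterfactual lifetime
    res.overdiagnosed = screen & ~np.isfinite(clin_cf)

    # stage-shift survival for screen-detected cases with a counterfactual dx
    shift = screen & np.isfinite(clin_cf)
    cancer_death = np.where(
        np.isfinite(cohort.cancer_death_age_ns), cohort.cancer_death_age_ns, np.inf
    )
    if shift.any():
        t = sample_survival_time(
            cohort.params,
            res.screen_tcat[shift].astype(int),
            res.screen_met[shift],
            cohort.grade[shift].astype(int),
            cohort.u_surv[shift],
        )
        cd = clin_cf[shift] + t
        cancer_death = cancer_death.copy()
        cancer_death[shift] = cd
    # overdiagnosed and undiagnosed screen cases: no cancer death
    cancer_death[screen & ~np.isfinite(clin_cf)] = np.inf

    death = np.minimum(cohort.oc_death_age, cancer_death)
    res.cancer_death_age = np.where(
        cancer_death < cohort.oc_death_age, cancer_death, np.nan
    )
    res.death_age = death


# ---------------------------------------------------------------------------
# event log for one person
# ---------------------------------------------------------------------------


@dataclass
class ScreeningRecord:
    """Ordered per-person event log: (age, event_kind, payload)."""

    person_id: int
    strategy: str
    events: list

    def to_frame(self):
        """Tidy events table (person_id, age, event_kind, result)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "person_id": self.person_id,
                    "age": age,
                    "event_kind": kind,
                    "result": "" if payload is None else str(payload),
                }
                for age, kind, payload in self.events
            ],
            columns=["person_id", "age", "event_kind", "result"],
        )


def run_screening(
    history: LifeHistory,
    strategy: StrategyDefinition,
    tests: dict,
    seed: int,
    cohort: Optional[Cohort] = None,
    params=None,
    life_table=None,
) -> ScreeningRecord:
    """Apply a strategy to one man and return his ordered event log.

    When ``cohort`` is not given, the man's natural course is re-simulated
    from ``(person_id, seed)`` using ``params`` and ``life_table``.
    """
    from .natural_history import simulate_cohort

    if cohort is None:
        if params is None or life_table is None:
            raise ConfigurationError("pass a cohort, or params and life_table")
        cohort = simulate_cohort(
            params, life_table, seed=seed, person_ids=[history.person_id]
        )
    res = run_cohort_screening(cohort, strategy, tests, seed)
    i = int(np.flatnonzero(cohort.person_ids == history.person_id)[0])
    events = []
    for r in range(res.rounds):
        if not res.invited_r[i, r]:
            continue
        age = float(res.age_r[i, r])
        events.append((age, "invitation", None))
        if res.psa_r[i, r]:
            events.append((age, "psa_test", None))
        if res.dre_r[i, r]:
            events.append(
                (age, "dre_test", "positive" if res.reflex_psa_r[i, r] else None)
            )
        if res.mri_r[i, r]:
            events.append((age, "mri", None))
        if res.biopsy_r[i, r]:
            bx = (
                "combined"
                if strategy.biopsy_type_on_workup == "combined-targeted-systematic"
                else "systematic"
            )
            events.append((age, "biopsy", bx))
    if res.dx_mode[i] == DX_SCREEN:
        events.append((float(res.dx_age[i]), "screen_dx", _state_payload(res, i)))
    elif res.dx_mode[i] == DX_CLINICAL:
        events.append((float(res.dx_age[i]), "clinical_dx", _state_payload(res, i)))
    events.sort(key=lambda e: (e[0], e[1]))
    return ScreeningRecord(
        person_id=int(history.person_id), strategy=strategy.name, events=events
    )


def _state_payload(res, i):
    return DiseaseState(
        int(res.dx_tcat[i]), bool(res.dx_met[i]), int(max(res.dx_grade[i], 0))
    )


# ---------------------------------------------------------------------------
# active surveillance
# ---------------------------------------------------------------------------


def active_surveillance_schedule(
    dx_age: float,
    death_age: float,
    monitor_quarterly_years: float = 2.0,
    biopsy_times: tuple = (1.5, 3.0),
    biopsy_late_interval: float = 3.0,
) -> list:
    """Dated active-surveillance monitoring events.

    PSA + DRE every 3 months for the first two years, then every 6 months;
    MRI + combined biopsy at 18 and 36 months, then every 3 years, until
    death (or treatment switch, handled by truncating ``death_age``).
    """
    if not dx_age < death_age:
        raise ConfigurationError("dx_age must precede death_age")
    horizon = death_age - dx_age
    events = []
    t = 0.0
    while t < horizon - 1e-9:
        events.append((dx_age + t, "as_visit"))
        t += 0.25 if t < monitor_quarterly_years - 1e-9 else 0.5
    t_bx = list(biopsy_times)
    nxt = biopsy_times[-1] + biopsy_late_interval
    while nxt < horizon - 1e-9:
        t_bx.append(nxt)
        nxt += biopsy_late_interval
    for tb in t_bx:
        if tb < horizon - 1e-9:
            events.append((dx_age + tb, "as_mri_biopsy"))
    events.sort()
    return events


def as_event_counts(durations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form AS visit and biopsy counts for given durations (years).

    Mirrors :func:`active_surveillance_schedule`: visits at 0, .25, ..own
    quarterly grid for 2 years then biannual; MRI+biopsy at 1.5, 3, 6, 9, ...
    """
    d = np.asarray(durations, dtype=float)
    quarterly = np.ceil(np.clip(d, 0, 2.0) / 0.25 - 1e-9)
    biannual = np.ceil(np.clip(d - 2.0, 0, None) / 0.5 - 1e-9)
    visits = quarterly + biannual
    bx = (d > 1.5 + 1e-9).astype(float) + (d > 3.0 + 1e-9)
    bx = bx + np.floor(np.clip(d - 3.0 - 1e-9, 0, None) / 3.0)
    return visits, bx


# ---------------------------------------------------------------------------
# background screening for calibration / synthetic targets
# ---------------------------------------------------------------------------


def dre_background_diagnoses(cohort: Cohort, background: dict, seed: int):
    """Diagnoses under opportunistic annual-DRE background screening.

    Returns (dx_age, dx_grade, pca_death_age) arrays for registry-style
    tabulation.  Uses the same engine as the DRE strategy with the
    background uptake rates.
    """
    from .defaults import default_test_profiles

    strategy = StrategyDefinition(
        name="background_dre",
        start_age=45.0,
        stop_age=75.0,
        primary_test="DRE",
        dre_interval=1.0,
        reinvite_interval=1.0,
        participation={
            "first_screen": background["ever_attender"],
            "rescreen": background["per_round"],
            "biopsy": background["biopsy_acceptance"],
        },
    )
    res = run_cohort_screening(cohort, strategy, default_test_profiles(), seed)
    dx_age = np.where(res.dx_mode > 0, res.dx_age, np.nan)
    return dx_age, res.dx_grade, res.cancer_death_age
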