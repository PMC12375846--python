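"""Natural history of prostate cancer: PSA growth, onset, progression,
clinical presentation, cause-specific survival and stage shift.

The disease model is a continuous-time competing-hazards microsimulation:

* **Other-cause death** is drawn from an annual life table (piecewise
  constant hazard, ages 35-105).
* **Preclinical onset** follows a Weibull hazard in age measured from 35.
* **Grade** (Gleason <7 / =7 / >7) is fixed at onset and drawn from an
  age-linked multinomial (softmax of logits linear in onset age) — higher
  grades become more likely at older onset ages.
* **Local extent** progresses T1 -> T2 -> T3 with grade-specific exponential
  clocks; a separate metastasis clock runs from onset with a grade-specific
  base rate scaled by the current local extent.
* **PSA** is log-linear in age with person-level random intercept and slope,
  accelerating to a grade-specific slope after onset (continuous at onset);
  measurement noise is multiplicative on the natural scale.
* **Clinical presentation** has hazard proportional to the current true PSA
  level, scaled by stage (local extent and metastasis), so larger, more
  advanced cancers surface sooner.
* **Cause-specific survival** after clinical diagnosis follows a mixture
  cure model S(t) = c + (1-c) exp(-r t) per stage/grade.  Screen detection at
  an earlier stage substitutes the earlier stage's curve, with the survival
  clock starting at the counterfactual clinical diagnosis age (the end of the
  lead time), using the same uniform draw in both arms.

All sampling uses closed-form hazard inversion and vectorizes over a cohort;
per-person results are exactly reproducible from ``(person_id, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import _rand

# grade categories (Gleason score strata)
GS_LT7, GS_7, GS_GT7 = 0, 1, 2
GRADE_LABELS = ["gs_lt7", "gs_7", "gs_gt7"]
# local extent categories
T1, T2, T3 = 0, 1, 2

AGE_ENTRY = 35.0
AGE_MAX = 105.0

# slot layout inside the natural-history substream
_S_DEATH, _S_ONSET, _S_GRADE, _S_T12, _S_T23, _S_MET, _S_DX, _S_SURV = range(8)
_S_PSA_INT, _S_PSA_SLOPE = 8, 9
_N_SLOTS = 10


class ParameterError(ValueError):
    """Raised when natural-history parameters violate their invariants."""


class InputError(ValueError):
    """Raised for invalid inputs such as an incomplete life table."""


@dataclass
class DiseaseState:
    """One of the 18 preclinical/clinical disease states:
    3 local-extent levels x metastasis flag x 3 grade categories."""

    t_category: int
    metastasis: bool
    grade_category: int

    def __post_init__(self):
        if self.t_category not in (T1, T2, T3):
            raise ParameterError(f"t_category must be 0..2, got {self.t_category}")
        if self.grade_category not in (GS_LT7, GS_7, GS_GT7):
            raise ParameterError(f"grade_category must be 0..2, got {self.grade_category}")

    @property
    def index(self) -> int:
        return (self.t_category * 2 + int(self.metastasis)) * 3 + self.grade_category

    @staticmethod
    def all_states() -> list["DiseaseState"]:
        return [
            DiseaseState(t, bool(m), g)
            for t in (T1, T2, T3)
            for m in (0, 1)
            for g in (GS_LT7, GS_7, GS_GT7)
        ]


@dataclass
class NaturalHistoryParams:
    """Parameters of the natural-history model.

    Rates are per person-year; PSA slopes are per year on the log scale;
    grade mixture logits are relative to GS<7 at ``ref_age``.
    """

    onset_hazard_params: dict = field(
        default_factory=lambda: {"shape": 3.0, "scale": 31.0, "susceptible": 0.22}
    )
    grade_mixture_params: dict = field(
        default_factory=lambda: {
            "intercept_7": -0.45,
            "intercept_gt7": -0.95,
            "slope_7": 0.015,
            "slope_gt7": 0.045,
            "ref_age": 60.0,
        }
    )
    psa_baseline_level: float = 0.6  # ng/mL at age 35 (population median)
    psa_person_sd: dict = field(
        default_factory=lambda: {"intercept": 0.45, "slope": 0.004}
    )
    psa_pre_onset_slope: float = 0.025
    psa_post_onset_slope_by_grade: Sequence[float] = (0.09, 0.14, 0.22)
    progression_rate_params: dict = field(
        default_factory=lambda: {
            "t1_t2": [0.055, 0.11, 0.20],
            "t2_t3": [0.07, 0.13, 0.24],
            "met_base": [0.004, 0.018, 0.06],
            "met_tcat_mult": [0.25, 1.0, 2.0],
        }
    )
    clinical_dx_params: dict = field(
        default_factory=lambda: {
            "xi_by_tcat": [0.0035, 0.01, 0.022],
            "met_mult": 8.0,
        }
    )
    survival_params: dict = field(
        default_factory=lambda: {
            "cure_localized": [0.90, 0.65, 0.40],
            "rate_localized": [float(np.log(2) / 15.0), 0.0693, 0.099],
            "tcat_rate_mult": [1.0, 1.4, 2.0],
            "cure_metastatic": [0.07, 0.05, 0.03],
            "rate_metastatic": [0.139, 0.173, 0.225],
        }
    )
    noise_sd: float = 0.20

    def __post_init__(self):
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        o = self.onset_hazard_params
        if o["shape"] <= 0 or o["scale"] <= 0:
            raise ParameterError("onset Weibull shape/scale must be > 0")
        if not (0.0 <= o.get("susceptible", 1.0) <= 1.0):
            raise ParameterError("susceptible fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.psa_baseline_level <= 0:
            raise ParameterError("noise_sd must be >= 0 and baseline PSA > 0")
        if any(sd < 0 for sd in self.psa_person_sd.values()):
            raise ParameterError("person-effect SDs must be >= 0")
        post = np.asarray(self.psa_post_onset_slope_by_grade, dtype=float)
        if np.any(post < self.psa_pre_onset_slope):
            raise ParameterError(
                "post-onset PSA slope must be >= pre-onset slope (acceleration)"
            )
        for key in ("t1_t2", "t2_t3", "met_base", "met_tcat_mult"):
            if np.any(np.asarray(self.progression_rate_params[key]) < 0):
                raise ParameterError(f"progression rates '{key}' must be >= 0")
        if np.any(np.asarray(self.clinical_dx_params["xi_by_tcat"]) < 0):
            raise ParameterError("diagnosis hazard coefficients must be >= 0")
        s = self.survival_params
        for key in ("cure_localized", "cure_metastatic"):
            c = np.asarray(s[key], dtype=float)
            if np.any((c < 0) | (c > 1)):
                raise ParameterError("cure fractions must lie in [0, 1]")
        for key in ("rate_localized", "rate_metastatic", "tcat_rate_mult"):
            if np.any(np.asarray(s[key]) < 0):
                raise ParameterError("survival rates must be >= 0")

    # -- grade mixture -----------------------------------------------------
    def grade_probabilities(self, onset_age) -> np.ndarray:
        """Multinomial grade probabilities at given onset age(s); rows sum to 1."""
        a = np.atleast_1d(np.asarray(onset_age, dtype=float))
        g = self.grade_mixture_params
        d = a - g["ref_age"]
        logits = np.stack(
            [
                np.zeros_like(d),
                g["intercept_7"] + g["slope_7"] * d,
                g["intercept_gt7"] + g["slope_gt7"] * d,
            ],
            axis=-1,
        )
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=-1, keepdims=True)

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["psa_post_onset_slope_by_grade"] = list(
            map(float, self.psa_post_onset_slope_by_grade)
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalHistoryParams":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "NaturalHistoryParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class LifeHistory:
    """One man's simulated disease trajectory under no screening."""

    person_id: int
    random_stream_key: int
    onset_age: Optional[float]
    grade_category: Optional[int]
    state_trajectory: list  # ordered (age, DiseaseState)
    counterfactual_clinical_dx_age: Optional[float]
    actual_dx_age: Optional[float]
    dx_mode: str  # "screen" | "clinical" | "none"
    stage_at_dx: Optional[DiseaseState]
    other_cause_death_age: float
    cancer_death_age: Optional[float]
    death_age: float
    psa_person_effects: tuple  # (intercept deviation, slope deviation)


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------


def load_life_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Validate a life table (columns age, mortality_rate; half-open annual
    intervals) and return (hazard per year for ages 35..104, cumulative
    hazard at the start of each year)."""
    if not {"age", "mortality_rate"}.issubset(table.columns):
        raise InputError("life table needs columns 'age' and 'mortality_rate'")
    t = table.sort_values("age")
    ages = t["age"].to_numpy(dtype=float)
    if ages[0] > AGE_ENTRY or ages[-1] < AGE_MAX - 1:
        raise InputError("life table must cover ages 35-105")
    rates = t["mortality_rate"].to_numpy(dtype=float)
    if np.any(rates < 0):
        raise InputError("mortality rates must be >= 0")
    idx = np.searchsorted(ages, np.arange(AGE_ENTRY, AGE_MAX), side="right") - 1
    haz = rates[idx]
    cum = np.concatenate([[0.0], np.cumsum(haz)])
    return haz, cum


def _sample_life_table(haz: np.ndarray, cum: np.ndarray, u: np.ndarray) -> np.ndarray:
    e = -np.log(u)
    idx = np.clip(np.searchsorted(cum, e, side="right") - 1, 0, len(haz) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(haz[idx] > 0, (e - cum[idx]) / haz[idx], 0.0)
    age = AGE_ENTRY + idx + np.minimum(frac, 1.0)
    return np.where(e >= cum[-1], AGE_MAX, np.minimum(age, AGE_MAX))


# ---------------------------------------------------------------------------
# PSA growth
# ---------------------------------------------------------------------------


def log_psa_mean(params, intercept_dev, slope_dev, onset_age, grade, age):
    """True (noise-free) log PSA at ``age``; vectorized."""
    age = np.asarray(age, dtype=float)
    base = (
        np.log(params.psa_baseline_level)
        + intercept_dev
        + (params.psa_pre_onset_slope + slope_dev) * (age - AGE_ENTRY)
    )
    post = np.asarray(params.psa_post_onset_slope_by_grade, dtype=float)
    if onset_age is None:
        return base
    onset = np.asarray(onset_age, dtype=float)
    g = np.asarray(grade)
    g_safe = np.where(np.isfinite(onset) & (g >= 0), g, 0).astype(int)
    extra = (post[g_safe] - params.psa_pre_onset_slope) * np.maximum(
        0.0, age - np.where(np.isfinite(onset), onset, np.inf)
    )
    return base + np.where(np.isfinite(onset), extra, 0.0)


def psa_at_age(
    params: NaturalHistoryParams,
    person_effects: tuple,
    onset_age: Optional[float],
    grade_category: Optional[int],
    age: float,
    with_noise: bool = False,
    noise_z: float = 0.0,
) -> float:
    """PSA level (ng/mL) at ``age`` for one man.

    Log PSA is linear in age with the pre-onset slope, switching to the
    grade-specific post-onset slope at ``onset_age`` (continuous there).
    ``noise_z`` is a standard-normal deviate applied on the log scale when
    ``with_noise`` is set.
    """
    if age < AGE_ENTRY:
        raise ParameterError(f"age must be >= {AGE_ENTRY}, got {age}")
    if onset_age is not None and onset_age < AGE_ENTRY:
        raise ParameterError("onset_age must be >= 35 or None")
    intercept_dev, slope_dev = person_effects
    lp = log_psa_mean(
        params,
        intercept_dev,
        slope_dev,
        np.nan if onset_age is None else onset_age,
        -1 if grade_category is None else grade_category,
        age,
    )
    if with_noise:
        lp = lp + params.noise_sd * noise_z
    return float(np.exp(lp))


# ---------------------------------------------------------------------------
# survival curves and stage shift
# ---------------------------------------------------------------------------


def _surv_cure_rate(params: NaturalHistoryParams, tcat, met, grade):
    s = params.survival_params
    tcat = np.asarray(tcat, dtype=int)
    met = np.asarray(met, dtype=bool)
    grade = np.asarray(grade, dtype=int)
    cure_loc = np.asarray(s["cure_localized"], dtype=float)[grade]
    rate_loc = (
        np.asarray(s["rate_localized"], dtype=float)[grade]
        * np.asarray(s["tcat_rate_mult"], dtype=float)[tcat]
    )
    cure_met = np.asarray(s["cure_metastatic"], dtype=float)[grade]
    rate_met = np.asarray(s["rate_metastatic"], dtype=float)[grade]
    cure = np.where(met, cure_met, cure_loc)
    rate = np.where(met, rate_met, rate_loc)
    return cure, rate


def survival_probability(
    params: NaturalHistoryParams, state: DiseaseState, t: float
) -> float:
    """Cause-specific survival S(t) from the survival clock start for a
    cancer diagnosed in ``state``: mixture cure model c + (1-c) e^{-rt}."""
    cure, rate = _surv_cure_rate(
        params, state.t_category, state.metastasis, state.grade_category
    )
    return float(cure + (1.0 - cure) * np.exp(-rate * t))


def sample_survival_time(params, tcat, met, grade, u) -> np.ndarray:
    """Invert the cure-mixture survival curve at uniform(s) ``u``.

    Returns +inf for cured draws (u <= cure).  Using the *same* u for two
    states makes the earlier-state draw stochastically no shorter whenever
    the earlier curve dominates, which the default parameterization
    guarantees (cure non-increasing, rate non-decreasing with stage).
    """
    cure, rate = _surv_cure_rate(params, tcat, met, grade)
    u = np.asarray(u, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -np.log(np.clip((u - cure) / (1.0 - cure), 1e-300, None)) / rate
    return np.where(u <= cure, np.inf, t)


# ---------------------------------------------------------------------------
# vectorized cohort simulation
# ---------------------------------------------------------------------------


class Cohort:
    """Struct-of-arrays container for simulated natural courses.

    All ages are in years; NaN marks "never".  ``clin_dx_age`` is the
    counterfactual clinical diagnosis age (no screening); it is only realized
    if it precedes death.
    """

    def __init__(self, params, seed, person_ids):
        self.params = params
        self.seed = int(seed)
        self.person_ids = np.asarray(person_ids, dtype=np.int64)
        self.n = len(self.person_ids)

    # array attributes filled by simulate_cohort:
    # oc_death_age, onset_age, grade, t2_age, t3_age, met_age, clin_dx_age,
    # stage_tcat_dx, stage_met_dx, cancer_death_age_ns, death_age_ns,
    # psa_intercept_dev, psa_slope_dev, u_surv

    def tcat_at(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        t = np.zeros(self.n, dtype=np.int8)
        t += (age >= np.nan_to_num(self.t2_age, nan=np.inf)).astype(np.int8)
        t += (age >= np.nan_to_num(self.t3_age, nan=np.inf)).astype(np.int8)
        return t

    def met_at(self, age) -> np.ndarray:
        return np.asarray(age, dtype=float) >= np.nan_to_num(self.met_age, nan=np.inf)

    def has_preclinical(self, age) -> np.ndarray:
        """True for men with undiagnosed cancer present at ``age`` (onset has
        occurred, counterfactual clinical diagnosis has not)."""
        age = np.asarray(age, dtype=float)
        onset = np.nan_to_num(self.onset_age, nan=np.inf)
        return (age >= onset) & (age < np.nan_to_num(self.clin_dx_age, nan=np.inf))

    def true_log_psa(self, age) -> np.ndarray:
        return log_psa_mean(
            self.params,
            self.psa_intercept_dev,
            self.psa_slope_dev,
            self.onset_age,
            self.grade,
            age,
        )


def simulate_cohort(
    params: NaturalHistoryParams,
    life_table: pd.DataFrame,
    n: Optional[int] = None,
    seed: int = 0,
    person_ids=None,
) -> Cohort:
    """Simulate the no-screening natural course for a cohort.

    Each person's draws depend only on ``(seed, person_id)``; the default
    person ids are 0..n-1.
    """
    if person_ids is None:
        if n is None:
            raise InputError("pass n or person_ids")
        person_ids = np.arange(n, dtype=np.int64)
    c = Cohort(params, seed, person_ids)
    haz, cum = load_life_table(life_table)
    u = _rand.uniforms(seed, c.person_ids, _rand.PURPOSE_NATURAL_HISTORY, _N_SLOTS)

    # other-cause death
    c.oc_death_age = _sample_life_table(haz, cum, u[:, _S_DEATH])

    # onset: Weibull in age from 35 within a susceptible fraction; the
    # non-susceptible majority never develops preclinical disease, which
    # makes the population onset flow peak and then decline at old age
    k = params.onset_hazard_params["shape"]
    lam = params.onset_hazard_params["scale"]
    fsus = params.onset_hazard_params.get("susceptible", 1.0)
    u_on = u[:, _S_ONSET]
    susceptible = u_on < fsus
    q = np.where(susceptible, u_on / max(fsus, 1e-12), 0.5)
    e_on = -np.log1p(-q)
    onset = AGE_ENTRY + lam * e_on ** (1.0 / k)
    onset = np.where(susceptible & (onset < AGE_MAX), onset, np.nan)
    c.onset_age = onset
    has_onset = np.isfinite(onset)

    # grade at onset
    probs = params.grade_probabilities(np.where(has_onset, onset, 60.0))
    cdf = np.cumsum(probs, axis=1)
    g = (u[:, _S_GRADE, None] > cdf[:, :2]).sum(axis=1).astype(np.int8)
    c.grade = np.where(has_onset, g, -1).astype(np.int8)
    gi = np.where(has_onset, c.grade, 0).astype(int)

    # local-extent progression
    pr = params.progression_rate_params
    r12 = np.asarray(pr["t1_t2"], dtype=float)[gi]
    r23 = np.asarray(pr["t2_t3"], dtype=float)[gi]
    with np.errstate(divide="ignore"):
        dt12 = np.where(r12 > 0, -np.log(u[:, _S_T12]) / np.maximum(r12, 1e-300), np.inf)
        dt23 = np.where(r23 > 0, -np.log(u[:, _S_T23]) / np.maximum(r23, 1e-300), np.inf)
        t2 = onset + dt12
        t3 = t2 + dt23
    c.t2_age = np.where(has_onset & (t2 < AGE_MAX), t2, np.nan)
    c.t3_age = np.where(has_onset & (t3 < AGE_MAX), t3, np.nan)

    # metastasis: piecewise-constant hazard met_base[g] * mult[tcat(t)]
    mbase = np.asarray(pr["met_base"], dtype=float)[gi]
    mult = np.asarray(pr["met_tcat_mult"], dtype=float)
    e_met = -np.log(u[:, _S_MET])
    b1 = np.where(np.isfinite(t2), t2, AGE_MAX) - np.where(has_onset, onset, 0.0)
    b2 = np.where(np.isfinite(t3), t3, AGE_MAX) - np.where(
        np.isfinite(t2), t2, AGE_MAX
    )
    b1 = np.maximum(b1, 0.0)
    b2 = np.maximum(b2, 0.0)
    h1 = mbase * mult[0] * b1
    h2 = mbase * mult[1] * b2
    met_dt = np.full(c.n, np.inf)
    in1 = e_met < h1
    with np.errstate(divide="ignore", invalid="ignore"):
        met_dt = np.where(in1, e_met / np.maximum(mbase * mult[0], 1e-300), met_dt)
        in2 = ~in1 & (e_met < h1 + h2)
        met_dt = np.where(
            in2, b1 + (e_met - h1) / np.maximum(mbase * mult[1], 1e-300), met_dt
        )
        in3 = ~in1 & ~in2
        met_dt = np.where(
            in3, b1 + b2 + (e_met - h1 - h2) / np.maximum(mbase * mult[2], 1e-300), met_dt
        )
    met = np.where(has_onset, onset, np.nan) + met_dt
    c.met_age = np.where(has_onset & (met < AGE_MAX), met, np.nan)

    # clinical diagnosis: hazard xi(stage) * PSA_true(t), piecewise intervals
    c.psa_intercept_dev = params.psa_person_sd["intercept"] * ndtri_cached(
        u[:, _S_PSA_INT]
    )
    c.psa_slope_dev = params.psa_person_sd["slope"] * ndtri_cached(u[:, _S_PSA_SLOPE])
    c.clin_dx_age = _sample_clinical_dx(c, u[:, _S_DX])

    # counterfactual (no-screening) cancer death
    c.u_surv = u[:, _S_SURV]
    dx_valid = np.isfinite(c.clin_dx_age) & (c.clin_dx_age < c.oc_death_age)
    dxa = np.where(dx_valid, c.clin_dx_age, AGE_ENTRY)
    c.stage_tcat_dx = np.where(dx_valid, c.tcat_at(dxa), -1).astype(np.int8)
    c.stage_met_dx = dx_valid & c.met_at(dxa)
    tsurv = sample_survival_time(
        params,
        np.maximum(c.stage_tcat_dx, 0),
        c.stage_met_dx,
        gi,
        c.u_surv,
    )
    cd = np.where(dx_valid, dxa + tsurv, np.inf)
    c.cancer_death_age_ns = np.where(cd < c.oc_death_age, cd, np.nan)
    c.death_age_ns = np.where(
        np.isfinite(c.cancer_death_age_ns), c.cancer_death_age_ns, c.oc_death_age
    )
    # clinical dx only realized before death
    c.clin_dx_age = np.where(
        np.isfinite(c.clin_dx_age) & (c.clin_dx_age < c.death_age_ns),
        c.clin_dx_age,
        np.nan,
    )
    return c


def ndtri_cached(u):
    from scipy.special import ndtri

    return ndtri(u)


def _sample_clinical_dx(c: Cohort, u_dx: np.ndarray) -> np.ndarray:
    """Invert the cumulative diagnosis hazard.

    Within an interval where log PSA has slope s and the stage multiplier is
    xi, the cumulative hazard is xi * (PSA(b) - PSA(a)) / s.
    """
    p = c.params
    n = c.n
    onset = c.onset_age
    has_onset = np.isfinite(onset)
    if not np.any(has_onset):
        return np.full(n, np.nan)

    xi_t = np.asarray(p.clinical_dx_params["xi_by_tcat"], dtype=float)
    met_mult = float(p.clinical_dx_params["met_mult"])
    gi = np.where(has_onset, c.grade, 0).astype(int)
    slope = (
        np.asarray(p.psa_post_onset_slope_by_grade, dtype=float)[gi] + c.psa_slope_dev
    )
    slope = np.maximum(slope, 1e-6)

    start = np.where(has_onset, onset, AGE_MAX)
    end = np.full(n, AGE_MAX)
    # breakpoints: t2, t3, met (already ordered t2 < t3; met anywhere)
    b = np.stack(
        [
            np.nan_to_num(c.t2_age, nan=np.inf),
            np.nan_to_num(c.t3_age, nan=np.inf),
            np.nan_to_num(c.met_age, nan=np.inf),
        ],
        axis=1,
    )
    b = np.sort(b, axis=1)
    edges = np.concatenate(
        [start[:, None], np.clip(b, None, end[:, None]), end[:, None]], axis=1
    )
    edges = np.maximum.accumulate(np.clip(edges, start[:, None], end[:, None]), axis=1)

    e_dx = -np.log(u_dx)
    cum = np.zeros(n)
    dx_age = np.full(n, np.nan)
    found = np.zeros(n, dtype=bool)
    lp0 = c.true_log_psa(np.where(has_onset, onset, AGE_ENTRY))
    for j in range(4):
        a0 = edges[:, j]
        a1 = edges[:, j + 1]
        width = np.maximum(a1 - a0, 0.0)
        mid = a0 + 1e-9
        tcat = c.tcat_at(mid)
        met = c.met_at(mid)
        xi = xi_t[tcat] * np.where(met, met_mult, 1.0)
        psa0 = np.exp(lp0 + slope * (a0 - np.where(has_onset, onset, AGE_ENTRY)))
        dh = xi * psa0 * (np.exp(slope * width) - 1.0) / slope
        crosses = has_onset & ~found & (e_dx < cum + dh)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_in = (
                np.log1p(slope * (e_dx - cum) / np.maximum(xi * psa0, 1e-300)) / slope
            )
        dx_age = np.where(crosses, a0 + t_in, dx_age)
        found |= crosses
        cum = cum + np.where(has_onset, dh, 0.0)
    return np.where(found & (dx_age < AGE_MAX), dx_age, np.nan)


# ---------------------------------------------------------------------------
# single-person API
# ---------------------------------------------------------------------------


def simulate_natural_course(
    params: NaturalHistoryParams,
    life_table: pd.DataFrame,
    person_id: int,
    seed: int,
) -> LifeHistory:
    """Simulate one man's natural course (no screening).

    The result is a pure function of ``(person_id, seed)``: simulating the
    same person inside any cohort yields bitwise-identical values.
    """
    c = simulate_cohort(params, life_table, seed=seed, person_ids=[person_id])
    return cohort_life_history(c, 0)


def cohort_life_history(c: Cohort, i: int) -> LifeHistory:
    onset = float(c.onset_age[i]) if np.isfinite(c.onset_age[i]) else None
    grade = int(c.grade[i]) if c.grade[i] >= 0 else None
    traj = []
    if onset is not None:
        traj.append((onset, DiseaseState(T1, False, grade)))
        events = []
        if np.isfinite(c.t2_age[i]):
            events.append((float(c.t2_age[i]), "t2"))
        if np.isfinite(c.t3_age[i]):
            events.append((float(c.t3_age[i]), "t3"))
        if np.isfinite(c.met_age[i]):
            events.append((float(c.met_age[i]), "met"))
        events.sort()
        tcat, met = T1, False
        for age, kind in events:
            if age >= c.death_age_ns[i]:
                break
            tcat = {"t2": T2, "t3": T3}.get(kind, tcat)
            met = met or kind == "met"
            traj.append((age, DiseaseState(tcat, met, grade)))
    clin = float(c.clin_dx_age[i]) if np.isfinite(c.clin_dx_age[i]) else None
    cancer_death = (
        float(c.cancer_death_age_ns[i]) if np.isfinite(c.cancer_death_age_ns[i]) else None
    )
    stage = None
    if clin is not None:
        stage = DiseaseState(int(c.stage_tcat_dx[i]), bool(c.stage_met_dx[i]), grade)
    return LifeHistory(
        person_id=int(c.person_ids[i]),
        random_stream_key=int(c.seed),
        onset_age=onset,
        grade_category=grade,
        state_trajectory=traj,
        counterfactual_clinical_dx_age=clin,
        actual_dx_age=clin,
        dx_mode="clinical" if clin is not None else "none",
        stage_at_dx=stage,
        other_cause_death_age=float(c.oc_death_age[i]),
        cancer_death_age=cancer_death,
        death_age=float(c.death_age_ns[i]),
        psa_person_effects=(float(c.psa_intercept_dev[i]), float(c.psa_slope_dev[i])),
    )


def stage_shift_survival(
    params: NaturalHistoryParams,
    history: LifeHistory,
    screen_dx_age: float,
    stage_at_screen_dx: DiseaseState,
    seed: int,
) -> Optional[float]:
    """Cancer death age for a screen-detected case under the stage-shift
    mechanism.

    The survival time is drawn (by inverting the cure-mixture curve at the
    person's reserved survival uniform) from the curve of the stage *at
    screen detection*, but the clock starts at the counterfactual clinical
    diagnosis age — the end of the lead time.  An overdiagnosed case (no
    counterfactual clinical diagnosis in the lifetime) never dies of cancer.
    Returns None when cancer death does not precede other-cause death.
    """
    cf = history.counterfactual_clinical_dx_age
    if cf is not None and screen_dx_age > cf + 1e-9:
        raise ParameterError(
            "screen_dx_age must not exceed the counterfactual clinical dx age"
        )
    if cf is None:
        return None
    u = _rand.uniforms(
        seed, [history.person_id], _rand.PURPOSE_NATURAL_HISTORY, _N_SLOTS
    )[0, _S_SURV]
    t = sample_survival_time(
        params,
        stage_at_screen_dx.t_category,
        stage_at_screen_dx.metastasis,
        stage_at_screen_dx.grade_category,
        u,
    )
    death = cf + float(t)
    if not np.isfinite(death) or death >= history.other_cause_death_age:
        return None
    return death
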