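"""Synthetic external inputs: life table and registry-style calibration /
validation targets.

The generator emulates the tabular inputs a screening cost-effectiveness
analysis would take from national statistics and cancer registries: an
all-cause male life table, age-group prostate-cancer incidence with
person-year denominators, Gleason-category proportions by age group, and
age-group cancer mortality for validation.  Targets are produced by
simulating a large cohort from a known ground-truth parameter set under
background opportunistic DRE screening, so calibration tests can close the
loop against a truth that is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _rand
from .natural_history import AGE_ENTRY, AGE_MAX, NaturalHistoryParams, simulate_cohort


@dataclass
class SyntheticConfig:
    """Ground truth and sampling frame for generating registry-style inputs.

    ``life_table_params`` are Gompertz-Makeham coefficients: hazard at age a
    is ``makeham + b * exp(theta * (a - 35))``.  ``registry_person_years``
    is the per-age-group denominator (default: of the order of a national
    male registry observed over several years).
    """

    seed: int = 20140601
    cohort_birth_year: int = 1969
    life_table_params: dict = field(
        default_factory=lambda: {"makeham": 3.0e-4, "b": 7.0e-4, "theta": 0.097}
    )
    true_natural_history: NaturalHistoryParams = field(
        default_factory=NaturalHistoryParams
    )
    registry_person_years: float = 1.2e7
    age_groups: tuple = tuple((a, a + 5) for a in range(40, 85, 5))
    poisson_noise: bool = True
    n_sim: int = 200_000


def make_life_table(config: Optional[SyntheticConfig] = None) -> pd.DataFrame:
    """Annual all-cause mortality rates for ages 35-105 (Gompertz-Makeham)."""
    config = config or SyntheticConfig()
    p = config.life_table_params
    ages = np.arange(int(AGE_ENTRY), int(AGE_MAX) + 1)
    rates = p["makeham"] + p["b"] * np.exp(p["theta"] * (ages - AGE_ENTRY))
    return pd.DataFrame({"age": ages, "mortality_rate": rates})


def life_expectancy(life_table: pd.DataFrame, from_age: float = 45.0) -> float:
    """Remaining life expectancy at ``from_age`` by numerical integration of
    the survival curve implied by the annual hazards."""
    t = life_table.sort_values("age")
    ages = t["age"].to_numpy(dtype=float)
    rates = t["mortality_rate"].to_numpy(dtype=float)
    grid = np.arange(from_age, AGE_MAX, 1.0 / 12.0)
    idx = np.clip(np.searchsorted(ages, grid, side="right") - 1, 0, len(rates) - 1)
    cum = np.concatenate([[0.0], np.cumsum(rates[idx] / 12.0)])
    surv = np.exp(-cum)
    return float(np.trapezoid(surv, dx=1.0 / 12.0))


def default_background_screening() -> dict:
    """Opportunistic annual-DRE background used for calibration targets.

    Uptake of the statutory DRE offer is not published for the registry
    period; the default assumes half of men ever attend and attenders take
    up 40% of annual offers, with the usual biopsy acceptance.
    """
    return {"ever_attender": 0.50, "per_round": 0.40, "biopsy_acceptance": 0.65}


@dataclass
class CalibrationTargets:
    """Registry-style calibration targets.

    ``incidence`` columns: age_low, age_high, cases, person_years,
    p_gs_lt7, p_gs_7, p_gs_gt7.  ``mortality`` (optional) columns:
    age_low, age_high, deaths, person_years.
    """

    incidence: pd.DataFrame
    mortality: Optional[pd.DataFrame] = None
    truth: Optional[NaturalHistoryParams] = None

    def validate(self) -> None:
        inc = self.incidence
        need = {"age_low", "age_high", "cases", "person_years",
                "p_gs_lt7", "p_gs_7", "p_gs_gt7"}
        if not need.issubset(inc.columns):
            raise ValueError(f"incidence targets need columns {sorted(need)}")
        if (inc["person_years"] <= 0).any():
            raise ValueError("person_years must be > 0")
        if (inc["cases"] < 0).any():
            raise ValueError("cases must be >= 0")
        psum = inc[["p_gs_lt7", "p_gs_7", "p_gs_gt7"]].sum(axis=1)
        if not np.allclose(psum[inc["cases"] > 0], 1.0, atol=1e-6):
            raise ValueError("grade proportions must sum to 1 per age group")

    def to_csv(self, path) -> None:
        self.incidence.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mortality_path=None) -> "CalibrationTargets":
        inc = pd.read_csv(path)
        mort = pd.read_csv(mortality_path) if mortality_path else None
        t = cls(incidence=inc, mortality=mort)
        t.validate()
        return t


def tabulate_rates(cohort, dx_age, dx_grade, age_groups, pca_death_age=None):
    """Age-group diagnosed incidence rates (per person-year alive) and grade
    proportions among cases; optionally cancer mortality rates."""
    rows = []
    death = cohort.death_age_ns
    for lo, hi in age_groups:
        alive_entry = np.minimum(death, hi) - np.minimum(death, lo)
        py = float(alive_entry.sum())
        in_group = np.isfinite(dx_age) & (dx_age >= lo) & (dx_age < hi)
        cases = int(in_group.sum())
        if cases > 0:
            g = dx_grade[in_group]
            props = [float((g == k).mean()) for k in range(3)]
        else:
            props = [np.nan] * 3
        row = {
            "age_low": lo,
            "age_high": hi,
            "cases": cases,
            "person_years": py,
            "p_gs_lt7": props[0],
            "p_gs_7": props[1],
            "p_gs_gt7": props[2],
        }
        if pca_death_age is not None:
            dmask = np.isfinite(pca_death_age) & (pca_death_age >= lo) & (
                pca_death_age < hi
            )
            row["deaths"] = int(dmask.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def make_registry_targets(
    config: Optional[SyntheticConfig] = None,
) -> CalibrationTargets:
    """Simulate a cohort from the ground truth under background DRE screening
    and tabulate noisy registry-style targets."""
    from .screening import dre_background_diagnoses

    config = config or SyntheticConfig()
    life = make_life_table(config)
    cohort = simulate_cohort(
        config.true_natural_history, life, n=config.n_sim, seed=config.seed
    )
    dx_age, dx_grade, pca_death = dre_background_diagnoses(
        cohort, default_background_screening(), seed=config.seed
    )
    model = tabulate_rates(
        cohort, dx_age, dx_grade, config.age_groups, pca_death_age=pca_death
    )

    rng = np.random.default_rng(config.seed % (2**31))
    inc = model.copy()
    rate = inc["cases"] / inc["person_years"]
    expected = rate * config.registry_person_years
    if config.poisson_noise:
        # per-grade Poisson counts at registry denominators
        counts = np.zeros((len(inc), 3))
        for k, col in enumerate(["p_gs_lt7", "p_gs_7", "p_gs_gt7"]):
            mean = expected.to_numpy() * inc[col].fillna(1 / 3).to_numpy()
            counts[:, k] = rng.poisson(np.maximum(mean, 0.0))
        total = counts.sum(axis=1)
        inc["cases"] = total
        with np.errstate(invalid="ignore", divide="ignore"):
            props = counts / np.where(total > 0, total, np.nan)[:, None]
        inc[["p_gs_lt7", "p_gs_7", "p_gs_gt7"]] = props
    else:
        inc["cases"] = expected
    inc["person_years"] = config.registry_person_years

    mort = model[["age_low", "age_high", "deaths"]].copy()
    mort_rate = model["deaths"] / model["person_years"]
    mort_expected = mort_rate * config.registry_person_years
    mort["deaths"] = (
        rng.poisson(np.maximum(mort_expected, 0.0))
        if config.poisson_noise
        else mort_expected
    )
    mort["person_years"] = config.registry_person_years

    targets = CalibrationTargets(
        incidence=inc, mortality=mort, truth=config.true_natural_history
    )
    targets.validate()
    return targets
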