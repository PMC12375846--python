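"""Deterministic scenario analyses and probabilistic sensitivity analysis.

Scenarios are declarative overrides on the base configuration (dot-paths
into the nested config dict).  Every scenario runs on the same cohort with
identical random substreams, so a scenario that touches only costs or
utilities leaves every count outcome bit-identical to the base case and
differences are attributable to the overrides alone.

The probabilistic analysis draws test characteristics, costs and
health-state utilities (beta for probabilities/utilities, gamma for
costs), re-runs screening and economics for every strategy on a shared
cohort per iteration, and feeds the per-iteration (cost, QALY) pairs to
the acceptability-curve machinery.  The reference configuration in the
source analysis is 1000 iterations of one million men; the defaults here
are scaled down for desk-scale runs and are configurable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .defaults import default_economic_config, default_test_profiles
from .economics import cohort_economics
from .natural_history import NaturalHistoryParams, simulate_cohort
from .outcomes import StrategyOutcome, ceac_from_draws, summarize_per_100k
from .screening import StrategyDefinition, TestProfile, run_cohort_screening, strategy_preset
from .synthetic import make_life_table


class ConfigurationError(ValueError):
    pass


@dataclass
class ScenarioSpec:
    name: str
    overrides: dict = field(default_factory=dict)  # dot-path -> value


@dataclass
class PsaDistributionSet:
    """Sampling distributions for the probabilistic analysis.

    ``entries`` maps a config dot-path to {"dist": "beta"|"gamma",
    "mean": m, "cv": coefficient_of_variation}.
    """

    entries: dict

    def validate(self) -> None:
        for path, spec in self.entries.items():
            if spec["dist"] not in ("beta", "gamma"):
                raise ConfigurationError(f"{path}: unknown distribution")
            m, cv = spec["mean"], spec["cv"]
            if cv < 0 or m <= 0:
                raise ConfigurationError(f"{path}: invalid moments")
            if spec["dist"] == "beta" and not m < 1:
                raise ConfigurationError(f"{path}: beta mean must be < 1")

    def sample(self, rng: np.random.Generator) -> dict:
        out = {}
        for path, spec in self.entries.items():
            m, cv = float(spec["mean"]), float(spec["cv"])
            if cv == 0:
                out[path] = m
                continue
            sd = m * cv
            if spec["dist"] == "beta":
                v = min(sd**2, m * (1 - m) * 0.99)
                k = m * (1 - m) / v - 1
                a, b = m * k, (1 - m) * k
                out[path] = float(rng.beta(a, b))
            else:
                k = 1.0 / cv**2
                out[path] = float(rng.gamma(k, m / k))
        return out


# ---------------------------------------------------------------------------
# base configuration and overrides
# ---------------------------------------------------------------------------


def base_config(
    strategies: Optional[list] = None,
    n_persons: int = 50_000,
    seed: int = 1,
) -> dict:
    """Nested base configuration for the comparison pipeline."""
    from .screening import PRESET_NAMES

    names = strategies or list(PRESET_NAMES)
    return {
        "n_persons": int(n_persons),
        "seed": int(seed),
        "natural_history": NaturalHistoryParams().to_dict(),
        "econ": default_economic_config(),
        "tests": {k: _profile_dict(v) for k, v in default_test_profiles().items()},
        "strategies": {name: strategy_preset(name).to_dict() for name in names},
    }


def _profile_dict(p: TestProfile) -> dict:
    return {
        "test_name": p.test_name,
        "sensitivity": copy.deepcopy(p.sensitivity),
        "specificity": p.specificity,
    }


def apply_overrides(config: dict, overrides: dict) -> dict:
    """Return a deep copy of ``config`` with dot-path overrides applied.

    Raises :class:`ConfigurationError` naming the first unresolvable path.
    """
    cfg = copy.deepcopy(config)
    for path, value in overrides.items():
        node = cfg
        keys = path.split(".")
        for k in keys[:-1]:
            if isinstance(node, dict) and k in node:
                node = node[k]
            else:
                raise ConfigurationError(f"override path '{path}' does not resolve")
        leaf = keys[-1]
        if not isinstance(node, dict) or leaf not in node:
            raise ConfigurationError(f"override path '{path}' does not resolve")
        node[leaf] = copy.deepcopy(value)
    return cfg


def run_config(config: dict) -> tuple[list[StrategyOutcome], dict]:
    """Run the simulate -> screen -> economics -> summarize pipeline for
    every strategy in the configuration on a shared cohort."""
    params = NaturalHistoryParams.from_dict(config["natural_history"])
    life = make_life_table()
    seed = config["seed"]
    cohort = simulate_cohort(params, life, n=config["n_persons"], seed=seed)
    tests = {
        k: TestProfile(**v) for k, v in config["tests"].items()
    }
    econ = config["econ"]
    outcomes = []
    frames = {}
    for name, sdict in config["strategies"].items():
        strategy = StrategyDefinition.from_dict(sdict)
        res = run_cohort_screening(cohort, strategy, tests, seed)
        df = cohort_economics(cohort, res, econ)
        outcomes.append(summarize_per_100k(df, name))
        frames[name] = df
    return outcomes, frames


# ---------------------------------------------------------------------------
# deterministic scenarios
# ---------------------------------------------------------------------------


def _strategy_paths(config, pattern):
    return [n for n in config["strategies"] if pattern in n]


def preset_scenarios(config: Optional[dict] = None) -> list[ScenarioSpec]:
    """The shipped deterministic scenarios: reduced MRI cost (120 and -50%),
    reduced low-risk screening intensity with a 4 or 3 ng/mL threshold,
    0%/5% discounting, the EQ-5D utility swap, DRE stopping at 70, raised
    ADT/chemo costs, and participation variants."""
    from .defaults import default_utilities

    cfg = config or base_config()
    scenarios = [
        ScenarioSpec("scenario1_mri_120", {"econ.costs.mri": 120.0}),
        ScenarioSpec("mri_cost_minus_50pct", {"econ.costs.mri": 250.0}),
        ScenarioSpec("discount_0pct", {"econ.discount_rate": 0.0}),
        ScenarioSpec("discount_5pct", {"econ.discount_rate": 0.05}),
        ScenarioSpec("eq5d_utilities", {"econ.utilities": default_utilities("EQ-5D")}),
        ScenarioSpec("adt_chemo_high", {"econ.costs.adt_chemo_per_year": 24000.0}),
    ]
    if "dre_45_75" in cfg["strategies"]:
        scenarios.append(
            ScenarioSpec("dre_stop_70", {"strategies.dre_45_75.stop_age": 70.0})
        )
    # scenario 2/3: drop rescreening for PSA < 1.5; threshold 4 resp. 3 ng/mL
    for tag, threshold in (("scenario2_thresh4", 4.0), ("scenario3_thresh3", 3.0)):
        ov = {}
        for name in _strategy_paths(cfg, "psa_ras"):
            ov[f"strategies.{name}.risk_bands"] = ((1.5, None), (threshold, 2.0))
            ov[f"strategies.{name}.workup_threshold"] = threshold
        if ov:
            scenarios.append(ScenarioSpec(tag, ov))
    for tag, first, re_, bx in (
        ("participation_low", 0.50, 0.80, 0.50),
        ("participation_full", 1.00, 1.00, 1.00),
    ):
        ov = {}
        for name in cfg["strategies"]:
            if cfg["strategies"][name]["primary_test"] != "none":
                ov[f"strategies.{name}.participation"] = {
                    "first_screen": first, "rescreen": re_, "biopsy": bx,
                }
        scenarios.append(ScenarioSpec(tag, ov))
    return scenarios


def run_dsa(
    config: dict,
    scenarios: list[ScenarioSpec],
    n_sim: Optional[int] = None,
    seed: Optional[int] = None,
) -> dict[str, pd.DataFrame]:
    """Run the full pipeline per scenario with common random numbers.

    Returns scenario name -> per-strategy outcome table (the base case is
    included under 'base').
    """
    cfg = copy.deepcopy(config)
    if n_sim is not None:
        cfg["n_persons"] = int(n_sim)
    if seed is not None:
        cfg["seed"] = int(seed)
    from .outcomes import outcome_table

    out = {}
    base_outcomes, _ = run_config(cfg)
    out["base"] = outcome_table(base_outcomes)
    for sc in scenarios:
        sc_cfg = apply_overrides(cfg, sc.overrides)
        outcomes, _ = run_config(sc_cfg)
        out[sc.name] = outcome_table(outcomes)
    return out


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def default_psa_distributions() -> PsaDistributionSet:
    """Placeholder sampling distributions: beta around the base-case test
    characteristics and participation rates (bounds informed by the stated
    deterministic ranges), gamma with CV 0.2 around unit costs and CV 0.05
    around utilities."""
    entries = {
        "econ.costs.mri": {"dist": "gamma", "mean": 500.0, "cv": 0.2},
        "econ.costs.systematic_biopsy": {"dist": "gamma", "mean": 360.0, "cv": 0.2},
        "econ.costs.combined_biopsy": {"dist": "gamma", "mean": 740.0, "cv": 0.2},
        "econ.costs.radical_treatment": {"dist": "gamma", "mean": 13000.0, "cv": 0.2},
        "econ.costs.adt_chemo_per_year": {"dist": "gamma", "mean": 8000.0, "cv": 0.2},
        "tests.mri.specificity": {"dist": "beta", "mean": 0.70, "cv": 0.05},
        "tests.dre.specificity": {"dist": "beta", "mean": 0.94, "cv": 0.02},
        "econ.utilities.state_utility.active_surveillance": {
            "dist": "beta", "mean": 0.97, "cv": 0.01,
        },
        "econ.utilities.state_utility.radical_treatment": {
            "dist": "beta", "mean": 0.80, "cv": 0.05,
        },
        "econ.utilities.state_utility.adt_chemo": {
            "dist": "beta", "mean": 0.80, "cv": 0.05,
        },
    }
    return PsaDistributionSet(entries)


def run_probabilistic(
    config: dict,
    dists: Optional[PsaDistributionSet] = None,
    n_iter: int = 200,
    cohort_n: Optional[int] = 100_000,
    seed: int = 1,
    wtp_grid=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probabilistic sensitivity analysis.

    Draws one parameter set per iteration, re-runs every strategy on a
    shared natural-history cohort, and records discounted cost (M EUR per
    100,000) and discounted QALYs (per 100,000).  Returns (draws, ceac)
    where draws is tidy (iteration, strategy, cost, effect).
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    dists = dists or default_psa_distributions()
    dists.validate()
    cfg = copy.deepcopy(config)
    if cohort_n is not None:
        cfg["n_persons"] = int(cohort_n)
    params = NaturalHistoryParams.from_dict(cfg["natural_history"])
    life = make_life_table()
    cohort = simulate_cohort(params, life, n=cfg["n_persons"], seed=cfg["seed"])

    rows = []
    for it in range(n_iter):
        rng = np.random.default_rng([seed % (2**31), it])
        draw = dists.sample(rng)
        it_cfg = apply_overrides(cfg, draw)
        tests = {k: TestProfile(**v) for k, v in it_cfg["tests"].items()}
        for name, sdict in it_cfg["strategies"].items():
            strategy = StrategyDefinition.from_dict(sdict)
            res = run_cohort_screening(cohort, strategy, tests, cfg["seed"])
            df = cohort_economics(cohort, res, it_cfg["econ"])
            o = summarize_per_100k(df, name)
            rows.append(
                {
                    "iteration": it,
                    "strategy": name,
                    "cost": o.cost_disc_meur * 1e6,
                    "effect": o.qaly_disc,
                }
            )
    draws = pd.DataFrame(rows)
    grid = (
        np.asarray(wtp_grid, dtype=float)
        if wtp_grid is not None
        else np.linspace(0.0, 450_000.0, 46)
    )
    ceac = ceac_from_draws(draws, grid)
    return draws, ceac
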