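"""Calibration of natural-history parameters to registry-style targets.

The free parameters are the onset hazard's scale and susceptible fraction
and the two grade-mixture intercepts; the Weibull shape, progression,
diagnosis and survival parameters stay fixed (they are poorly identified
by incidence and grade data alone).  The objective simulates a cohort
under background opportunistic DRE screening — the registry period's
statutory offer — and sums a Poisson deviance over age-group incidence
and a multinomial deviance over grade proportions.  Optimization is
derivative-free (Nelder-Mead) with common random numbers: every
evaluation reuses the same substream seed, so the objective is a
deterministic function of the parameters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .natural_history import NaturalHistoryParams, simulate_cohort
from .screening import dre_background_diagnoses
from .synthetic import CalibrationTargets, make_life_table, tabulate_rates


class InputError(ValueError):
    pass


# free-parameter vector <-> params object ------------------------------------

FREE_PARAM_NAMES = (
    "log_onset_scale",
    "logit_susceptible",
    "grade_intercept_7",
    "grade_intercept_gt7",
)


def params_to_vector(params: NaturalHistoryParams) -> np.ndarray:
    o = params.onset_hazard_params
    g = params.grade_mixture_params
    f = min(max(o.get("susceptible", 1.0), 1e-6), 1 - 1e-6)
    return np.array(
        [
            np.log(o["scale"]),
            np.log(f / (1 - f)),
            g["intercept_7"],
            g["intercept_gt7"],
        ]
    )


def vector_to_params(x, base: NaturalHistoryParams) -> NaturalHistoryParams:
    d = base.to_dict()
    d = copy.deepcopy(d)
    d["onset_hazard_params"]["scale"] = float(np.exp(x[0]))
    d["onset_hazard_params"]["susceptible"] = float(1 / (1 + np.exp(-x[1])))
    d["grade_mixture_params"]["intercept_7"] = float(x[2])
    d["grade_mixture_params"]["intercept_gt7"] = float(x[3])
    return NaturalHistoryParams.from_dict(d)


# deviances ------------------------------------------------------------------


def poisson_deviance(obs_counts, expected_counts) -> float:
    """Summed Poisson deviance 2*sum(o*log(o/e) - (o - e))."""
    o = np.asarray(obs_counts, dtype=float)
    e = np.maximum(np.asarray(expected_counts, dtype=float), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(o > 0, o * np.log(o / e), 0.0)
    return float(2.0 * np.sum(term - (o - e)))


def multinomial_deviance(obs_counts, model_probs) -> float:
    """Summed multinomial deviance over grade categories per age group."""
    o = np.asarray(obs_counts, dtype=float)
    n = o.sum(axis=-1, keepdims=True)
    p = np.maximum(np.asarray(model_probs, dtype=float), 1e-9)
    e = n * p / p.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(o > 0, o * np.log(o / np.maximum(e, 1e-12)), 0.0)
    return float(2.0 * np.sum(term))


def _model_tables(params, targets, background_screening, n_sim, seed, life_table=None):
    life = make_life_table() if life_table is None else life_table
    cohort = simulate_cohort(params, life, n=n_sim, seed=seed)
    dx_age, dx_grade, pca_death = dre_background_diagnoses(
        cohort, background_screening, seed=seed
    )
    groups = list(
        zip(targets.incidence["age_low"], targets.incidence["age_high"])
    )
    return tabulate_rates(cohort, dx_age, dx_grade, groups, pca_death_age=pca_death)


def calibration_loss(
    params: NaturalHistoryParams,
    targets: CalibrationTargets,
    background_screening: dict,
    n_sim: int = 100_000,
    seed: int = 0,
    life_table: Optional[pd.DataFrame] = None,
) -> float:
    """Poisson (incidence) + multinomial (grade) deviance of the model
    against registry targets, simulated under background DRE screening."""
    targets.validate()
    if (targets.incidence["person_years"] <= 0).any():
        raise InputError("targets with zero person-year denominators")
    model = _model_tables(params, targets, background_screening, n_sim, seed, life_table)
    t = targets.incidence.reset_index(drop=True)
    model_rate = (model["cases"] / model["person_years"]).to_numpy()
    expected = model_rate * t["person_years"].to_numpy()
    loss = poisson_deviance(t["cases"].to_numpy(), expected)

    obs_grade = (
        t[["p_gs_lt7", "p_gs_7", "p_gs_gt7"]].to_numpy()
        * t["cases"].to_numpy()[:, None]
    )
    model_probs = model[["p_gs_lt7", "p_gs_7", "p_gs_gt7"]].to_numpy()
    ok = ~np.isnan(model_probs).any(axis=1) & ~np.isnan(obs_grade).any(axis=1)
    loss += multinomial_deviance(obs_grade[ok], model_probs[ok])
    return loss


@dataclass
class FitReport:
    params: NaturalHistoryParams
    loss: float
    converged: bool
    n_evaluations: int
    loss_trace: list = field(default_factory=list)
    message: str = ""


def fit_natural_history(
    targets: CalibrationTargets,
    background_screening: dict,
    optimizer_config: Optional[dict] = None,
    seed: int = 0,
    base_params: Optional[NaturalHistoryParams] = None,
    life_table: Optional[pd.DataFrame] = None,
) -> FitReport:
    """Fit onset and grade-mixture parameters by Nelder-Mead with common
    random numbers; other natural-history parameters stay fixed.

    ``optimizer_config`` keys: n_sim (cohort size per evaluation), maxiter
    (per restart), n_restarts (fresh simplex from the incumbent; the
    Nelder-Mead simplex on this objective collapses prematurely without
    restarts), xatol, fatol, free (False to skip fitting and evaluate once).
    """
    cfg = {
        "n_sim": 100_000,
        "maxiter": 80,
        "n_restarts": 3,
        "xatol": 1e-3,
        "fatol": 0.5,
        "free": True,
    }
    cfg.update(optimizer_config or {})
    base = base_params or NaturalHistoryParams()
    trace: list = []

    def objective(x):
        p = vector_to_params(x, base)
        val = calibration_loss(
            p, targets, background_screening, cfg["n_sim"], seed, life_table
        )
        trace.append(val)
        return val

    x0 = params_to_vector(base)
    if not cfg["free"]:
        val = objective(x0)
        return FitReport(base, val, True, 1, trace, "no free parameters")

    x = x0
    nfev = 0
    best = None
    for _ in range(max(1, int(cfg["n_restarts"]))):
        result = minimize(
            objective,
            x,
            method="Nelder-Mead",
            options={
                "maxiter": cfg["maxiter"],
                "xatol": cfg["xatol"],
                "fatol": cfg["fatol"],
                "adaptive": True,
            },
        )
        nfev += int(result.nfev)
        if best is None or result.fun < best.fun:
            best = result
        x = result.x
    return FitReport(
        params=vector_to_params(best.x, base),
        loss=float(best.fun),
        converged=bool(best.success),
        n_evaluations=nfev,
        loss_trace=trace,
        message=str(best.message),
    )


def validate_mortality(
    fitted_params: NaturalHistoryParams,
    mortality_targets: Optional[pd.DataFrame],
    n_sim: int = 100_000,
    seed: int = 0,
    background_screening: Optional[dict] = None,
    life_table: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Simulated age-specific cancer mortality with 95% Monte-Carlo
    intervals alongside the targets; no fitting is performed."""
    from .synthetic import default_background_screening

    if mortality_targets is None or len(mortality_targets) == 0:
        return pd.DataFrame(
            columns=[
                "age_low", "age_high", "target_rate", "model_rate",
                "model_lo", "model_hi",
            ]
        )
    bg = background_screening or default_background_screening()
    life = make_life_table() if life_table is None else life_table
    cohort = simulate_cohort(fitted_params, life, n=n_sim, seed=seed)
    _, _, pca_death = dre_background_diagnoses(cohort, bg, seed=seed)
    rows = []
    for _, row in mortality_targets.iterrows():
        lo, hi = row["age_low"], row["age_high"]
        death = cohort.death_age_ns
        py = float((np.minimum(death, hi) - np.minimum(death, lo)).sum())
        d = int((np.isfinite(pca_death) & (pca_death >= lo) & (pca_death < hi)).sum())
        rate = d / py if py > 0 else np.nan
        # exact (Garwood) Poisson interval for the simulated death count
        from scipy.stats import chi2

        lo_ci = chi2.ppf(0.025, 2 * d) / 2.0 / py if d > 0 else 0.0
        hi_ci = chi2.ppf(0.975, 2 * (d + 1)) / 2.0 / py
        rows.append(
            {
                "age_low": lo,
                "age_high": hi,
                "target_rate": row["deaths"] / row["person_years"],
                "model_rate": rate,
                "model_lo": lo_ci,
                "model_hi": hi_ci,
            }
        )
    return pd.DataFrame(rows)
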