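"""Aggregation and cost-effectiveness machinery: per-100,000 outcome
tables, overdiagnosis, strategy comparisons, the efficiency frontier with
ICERs and extended dominance, and cost-effectiveness acceptability curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .screening import DX_CLINICAL, DX_SCREEN


class InputError(ValueError):
    pass


SCALE = 100_000


@dataclass
class StrategyOutcome:
    """Per-100,000-men outcomes for one strategy (Table-style row)."""

    strategy: str
    n_psa_tests: float = 0.0
    n_dre_tests: float = 0.0
    n_mri: float = 0.0
    n_biopsies_total: float = 0.0
    n_biopsies_clinical: float = 0.0
    n_biopsies_screen: float = 0.0
    n_dx_total: float = 0.0
    n_dx_clinical: float = 0.0
    n_dx_screen: float = 0.0
    dx_localized_gs_lt7: float = 0.0
    dx_localized_gs_7: float = 0.0
    dx_localized_gs_gt7: float = 0.0
    dx_metastatic: float = 0.0
    n_overdiagnosed: float = 0.0
    n_pca_deaths: float = 0.0
    ly_undisc: float = 0.0
    ly_disc: float = 0.0
    qaly_undisc: float = 0.0
    qaly_disc: float = 0.0
    cost_undisc_meur: float = 0.0
    cost_disc_meur: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def count_overdiagnosis(history) -> bool:
    """True iff the man was screen-detected and would never have been
    clinically diagnosed in his lifetime without screening."""
    if history.dx_mode != "screen":
        return False
    cf = history.counterfactual_clinical_dx_age
    return cf is None or history.other_cause_death_age < cf


def summarize_per_100k(person_results: pd.DataFrame, strategy: str = "") -> StrategyOutcome:
    """Scale person-level results (columns as produced by
    :func:`prostasim.economics.cohort_economics`) to per-100,000 men."""
    if person_results is None or len(person_results) == 0:
        raise InputError("person_results must be non-empty")
    df = person_results
    f = SCALE / len(df)
    dx = df["dx_mode"] > 0
    localized = dx & ~df["dx_met"]
    out = StrategyOutcome(
        strategy=strategy,
        n_psa_tests=f * df["n_psa"].sum(),
        n_dre_tests=f * df["n_dre"].sum(),
        n_mri=f * df["n_mri"].sum(),
        n_biopsies_screen=f * df["n_biopsy_screen"].sum(),
        n_biopsies_clinical=f * df["n_biopsy_clin"].sum(),
        n_biopsies_total=f * (df["n_biopsy_screen"].sum() + df["n_biopsy_clin"].sum()),
        n_dx_total=f * dx.sum(),
        n_dx_clinical=f * (df["dx_mode"] == DX_CLINICAL).sum(),
        n_dx_screen=f * (df["dx_mode"] == DX_SCREEN).sum(),
        dx_localized_gs_lt7=f * (localized & (df["dx_grade"] == 0)).sum(),
        dx_localized_gs_7=f * (localized & (df["dx_grade"] == 1)).sum(),
        dx_localized_gs_gt7=f * (localized & (df["dx_grade"] == 2)).sum(),
        dx_metastatic=f * (dx & df["dx_met"]).sum(),
        n_overdiagnosed=f * df["overdiagnosed"].sum(),
        n_pca_deaths=f * df["pca_death"].sum(),
        ly_undisc=f * df["ly_undisc"].sum(),
        ly_disc=f * df["ly_disc"].sum(),
        qaly_undisc=f * df["qaly_undisc"].sum(),
        qaly_disc=f * df["qaly_disc"].sum(),
        cost_undisc_meur=f * df["cost_undisc"].sum() / 1e6,
        cost_disc_meur=f * df["cost_disc"].sum() / 1e6,
    )
    return out


def reduction_vs_reference(value, reference, as_percent_of=None):
    """(absolute, percent) reduction of ``value`` relative to ``reference``.

    Absolute = reference - value; percent is rounded half away from zero to
    an integer.  Returns (absolute, None) when the reference is zero.
    """
    absolute = reference - value
    if reference == 0:
        return absolute, None
    pct = 100.0 * absolute / reference
    percent = int(math.floor(abs(pct) + 0.5)) * (1 if pct >= 0 else -1)
    return absolute, percent


# ---------------------------------------------------------------------------
# efficiency frontier
# ---------------------------------------------------------------------------


@dataclass
class FrontierResult:
    """Efficient strategies ordered by increasing effect, with pairwise
    ICERs and a dominance label for every excluded strategy."""

    efficient: list  # strategy names, ordered by effect
    icers: list  # ICER vs previous efficient strategy; first entry None
    dominated: dict = field(default_factory=dict)  # name -> "strictly" | "extended"
    points: dict = field(default_factory=dict)  # name -> (effect, cost)

    def to_dict(self) -> dict:
        return {
            "efficient": self.efficient,
            "icers": self.icers,
            "dominated": self.dominated,
            "points": {k: list(v) for k, v in self.points.items()},
        }


def efficiency_frontier(points: dict, tol: float = 1e-12) -> FrontierResult:
    """Efficiency frontier over ``{name: (effect, cost)}`` pairs.

    Strictly dominated points (another point with >= effect and <= cost,
    one strictly) are removed first; then extended dominance removes points
    whose incremental ICER exceeds that of a later, more effective
    alternative, leaving strictly increasing ICERs along the frontier.
    Ties in effect keep the cheaper point; ties in both keep one
    representative (first by name order).
    """
    if len(points) < 2:
        raise InputError("need at least 2 strategies")
    names = sorted(points)  # deterministic, input-order invariant
    eff = {k: float(points[k][0]) for k in names}
    cost = {k: float(points[k][1]) for k in names}

    dominated: dict = {}
    # collapse exact duplicates to one representative
    seen = {}
    for k in names:
        key = (eff[k], cost[k])
        if key in seen:
            dominated[k] = "strictly"
        else:
            seen[key] = k
    cands = [k for k in names if k not in dominated]

    # strict dominance
    for k in cands:
        for j in cands:
            if j == k:
                continue
            if (
                eff[j] >= eff[k] - tol
                and cost[j] <= cost[k] + tol
                and (eff[j] > eff[k] + tol or cost[j] < cost[k] - tol)
            ):
                dominated[k] = "strictly"
                break
    cands = [k for k in cands if k not in dominated]

    # extended dominance: iterate until ICERs strictly increase
    cands.sort(key=lambda k: (eff[k], cost[k]))
    changed = True
    while changed and len(cands) > 2:
        changed = False
        for i in range(1, len(cands) - 1):
            a, b, c = cands[i - 1], cands[i], cands[i + 1]
            icer_ab = (cost[b] - cost[a]) / (eff[b] - eff[a])
            icer_bc = (cost[c] - cost[b]) / (eff[c] - eff[b])
            if icer_ab > icer_bc - tol:
                dominated[b] = "extended"
                cands.pop(i)
                changed = True
                break

    icers = [None]
    for prev, cur in zip(cands, cands[1:]):
        icers.append((cost[cur] - cost[prev]) / (eff[cur] - eff[prev]))
    return FrontierResult(
        efficient=cands,
        icers=icers,
        dominated=dominated,
        points={k: (eff[k], cost[k]) for k in names},
    )


def frontier_from_outcomes(
    outcomes: list[StrategyOutcome],
    effect_field: str = "qaly_disc",
    cost_field: str = "cost_disc_meur",
) -> FrontierResult:
    points = {
        o.strategy: (getattr(o, effect_field), getattr(o, cost_field)) for o in outcomes
    }
    return efficiency_frontier(points)


# ---------------------------------------------------------------------------
# CEAC
# ---------------------------------------------------------------------------


def ceac_from_draws(psa_draws: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    ``psa_draws`` is tidy with columns (iteration, strategy, cost, effect).
    For each willingness-to-pay value the curve gives the probability that a
    strategy maximizes net monetary benefit ``wtp * effect - cost`` across
    iterations; exact ties split equally.
    """
    wtp_grid = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    if wtp_grid.size == 0:
        raise InputError("empty willingness-to-pay grid")
    strategies = sorted(psa_draws["strategy"].unique())
    if len(strategies) < 2:
        raise InputError("need at least 2 strategies")
    iters = np.sort(psa_draws["iteration"].unique())
    cost = psa_draws.pivot_table(index="iteration", columns="strategy", values="cost").loc[iters, strategies].to_numpy()
    effect = psa_draws.pivot_table(index="iteration", columns="strategy", values="effect").loc[iters, strategies].to_numpy()
    rows = []
    for lam in wtp_grid:
        nmb = lam * effect - cost
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        share = winners / winners.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        for s, p in zip(strategies, probs):
            rows.append({"wtp": lam, "strategy": s, "p_cost_effective": p})
    return pd.DataFrame(rows)


def outcome_table(outcomes: list[StrategyOutcome]) -> pd.DataFrame:
    """Tidy per-100,000 outcome table (one row per strategy)."""
    return pd.DataFrame([o.to_dict() for o in outcomes]).set_index("strategy")
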