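"""Single-realisation execution of the fixed and adaptive trial designs.

Two designs are simulated:

* the fixed "5+5+5+5" benchmark — five active participants at each of
  10, 20, 40 and 80 mg, with rule-based final selection only;
* the three-period adaptive design — period 1 doses 10/20/40/80 mg with
  two active participants each (escalating low to high), period 2 five
  cohorts of two allocated by the CRM (posterior refit before every
  cohort; next dose = the one whose estimated inefficacy probability is
  closest to the target inefficacy level, TIL), and an optional period-3
  confirmation cohort of two at the model-selected dose.

Final-dose criteria (computed on period 1-2 data only):

* rule-based — lowest administered dose with no failures at it or any
  higher administered dose;
* model-based — lowest grid dose whose posterior estimate of inefficacy
  is below the TIL.

Ties in the next-cohort rule break toward the higher dose: selecting too
low a dose is considered worse than selecting too high a dose.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import logit

from .dose_model import DoseGrid, ModelSpec, PosteriorSummary, posterior_update
from .history import TrialHistory
from .scenarios import Scenario

__all__ = [
    "DesignSpec",
    "SelectionResult",
    "run_fixed_realisation",
    "run_period1",
    "closest_to_target",
    "choose_next_dose",
    "run_adaptive_realisation",
    "select_dose_rule_based",
    "select_dose_model_based",
]


@dataclass(frozen=True)
class DesignSpec:
    """Configuration of one trial design."""

    design_kind: str  # "fixed" | "adaptive"
    til: float | None = None
    cohort_size: int = 2
    period1_per_dose: int = 2
    adaptive_n: int = 10
    period3_n: int = 2
    period3_enabled: bool = False
    fixed_per_dose: int = 5
    decision_rule: str = "closest"  # "closest" | "interval"
    interval_halfwidth: float = 0.025
    selection_criteria: str = "both"  # "rule" | "model" | "both"

    def __post_init__(self) -> None:
        if self.design_kind not in ("fixed", "adaptive"):
            raise ValueError(f"unknown design kind {self.design_kind!r}")
        if self.design_kind == "adaptive":
            if self.til is None or not 0.0 <= self.til < 1.0:
                raise ValueError("adaptive design requires a TIL in [0, 1)")
            if self.adaptive_n % self.cohort_size:
                raise ValueError("adaptive_n must be a multiple of cohort_size")
        if self.decision_rule not in ("closest", "interval"):
            raise ValueError(f"unknown decision rule {self.decision_rule!r}")

    @classmethod
    def fixed(cls) -> "DesignSpec":
        return cls(design_kind="fixed", selection_criteria="rule")

    @classmethod
    def adaptive(cls, til: float, **kwargs) -> "DesignSpec":
        return cls(design_kind="adaptive", til=til, **kwargs)

    @property
    def label(self) -> str:
        if self.design_kind == "fixed":
            return "5+5+5+5"
        return f"{round(self.til * 100)}% TIL"

    def active_budget(self) -> int:
        """Maximum number of active-treatment participants."""
        if self.design_kind == "fixed":
            return self.fixed_per_dose * 4
        n = self.period1_per_dose * 4 + self.adaptive_n
        return n + (self.period3_n if self.period3_enabled else 0)


@dataclass(frozen=True)
class SelectionResult:
    """Dose recommended for the multiple-dosing stage under each criterion."""

    rule_dose: int | None
    model_dose: int | None


def _draw(rng: np.random.Generator, p: float) -> int:
    return int(rng.random() < p)


def run_fixed_realisation(
    scenario: Scenario,
    rng: np.random.Generator,
    grid: DoseGrid = DoseGrid(),
    per_dose: int = 5,
) -> tuple[TrialHistory, SelectionResult]:
    """One realisation of the fixed benchmark design (rule-based selection only)."""
    history = TrialHistory()
    for dose in sorted(grid.period1_mg):
        for _ in range(per_dose):
            history.append(dose, _draw(rng, scenario.prob(dose)), period=1)
    return history, SelectionResult(select_dose_rule_based(history), None)


def run_period1(
    scenario: Scenario,
    rng: np.random.Generator,
    grid: DoseGrid = DoseGrid(),
    per_dose: int = 2,
) -> TrialHistory:
    """Escalation phase: ``per_dose`` participants at each period-1 dose, low to high."""
    history = TrialHistory()
    for dose in sorted(grid.period1_mg):
        for _ in range(per_dose):
            history.append(dose, _draw(rng, scenario.prob(dose)), period=1)
    return history


def closest_to_target(estimates: Mapping[int, float], til: float) -> int:
    """Dose whose estimated inefficacy probability is closest to the TIL.

    Exact ties break toward the higher dose.
    """
    tol = 1e-12  # floating-point ties count as exact ties
    best_dose, best_diff = None, None
    for dose in sorted(estimates):
        diff = abs(estimates[dose] - til)
        if best_diff is None or diff <= best_diff + tol:
            best_dose, best_diff = dose, min(diff, best_diff) if best_diff is not None else diff
    return best_dose


def _interval_mass(post: PosteriorSummary, d_std: float, lo_p: float, hi_p: float) -> float:
    # p = expit(intercept - beta*d) is decreasing in beta, so a p-interval
    # maps to a beta-interval [ (intercept - logit(hi_p))/d, (intercept - logit(lo_p))/d ]
    if d_std <= 0:
        return 0.0
    b_lo = (post.intercept - float(logit(hi_p))) / d_std
    b_hi = (post.intercept - float(logit(lo_p))) / d_std
    inside = (post.beta_support >= b_lo) & (post.beta_support <= b_hi)
    return float(post.beta_weights[inside].sum())


def choose_next_dose(
    post: PosteriorSummary,
    til: float,
    grid: DoseGrid = DoseGrid(),
    rule: str = "closest",
    interval_halfwidth: float = 0.025,
) -> int:
    """Dose for the next adaptive cohort.

    ``closest`` (default): grid dose whose point estimate of inefficacy is
    closest to the TIL.  ``interval``: grid dose maximising the posterior
    mass of p_d within [TIL - hw, TIL + hw].  Both break ties toward the
    higher dose.
    """
    if rule == "closest":
        estimates = dict(zip(post.doses_mg, post.point_estimates()))
        return closest_to_target(estimates, til)
    if rule == "interval":
        lo_p = max(1e-9, til - interval_halfwidth)
        hi_p = min(1 - 1e-9, til + interval_halfwidth)
        best_dose, best_mass = None, None
        for dose, d_std in zip(post.doses_mg, post.standardised):
            mass = _interval_mass(post, d_std, lo_p, hi_p)
            if best_mass is None or mass >= best_mass:
                best_dose, best_mass = dose, mass
        return best_dose
    raise ValueError(f"unknown decision rule {rule!r}")


def select_dose_rule_based(history: TrialHistory) -> int | None:
    """Lowest administered dose with no failures at it or any higher administered dose.

    Only period 1-2 data and only doses actually administered are considered.
    """
    phase = history.subset((1, 2))
    administered = phase.administered_doses((1, 2))
    if not administered:
        raise ValueError("empty history")
    failed = {d: False for d in administered}
    for r in phase:
        if r.response:
            failed[r.dose_mg] = True
    for dose in administered:
        if not any(failed[d] for d in administered if d >= dose):
            return dose
    return None


def select_dose_model_based(
    post: PosteriorSummary, til: float, grid: DoseGrid = DoseGrid()
) -> int | None:
    """Lowest grid dose whose posterior inefficacy estimate is below the TIL."""
    for dose, est in zip(post.doses_mg, post.point_estimates()):
        if est < til:
            return dose
    return None


def run_adaptive_realisation(
    scenario: Scenario,
    design: DesignSpec,
    model: ModelSpec = ModelSpec(),
    rng: np.random.Generator | None = None,
    grid: DoseGrid = DoseGrid(),
) -> tuple[TrialHistory, SelectionResult]:
    """One realisation of the three-period adaptive design.

    The posterior is refit before every adaptive cohort using all previous
    responses.  Both selection criteria are computed on period 1-2 data;
    period 3, when enabled and a model-based dose exists, doses the final
    confirmation cohort at that dose without feeding back into selection.
    """
    if design.design_kind != "adaptive":
        raise ValueError("run_adaptive_realisation requires an adaptive design")
    if rng is None:
        rng = np.random.default_rng()
    history = run_period1(scenario, rng, grid, per_dose=design.period1_per_dose)
    n_cohorts = design.adaptive_n // design.cohort_size
    for _ in range(n_cohorts):
        post = posterior_update(history, model, grid)
        dose = choose_next_dose(
            post, design.til, grid, design.decision_rule, design.interval_halfwidth
        )
        for _ in range(design.cohort_size):
            history.append(dose, _draw(rng, scenario.prob(dose)), period=2)
    final_post = posterior_update(history.subset((1, 2)), model, grid)
    rule_dose = select_dose_rule_based(history)
    model_dose = select_dose_model_based(final_post, design.til, grid)
    if design.period3_enabled and model_dose is not None:
        for _ in range(design.period3_n):
            history.append(model_dose, _draw(rng, scenario.prob(model_dose)), period=3)
    return history, SelectionResult(rule_dose, model_dose)
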