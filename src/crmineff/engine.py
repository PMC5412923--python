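"""Monte-Carlo evaluation of trial designs: operating characteristics.

For each (design, scenario) pair the engine runs many independent trial
realisations on a splittable seeded stream and averages the quantities
the trial team cares about: the probability of selecting each dose (or
no dose) for the next stage, the mean number of participants per dose,
the mean number of ineffective responses, and the mean number of
participants dosed below the scenario's target dose.  For the fixed
benchmark an exact enumeration oracle is provided as an independent
check on the stochastic engine.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import DesignSpec, run_adaptive_realisation, run_fixed_realisation
from .dose_model import DoseGrid, ModelSpec
from .scenarios import Scenario

__all__ = [
    "OperatingCharacteristics",
    "simulate_design",
    "fixed_design_oracle",
    "repeat_stability",
]


@dataclass
class OperatingCharacteristics:
    """Per-design, per-scenario means over realisations."""

    design: str
    scenario: str
    n_realisations: int
    p_select: dict[str, dict[int | None, float]]
    n_per_dose: dict[int, float]
    n_ineffective: float
    n_below_target: float | None
    metadata: dict = field(default_factory=dict)

    def selection_series(self, criterion: str) -> pd.Series:
        sel = self.p_select[criterion]
        doses = sorted(d for d in sel if d is not None)
        return pd.Series([sel[None]] + [sel[d] for d in doses], index=["none"] + doses)

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "scenario": self.scenario,
            "n_realisations": self.n_realisations,
            "p_select": {
                crit: {("none" if d is None else str(d)): v for d, v in sel.items()}
                for crit, sel in self.p_select.items()
            },
            "n_per_dose": {str(d): v for d, v in self.n_per_dose.items()},
            "n_ineffective": self.n_ineffective,
            "n_below_target": self.n_below_target,
            "metadata": self.metadata,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "OperatingCharacteristics":
        return cls(
            design=d["design"],
            scenario=d["scenario"],
            n_realisations=d["n_realisations"],
            p_select={
                crit: {(None if k == "none" else int(k)): float(v) for k, v in sel.items()}
                for crit, sel in d["p_select"].items()
            },
            n_per_dose={int(k): float(v) for k, v in d["n_per_dose"].items()},
            n_ineffective=float(d["n_ineffective"]),
            n_below_target=None if d["n_below_target"] is None else float(d["n_below_target"]),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, text: str) -> "OperatingCharacteristics":
        return cls.from_dict(json.loads(text))


def _empty_selection(grid: DoseGrid) -> dict[int | None, float]:
    sel: dict[int | None, float] = {None: 0.0}
    sel.update({d: 0.0 for d in grid.actual_mg})
    return sel


def simulate_design(
    design: DesignSpec,
    scenario: Scenario,
    model: ModelSpec = ModelSpec(),
    n_realisations: int = 1000,
    seed: int = 0,
    grid: DoseGrid = DoseGrid(),
) -> OperatingCharacteristics:
    """Average operating characteristics over independent realisations.

    One master seed spawns a child stream per realisation, so results are
    reproducible and independent of execution order.
    """
    if n_realisations < 1:
        raise ValueError("n_realisations must be at least 1")
    criteria = (
        ("rule",)
        if design.design_kind == "fixed" or design.selection_criteria == "rule"
        else ("model",) if design.selection_criteria == "model" else ("rule", "model")
    )
    counts = {crit: _empty_selection(grid) for crit in criteria}
    alloc = {d: 0.0 for d in grid.actual_mg}
    total_ineffective = 0.0
    total_below = 0.0
    target = scenario.target_mg

    streams = np.random.SeedSequence(seed).spawn(n_realisations)
    for child in streams:
        rng = np.random.default_rng(child)
        if design.design_kind == "fixed":
            history, result = run_fixed_realisation(
                scenario, rng, grid, per_dose=design.fixed_per_dose
            )
        else:
            history, result = run_adaptive_realisation(scenario, design, model, rng, grid)
        for crit in criteria:
            dose = result.rule_dose if crit == "rule" else result.model_dose
            counts[crit][dose] += 1.0
        for r in history:
            alloc[r.dose_mg] += 1.0
            total_ineffective += r.response
            if target is not None and r.dose_mg < target:
                total_below += 1.0

    n = float(n_realisations)
    return OperatingCharacteristics(
        design=design.label,
        scenario=scenario.name,
        n_realisations=n_realisations,
        p_select={crit: {d: c / n for d, c in sel.items()} for crit, sel in counts.items()},
        n_per_dose={d: c / n for d, c in alloc.items()},
        n_ineffective=total_ineffective / n,
        n_below_target=None if target is None else total_below / n,
        metadata={
            "seed": seed,
            "design_kind": design.design_kind,
            "til": design.til,
            "decision_rule": design.decision_rule,
            "prior": [model.prior_name, list(model.prior_params)],
            "point_convention": model.point_convention,
            "period3_enabled": design.period3_enabled,
        },
    )


def fixed_design_oracle(
    scenario: Scenario, grid: DoseGrid = DoseGrid(), per_dose: int = 5
) -> OperatingCharacteristics:
    """Exact operating characteristics of the fixed design by enumeration.

    Rule-based selection depends only on which administered doses have
    zero failures, so the 2^4 joint zero-failure patterns with binomial
    probabilities (1 - p_d)^per_dose enumerate the selection distribution
    exactly; allocation and expected failure counts follow by linearity.
    """
    doses = sorted(grid.period1_mg)
    q = {d: (1.0 - scenario.prob(d)) ** per_dose for d in doses}
    p_select = _empty_selection(grid)
    for pattern in range(2 ** len(doses)):
        zero_fail = {d: bool(pattern >> i & 1) for i, d in enumerate(doses)}
        prob = 1.0
        for d in doses:
            prob *= q[d] if zero_fail[d] else 1.0 - q[d]
        chosen = None
        for d in doses:
            if all(zero_fail[e] for e in doses if e >= d):
                chosen = d
                break
        p_select[chosen] += prob

    target = scenario.target_mg
    n_below = None
    if target is not None:
        n_below = float(per_dose * sum(1 for d in doses if d < target))
    alloc = {d: (float(per_dose) if d in doses else 0.0) for d in grid.actual_mg}
    return OperatingCharacteristics(
        design="5+5+5+5",
        scenario=scenario.name,
        n_realisations=0,
        p_select={"rule": p_select},
        n_per_dose=alloc,
        n_ineffective=per_dose * sum(scenario.prob(d) for d in doses),
        n_below_target=n_below,
        metadata={"exact": True},
    )


def repeat_stability(
    design: DesignSpec,
    scenario: Scenario,
    model: ModelSpec = ModelSpec(),
    n_realisations: int = 1000,
    n_repeats: int = 5,
    seeds: list[int] | None = None,
    criterion: str = "rule",
    grid: DoseGrid = DoseGrid(),
) -> dict[str, float]:
    """Max - min of each summary measure across repeated simulation runs."""
    from .metrics import summary_measures

    if n_repeats < 2:
        raise ValueError("n_repeats must be at least 2")
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("seeds must have length n_repeats")
    values: dict[str, list[float]] = {m: [] for m in ("sm1", "sm2", "sm3", "sm4", "wsm")}
    for seed in seeds:
        oc = simulate_design(design, scenario, model, n_realisations, seed, grid)
        sm = summary_measures(oc, scenario, criterion)
        for m in values:
            values[m].append(getattr(sm, m))
    return {m: max(v) - min(v) for m, v in values.items()}
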