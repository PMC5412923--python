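"""True dose-inefficacy scenarios for evaluating the trial designs.

Scenario 1 (the "standard PK model, 40 mg effective dose" case) is fully
specified by its published per-dose probabilities.  The remaining bank
scenarios are emulated: parametric curves constrained to reproduce each
scenario's target dose and shape (logistic-like with targets at 60 mg,
80 mg, none and 10 mg; a shallow curve; and a reverse-J curve that tracks
Scenario 1 up to 40 mg before turning upwards).  The target dose of a
scenario is the dose with the highest true inefficacy probability at or
below the tolerable level (5% by default) — for a monotone curve, the
lowest qualifying dose.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd
from scipy.special import expit, logit

from .dose_model import DoseGrid

__all__ = [
    "Scenario",
    "derive_target_dose",
    "scenario1",
    "make_logistic_scenario",
    "make_shallow_scenario",
    "make_ushape_scenario",
    "default_bank",
]

TOLERABLE_INEFFICACY = 0.05


@dataclass
class Scenario:
    """A named true dose-inefficacy curve with its derived target dose."""

    name: str
    probs: dict[int, float]
    target_mg: int | None
    shape_tags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d, p in self.probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability at {d} mg outside [0, 1]: {p}")

    def prob(self, dose_mg: int) -> float:
        return self.probs[dose_mg]

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "probs": {str(d): p for d, p in self.probs.items()},
            "target_mg": self.target_mg,
            "shape_tags": dict(self.shape_tags),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            name=d["name"],
            probs={int(k): float(v) for k, v in d["probs"].items()},
            target_mg=d["target_mg"],
            shape_tags=dict(d.get("shape_tags", {})),
        )

    @classmethod
    def from_json(cls, text: str) -> "Scenario":
        return cls.from_dict(json.loads(text))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"dose_mg": list(self.probs), "p_ineffective": list(self.probs.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str = "from_csv", tolerable: float = TOLERABLE_INEFFICACY) -> "Scenario":
        frame = pd.read_csv(path)
        probs = {int(d): float(p) for d, p in zip(frame["dose_mg"], frame["p_ineffective"])}
        return cls(name=name, probs=probs, target_mg=derive_target_dose(probs, tolerable))


def derive_target_dose(probs: dict[int, float], tolerable: float = TOLERABLE_INEFFICACY) -> int | None:
    """The dose with the highest inefficacy probability <= the tolerable level.

    On a monotone decreasing curve this is the lowest qualifying dose; the
    literal highest-probability rule is applied so that non-monotone
    (reverse-J) curves still resolve to the pre-turn qualifying dose.
    Ties on probability resolve to the lower dose, matching the monotone
    equivalence.  Returns None when no dose qualifies.
    """
    qualifying = [(p, d) for d, p in probs.items() if p <= tolerable]
    if not qualifying:
        return None
    best_p = max(p for p, _ in qualifying)
    return min(d for p, d in qualifying if p == best_p)


def scenario1(grid: DoseGrid = DoseGrid()) -> Scenario:
    """The published benchmark scenario: target dose 40 mg."""
    probs = {10: 0.95, 20: 0.75, 30: 0.40, 40: 0.05, 50: 0.04, 60: 0.03, 70: 0.02, 80: 0.01}
    if set(probs) != set(grid.actual_mg):
        raise ValueError("scenario1 is defined on the default 8-dose grid")
    return Scenario(
        name="scenario1",
        probs=probs,
        target_mg=derive_target_dose(probs),
        shape_tags={"logistic_like": True, "monotonic": True, "boundary_target": False},
    )


def _logistic_probs(grid: DoseGrid, crossing_d: float, steepness: float) -> dict[int, float]:
    # inefficacy = expit(a - b*d) with the 5% crossing placed at crossing_d
    a = float(logit(TOLERABLE_INEFFICACY)) + steepness * crossing_d
    return {
        mg: float(expit(a - steepness * d))
        for mg, d in zip(grid.actual_mg, grid.standardised)
    }


def make_logistic_scenario(
    target_mg: int | None,
    steepness: float = 1.75,
    grid: DoseGrid = DoseGrid(),
    name: str | None = None,
) -> Scenario:
    """Emulated logistic-shaped scenario whose target rule yields ``target_mg``.

    The 5% crossing is placed midway between the target and the dose one
    level below it (beyond the grid when ``target_mg`` is None), so the
    target-dose rule recovers ``target_mg`` by construction for any
    positive steepness.
    """
    if steepness <= 0:
        raise ValueError("steepness must be positive")
    std = dict(zip(grid.actual_mg, grid.standardised))
    if target_mg is None:
        step = grid.standardised[-1] - grid.standardised[-2]
        crossing = grid.standardised[-1] + step
    else:
        if target_mg not in std:
            raise ValueError(f"target {target_mg} mg not on the grid")
        i = grid.actual_mg.index(target_mg)
        below = grid.standardised[i - 1] if i > 0 else 0.0
        crossing = 0.5 * (std[target_mg] + below)
    probs = _logistic_probs(grid, crossing, steepness)
    derived = derive_target_dose(probs)
    if derived != target_mg:
        raise ValueError(f"target {target_mg} mg infeasible on this grid")
    boundary = target_mg in (grid.actual_mg[0], grid.actual_mg[-1])
    return Scenario(
        name=name or f"logistic_target_{target_mg}",
        probs=probs,
        target_mg=derived,
        shape_tags={"logistic_like": True, "monotonic": True, "boundary_target": boundary},
    )


def make_shallow_scenario(
    target_mg: int,
    steepness: float = 0.5,
    grid: DoseGrid = DoseGrid(),
    name: str | None = None,
) -> Scenario:
    """Emulated shallow monotone scenario (partial efficacy at very low doses)."""
    s = make_logistic_scenario(target_mg, steepness=steepness, grid=grid,
                               name=name or f"shallow_target_{target_mg}")
    s.shape_tags = {"logistic_like": False, "monotonic": True,
                    "boundary_target": target_mg in (grid.actual_mg[0], grid.actual_mg[-1])}
    return s


def make_ushape_scenario(
    turn_mg: int = 40,
    rise: float = 0.15,
    grid: DoseGrid = DoseGrid(),
    name: str = "ushape",
) -> Scenario:
    """Reverse-J scenario: tracks scenario 1 up to ``turn_mg``, then rises.

    Above the turn the probability increases by ``rise`` per dose step,
    capped below 1, emulating unexpected auto-induction of the drug.
    """
    base = scenario1(grid).probs
    if turn_mg not in grid.actual_mg:
        raise ValueError(f"turn dose {turn_mg} mg not on the grid")
    probs: dict[int, float] = {}
    last = None
    for k, mg in enumerate(grid.actual_mg):
        if mg <= turn_mg:
            probs[mg] = base[mg]
            last = probs[mg]
        else:
            steps = k - grid.actual_mg.index(turn_mg)
            probs[mg] = min(0.99, last + rise * steps)
    return Scenario(
        name=name,
        probs=probs,
        target_mg=derive_target_dose(probs),
        shape_tags={"logistic_like": False, "monotonic": False, "boundary_target": False},
    )


def default_bank(grid: DoseGrid = DoseGrid()) -> dict[str, Scenario]:
    """The seven-scenario test bank (scenarios 2-7 are emulated curves)."""
    return {
        "scenario1": scenario1(grid),
        "scenario2": make_logistic_scenario(60, grid=grid, name="scenario2"),
        "scenario3": make_logistic_scenario(80, grid=grid, name="scenario3"),
        "scenario4": make_logistic_scenario(None, grid=grid, name="scenario4"),
        "scenario5": make_logistic_scenario(10, grid=grid, name="scenario5"),
        "scenario6": make_shallow_scenario(60, grid=grid, name="scenario6"),
        "scenario7": make_ushape_scenario(40, grid=grid, name="scenario7"),
    }
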