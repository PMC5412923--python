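"""Summary measures of design performance relative to the target dose.

Four probabilities of choosing a "good dose" condense a selection
distribution (SM1: target or any higher dose; SM2: target or one step
higher; SM3: target exactly; SM4: target or one step higher or lower),
plus a weighted summary measure (WSM) that linearly down-weights
selections above the target and penalises failing to select any dose.
When a scenario has no target dose, every measure is the probability of
correctly selecting no dose.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .engine import OperatingCharacteristics
from .scenarios import Scenario

__all__ = ["SummaryMeasures", "summary_measures", "weighted_summary_measure", "design_difference"]

_DOSE_STEP_MG = 10
_MAX_INDEX = 8  # dose grid runs 10..80 mg, indexed 1..8 as dose/10


@dataclass
class SummaryMeasures:
    sm1: float
    sm2: float
    sm3: float
    sm4: float
    wsm: float
    target_mg: int | None
    criterion: str
    scenario: str
    design: str

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in ("sm1", "sm2", "sm3", "sm4", "wsm")}


def weighted_summary_measure(
    p_select: Mapping[int | None, float], target_mg: int | None
) -> float:
    """WSM: p(target) + sum over up to four higher doses of p weighted by
    1 - (steps above target)/5, minus twice the probability of no selection.

    With no target dose the measure is the probability of selecting no dose.
    Doses are indexed as mg/10; the sum runs from the index above the target
    to min(8, target index + 4).
    """
    if target_mg is None:
        return float(p_select.get(None, 0.0))
    t = target_mg // _DOSE_STEP_MG
    value = float(p_select.get(target_mg, 0.0))
    for i in range(t + 1, min(_MAX_INDEX, t + 4) + 1):
        value += p_select.get(i * _DOSE_STEP_MG, 0.0) * (1.0 - (i - t) / 5.0)
    value -= 2.0 * p_select.get(None, 0.0)
    return value


def summary_measures(
    oc: OperatingCharacteristics, scenario: Scenario, criterion: str = "rule"
) -> SummaryMeasures:
    """Condense one selection distribution into SM1-SM4 and the WSM."""
    if oc.scenario != scenario.name:
        raise ValueError(
            f"operating characteristics are for {oc.scenario!r}, not {scenario.name!r}"
        )
    sel = oc.p_select[criterion]
    target = scenario.target_mg
    if target is None:
        p_none = sel.get(None, 0.0)
        return SummaryMeasures(
            p_none, p_none, p_none, p_none, p_none, None, criterion, scenario.name, oc.design
        )
    sm3 = sel.get(target, 0.0)
    sm1 = sum(v for d, v in sel.items() if d is not None and d >= target)
    sm2 = sm3 + sel.get(target + _DOSE_STEP_MG, 0.0)
    sm4 = sm2 + sel.get(target - _DOSE_STEP_MG, 0.0)
    wsm = weighted_summary_measure(sel, target)
    return SummaryMeasures(sm1, sm2, sm3, sm4, wsm, target, criterion, scenario.name, oc.design)


def design_difference(
    adaptive_sm: SummaryMeasures, benchmark_sm: SummaryMeasures
) -> dict[str, float]:
    """Adaptive minus benchmark, per measure; positive favours the adaptive design."""
    if adaptive_sm.scenario != benchmark_sm.scenario:
        raise ValueError("summary measures compare different scenarios")
    if adaptive_sm.target_mg != benchmark_sm.target_mg:
        raise ValueError("summary measures use different target doses")
    a, b = adaptive_sm.as_dict(), benchmark_sm.as_dict()
    return {m: a[m] - b[m] for m in a}
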