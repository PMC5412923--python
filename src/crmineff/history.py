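"""Per-participant trial records for a single realisation.

A history is the ordered list of (participant, dose, response, period)
tuples for one simulated trial.  The response is the binary inefficacy
endpoint: 1 means the participant failed to reach the required drug
concentration (ineffective), 0 means the dose was effective for them.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ParticipantRecord", "TrialHistory"]


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: dose in mg, response (1 = ineffective), trial period."""

    participant: int
    dose_mg: int
    response: int
    period: int

    def __post_init__(self) -> None:
        if self.response not in (0, 1):
            raise ValueError(f"response must be 0 or 1, got {self.response}")
        if self.period not in (1, 2, 3):
            raise ValueError(f"period must be 1, 2 or 3, got {self.period}")


class TrialHistory:
    """Ordered per-participant records for one trial realisation."""

    def __init__(self, records: Iterable[ParticipantRecord] = ()) -> None:
        self.records: list[ParticipantRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, TrialHistory) and self.records == other.records

    def append(self, dose_mg: int, response: int, period: int) -> None:
        self.records.append(
            ParticipantRecord(len(self.records) + 1, int(dose_mg), int(response), period)
        )

    def subset(self, periods: Sequence[int]) -> "TrialHistory":
        """Records from the given periods only, original order preserved."""
        keep = set(periods)
        return TrialHistory(r for r in self.records if r.period in keep)

    def administered_doses(self, periods: Sequence[int] = (1, 2)) -> list[int]:
        keep = set(periods)
        return sorted({r.dose_mg for r in self.records if r.period in keep})

    def response_counts(self, doses_mg: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        """Counts of ineffective (y=1) and effective (y=0) responses per dose.

        Raises if any administered dose is not in ``doses_mg``.
        """
        index = {d: j for j, d in enumerate(doses_mg)}
        n1 = np.zeros(len(doses_mg))
        n0 = np.zeros(len(doses_mg))
        for r in self.records:
            if r.dose_mg not in index:
                raise ValueError(f"dose {r.dose_mg} mg not on the dose grid")
            if r.response:
                n1[index[r.dose_mg]] += 1
            else:
                n0[index[r.dose_mg]] += 1
        return n1, n0

    def n_ineffective(self) -> int:
        return sum(r.response for r in self.records)

    # -- serialisation --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.participant, r.period, r.dose_mg, r.response) for r in self.records],
            columns=["participant", "period", "dose_mg", "y"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialHistory":
        frame = frame.sort_values("participant")
        return cls(
            ParticipantRecord(int(p), int(d), int(y), int(per))
            for p, per, d, y in frame[["participant", "period", "dose_mg", "y"]].itertuples(
                index=False
            )
        )

    @classmethod
    def from_csv(cls, path) -> "TrialHistory":
        return cls.from_frame(pd.read_csv(path))

    def to_json(self) -> str:
        return json.dumps(
            [
                {"participant": r.participant, "period": r.period, "dose_mg": r.dose_mg, "y": r.response}
                for r in self.records
            ]
        )

    @classmethod
    def from_json(cls, text: str) -> "TrialHistory":
        return cls(
            ParticipantRecord(e["participant"], e["dose_mg"], e["y"], e["period"])
            for e in json.loads(text)
        )
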