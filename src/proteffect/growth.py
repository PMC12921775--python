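"""Aquaculture production indices for a feeding trial.

Three standard indices over a trial of ``days`` duration:

* specific growth rate, SGR = (ln W_final − ln W_initial)/days × 100   [%/day]
* food conversion ratio, FCR = feed intake / wet weight gain           [–]
* relative food intake, RFI = daily intake / geometric-mean body weight
  in kg                                                                [g/kgBW/day]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GrowthRecord", "sgr", "fcr", "rfi", "indices_table"]


def sgr(initial: float, final: float, days: float) -> float:
    """Specific growth rate in % per day."""
    if initial <= 0 or final <= 0:
        raise ValueError("weights must be positive")
    if days <= 0:
        raise ValueError("days must be positive")
    return (np.log(final) - np.log(initial)) / days * 100.0


def fcr(feed_intake: float, gain: float) -> float:
    """Food conversion ratio: grams of feed per gram of wet weight gained."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    if feed_intake < 0:
        raise ValueError("feed intake must be non-negative")
    return feed_intake / gain


def rfi(daily_intake: float, initial: float, final: float) -> float:
    """Relative food intake: g feed per kg geometric-mean body weight per day."""
    if initial <= 0 or final <= 0:
        raise ValueError("weights must be positive")
    if daily_intake < 0:
        raise ValueError("daily intake must be non-negative")
    gm_kg = np.sqrt(initial * final) / 1000.0
    return daily_intake / gm_kg


@dataclass
class GrowthRecord:
    """Per-group (or per-tank) growth measurements in grams and days."""

    group: str
    initial_weight: float
    final_weight: float
    days: int
    feed_intake: float
    gain: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.initial_weight <= 0 or self.final_weight <= 0:
            raise ValueError("weights must be positive")
        if self.days <= 0:
            raise ValueError("days must be positive")
        derived = self.final_weight - self.initial_weight
        if self.gain is None:
            self.gain = derived
        elif abs(self.gain - derived) >= 0.01:
            raise ValueError(
                f"gain {self.gain} inconsistent with final-initial={derived:.3f}"
            )

    @property
    def daily_intake(self) -> float:
        return self.feed_intake / self.days

    def indices(self) -> dict:
        return {
            "group": self.group,
            "sgr": sgr(self.initial_weight, self.final_weight, self.days),
            "fcr": fcr(self.feed_intake, self.gain),
            "rfi": rfi(self.daily_intake, self.initial_weight, self.final_weight),
        }


def indices_table(records) -> pd.DataFrame:
    """SGR/FCR/RFI per record, values rounded to 3 decimals for reporting."""
    rows = [r.indices() for r in records]
    df = pd.DataFrame(rows)
    for col in ("sgr", "fcr", "rfi"):
        df[col] = df[col].round(3)
    return df
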