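"""First-order elimination models for breath CO and urine cotinine.

Breath CO is a short-half-life marker of recent smoking (3-6 h);
cotinine, the primary nicotine metabolite, clears much more slowly and
the rate depends on pregnancy status (half-life about 9 h in pregnant
and 17 h in nonpregnant women).  Both analytes are modelled as
first-order (exponential) elimination with additive superposition
across cigarettes: each cigarette deposits a fixed boost that decays as
``2 ** (-dt / half_life)``.  Breath CO additionally rides on a small
endogenous level produced by heme catabolism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["PhysioParams", "co_level", "cotinine_level", "apply_lab_floor"]

#: A smoking event: (time in hours from an arbitrary origin, cigarettes smoked).
Event = tuple[float, float]


@dataclass(frozen=True)
class PhysioParams:
    """Pharmacokinetic constants driving the analyte models.

    co_half_life : hours, default 4.5 (midpoint of the 3-6 h range).
    co_boost_per_cigarette : ppm added to breath CO per cigarette (3).
    endogenous_co : ppm of smoking-independent breath CO (1).
    cotinine_half_life_pregnant / _nonpregnant : hours (9 / 17).
    cotinine_boost_per_cigarette : ng/mL per cigarette (100).
    lab_floor : ng/mL, assay limit of quantitation (10).
    lab_floor_estimate : ng/mL substituted for sub-floor reports (5).
    """

    co_half_life: float = 4.5
    co_boost_per_cigarette: float = 3.0
    endogenous_co: float = 1.0
    cotinine_half_life_pregnant: float = 9.0
    cotinine_half_life_nonpregnant: float = 17.0
    cotinine_boost_per_cigarette: float = 100.0
    lab_floor: float = 10.0
    lab_floor_estimate: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "co_half_life",
            "cotinine_half_life_pregnant",
            "cotinine_half_life_nonpregnant",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lab_floor_estimate >= self.lab_floor:
            raise ValueError("lab_floor_estimate must lie below lab_floor")


def _superpose(
    events: Sequence[Event], t: float, boost: float, half_life: float
) -> float:
    """Sum of decayed boosts from all events at or before ``t``."""
    total = 0.0
    for when, n in events:
        if when <= t:
            total += n * boost * 2.0 ** (-(t - when) / half_life)
    return total


def co_level(events: Sequence[Event], t: float, p: PhysioParams) -> float:
    """Breath CO in ppm at time ``t`` given a smoking-event history.

    ``events`` is a time-sorted sequence of ``(time_h, n_cigarettes)``;
    events after ``t`` contribute nothing.  Returns endogenous CO plus
    the superposed exponential decay of each cigarette's boost.
    """
    _check_sorted(events)
    return p.endogenous_co + _superpose(events, t, p.co_boost_per_cigarette, p.co_half_life)


def cotinine_level(
    events: Sequence[Event],
    t: float,
    p: PhysioParams,
    pregnant: bool,
    raw: bool = False,
) -> float:
    """Urine cotinine in ng/mL at time ``t``, pregnancy-dependent half-life.

    By default the value is passed through the assay's reporting floor:
    raw concentrations strictly below ``lab_floor`` are reported as
    ``lab_floor_estimate``.  Set ``raw=True`` for the model value.
    """
    _check_sorted(events)
    hl = p.cotinine_half_life_pregnant if pregnant else p.cotinine_half_life_nonpregnant
    value = _superpose(events, t, p.cotinine_boost_per_cigarette, hl)
    return value if raw else apply_lab_floor(value, p)


def apply_lab_floor(raw_value: float, p: PhysioParams) -> float:
    """Assay reporting rule: raw < floor reports the floor estimate."""
    if raw_value < 0:
        raise ValueError("cotinine concentration cannot be negative")
    return p.lab_floor_estimate if raw_value < p.lab_floor else raw_value


def _check_sorted(events: Sequence[Event]) -> None:
    times = [e[0] for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("events must be sorted by time")
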