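"""Escalating-reward contingency management and the remote-test lifecycle.

Contingency management reinforces biochemically verified abstinence:
each consecutive smoke-free (CO-negative) breath test earns more tokens
than the last, and a positive or missed test resets the escalation.
Remote tests arrive as app notifications inside a daytime window and
expire after a fixed number of hours; failed deliveries may be replaced
in office or remotely, and a participant may challenge a result, which
staff can overturn as a false positive (the test is then dropped from
the reward streak and replaced).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RewardSchedule",
    "RemoteTestEvent",
    "award_tokens",
    "schedule_notification",
    "resolve_remote_test",
]

#: Test statuses recognised by the reward engine.
NEGATIVE, POSITIVE, MISSED = "negative", "positive", "missed"


@dataclass(frozen=True)
class RewardSchedule:
    """Escalation schedule: the k-th consecutive negative test earns
    ``min(base + (k-1) * increment, cap)`` tokens.

    ``reset_policy='reset_to_base'`` restarts the escalation after a
    positive or missed test; ``'none'`` resumes where it left off.
    """

    base_tokens: int = 1
    increment_tokens: int = 1
    reset_policy: str = "reset_to_base"
    max_tokens: int | None = None

    def __post_init__(self) -> None:
        if self.base_tokens <= 0:
            raise ValueError("base_tokens must be positive")
        if self.increment_tokens < 0:
            raise ValueError("increment_tokens must be non-negative")
        if self.reset_policy not in ("reset_to_base", "none"):
            raise ValueError("reset_policy must be 'reset_to_base' or 'none'")
        if self.max_tokens is not None and self.max_tokens < self.base_tokens:
            raise ValueError("cap cannot fall below base_tokens")

    def award_for(self, k: int) -> int:
        """Tokens for the k-th (1-based) consecutive negative test."""
        amount = self.base_tokens + (k - 1) * self.increment_tokens
        return amount if self.max_tokens is None else min(amount, self.max_tokens)


def award_tokens(
    history: Sequence[str], schedule: RewardSchedule | None = None
) -> list[int]:
    """Token award for each test in a status history.

    ``history`` is an ordered sequence over {negative, positive,
    missed}.  Negatives escalate; positives and missed tests earn
    nothing and, under ``reset_to_base``, restart the escalation.
    """
    if len(history) == 0:
        raise ValueError("history must be nonempty")
    schedule = schedule or RewardSchedule()
    awards = []
    k = 0
    for status in history:
        if status == NEGATIVE:
            k += 1
            awards.append(schedule.award_for(k))
        elif status in (POSITIVE, MISSED):
            awards.append(0)
            if schedule.reset_policy == "reset_to_base":
                k = 0
        else:
            raise ValueError(f"unknown test status {status!r}")
    return awards


def schedule_notification(
    day: pd.Timestamp,
    window: tuple[dt.time, dt.time],
    rng: np.random.Generator,
) -> pd.Timestamp:
    """Draw a notification time uniformly inside the day's clock window."""
    lo, hi = window
    lo_h = lo.hour + lo.minute / 60.0 + lo.second / 3600.0
    hi_h = hi.hour + hi.minute / 60.0 + hi.second / 3600.0
    if hi_h < lo_h:
        raise ValueError("notification window must not be empty")
    day = pd.Timestamp(day).normalize()
    return day + pd.Timedelta(hours=float(rng.uniform(lo_h, hi_h)))


@dataclass
class RemoteTestEvent:
    """One remote breath-test notification and its resolution."""

    notification_time: pd.Timestamp
    expiry_hours: float = 5.0
    outcome: str = "completed"  # completed | expired | delivery_failed
    replacement: str = "none"  # none | in_office | remote
    verification: dict = field(
        default_factory=lambda: {
            "face_ok": True,
            "mouth_visible": True,
            "audio_present": True,
            "audio_interpretable": True,
        }
    )
    challenged: bool = False
    challenge_result: str = "none"  # none | upheld | replaced

    def __post_init__(self) -> None:
        if self.outcome not in ("completed", "expired", "delivery_failed"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "expired" and self.verification:
            # an expired notification never produced media to verify
            self.verification = {}

    @property
    def expiry_time(self) -> pd.Timestamp:
        return self.notification_time + pd.Timedelta(hours=self.expiry_hours)


def resolve_remote_test(
    event: RemoteTestEvent,
    rng: np.random.Generator | None = None,
    replacement_policy: dict[str, float] | None = None,
    staff_ruled_false_positive: bool = False,
) -> RemoteTestEvent:
    """Apply the replacement/challenge workflow to one remote test.

    A failed delivery draws a replacement setting from
    ``replacement_policy`` (proportions over in_office/remote/none).  A
    challenged result that staff rule a false positive is replaced
    remotely and marked for exclusion from the reward streak.  A
    completed, unchallenged test passes through unchanged; asking for a
    replacement on one is an invalid transition.
    """
    if event.outcome == "delivery_failed":
        policy = replacement_policy or {"in_office": 0.5, "remote": 0.5}
        options = list(policy)
        probs = np.array([policy[o] for o in options], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("replacement policy must have positive mass")
        probs /= probs.sum()
        if rng is None:
            raise ValueError("rng required to draw a replacement")
        choice = options[int(rng.choice(len(options), p=probs))]
        return replace(event, replacement=choice)
    if event.challenged:
        if staff_ruled_false_positive:
            return replace(event, challenge_result="replaced", replacement="remote")
        return replace(event, challenge_result="upheld")
    if staff_ruled_false_positive:
        raise ValueError("cannot replace a completed, unchallenged test")
    return event


def streak_after_replacement(
    history: Sequence[str],
    replaced_index: int,
    schedule: RewardSchedule | None = None,
) -> list[int]:
    """Awards recomputed as if a replaced (false-positive) test never happened.

    Removing a positive test can only merge neighbouring runs of
    negatives, so the recomputed total never falls below the original.
    """
    edited = [s for i, s in enumerate(history) if i != replaced_index]
    if not edited:
        return []
    return award_tokens(edited, schedule)
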