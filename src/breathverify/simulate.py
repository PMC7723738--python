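"""Synthetic cohort, sensor, and study-ledger generator.

The real validation data behind a remote breath-CO monitoring study are
never deposited, so this module generates everything the analysis
pipeline consumes with the statistical structure that pipeline assumes:
daily smokers (6-20 cigarettes/day, most 6-10), first-order CO and
cotinine kinetics, an electrochemical sensor with a 1 ppm resolution,
±10% accuracy and a charging/pollution baseline offset, an 18-visit
in-office schedule (5 visits in week 1, 2 in weeks 2-3, then weekly),
and remote test notifications in an 8:30 AM-3 PM window that expire
after 5 hours.  Per-participant random intercepts induce the
within-participant correlation that the clustered statistics must
absorb.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .physiology import Event, PhysioParams, co_level, cotinine_level
from .rewards import schedule_notification
from .traces import BreathTrace, momba_co_estimate

__all__ = [
    "SimParticipant",
    "SensorParams",
    "SimConfig",
    "StudyData",
    "draw_cohort",
    "synthesize_trace",
    "simulate_study",
    "simulate_diagnostic_ledger",
]

#: Ledger column order (the CSV interchange schema).
LEDGER_COLUMNS = [
    "test_id",
    "participant_id",
    "timestamp",
    "setting",
    "momba_ppm",
    "pico_ppm",
    "cotinine_ng_ml",
    "cigs_24h",
    "last_cig_time",
    "pregnant_at_test",
    "notification_status",
    "verified_face",
    "verified_mouth",
    "audio_ok",
    "challenged",
]


@dataclass
class SimParticipant:
    """One simulated enrollee.

    ``quit_propensity`` is the long-run fraction of fully abstinent
    days; abstinence arrives in multi-day spells governed by
    ``quit_persistence`` (the day-to-day probability of remaining
    abstinent), so that slow-clearing cotinine can actually fall below
    its cutoff during a quit attempt.  ``co_intercept`` and
    ``cotinine_intercept`` are per-person random shifts (the cluster
    effects) applied to every measurement.
    """

    participant_id: str
    cigarettes_per_day: int
    quit_propensity: float = 0.2
    quit_persistence: float = 0.85
    pregnant_at_enrollment: bool = True
    delivery_offset_days: float | None = None
    co_intercept: float = 0.0
    cotinine_intercept: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.cigarettes_per_day <= 40:
            raise ValueError("cigarettes_per_day must be in [1, 40]")
        if not 0.0 <= self.quit_propensity <= 1.0:
            raise ValueError("quit_propensity must be a probability")


@dataclass(frozen=True)
class SensorParams:
    """Electrochemical CO sensor model.

    resolution : ppm quantization step (1 for the deployed sensor).
    relative_accuracy : half-width of the per-test multiplicative gain
        error, as a fraction (0.10 = readings accurate to within 10%).
    baseline_offset : distribution of the charging/pollution offset,
        one of ``("degenerate", v)``, ``("exponential", scale)`` or
        ``("uniform", lo, hi)``; drawn once per test.
    noise_sd : additive per-sample Gaussian noise, ppm.
    quantize : snap readings to ``resolution`` (sensor property).
    """

    resolution: float = 1.0
    relative_accuracy: float = 0.10
    baseline_offset: tuple = ("exponential", 1.0)
    noise_sd: float = 0.3
    sample_rate: float = 5.0
    duration: float = 20.0
    pre_exhalation_seconds: float = 2.0
    rise_seconds: float = 1.0
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.relative_accuracy < 0 or self.noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def noiseless(cls) -> "SensorParams":
        """Ideal sensor: no gain error, no noise, no offset, no quantization."""
        return cls(
            relative_accuracy=0.0,
            baseline_offset=("degenerate", 0.0),
            noise_sd=0.0,
            quantize=False,
        )

    def draw_offset(self, rng: np.random.Generator) -> float:
        kind = self.baseline_offset[0]
        if kind == "degenerate":
            return float(self.baseline_offset[1])
        if kind == "exponential":
            return float(rng.exponential(self.baseline_offset[1]))
        if kind == "uniform":
            return float(rng.uniform(self.baseline_offset[1], self.baseline_offset[2]))
        raise ValueError(f"unknown offset distribution {kind!r}")


@dataclass
class SimConfig:
    """Study-design parameters for :func:`simulate_study`."""

    n_participants: int = 10
    study_weeks: int = 12
    in_office_visit_pattern: Sequence[int] = field(
        default_factory=lambda: [5, 2, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1]
    )
    remote_notification_window: tuple[dt.time, dt.time] = (
        dt.time(8, 30),
        dt.time(15, 0),
    )
    notification_expiry_hours: float = 5.0
    office_visit_hour: float = 14.0
    remote_per_week: int = 1
    remote_completion_prob: float = 0.5
    delivery_failure_prob: float = 0.07
    recency_missing_prob: float = 0.056
    challenge_prob: float = 0.08
    start_date: dt.date = dt.date(2024, 1, 1)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.study_weeks <= 0:
            raise ValueError("study must run at least one week")
        if sum(self.in_office_visit_pattern) > 18:
            raise ValueError("in-office schedule exceeds 18 visits")
        if self.notification_expiry_hours <= 0:
            raise ValueError("notification expiry must be positive")
        for p in (
            self.remote_completion_prob,
            self.delivery_failure_prob,
            self.recency_missing_prob,
            self.challenge_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class StudyData:
    """A simulated study: the test ledger plus the raw device traces."""

    ledger: pd.DataFrame
    traces: list[BreathTrace]
    participants: list[SimParticipant]


def draw_cohort(
    n: int,
    rng: np.random.Generator,
    quit_propensity: float = 0.2,
    delivery_fraction: float = 0.4,
    study_days: int = 84,
    co_intercept_sd: float = 0.5,
    cotinine_intercept_sd: float = 20.0,
) -> list[SimParticipant]:
    """Draw ``n`` enrollees: daily smokers, mostly 6-10 cigarettes/day.

    90% of participants smoke 6-10 cigarettes/day and the rest 11-20,
    mirroring the intake distribution of a perinatal smoking cohort;
    ``delivery_fraction`` of them deliver at a uniform day mid-study.
    """
    cohort = []
    for i in range(n):
        heavy = rng.random() < 0.10
        cpd = int(rng.integers(11, 21)) if heavy else int(rng.integers(6, 11))
        delivers = rng.random() < delivery_fraction
        cohort.append(
            SimParticipant(
                participant_id=f"P{i + 1:02d}",
                cigarettes_per_day=cpd,
                quit_propensity=quit_propensity,
                delivery_offset_days=(
                    float(rng.uniform(study_days * 0.25, study_days * 0.75))
                    if delivers
                    else None
                ),
                co_intercept=float(rng.normal(0.0, co_intercept_sd)),
                cotinine_intercept=float(rng.normal(0.0, cotinine_intercept_sd)),
            )
        )
    return cohort


def synthesize_trace(
    true_co: float,
    s: SensorParams,
    rng: np.random.Generator,
    test_id: str = "T0",
    participant_id: str = "P0",
    timestamp: pd.Timestamp | None = None,
) -> BreathTrace:
    """Emit one raw sensor trace for a breath with alveolar CO ``true_co``.

    The trace sits at a baseline offset during the pre-exhalation
    segment, rises logistically over ``rise_seconds`` and plateaus near
    ``offset + gain * true_co``, where the gain is drawn uniformly in
    ``1 ± relative_accuracy`` once per test.  Per-sample Gaussian noise
    and optional quantization to the sensor resolution follow.
    """
    if true_co < 0:
        raise ValueError("true CO must be non-negative")
    n = round(s.sample_rate * s.duration)
    pre = round(s.sample_rate * s.pre_exhalation_seconds)
    t = np.arange(n) / s.sample_rate

    offset = s.draw_offset(rng)
    gain = 1.0 + s.relative_accuracy * rng.uniform(-1.0, 1.0)
    onset = pre / s.sample_rate
    # logistic rise rescaled to hit 0 at onset and exactly 1 at the end of
    # the rise window, so noiseless plateaus carry the plateau value exactly
    k = 10.0 / max(s.rise_seconds, 1e-6)
    z = np.clip((t - onset) / max(s.rise_seconds, 1e-6), 0.0, 1.0)
    sig = 1.0 / (1.0 + np.exp(-k * s.rise_seconds * (z - 0.5)))
    lo, hi = 1.0 / (1.0 + np.exp(5.0)), 1.0 / (1.0 + np.exp(-5.0))
    ramp = (sig - lo) / (hi - lo)
    signal = gain * true_co * ramp
    samples = offset + signal + rng.normal(0.0, s.noise_sd, size=n)
    samples = np.clip(samples, 0.0, None)
    if s.quantize:
        samples = np.round(samples / s.resolution) * s.resolution
    return BreathTrace(
        test_id=test_id,
        participant_id=participant_id,
        timestamp=timestamp if timestamp is not None else pd.Timestamp("2024-01-01"),
        samples=samples,
        sample_rate=s.sample_rate,
        duration=s.duration,
        pre_exhalation_count=pre,
        quantized=s.quantize,
    )


def _smoking_events(
    p: SimParticipant, n_days: int, rng: np.random.Generator
) -> list[Event]:
    """Daily event stream with spell-structured abstinence.

    Days alternate between smoking and abstinent states under a
    two-state Markov chain whose stationary abstinent fraction is
    ``quit_propensity`` and whose abstinent-to-abstinent transition is
    ``quit_persistence``.  On smoking days ``cigarettes_per_day``
    single cigarettes fall uniformly over 07:00-23:00.
    """
    pi, pers = p.quit_propensity, p.quit_persistence
    if pi >= 1.0:
        start_prob = 1.0
        relapse_to_quit = 1.0
    else:
        start_prob = pi
        relapse_to_quit = min(1.0, pi * (1.0 - pers) / (1.0 - pi))
    abstinent = rng.random() < start_prob
    events: list[Event] = []
    for day in range(n_days):
        if not abstinent:
            times = np.sort(rng.uniform(7.0, 23.0, size=p.cigarettes_per_day))
            events.extend((day * 24.0 + h, 1.0) for h in times)
        abstinent = rng.random() < (pers if abstinent else relapse_to_quit)
        if pi >= 1.0:
            abstinent = True
    return events


_VISIT_OFFSETS = {0: [], 1: [1], 2: [0, 3], 3: [0, 2, 4], 4: [0, 1, 3, 4], 5: [0, 1, 2, 3, 4]}


def simulate_study(
    cohort: list[SimParticipant] | int,
    config: SimConfig | None = None,
    physio: PhysioParams | None = None,
    sensor: SensorParams | None = None,
) -> StudyData:
    """Run one full synthetic study and return its ledger and traces.

    ``cohort`` may be a list of participants or an integer size (drawn
    via :func:`draw_cohort` from the study seed).  Every stochastic
    draw flows from ``config.rng_seed``: smoking histories, sensor
    noise, notification timing and outcomes, self-report missingness.
    """
    config = config or SimConfig()
    physio = physio or PhysioParams()
    sensor = sensor or SensorParams()
    rng = np.random.default_rng(config.rng_seed)
    n_days = config.study_weeks * 7
    if isinstance(cohort, int):
        cohort = draw_cohort(cohort, rng, study_days=n_days)

    start = pd.Timestamp(config.start_date)
    rows: list[dict] = []
    traces: list[BreathTrace] = []

    for part in cohort:
        events = _smoking_events(part, n_days, rng)
        seq = 0

        def take_test(t_hours: float, setting: str, status: str | None) -> None:
            nonlocal seq
            seq += 1
            test_id = f"{part.participant_id}-{seq:03d}"
            ts = start + pd.Timedelta(hours=t_hours)
            completed = status in (None, "completed")
            pregnant = part.delivery_offset_days is None or (
                t_hours / 24.0 < part.delivery_offset_days
            )
            row = {c: pd.NA for c in LEDGER_COLUMNS}
            row.update(
                test_id=test_id,
                participant_id=part.participant_id,
                timestamp=ts,
                setting=setting,
                pregnant_at_test=pregnant,
                notification_status=status if status else pd.NA,
            )
            if completed:
                true_co = max(0.0, co_level(events, t_hours, physio) + part.co_intercept)
                trace = synthesize_trace(
                    true_co, sensor, rng, test_id, part.participant_id, ts
                )
                traces.append(trace)
                row["momba_ppm"] = momba_co_estimate(trace).value
                past = [e for e in events if e[0] <= t_hours]
                row["cigs_24h"] = sum(1 for e in past if e[0] > t_hours - 24.0)
                if past and rng.random() >= config.recency_missing_prob:
                    row["last_cig_time"] = start + pd.Timedelta(hours=past[-1][0])
                if setting == "in_office":
                    # reference devices are only available at the office
                    pico = true_co + rng.normal(0.0, 0.75)
                    row["pico_ppm"] = float(max(0.0, np.round(pico)))
                    cot = cotinine_level(
                        events, t_hours, physio, pregnant, raw=True
                    )
                    cot = max(0.0, cot + part.cotinine_intercept)
                    row["cotinine_ng_ml"] = (
                        physio.lab_floor_estimate if cot < physio.lab_floor else cot
                    )
                    row.update(verified_face=True, verified_mouth=True, audio_ok=True,
                               challenged=False)
                else:
                    row["verified_face"] = True
                    row["verified_mouth"] = bool(rng.random() < 0.98)
                    row["audio_ok"] = bool(rng.random() < 0.98)
                    row["challenged"] = bool(rng.random() < config.challenge_prob)
            rows.append(row)

        # in-office visits, weekday cadence per the visit pattern
        pattern = list(config.in_office_visit_pattern)[: config.study_weeks]
        office_days = set()
        for week, k in enumerate(pattern):
            for off in _VISIT_OFFSETS.get(k, list(range(min(k, 5)))):
                day = week * 7 + off
                office_days.add(day)
                take_test(day * 24.0 + config.office_visit_hour, "in_office", None)

        # remote notifications on non-office days
        for week in range(config.study_weeks):
            candidates = [d for d in range(week * 7, week * 7 + 7) if d not in office_days]
            days = rng.choice(len(candidates), size=min(config.remote_per_week, len(candidates)), replace=False)
            for di in np.sort(days):
                day = candidates[int(di)]
                notif = schedule_notification(
                    start + pd.Timedelta(days=day),
                    config.remote_notification_window,
                    rng,
                )
                notif_hours = (notif - start).total_seconds() / 3600.0
                if rng.random() < config.delivery_failure_prob:
                    take_test(notif_hours, "remote", "delivery_failed")
                elif rng.random() < config.remote_completion_prob:
                    done = notif_hours + rng.uniform(0.0, config.notification_expiry_hours)
                    take_test(done, "remote", "completed")
                else:
                    take_test(notif_hours, "remote", "expired")

    ledger = pd.DataFrame(rows, columns=LEDGER_COLUMNS)
    ledger = ledger.sort_values(["participant_id", "timestamp"], kind="stable")
    ledger = ledger.reset_index(drop=True)
    return StudyData(ledger=ledger, traces=traces, participants=list(cohort))


def simulate_diagnostic_ledger(
    n_participants: int,
    tests_per_participant: int,
    sensitivity: float,
    specificity: float,
    rng: np.random.Generator,
    prevalence: float = 0.5,
    concentration: float = 50.0,
) -> pd.DataFrame:
    """Clustered binary index/reference pairs at known marginal accuracy.

    Per-participant sensitivity and specificity are Beta-distributed
    around the marginal values with the given concentration (larger =
    less between-cluster heterogeneity), which induces the
    within-participant correlation a clustered interval must absorb.
    Returns columns participant_id, index_status, reference_status
    (1 = smoking).
    """

    def draw_rate(mean: float) -> float:
        if mean <= 0.0 or mean >= 1.0:
            return mean
        return float(rng.beta(mean * concentration, (1.0 - mean) * concentration))

    rows = []
    for i in range(n_participants):
        sens_i, spec_i = draw_rate(sensitivity), draw_rate(specificity)
        ref = rng.random(tests_per_participant) < prevalence
        pos_rate = np.where(ref, sens_i, 1.0 - spec_i)
        idx = rng.random(tests_per_participant) < pos_rate
        for r, x in zip(ref, idx):
            rows.append(
                {
                    "participant_id": f"P{i + 1:02d}",
                    "index_status": int(x),
                    "reference_status": int(r),
                }
            )
    return pd.DataFrame(rows)
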