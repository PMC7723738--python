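"""Biochemical smoking-status cutoffs and recency dichotomization.

Smoking abstinence is read off breath CO at or below 6 ppm (boundary
included, for both the app's estimate and the piCO+ reference monitor)
and off urine cotinine strictly below 50 ng/mL.  Self-reported time of
last cigarette is dichotomized at 5 hours — roughly one to two breath-CO
half-lives, after which breath CO has largely cleared.  Cutoffs are
overridable: the literature recommends lower CO cutoffs (2-4 ppm)
during pregnancy, so nothing here hard-codes 6.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "StatusLabel",
    "classify_co",
    "classify_cotinine",
    "dichotomize_recency",
    "classify_ledger",
]

ABSTINENT, SMOKING = "abstinent", "smoking"
WITHIN, BEYOND, MISSING = "within", "beyond", "missing"

CO_CUTOFF_PPM = 6.0
COTININE_CUTOFF_NG_ML = 50.0
RECENCY_HOURS = 5.0


@dataclass(frozen=True)
class StatusLabel:
    """A smoking-status call with its provenance."""

    source: str  # momba | pico | cotinine
    status: str  # abstinent | smoking
    measured_value: float
    cutoff_used: float

    @property
    def is_abstinent(self) -> bool:
        return self.status == ABSTINENT


def classify_co(
    value: float, cutoff: float = CO_CUTOFF_PPM, source: str = "momba"
) -> StatusLabel:
    """Breath-CO call: abstinent iff value <= cutoff (boundary abstinent)."""
    if value < 0:
        raise ValueError("breath CO cannot be negative")
    status = ABSTINENT if value <= cutoff else SMOKING
    return StatusLabel(source=source, status=status, measured_value=value, cutoff_used=cutoff)


def classify_cotinine(value: float, cutoff: float = COTININE_CUTOFF_NG_ML) -> StatusLabel:
    """Cotinine call: abstinent iff value < cutoff (strict boundary)."""
    if value < 0:
        raise ValueError("cotinine concentration cannot be negative")
    status = ABSTINENT if value < cutoff else SMOKING
    return StatusLabel(
        source="cotinine", status=status, measured_value=value, cutoff_used=cutoff
    )


def dichotomize_recency(
    last_cig_time: pd.Timestamp | None,
    test_time: pd.Timestamp,
    threshold_hours: float = RECENCY_HOURS,
) -> str:
    """Recency of last cigarette relative to the breath test.

    ``within`` when the cigarette was at most ``threshold_hours`` before
    the test (the boundary counts as within), ``beyond`` when strictly
    more, ``missing`` when no time was reported.
    """
    if last_cig_time is None or pd.isna(last_cig_time):
        return MISSING
    last_cig_time = pd.Timestamp(last_cig_time)
    test_time = pd.Timestamp(test_time)
    if last_cig_time > test_time:
        raise ValueError("last cigarette cannot postdate the breath test")
    elapsed_h = (test_time - last_cig_time).total_seconds() / 3600.0
    return WITHIN if elapsed_h <= threshold_hours else BEYOND


def classify_ledger(
    ledger: pd.DataFrame,
    co_cutoff: float = CO_CUTOFF_PPM,
    cotinine_cutoff: float = COTININE_CUTOFF_NG_ML,
    recency_hours: float = RECENCY_HOURS,
) -> pd.DataFrame:
    """Append status_momba, status_pico, status_cotinine and recency columns.

    Rows with a missing measurement get a missing status for that
    source (non-completed remote tests have no CO value; cotinine is
    collected in office only).
    """
    out = ledger.copy()

    def cot_status(v):
        return pd.NA if pd.isna(v) else classify_cotinine(float(v), cotinine_cutoff).status

    out["status_momba"] = [
        pd.NA if pd.isna(v) else classify_co(float(v), co_cutoff).status
        for v in out["momba_ppm"]
    ]
    out["status_pico"] = [
        pd.NA if pd.isna(v) else classify_co(float(v), co_cutoff, source="pico").status
        for v in out["pico_ppm"]
    ]
    out["status_cotinine"] = [cot_status(v) for v in out["cotinine_ng_ml"]]
    out["recency"] = [
        # recency is defined only for tests that actually happened
        pd.NA
        if pd.isna(m)
        else dichotomize_recency(lc, ts, recency_hours)
        for m, lc, ts in zip(out["momba_ppm"], out["last_cig_time"], out["timestamp"])
    ]
    return out
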