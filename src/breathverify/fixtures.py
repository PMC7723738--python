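"""A deterministic ledger whose margins match the pilot-study tallies.

No raw data from the original deployment are available, so this module
constructs a minimal, schema-valid ledger that reproduces the published
marginal counts exactly: 10 participants contributing 143 in-office
tests (102 taken within 5 hours of the last cigarette, 33 beyond, 8
with the time unreported), 102 remote notifications of which 51 were
completed (47 smoking-positive, 4 challenged), 7 of the 51 missed
notifications undeliverable, and 45 of the 51 missed notifications
preceded by a smoking-positive test.  Values inside cells are
arbitrary but valid; only the margins are meaningful.
"""

from __future__ import annotations

import pandas as pd

from .simulate import LEDGER_COLUMNS

__all__ = ["build_pilot_fixture", "EXPECTED_SUMMARY"]

#: Printed-precision proportions the fixture is built to reproduce.
EXPECTED_SUMMARY = {
    "n_participants": 10,
    "n_in_office": 143,
    "recency_within_pct": 71.3,
    "recency_beyond_pct": 23.1,
    "recency_missing_pct": 5.6,
    "remote_completed_pct": 50.0,
    "remote_completed_smoking_pct": 92.0,
    "missed_preceded_by_positive_pct": 88.0,
    "delivery_failed_pct": 14.0,
    "challenged_pct": 8.0,
    "mean_tests_per_participant": 14.3,
}

_OFFICE_N = [17, 16, 16, 15, 15, 14, 14, 13, 13, 10]  # sums to 143
_REMOTE_COMPLETED = [6, 6, 5, 5, 5, 5, 5, 5, 5, 4]  # sums to 51
_REMOTE_MISSED = [5, 5, 6, 5, 5, 5, 5, 5, 5, 5]  # sums to 51

_POSITIVE_PPM = 15.0
_NEGATIVE_PPM = 3.0


def build_pilot_fixture() -> tuple[pd.DataFrame, dict]:
    """Construct the margin-matching ledger and its expected summary.

    Returns ``(ledger, expected)`` where ``expected`` maps
    :class:`~breathverify.validity.LedgerSummary` field names to the
    proportions the ledger must summarize to, at printed precision.
    """
    rows: list[dict] = []
    start = pd.Timestamp("2024-01-01 09:00")
    office_global = 0  # running index over all in-office tests

    for i in range(10):
        pid = f"P{i + 1:02d}"
        seq = 0
        day = 0

        def base_row(ts: pd.Timestamp, setting: str) -> dict:
            nonlocal seq
            seq += 1
            row = {c: pd.NA for c in LEDGER_COLUMNS}
            row.update(
                test_id=f"{pid}-{seq:03d}",
                participant_id=pid,
                timestamp=ts,
                setting=setting,
            )
            return row

        # ----- in-office tests, one per day -----------------------------
        n_office = _OFFICE_N[i]
        for j in range(n_office):
            ts = start + pd.Timedelta(days=day)
            day += 1
            row = base_row(ts, "in_office")
            # the last office test of P03/P04 anchors a missed remote
            # notification to a negative predecessor (see below)
            negative = i in (2, 3) and j == n_office - 1
            ppm = _NEGATIVE_PPM if negative else _POSITIVE_PPM
            row.update(
                momba_ppm=ppm,
                pico_ppm=ppm,
                cotinine_ng_ml=5.0 if negative else 300.0,
                cigs_24h=0 if negative else 10,
                pregnant_at_test=True,
                verified_face=True,
                verified_mouth=True,
                audio_ok=True,
                challenged=False,
            )
            # global recency assignment: 102 within, then 33 beyond, then 8 missing
            if office_global < 102:
                row["last_cig_time"] = ts - pd.Timedelta(hours=2)
            elif office_global < 135:
                row["last_cig_time"] = ts - pd.Timedelta(hours=8)
            office_global += 1
            rows.append(row)

        # ----- remote notifications -------------------------------------
        # Sequences are laid out so each missed notification's most recent
        # completed predecessor has a controlled smoking status: 45 of the
        # 51 missed follow a positive test, 6 follow a negative one.
        def completed_remote(positive: bool, challenged: bool = False) -> None:
            nonlocal day
            ts = start + pd.Timedelta(days=day, hours=2)
            day += 1
            row = base_row(ts, "remote")
            ppm = _POSITIVE_PPM if positive else _NEGATIVE_PPM
            row.update(
                momba_ppm=ppm,
                cigs_24h=10 if positive else 0,
                last_cig_time=ts - pd.Timedelta(hours=2) if positive else pd.NA,
                pregnant_at_test=True,
                notification_status="completed",
                verified_face=True,
                verified_mouth=True,
                audio_ok=True,
                challenged=challenged,
            )
            rows.append(row)

        def missed_remote(failed: bool = False) -> None:
            nonlocal day
            ts = start + pd.Timedelta(days=day, hours=1)
            day += 1
            row = base_row(ts, "remote")
            row.update(
                pregnant_at_test=True,
                notification_status="delivery_failed" if failed else "expired",
            )
            rows.append(row)

        n_completed, n_missed = _REMOTE_COMPLETED[i], _REMOTE_MISSED[i]
        # completed-remote negatives: tests 2 and 3 of P01 and P02 (4 total)
        negatives = {1, 2} if i in (0, 1) else set()
        # the 4 challenged results: first 4 completed remotes of P05
        challenged_set = {0, 1, 2, 3} if i == 4 else set()
        # 7 undeliverable notifications: all 5 missed of P06, first 2 of P07
        failed_set = set(range(5)) if i == 5 else ({0, 1} if i == 6 else set())

        lead_missed = 1 if i in (2, 3) else 0  # predecessor = negative office test
        for k in range(lead_missed):
            missed_remote(failed=k in failed_set)
        paired = min(n_completed, n_missed - lead_missed)
        miss_idx = lead_missed
        for k in range(n_completed):
            completed_remote(positive=k not in negatives, challenged=k in challenged_set)
            if k < paired and miss_idx < n_missed:
                missed_remote(failed=miss_idx in failed_set)
                miss_idx += 1
        while miss_idx < n_missed:  # trailing missed follow the last completed
            missed_remote(failed=miss_idx in failed_set)
            miss_idx += 1

    ledger = pd.DataFrame(rows, columns=LEDGER_COLUMNS)
    return ledger, dict(EXPECTED_SUMMARY)
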