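"""Ledger file interchange and run configuration.

The ledger CSV is the interchange format between every stage of the
pipeline: one row per breath test (in-office or remote notification),
comma-separated, UTF-8, header required, naive-local ISO-8601
timestamps.  Malformed rows are collected into a rejects report rather
than silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classify import CO_CUTOFF_PPM, COTININE_CUTOFF_NG_ML, RECENCY_HOURS
from .physiology import PhysioParams
from .rewards import RewardSchedule
from .simulate import LEDGER_COLUMNS, SensorParams, SimConfig

__all__ = ["read_ledger", "write_ledger", "RunConfig"]

log = logging.getLogger("breathverify")

_NUMERIC = ["momba_ppm", "pico_ppm", "cotinine_ng_ml", "cigs_24h"]
_BOOLEAN = ["pregnant_at_test", "verified_face", "verified_mouth", "audio_ok", "challenged"]


def read_ledger(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a ledger CSV into typed records plus a rejects report.

    Returns ``(ledger, rejects)``; ``rejects`` has columns
    ``row_number`` (1-based data rows), ``reason`` — rows with negative
    concentrations or a last-cigarette time after the test are
    rejected, never silently dropped.  Missing mandatory columns raise
    a schema error naming them.
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ledger missing mandatory columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["last_cig_time"] = pd.to_datetime(df["last_cig_time"])
    for c in _NUMERIC:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in _BOOLEAN:
        df[c] = df[c].map(
            {True: True, False: False, "True": True, "False": False}
        )

    reasons = {}

    def reject(mask: pd.Series, reason: str) -> None:
        for i in df.index[mask.fillna(False)]:
            reasons.setdefault(i, []).append(reason)

    for c in ("momba_ppm", "pico_ppm", "cotinine_ng_ml"):
        reject(df[c] < 0, f"negative {c}")
    reject(df["last_cig_time"] > df["timestamp"], "last_cig_time after test time")
    reject(~df["setting"].isin(["in_office", "remote"]), "unknown setting")

    bad = sorted(reasons)
    rejects = pd.DataFrame(
        {
            "row_number": [i + 1 for i in bad],
            "reason": ["; ".join(reasons[i]) for i in bad],
        }
    )
    ledger = df.drop(index=bad).reset_index(drop=True)
    log.info("read %d ledger rows (%d rejected) from %s", len(ledger), len(bad), path)
    return ledger, rejects


def write_ledger(ledger: pd.DataFrame, path: str | Path) -> None:
    """Write a ledger CSV in the documented column order (ISO timestamps)."""
    out = ledger.copy()
    extra = [c for c in out.columns if c not in LEDGER_COLUMNS]
    out = out[LEDGER_COLUMNS + extra]
    out.to_csv(Path(path), index=False)
    log.info("wrote %d ledger rows to %s", len(out), path)


def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Validated end-to-end configuration for the CLI pipeline.

    Every field has a working default; unknown keys in a config file
    are rejected with an error naming them.
    """

    co_cutoff_ppm: float = CO_CUTOFF_PPM
    cotinine_cutoff_ng_ml: float = COTININE_CUTOFF_NG_ML
    recency_hours: float = RECENCY_HOURS
    estimator_mode: str = "corrected"
    decimals: int = 1
    rng_seed: int = 0
    reward: RewardSchedule = field(default_factory=RewardSchedule)
    sim: SimConfig = field(default_factory=SimConfig)
    physio: PhysioParams = field(default_factory=PhysioParams)
    sensor: SensorParams = field(default_factory=SensorParams)

    def __post_init__(self) -> None:
        if self.estimator_mode not in ("corrected", "literal"):
            raise ValueError("estimator_mode must be 'corrected' or 'literal'")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        nested = {
            "reward": RewardSchedule,
            "sim": SimConfig,
            "physio": PhysioParams,
            "sensor": SensorParams,
        }
        kwargs = {}
        for key, sub in nested.items():
            if key in data:
                kwargs[key] = _from_mapping(sub, data.pop(key), key)
        scalar_names = {
            f.name for f in dataclasses.fields(cls) if f.name not in nested
        }
        unknown = set(data) - scalar_names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def config_hash(self) -> str:
        """Stable digest of the full configuration, for run logging."""
        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
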