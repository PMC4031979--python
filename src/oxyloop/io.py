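"""Episode-log and configuration I/O.

An episode is stored as three small text files sharing a stem:

* ``<stem>.samples.csv`` — one row per 1-Hz sensor tick, fixed column
  order ``t_s, spo2, hr, pi, siq, signal_present, fio2_set,
  fio2_proposed, decision_reason``; times are seconds from episode start,
  FiO2 as a fraction with 3 decimals, SpO2 as integer percent;
* ``<stem>.events.csv`` — suction / desaturation / sensor events with
  ``kind, start_s, end_s, magnitude``;
* ``<stem>.meta.json`` — patient parameters, policy, seed and the exact
  effective configuration (plus its hash), which together suffice to
  regenerate the record.

CSV is deliberate: logs are short (<= ~1e5 rows) and human-auditable,
matching their clinical provenance.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from .controller import (
    DEFAULT_MH,
    DEFAULT_SH,
    ControllerConfig,
    Profile,
    validate_profile_pair,
)
from .sensor import SensorParams

__all__ = [
    "SAMPLE_COLUMNS",
    "EVENT_COLUMNS",
    "EpisodeRecord",
    "LogFormatError",
    "write_log",
    "read_log",
    "AppConfig",
    "load_config",
    "config_hash",
]

SAMPLE_COLUMNS = [
    "t_s",
    "spo2",
    "hr",
    "pi",
    "siq",
    "signal_present",
    "fio2_set",
    "fio2_proposed",
    "decision_reason",
]
EVENT_COLUMNS = ["kind", "start_s", "end_s", "magnitude"]

_NUMERIC_SAMPLE_COLUMNS = ["t_s", "spo2", "hr", "pi", "siq", "fio2_set", "fio2_proposed"]


class LogFormatError(ValueError):
    """Malformed episode log (message names the offending line)."""


@dataclass
class EpisodeRecord:
    """One simulated or recorded episode: metadata + sample and event tables."""

    metadata: dict[str, Any]
    samples: pd.DataFrame
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS)
    )


def _format_samples(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("fio2_set", "fio2_proposed"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{float(v):.3f}")
    if "spo2" in out.columns:
        out["spo2"] = out["spo2"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    return out


def write_log(record: EpisodeRecord, directory: "str | Path", stem: str = "episode") -> Path:
    """Write an episode to ``directory`` as CSV/JSON; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = [c for c in SAMPLE_COLUMNS if c in record.samples.columns] + [
        c for c in record.samples.columns if c not in SAMPLE_COLUMNS
    ]
    _format_samples(record.samples[cols]).to_csv(directory / f"{stem}.samples.csv", index=False)
    record.events.reindex(columns=EVENT_COLUMNS).to_csv(
        directory / f"{stem}.events.csv", index=False
    )
    meta = dict(record.metadata)
    meta.setdefault("written_utc", datetime.now(timezone.utc).isoformat(timespec="seconds"))
    (directory / f"{stem}.meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return directory


def _parse_samples(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in raw.columns if c not in SAMPLE_COLUMNS]
    if unknown:
        warnings.warn(f"unknown columns preserved opaquely: {unknown}", stacklevel=3)
    if "t_s" not in raw.columns or "spo2" not in raw.columns:
        raise LogFormatError(f"{path.name}: required columns t_s and spo2 missing")
    df = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        if col in _NUMERIC_SAMPLE_COLUMNS:
            s = raw[col].replace("", None)
            num = pd.to_numeric(s, errors="coerce")
            bad = num.isna() & s.notna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
                raise LogFormatError(
                    f"{path.name}: line {line}: non-numeric value "
                    f"{raw[col].iloc[bad.idxmax()]!r} in column '{col}'"
                )
            df[col] = num
        elif col == "signal_present":
            df[col] = raw[col].map({"True": True, "False": False, "": True}).astype(bool)
        else:
            df[col] = raw[col]
    t = df["t_s"].to_numpy()
    if len(t) > 1 and (pd.isna(t).any() or (pd.Series(t).diff()[1:] <= 0).any()):
        raise LogFormatError(f"{path.name}: t_s must be present and strictly increasing")
    return df


def read_log(directory: "str | Path", stem: str = "episode") -> EpisodeRecord:
    """Read an episode written by :func:`write_log` (lossless round-trip)."""
    directory = Path(directory)
    samples = _parse_samples(directory / f"{stem}.samples.csv")
    events_path = directory / f"{stem}.events.csv"
    if events_path.exists():
        events = pd.read_csv(events_path)
        if events.empty:
            events = pd.DataFrame(columns=EVENT_COLUMNS)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    meta_path = directory / f"{stem}.meta.json"
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return EpisodeRecord(metadata=metadata, samples=samples, events=events)


def config_hash(model: BaseModel | dict) -> str:
    """Stable sha256 over a canonical JSON dump of a configuration."""
    payload = model.model_dump() if isinstance(model, BaseModel) else model
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class ProfileTable(BaseModel):
    """Config-file form of a deviation-to-step table."""

    edges: list[float]
    steps: list[float]

    def build(self, name: str) -> Profile:
        return Profile(name, tuple(self.edges), tuple(self.steps))


class AppConfig(BaseModel):
    """Top-level configuration: controller constants, sensor noise model,
    optional custom profile tables.  An empty file yields full defaults
    (target 92–96%, lockout 30 s, SIQ 0.30, rescue 85% -> 100%)."""

    model_config = {"frozen": True}

    controller: ControllerConfig = Field(default_factory=ControllerConfig)
    sensor: SensorParams = Field(default_factory=SensorParams)
    profiles: dict[str, ProfileTable] = Field(default_factory=dict)
    #: trial-plan overrides (cohort sizes, period length, disturbance rates);
    #: validated when the TrialPlan is built from them at run time
    plan: dict[str, Any] = Field(default_factory=dict)

    def profile(self, name: str) -> Profile:
        if name in self.profiles:
            return self.profiles[name].build(name)
        if name == "SH":
            return DEFAULT_SH
        if name == "MH":
            return DEFAULT_MH
        raise ValueError(f"unknown profile '{name}'")


def load_config(path: "str | Path | None" = None) -> AppConfig:
    """Load and validate a YAML configuration file.

    All invariants (target ordering, profile step monotonicity, SH-over-MH
    dominance per bin) are checked at load; violations raise ``ValueError``
    naming the field or bin.  ``None`` or an empty file yields defaults.
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: top level must be a mapping")
            data = loaded
    try:
        cfg = AppConfig(**data)
    except ValidationError as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    validate_profile_pair(cfg.profile("SH"), cfg.profile("MH"))
    return cfg
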