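"""Plain-text data dialects: trial tables (CSV) and EMG sweeps (CSV + JSON).

Trial tables are written with empty cells for inapplicable fields (SSD on
go trials, RT on omissions).  Each EMG sweep is a two-column CSV
(time_ms, emg_mv) with a JSON sidecar of recording metadata next to it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emg_csp import EMGTrace
from .errors import ValidationError
from .synthetic_data import TRIAL_COLUMNS

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "read_emg_sweep",
    "write_emg_sweep",
]

_VALID_TRIAL_TYPES = {"go", "stop"}
_VALID_PHASES = {"practice", "experimental"}
_VALID_RESPONSES = {"left", "right", "none"}


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table = table[TRIAL_COLUMNS]
    table.to_csv(path, index=False, float_format="%.6g")


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Raises
    ------
    ValidationError
        On a missing column, a malformed value, or a stop trial without an
        SSD; messages carry the 1-based data row number.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")

    def _num(value: str, row: int, col: str, required: bool) -> float:
        if value == "":
            if required:
                raise ValidationError(f"{path} row {row}: {col} is required but empty")
            return np.nan
        try:
            return float(value)
        except ValueError:
            raise ValidationError(f"{path} row {row}: non-numeric {col} {value!r}") from None

    records = []
    for i, rec in enumerate(raw.itertuples(index=False), start=1):
        d = dict(zip(raw.columns, rec))
        if d["trial_type"] not in _VALID_TRIAL_TYPES:
            raise ValidationError(f"{path} row {i}: bad trial_type {d['trial_type']!r}")
        if d["phase"] not in _VALID_PHASES:
            raise ValidationError(f"{path} row {i}: bad phase {d['phase']!r}")
        if d["response"] not in _VALID_RESPONSES:
            raise ValidationError(f"{path} row {i}: bad response {d['response']!r}")
        is_stop = d["trial_type"] == "stop"
        ssd = _num(d["ssd_ms"], i, "ssd_ms", required=is_stop)
        rt = _num(d["rt_ms"], i, "rt_ms", required=d["response"] != "none")
        if d["response"] != "none" and not rt > 0:
            raise ValidationError(f"{path} row {i}: rt_ms must be positive, got {rt}")
        records.append(
            {
                "participant_id": d["participant_id"],
                "block": int(_num(d["block"], i, "block", required=True)),
                "trial": int(_num(d["trial"], i, "trial", required=True)),
                "phase": d["phase"],
                "trial_type": d["trial_type"],
                "direction": d["direction"],
                "ssd_ms": ssd,
                "response": d["response"],
                "rt_ms": rt,
                "correct": int(_num(d["correct"], i, "correct", required=True)),
            }
        )
    return pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)


def write_emg_sweep(trace: EMGTrace, csv_path: str | Path) -> None:
    """Write one sweep as (time_ms, emg_mv) CSV plus a JSON sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame({"time_ms": trace.times_ms(), "emg_mv": trace.samples})
    df.to_csv(csv_path, index=False, float_format="%.6g")
    sidecar = {
        "fs_hz": trace.fs,
        "stim_time_ms": trace.stim_time,
        "participant_id": trace.metadata.get("participant_id"),
        "pulse_index": trace.metadata.get("pulse_index"),
        "stim_intensity_pct_rmt": trace.metadata.get("stim_intensity_pct_rmt", 120.0),
        "rmt_pct_mso": trace.metadata.get("rmt_pct_mso"),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_emg_sweep(csv_path: str | Path) -> EMGTrace:
    """Read a sweep CSV and its JSON sidecar back into an :class:`EMGTrace`."""
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValidationError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs_hz", "stim_time_ms"):
        if key not in meta:
            raise ValidationError(f"{sidecar_path}: missing {key}")
    df = pd.read_csv(csv_path)
    if "emg_mv" not in df.columns:
        raise ValidationError(f"{csv_path}: missing emg_mv column")
    extra = {k: v for k, v in meta.items() if k not in ("fs_hz", "stim_time_ms")}
    return EMGTrace(
        samples=df["emg_mv"].to_numpy(dtype=float),
        fs=float(meta["fs_hz"]),
        stim_time=float(meta["stim_time_ms"]),
        metadata=extra,
    )
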