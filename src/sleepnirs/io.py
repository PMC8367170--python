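"""CSV / YAML interchange for every pipeline stage.

All floats are written with 12 significant digits so that a write/read
round trip is lossless at the precision the analysis cares about.  The
readers validate schema and basic sanity (monotone time, positive
intensities, event windows) and report offending lines, so externally
recorded CSVs enter the pipeline through the same doors as synthetic
ones.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd
import yaml

from .conditioning import UniformSeries
from .errors import DataError, ValidationError
from .events import HypopneaEvent
from .simulate import RawOpticalData

FLOAT_FMT = "%.12g"

RAW_COLUMNS = ["time_s", "wavelength_nm", "distance_cm", "i_dc", "i_ac", "phase_rad"]
SPO2_COLUMNS = ["time_s", "spo2_pct"]
EVENT_COLUMNS = ["event_id", "type", "condition", "start_s", "end_s"]
TRUTH_COLUMNS = ["time_s", "sao2", "svo2", "sto2"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")


def write_raw_csv(raw: RawOpticalData, path) -> None:
    raw.to_long().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_raw_csv(path) -> RawOpticalData:
    df = pd.read_csv(path)
    _require_columns(df, RAW_COLUMNS, path)
    for col in ("i_dc", "i_ac"):
        bad = ~(df[col].to_numpy() > 0)
        if bad.any():
            line = int(np.argwhere(bad)[0][0]) + 2  # 1-based, after header
            raise DataError(f"{path}, line {line}: non-positive {col}")
    raw = RawOpticalData.from_long(df)
    if not np.all(np.diff(raw.time_s) > 0):
        raise DataError(f"{path}: time_s is not strictly increasing")
    return raw


def write_series_csv(series: UniformSeries, path, value_name: str = "value") -> None:
    pd.DataFrame({"time_s": series.time_s, value_name: series.values,
                  "gap": series.gap_mask.astype(int)}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_spo2_csv(path) -> UniformSeries:
    """Read a fingertip SpO2 trace, reconstructing the uniform clock.

    Missing rows (time steps absent from the file) and NaN values become
    gap-masked samples rather than errors.
    """
    df = pd.read_csv(path)
    _require_columns(df, SPO2_COLUMNS, path)
    t = df["time_s"].to_numpy(dtype=float)
    v = df["spo2_pct"].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError(f"{path}: need at least 2 samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        line = int(np.argwhere(steps <= 0)[0][0]) + 3
        raise DataError(f"{path}, line {line}: time_s not strictly increasing")
    dt = float(np.min(steps))
    ratio = steps / dt
    if np.any(np.abs(ratio - np.round(ratio)) > 1e-6):
        raise DataError(f"{path}: sample times are not on a uniform grid")
    n = int(round((t[-1] - t[0]) / dt)) + 1
    values = np.full(n, np.nan)
    idx = np.round((t - t[0]) / dt).astype(int)
    values[idx] = v
    gap = ~np.isfinite(values)
    values[gap] = 0.0
    return UniformSeries(start_time_s=float(t[0]), sampling_rate_hz=1.0 / dt,
                         values=values, gap_mask=gap)


def write_events_csv(events, path) -> None:
    pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "type": ["hypopnea"] * len(events),
            "condition": [e.condition for e in events],
            "start_s": [e.start_s for e in events],
            "end_s": [e.end_s for e in events],
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_events_csv(path) -> List[HypopneaEvent]:
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, path)
    events = []
    for i, row in df.iterrows():
        line = int(i) + 2
        if not row["end_s"] > row["start_s"]:
            raise DataError(f"{path}, line {line}: end_s <= start_s")
        try:
            events.append(
                HypopneaEvent(
                    event_id=str(row["event_id"]),
                    condition=str(row["condition"]),
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                )
            )
        except ValidationError as exc:
            raise DataError(f"{path}, line {line}: {exc}") from exc
    return events


def write_report_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def save_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
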