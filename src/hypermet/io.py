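"""Integral-table container and the CSV dialect shared by all stages.

The on-disk dialect is comma-separated with '.' decimals, ``#``-prefixed
``key = value`` metadata lines (time reference, acquisition scheme, units)
followed by a header row whose first column is ``time_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

TIME_REFERENCES = ("injection", "dissolution")


@dataclass
class SignalTimeSeries:
    """Per-resonance integral trajectories on a common time axis.

    ``times`` are seconds relative to ``time_reference`` (injection by
    default); ``signals`` has one column per resonance, aligned with
    ``times`` row-wise.  ``meta`` carries acquisition metadata that the CSV
    dialect round-trips (flip angle, TR, transfer time, ...).
    """

    times: np.ndarray
    signals: pd.DataFrame
    time_reference: str = "injection"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise SchemaError("times must be 1-D")
        if len(self.times) != len(self.signals):
            raise SchemaError("times and signals must have the same length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise SchemaError("times must be strictly increasing")
        if self.time_reference not in TIME_REFERENCES:
            raise SchemaError(f"time_reference must be one of {TIME_REFERENCES}")

    @property
    def columns(self) -> list[str]:
        return list(self.signals.columns)

    def column(self, name: str) -> np.ndarray:
        if name not in self.signals.columns:
            raise SchemaError(f"no column {name!r} in time series")
        return self.signals[name].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Table with ``time_s`` as the first column."""
        df = self.signals.copy()
        df.insert(0, "time_s", self.times)
        return df


def _format_meta_value(value) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_timeseries_csv(ts: SignalTimeSeries, path: str | Path) -> None:
    """Write the integral table in the package CSV dialect."""
    path = Path(path)
    lines = [f"# time_reference = {ts.time_reference}"]
    for key, value in ts.meta.items():
        lines.append(f"# {key} = {_format_meta_value(value)}")
    # %.17g preserves float64 exactly, so write -> read is lossless
    body = ts.to_frame().to_csv(index=False, lineterminator="\n", float_format="%.17g")
    path.write_text("\n".join(lines) + "\n" + body)


def _parse_meta_value(raw: str):
    try:
        as_float = float(raw)
    except ValueError:
        return raw
    if raw.lstrip("+-").isdigit():
        return int(raw)
    return as_float


def read_timeseries_csv(path: str | Path) -> SignalTimeSeries:
    """Read an integral table written by :func:`write_timeseries_csv`."""
    path = Path(path)
    meta: dict = {}
    for line in path.read_text().splitlines():
        if not line.startswith("#"):
            break
        if "=" in line:
            key, raw = line.lstrip("# ").split("=", 1)
            meta[key.strip()] = _parse_meta_value(raw.strip())
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: missing required 'time_s' column")
    if df.isna().any().any():
        raise SchemaError(f"{path}: table contains missing values")
    time_reference = meta.pop("time_reference", "injection")
    return SignalTimeSeries(
        times=df["time_s"].to_numpy(),
        signals=df.drop(columns="time_s"),
        time_reference=str(time_reference),
        meta=meta,
    )
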