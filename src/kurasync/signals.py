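"""Uniformly sampled scalar time series (single-channel EEG-like signals).

A :class:`Signal` stores amplitude samples in millivolts together with the
sampling rate; timestamps are implied by uniform sampling and are never
stored per sample.  CSV I/O uses two columns ``time_s,value_mv`` (the time
column is validated for uniformity on read) or a single value column plus an
explicit sample rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Signal", "read_signal_csv", "write_signal_csv"]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    samples :
        Amplitude values in mV.  At least two samples are required.
    sample_rate_hz :
        Sampling rate, strictly positive.
    start_time_s :
        Time of the first sample.  Phases of spectral analyses are
        referenced to the first sample regardless of this offset.
    """

    samples: np.ndarray
    sample_rate_hz: float
    start_time_s: float = 0.0
    _: dataclass = field(init=False, default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError(
                f"signal needs at least 2 samples in one channel, got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if not (self.sample_rate_hz > 0):
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate_hz", float(self.sample_rate_hz))
        object.__setattr__(self, "start_time_s", float(self.start_time_s))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.start_time_s + np.arange(len(self)) / self.sample_rate_hz


def read_signal_csv(path: str | Path, sample_rate_hz: float | None = None) -> Signal:
    """Read a signal from CSV.

    Two layouts are accepted: ``time_s,value_mv`` with a header, or a single
    ``value_mv`` column in which case ``sample_rate_hz`` must be given.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: cannot parse CSV: {exc}") from exc
    if "value_mv" not in df.columns:
        raise ValueError(f"{path}: expected a 'value_mv' column, found {list(df.columns)}")
    numeric = pd.to_numeric(df["value_mv"], errors="coerce")
    bad = df.index[numeric.isna()]
    if len(bad):
        raise ValueError(f"{path}: malformed/missing value_mv at data row {int(bad[0])}")
    values = numeric.to_numpy(dtype=float)
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        if np.any(np.isnan(t)):
            row = int(np.flatnonzero(np.isnan(t))[0])
            raise ValueError(f"{path}: malformed time_s at data row {row}")
        dt = np.diff(t)
        if len(dt) == 0 or np.any(dt <= 0):
            raise ValueError(f"{path}: time column must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
            raise ValueError(f"{path}: time column is not uniformly sampled")
        inferred = 1.0 / dt[0]
        if sample_rate_hz is not None and abs(inferred - sample_rate_hz) > 1e-6 * sample_rate_hz:
            raise ValueError(
                f"{path}: time column implies fs={inferred:g} Hz, got --fs {sample_rate_hz:g}"
            )
        return Signal(values, inferred, start_time_s=float(t[0]))
    if sample_rate_hz is None:
        raise ValueError(f"{path}: no time_s column; a sample rate is required")
    return Signal(values, sample_rate_hz)


def write_signal_csv(signal: Signal, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": signal.times, "value_mv": signal.samples})
    df.to_csv(path, index=False, float_format="%.12g")
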