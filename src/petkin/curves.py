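"""Sampled time-activity curves (arterial inputs, tissue TACs)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SampledCurve"]


@dataclass(frozen=True)
class SampledCurve:
    """A curve sampled at increasing time points.

    Times are in minutes, values in activity-concentration units (MBq/cc for
    measured data; model curves inherit whatever scale their inputs carry).
    Evaluation between samples is linear; outside the sampled range the curve
    is clamped to its end values (an AIF sampled from time zero therefore
    evaluates to zero before its first sample).
    """

    time_min: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size == 0:
            raise ValueError("time_min and values must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.time_min, self.values)

    @property
    def peak(self) -> float:
        return float(self.values.max())

    def integral(self) -> float:
        """Running-integral total, by the trapezoid rule (min * value units)."""
        return float(np.trapezoid(self.values, self.time_min))

    def scaled(self, factor: float) -> "SampledCurve":
        return SampledCurve(self.time_min, factor * self.values, self.label)

    def shifted(self, delay_min: float) -> "SampledCurve":
        """Shift the curve later by ``delay_min``, padding with the left value."""
        return SampledCurve(self.time_min + delay_min, self.values, self.label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.time_min, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "SampledCurve":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(), df["value"].to_numpy(), label)
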