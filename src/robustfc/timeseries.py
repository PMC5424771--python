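"""Uniformly sampled channel data — the substrate every estimator operates on."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries"]


@dataclass(frozen=True)
class TimeSeries:
    """A single uniformly sampled channel.

    Parameters
    ----------
    values : array_like
        Signal samples (arbitrary units). Must be finite and of length >= 2.
    fs : float
        Sampling rate in Hz, strictly positive.
    label : str, optional
        Channel identifier.
    """

    values: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if values.size < 2:
            raise ValueError("TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("TimeSeries values must be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        """New series with the same sampling rate but different samples."""
        return TimeSeries(values, self.fs, self.label if label is None else label)

    def centered(self) -> "TimeSeries":
        return self.with_values(self.values - self.values.mean())


def as_timeseries(x, fs: float, label: str = "") -> TimeSeries:
    """Coerce an array (or pass through a TimeSeries) to a TimeSeries."""
    if isinstance(x, TimeSeries):
        return x
    return TimeSeries(np.asarray(x, dtype=float), fs, label)
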