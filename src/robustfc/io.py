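"""Delimited-text I/O and all-to-all connectivity matrices."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .correlation import METHODS, PairCorrelation
from .timeseries import TimeSeries

__all__ = [
    "ConnectivityMatrix",
    "read_timeseries_table",
    "write_timeseries_table",
    "connectivity_all_pairs",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """All-to-all pairwise connectivity over a set of channels.

    ``r`` and ``pvalues`` are symmetric with unit diagonal / unit p on the
    diagonal; ``qvalues`` holds Benjamini-Hochberg adjusted p-values over
    the strictly upper triangle when requested.
    """

    labels: tuple
    r: np.ndarray
    pvalues: np.ndarray
    dof: np.ndarray
    method: str
    qvalues: np.ndarray | None = None

    def to_frames(self) -> dict[str, pd.DataFrame]:
        idx = list(self.labels)
        out = {
            "r": pd.DataFrame(self.r, index=idx, columns=idx),
            "pvalues": pd.DataFrame(self.pvalues, index=idx, columns=idx),
            "dof": pd.DataFrame(self.dof, index=idx, columns=idx),
        }
        if self.qvalues is not None:
            out["qvalues"] = pd.DataFrame(self.qvalues, index=idx, columns=idx)
        return out

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in self.to_frames().items():
            frame.to_csv(outdir / f"{name}.csv")


def read_timeseries_table(path, fs: float) -> list[TimeSeries]:
    """Read a delimited table (CSV or TSV, one header row, one column per
    channel) into labeled TimeSeries sharing a sampling rate.

    Non-numeric cells and ragged rows raise with the offending location.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed table ({exc})") from exc
    if frame.empty:
        raise ValueError(f"{path}: table has no data rows")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric cell at data row {row + 1}, column {col!r}: "
                f"{frame[col].iloc[row]!r}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing cell at data row {row + 1}, column {col!r}")
        frame[col] = numeric
    return [TimeSeries(frame[col].to_numpy(float), fs, str(col)) for col in frame.columns]


def write_timeseries_table(path, channels: list[TimeSeries]) -> None:
    """Write channels as a CSV with one header row of labels."""
    if len({len(c) for c in channels}) != 1:
        raise ValueError("channels must have equal length")
    frame = pd.DataFrame({c.label or f"ch{i}": c.values for i, c in enumerate(channels)})
    frame.to_csv(path, index=False)


def connectivity_all_pairs(
    channels: list[TimeSeries],
    method: str = "AR-W-COR",
    fdr_correct: bool = False,
    alpha: float = 0.05,
    **kwargs,
) -> ConnectivityMatrix:
    """Apply one estimator to every unordered channel pair.

    Diagonal r is set to 1.  With ``fdr_correct``, Benjamini-Hochberg
    adjusted p-values over the strictly-upper-triangle are included.
    """
    k = len(channels)
    if k < 2:
        raise ValueError("need at least 2 channels")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    labels = tuple(c.label or f"ch{i}" for i, c in enumerate(channels))
    r = np.eye(k)
    p = np.zeros((k, k))
    dof = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = PairCorrelation(channels[i], channels[j], method=method, **kwargs).fit()
            r[i, j] = r[j, i] = res.r
            p[i, j] = p[j, i] = res.pvalue
            dof[i, j] = dof[j, i] = res.dof
    q = None
    if fdr_correct:
        iu = np.triu_indices(k, 1)
        q = np.zeros((k, k))
        _, q_flat, _, _ = multipletests(p[iu], alpha=alpha, method="fdr_bh")
        q[iu] = q_flat
        q = q + q.T
    return ConnectivityMatrix(labels, r, p, dof, method, q)
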