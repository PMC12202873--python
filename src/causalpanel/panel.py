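"""Daily multivariate panel container and CSV I/O.

A :class:`TimeSeriesPanel` is the object every pipeline stage consumes and
produces: a gap-free daily date index, a ``(T, N)`` float matrix, and one
unique name per column.  Panels round-trip through plain CSV with an
ISO-8601 ``date`` column.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesPanel", "read_panel_csv", "write_panel_csv"]

_ONE_DAY = np.timedelta64(1, "D")


@dataclass
class TimeSeriesPanel:
    """A strictly daily, gap-free multivariate time series.

    Parameters
    ----------
    dates
        Strictly increasing daily timestamps of length ``T``.
    values
        ``(T, N)`` real matrix, no missing values.
    names
        ``N`` unique variable labels.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d (T, N) matrix")
        if len(self.dates) != self.values.shape[0]:
            raise ValueError("dates and values disagree on T")
        if self.values.shape[0] < 2:
            raise ValueError("panel needs T >= 2 rows")
        if not self.names:
            self.names = [f"x{i}" for i in range(self.values.shape[1])]
        self.names = [str(n) for n in self.names]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names and values disagree on N")
        if len(set(self.names)) != len(self.names):
            raise ValueError("variable names must be unique")
        if np.isnan(self.values).any():
            raise ValueError("panel contains missing values")
        deltas = np.diff(self.dates.values.astype("datetime64[D]"))
        if (deltas == np.timedelta64(0, "D")).any():
            bad = self.dates[1:][deltas == np.timedelta64(0, "D")][0]
            raise ValueError(f"duplicate timestamp {bad.date()}")
        if (deltas != _ONE_DAY).any():
            prev = self.dates[:-1][deltas != _ONE_DAY][0]
            missing = (prev + pd.Timedelta(days=1)).date()
            raise ValueError(f"calendar gap at {missing}")

    # -- basic geometry -------------------------------------------------
    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    # -- conversion -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.names)
        frame.insert(0, "date", self.dates.strftime("%Y-%m-%d"))
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TimeSeriesPanel":
        date_col = frame.columns[0]
        dates = pd.DatetimeIndex(pd.to_datetime(frame[date_col], format="ISO8601"))
        value_cols = [c for c in frame.columns if c != date_col]
        values = frame[value_cols].apply(pd.to_numeric, errors="raise").to_numpy(float)
        return cls(dates=dates, values=values, names=list(value_cols))

    def with_values(self, values: np.ndarray) -> "TimeSeriesPanel":
        """Same dates/names, new matrix (shape must match)."""
        return TimeSeriesPanel(dates=self.dates, values=values, names=list(self.names))


def read_panel_csv(path) -> TimeSeriesPanel:
    """Read a panel from CSV (first column ISO-8601 dates, rest numeric)."""
    frame = pd.read_csv(path)
    return TimeSeriesPanel.from_frame(frame)


def write_panel_csv(panel: TimeSeriesPanel, path) -> None:
    panel.to_frame().to_csv(path, index=False, float_format="%.12g")
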