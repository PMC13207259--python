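"""Calendar plumbing.

All window arithmetic inside the package runs on integer day offsets from a
fixed epoch; calendar dates appear only at I/O boundaries.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

#: Day 0 of the internal integer timeline.
EPOCH = _dt.date(2016, 1, 1)


def to_day(d: _dt.date | str) -> int:
    """Convert a calendar date (or ISO string) to an integer day offset."""
    if isinstance(d, str):
        d = _dt.date.fromisoformat(d)
    return (d - EPOCH).days


def from_day(day: int) -> _dt.date:
    """Convert an integer day offset back to a calendar date."""
    return EPOCH + _dt.timedelta(days=int(day))


def days_to_dates(days: pd.Series | np.ndarray) -> pd.Series:
    """Vectorised offset -> ISO date string conversion."""
    base = pd.Timestamp(EPOCH)
    return (base + pd.to_timedelta(np.asarray(days, dtype="int64"), unit="D")).strftime(
        "%Y-%m-%d"
    )


def dates_to_days(dates: pd.Series) -> pd.Series:
    """Vectorised ISO date -> integer offset conversion."""
    base = pd.Timestamp(EPOCH)
    return (pd.to_datetime(dates, format="%Y-%m-%d") - base).dt.days.astype("int64")
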