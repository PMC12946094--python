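"""Daily activity/glucose gradients and the personalised PA baseline.

A gradient is the finite difference of a windowed quantity between two
consecutive merged windows, divided by the window width — counts/min for
activity and mmol/L per min for glucose.  For example, glucose falling from
7.0 to 6.5 mmol/L across a 20 min window gives (6.5 − 7.0)/20 =
−0.025 mmol/L per min.  Gradients are computed per calendar day within the
daytime span (06:00–23:59); pairs spanning a gap, a day boundary, or the
night are skipped and counted.

"Non-standard" physical activity is personalised: a window whose activity
measure strictly exceeds the participant's own mean over all daytime windows
of the record.  Ties and everything below the mean are "standard" —
habitual activity assumed compensated by basal insulin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import time

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError

logger = logging.getLogger(__name__)

DAY_START = time(6, 0)
DAY_END = time(23, 59)

STANDARD = "standard"
NON_STANDARD = "non_standard"

#: quantity differenced as the glucose signal
GLUCOSE_BASES = ("level", "std")
#: quantity averaged into / compared against the PA baseline
BASELINE_BASES = ("activity_std", "activity_gradient")


@dataclass(frozen=True)
class PABaseline:
    """A participant's habitual-activity reference level.

    ``mean_value`` is the arithmetic mean of ``basis`` over all daytime
    windows (or gradient points) of the participant's full record.
    """

    participant_id: str
    basis: str
    mean_value: float
    n_windows: int

    def __post_init__(self):
        if self.basis not in BASELINE_BASES:
            raise ConfigurationError(f"baseline basis {self.basis!r} not in {BASELINE_BASES}")
        if self.n_windows < 1:
            raise ConfigurationError("baseline requires n_windows >= 1")


def daytime_mask(timestamps: pd.Series,
                 day_start: time = DAY_START, day_end: time = DAY_END) -> pd.Series:
    """True where the timestamp's time-of-day lies in [day_start, day_end]."""
    tod = pd.Series([t.time() for t in timestamps], index=timestamps.index)
    return (tod >= day_start) & (tod <= day_end)


def compute_gradients(merged: pd.DataFrame, basis: str = "level", *,
                      day_start: time = DAY_START, day_end: time = DAY_END) -> pd.DataFrame:
    """Difference consecutive daytime windows into per-minute gradients.

    ``basis`` selects the differenced glucose quantity: ``"level"`` (the BG
    concentration at the window end, default) or ``"std"`` (the in-window
    variability).  Activity is always differenced on ``activity_std``.  The
    gradient is attributed to the later window's ``window_end``.

    Returns ``timestamp, width_minutes, activity_gradient, glucose_gradient``
    plus the later window's ``activity_std`` (used downstream for PA
    categorisation at that instant).
    """
    if basis not in GLUCOSE_BASES:
        raise ConfigurationError(f"gradient basis {basis!r} not in {GLUCOSE_BASES}")
    glucose_col = "glucose_level" if basis == "level" else "glucose_std"
    if merged.empty:
        return pd.DataFrame(columns=["timestamp", "width_minutes", "activity_gradient",
                                     "glucose_gradient", "activity_std"])
    df = merged.sort_values("window_end").reset_index(drop=True)
    df = df.loc[daytime_mask(df["window_end"], day_start, day_end)].reset_index(drop=True)

    rows = []
    n_skipped = 0
    for day, group in df.groupby(df["window_end"].dt.normalize()):
        if len(group) < 2:
            logger.warning("compute_gradients: day %s has <2 windows, no points",
                           day.date())
            continue
        g = group.reset_index(drop=True)
        width = g["width_minutes"].to_numpy()
        dt_min = g["window_end"].diff().dt.total_seconds().to_numpy() / 60.0
        consecutive = dt_min == width  # exactly one window width apart
        n_skipped += int((~consecutive[1:]).sum())
        keep = np.flatnonzero(consecutive)
        if keep.size == 0:
            continue
        rows.append(pd.DataFrame({
            "timestamp": g["window_end"].to_numpy()[keep],
            "width_minutes": width[keep].astype(int),
            "activity_gradient": (g["activity_std"].to_numpy()[keep]
                                  - g["activity_std"].to_numpy()[keep - 1]) / width[keep],
            "glucose_gradient": (g[glucose_col].to_numpy()[keep]
                                 - g[glucose_col].to_numpy()[keep - 1]) / width[keep],
            "activity_std": g["activity_std"].to_numpy()[keep],
        }))
    if n_skipped:
        logger.info("compute_gradients: skipped %d non-consecutive pairs", n_skipped)
    columns = ["timestamp", "width_minutes", "activity_gradient",
               "glucose_gradient", "activity_std"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.concat(rows, ignore_index=True)[columns]


def compute_baseline(series: pd.DataFrame, basis: str = "activity_std", *,
                     participant_id: str = "", scope: str = "record",
                     day_start: time = DAY_START, day_end: time = DAY_END) -> PABaseline:
    """Mean habitual activity over the participant's daytime windows.

    ``series`` is a merged-window frame (basis ``"activity_std"``) or a
    gradient frame (basis ``"activity_gradient"``).  ``scope`` is
    ``"record"`` (the default: pool every daytime window of the record) —
    a per-day variant is intentionally not the default and can be obtained
    by slicing the input before calling.
    """
    if basis not in BASELINE_BASES:
        raise ConfigurationError(f"baseline basis {basis!r} not in {BASELINE_BASES}")
    if scope != "record":
        raise ConfigurationError(f"baseline scope {scope!r}; only 'record' is supported")
    ts_col = "window_end" if "window_end" in series.columns else "timestamp"
    if basis not in series.columns:
        raise AnalysisError(f"series lacks column {basis!r} required by the baseline basis")
    day = series.loc[daytime_mask(series[ts_col], day_start, day_end), basis].dropna()
    if day.empty:
        raise AnalysisError("no daytime windows available to compute a baseline")
    return PABaseline(participant_id=participant_id, basis=basis,
                      mean_value=float(day.mean()), n_windows=int(day.size))


def classify_pa(series: pd.DataFrame, baseline: PABaseline) -> pd.DataFrame:
    """Categorise each window as standard vs non-standard activity.

    Non-standard iff the basis value strictly exceeds the participant's
    mean; a value exactly at the mean is standard (conservative: fewer
    positives).  Returns ``timestamp, category``.
    """
    ts_col = "window_end" if "window_end" in series.columns else "timestamp"
    if baseline.basis not in series.columns:
        raise AnalysisError(f"series lacks column {baseline.basis!r} matching the baseline")
    values = series[baseline.basis]
    category = np.where(values > baseline.mean_value, NON_STANDARD, STANDARD)
    return pd.DataFrame({"timestamp": series[ts_col].to_numpy(),
                         "category": category})
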