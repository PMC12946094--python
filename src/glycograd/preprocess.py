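"""Raw-stream ingestion, epoch cleaning, std-resampling and timestamp merge.

Two free-living streams enter the pipeline: wrist actigraphy (activity
counts at 15 s epochs, each carrying an interval-status label) and CGM
glucose (mmol/L at 5 min intervals).  Both are reduced to a common grid of
20/40/60 min windows summarised by the in-window standard deviation, then
inner-joined on the window timestamp.  Windows are half-open ``(start, end]``
and labelled by their right edge: the window covering 10:00:15–10:20:00 is
reported at 10:20:00.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError

logger = logging.getLogger(__name__)

#: Interval-status vocabulary of the actigraphy export.
ACTIVE = "ACTIVE"
REST = "REST"
REST_S = "REST-S"
EXCLUDED = "EXCLUDED"

#: Resampling widths the analysis is defined for (minutes).
STANDARD_WIDTHS = (20, 40, 60)

#: Physiologically plausible CGM range (mmol/L, exclusive bounds).
GLUCOSE_MIN, GLUCOSE_MAX = 0.0, 30.0

ACTIGRAPHY_COLUMNS = ("timestamp", "activity_count", "interval_status")
CGM_COLUMNS = ("timestamp", "glucose_mmol_l")


@dataclass(frozen=True)
class PACategory:
    """PA category of one evaluable window (defined here to avoid cycles)."""

    timestamp: pd.Timestamp
    category: str  # "standard" | "non_standard"


def _read_csv(source, expected: tuple[str, ...], column_map: dict | None) -> pd.DataFrame:
    try:
        df = pd.read_csv(source)
    except pd.errors.EmptyDataError:
        logger.warning("empty input file: %s", source)
        return pd.DataFrame(columns=list(expected))
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s) {missing} in {source}; "
                         f"pass a column_map for vendor exports")
    return df[list(expected)]


def _parse_timestamps(df: pd.DataFrame, source) -> pd.DataFrame:
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = ts.isna() & df["timestamp"].notna() | df["timestamp"].isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise ParseError(f"malformed timestamp at line {line} of {source}")
    out = df.copy()
    out["timestamp"] = ts
    return out


def _order_and_dedup(df: pd.DataFrame, source) -> pd.DataFrame:
    df = df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    dup = df["timestamp"].duplicated()
    if dup.any():
        raise ParseError(
            f"duplicate timestamp {df.loc[dup.idxmax(), 'timestamp']} in {source}; "
            "ambiguous provenance is rejected rather than averaged")
    return df


def read_actigraphy(source, column_map: dict | None = None) -> pd.DataFrame:
    """Read an actigraphy CSV into ``timestamp, activity_count, interval_status``.

    Rows are re-sorted into timestamp order; duplicate timestamps are a hard
    error.  Unknown status strings are preserved verbatim for
    :func:`clean_epochs` to judge.
    """
    df = _read_csv(source, ACTIGRAPHY_COLUMNS, column_map)
    if df.empty:
        return df
    df = _parse_timestamps(df, source)
    counts = pd.to_numeric(df["activity_count"], errors="coerce")
    bad = counts.isna() | (counts < 0)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ParseError(f"invalid activity count at line {line} of {source} "
                         "(must be a non-negative number)")
    df["activity_count"] = counts.astype(float)
    df["interval_status"] = df["interval_status"].astype(str).str.strip()
    return _order_and_dedup(df, source)


def read_cgm(source, column_map: dict | None = None) -> pd.DataFrame:
    """Read a CGM CSV into ``timestamp, glucose_mmol_l`` (mmol/L)."""
    df = _read_csv(source, CGM_COLUMNS, column_map)
    if df.empty:
        return df
    df = _parse_timestamps(df, source)
    glucose = pd.to_numeric(df["glucose_mmol_l"], errors="coerce")
    if glucose.isna().any():
        line = int(df.index[glucose.isna()][0]) + 2
        raise ParseError(f"malformed glucose value at line {line} of {source}")
    out_of_range = (glucose <= GLUCOSE_MIN) | (glucose >= GLUCOSE_MAX)
    if out_of_range.any():
        line = int(df.index[out_of_range][0]) + 2
        value = float(glucose[out_of_range].iloc[0])
        hint = (" — magnitudes above 30 suggest mg/dL; divide by 18.016 to convert"
                if value >= GLUCOSE_MAX else "")
        raise ParseError(f"glucose {value} out of range ({GLUCOSE_MIN}, {GLUCOSE_MAX}) "
                         f"mmol/L at line {line} of {source}{hint}")
    df["glucose_mmol_l"] = glucose.astype(float)
    return _order_and_dedup(df, source)


def clean_epochs(epochs: pd.DataFrame) -> pd.DataFrame:
    """Apply the status-consolidation rule to a parsed actigraphy stream.

    Records whose label contains ``REST-S`` (sleep) or ``EXCLUDED`` are
    dropped; among survivors, labels containing ``ACTIVE`` are normalised to
    ``ACTIVE`` and everything else to ``REST``.  Cleaning is total and
    idempotent; drop counts are logged.
    """
    if epochs.empty:
        return epochs.copy()
    status = epochs["interval_status"].astype(str)
    drop = status.str.contains(REST_S, regex=False) | status.str.contains(EXCLUDED, regex=False)
    kept = epochs.loc[~drop].copy()
    logger.info("clean_epochs: dropped %d of %d records (%d REST-S)",
                int(drop.sum()), len(epochs),
                int(status.str.contains(REST_S, regex=False).sum()))
    kept["interval_status"] = np.where(
        kept["interval_status"].astype(str).str.contains(ACTIVE, regex=False), ACTIVE, REST)
    return kept.reset_index(drop=True)


def _check_width(width_minutes: int, allow_nonstandard: bool) -> None:
    if width_minutes in STANDARD_WIDTHS:
        return
    if allow_nonstandard and width_minutes > 0:
        return
    raise ConfigurationError(
        f"width_minutes={width_minutes} not in {STANDARD_WIDTHS}; "
        "pass allow_nonstandard_width=True to override")


def _detect_grid_breaks(timestamps: pd.Series, expected_seconds: float) -> None:
    gaps = timestamps.diff().dt.total_seconds().dropna()
    irregular = gaps[(gaps > expected_seconds) & (gaps % expected_seconds != 0)]
    if not irregular.empty:
        logger.warning("%d off-grid gaps detected (possible DST transition or clock jump)",
                       len(irregular))


def resample_activity(epochs: pd.DataFrame, width_minutes: int, *,
                      ddof: int = 1, allow_nonstandard_width: bool = False) -> pd.DataFrame:
    """Aggregate cleaned epochs into windows summarised by activity std.

    Returns one row per non-empty window: ``window_end, width_minutes,
    activity_std, status, n_activity``.  ``activity_std`` uses the sample
    (n−1) standard deviation by default (``ddof=0`` switches to population
    for sensitivity analysis); a single-sample window therefore has a null
    std and is discarded later by :func:`merge_streams`.  Window status is
    ``ACTIVE`` if any in-window epoch is ``ACTIVE``, else ``REST``.
    """
    _check_width(width_minutes, allow_nonstandard_width)
    _detect_grid_breaks(epochs["timestamp"], 15)
    grouped = (epochs.set_index("timestamp")
               .resample(f"{width_minutes}min", closed="right", label="right"))
    out = grouped.agg(
        activity_std=("activity_count", lambda v: v.std(ddof=ddof)),
        n_activity=("activity_count", "size"),
        status=("interval_status", lambda s: ACTIVE if (s == ACTIVE).any() else REST),
    )
    out = out[out["n_activity"] > 0].reset_index(names="window_end")
    out.insert(1, "width_minutes", width_minutes)
    return out


def resample_glucose(cgm: pd.DataFrame, width_minutes: int, *,
                     ddof: int = 1, allow_nonstandard_width: bool = False) -> pd.DataFrame:
    """Aggregate CGM readings into windows of glucose std plus level.

    Alongside the in-window variability (``glucose_std``) the last in-window
    reading is retained as ``glucose_level`` so that gradients can be taken
    on concentration (the default basis) as well as on variability.
    """
    _check_width(width_minutes, allow_nonstandard_width)
    _detect_grid_breaks(cgm["timestamp"], 300)
    grouped = (cgm.set_index("timestamp")
               .resample(f"{width_minutes}min", closed="right", label="right"))
    out = grouped.agg(
        glucose_std=("glucose_mmol_l", lambda v: v.std(ddof=ddof)),
        glucose_level=("glucose_mmol_l", "last"),
        n_glucose=("glucose_mmol_l", "size"),
    )
    out = out[out["n_glucose"] > 0].reset_index(names="window_end")
    out.insert(1, "width_minutes", width_minutes)
    return out


def merge_streams(pa_windows: pd.DataFrame, bg_windows: pd.DataFrame) -> pd.DataFrame:
    """Inner-join resampled activity and glucose windows on ``window_end``.

    Any window present on only one side, or holding a null summary on either
    side, is excluded; the number of dropped rows is logged.
    """
    if pa_windows.empty or bg_windows.empty:
        return pd.DataFrame(columns=["window_end", "width_minutes", "activity_std",
                                     "glucose_std", "glucose_level", "status",
                                     "n_activity", "n_glucose"])
    wa = int(pa_windows["width_minutes"].iloc[0])
    wb = int(bg_windows["width_minutes"].iloc[0])
    if wa != wb:
        raise ConfigurationError(f"width_minutes mismatch: activity {wa} vs glucose {wb}")
    merged = pd.merge(
        pa_windows, bg_windows.drop(columns=["width_minutes"]),
        on="window_end", how="inner")
    n_candidates = len(merged)
    merged = merged.dropna(subset=["activity_std", "glucose_std", "glucose_level"])
    n_union = len(set(pa_windows["window_end"]) | set(bg_windows["window_end"]))
    logger.info("merge_streams: kept %d of %d candidate windows (%d dropped incl. "
                "one-sided)", len(merged), n_candidates, n_union - len(merged))
    cols = ["window_end", "width_minutes", "activity_std", "glucose_std",
            "glucose_level", "status", "n_activity", "n_glucose"]
    return merged[cols].sort_values("window_end").reset_index(drop=True)
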