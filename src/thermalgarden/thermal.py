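"""Summer thermal-regime characterization: climatology, MHW/MHS, T23.

Builds a day-of-year percentile climatology from a multi-year daily
temperature series (pooling ±window days across baseline years and
smoothing, the construction of Hobday et al.'s marine-heatwave
definition), segments exceedances of the interannual 90th-percentile
threshold (iT90) into marine heatwaves (runs of ≥ 5 days) and marine
heat spikes (shorter runs), assigns severity categories from the peak
anomaly in folds of the threshold width, and summarises the June–August
window per year including the T23 extreme-heat-day count (daily mean
≥ 23 °C, an ecological threshold for *Paramuricea clavata*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("Low", "Moderate", "Strong", "Severe", "Extreme")


def validate_series(series: pd.DataFrame) -> pd.DataFrame:
    """Check a daily temperature series; returns a date-sorted copy.

    Requires strictly increasing dates and temperatures within the
    −2…35 °C sanity range for shallow Mediterranean records; gaps are
    allowed (event segmentation breaks at them) but reported.
    """
    if not {"date", "temp_c"} <= set(series.columns):
        raise ValueError("series needs 'date' and 'temp_c' columns")
    out = series.copy()
    out["date"] = pd.to_datetime(out["date"])
    out = out.sort_values("date").reset_index(drop=True)
    if out["date"].duplicated().any():
        raise ValueError("duplicate dates in temperature series")
    t = out["temp_c"].to_numpy(float)
    if ((t < -2) | (t > 35)).any():
        raise ValueError("temperatures outside the -2..35 degC sanity range")
    return out


def _doy366(dates: pd.Series) -> np.ndarray:
    """Day-of-year on a fixed 366-day calendar (Mar 1 is always 61)."""
    doy = dates.dt.dayofyear.to_numpy().copy()
    leap = dates.dt.is_leap_year.to_numpy()
    doy[~leap & (doy >= 60)] += 1
    return doy


def _circular_smooth(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    half = width // 2
    padded = np.concatenate([values[-half:], values, values[:half]])
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    return np.convolve(padded, kernel, mode="valid")


@dataclass
class Climatology:
    """Day-of-year climatological mean and iT90 threshold."""

    table: pd.DataFrame           # doy (1..366), clim_mean, it90
    baseline_years: tuple[int, int]
    window_halfwidth: int
    smooth_width: int

    def lookup(self, dates: pd.Series) -> pd.DataFrame:
        doy = _doy366(pd.Series(pd.to_datetime(dates)))
        idx = self.table.set_index("doy")
        return idx.loc[doy].reset_index(drop=True)


def build_climatology(series: pd.DataFrame, window_halfwidth: int = 5,
                      smooth_width: int = 31,
                      baseline: tuple[int, int] | None = None) -> Climatology:
    """Day-of-year mean and 90th-percentile (iT90) climatology.

    For every day-of-year, pools observations within ±``window_halfwidth``
    days across the baseline years, takes the mean and the 90th
    percentile of the pool, then smooths both curves with a circular
    moving average of ``smooth_width`` days.  Feb 29 is filled by
    interpolation where no leap-year data fall in its pool.
    """
    series = validate_series(series)
    years = series["date"].dt.year
    if baseline is None:
        baseline = (int(years.min()), int(years.max()))
    sel = (years >= baseline[0]) & (years <= baseline[1])
    sub = series[sel]
    if sub["date"].dt.year.nunique() < 1:
        raise ValueError("baseline selects no data")
    doy = _doy366(sub["date"])
    temp = sub["temp_c"].to_numpy(float)

    mean = np.full(366, np.nan)
    q90 = np.full(366, np.nan)
    for d in range(1, 367):
        lo, hi = d - window_halfwidth, d + window_halfwidth
        window = (np.arange(lo, hi + 1) - 1) % 366 + 1
        pool = temp[np.isin(doy, window)]
        if pool.size:
            mean[d - 1] = pool.mean()
            q90[d - 1] = np.percentile(pool, 90)
    gaps = np.flatnonzero(np.isnan(mean)) + 1
    # Feb 29 (doy 60) may be empty in short non-leap baselines: interpolate
    if gaps.size:
        interp_ok = set(gaps) <= {60}
        if not interp_ok:
            raise ValueError(f"no data for day-of-year pools: {gaps.tolist()}")
        for arr in (mean, q90):
            arr[59] = 0.5 * (arr[58] + arr[60])
    mean = _circular_smooth(mean, smooth_width)
    q90 = _circular_smooth(q90, smooth_width)
    q90 = np.maximum(q90, mean)  # percentile can cross the mean only by noise
    table = pd.DataFrame({"doy": np.arange(1, 367), "clim_mean": mean,
                          "it90": q90})
    return Climatology(table, baseline, window_halfwidth, smooth_width)


@dataclass
class ThermalEvent:
    type: str                     # "MHW" or "MHS"
    start: pd.Timestamp
    end: pd.Timestamp
    duration: int
    max_anomaly: float            # degC above climatological mean at peak
    peak_fold: float              # anomaly in units of (iT90 - clim_mean)
    category: str


def _category(fold: float) -> str:
    if fold < 1:
        return "Low"
    if fold < 2:
        return "Moderate"
    if fold < 3:
        return "Strong"
    if fold < 4:
        return "Severe"
    return "Extreme"


def detect_thermal_events(series: pd.DataFrame, clim: Climatology,
                          min_mhw_duration: int = 5,
                          join_gap: int = 0) -> list[ThermalEvent]:
    """Segment threshold exceedances into MHW / MHS events.

    Maximal runs of consecutive days with temperature strictly above the
    iT90 threshold: runs of ≥ ``min_mhw_duration`` days are marine
    heatwaves, shorter runs marine heat spikes.  The category follows
    the peak fold (temp − clim_mean)/(iT90 − clim_mean).  Runs break at
    calendar gaps; ``join_gap`` > 0 merges events separated by at most
    that many below-threshold days (off by default so short spikes stay
    distinct events).
    """
    series = validate_series(series)
    look = clim.lookup(series["date"])
    temp = series["temp_c"].to_numpy(float)
    above = temp > look["it90"].to_numpy() + 1e-9  # guards smoothing round-off
    dates = series["date"]
    day_gap = dates.diff().dt.days.fillna(1).to_numpy()

    runs: list[tuple[int, int]] = []
    start = None
    for i in range(len(series)):
        if above[i]:
            if start is None:
                start = i
            elif day_gap[i] > 1:  # calendar gap breaks the run
                runs.append((start, i - 1))
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(series) - 1))

    if join_gap > 0 and runs:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            gap_days = (dates.iloc[s] - dates.iloc[pe]).days - 1
            if 0 < gap_days <= join_gap:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged

    events = []
    for s, e in runs:
        width = (look["it90"] - look["clim_mean"]).to_numpy()[s:e + 1]
        anom = temp[s:e + 1] - look["clim_mean"].to_numpy()[s:e + 1]
        if (width <= 0).any():
            raise ValueError(
                "iT90 equals the climatological mean inside an exceedance "
                "run; anomaly fold is undefined (degenerate climatology)")
        folds = anom / width
        peak = int(np.argmax(folds))
        duration = int((dates.iloc[e] - dates.iloc[s]).days + 1)
        events.append(ThermalEvent(
            type="MHW" if duration >= min_mhw_duration else "MHS",
            start=dates.iloc[s], end=dates.iloc[e], duration=duration,
            max_anomaly=float(anom[peak]), peak_fold=float(folds[peak]),
            category=_category(float(folds[peak])),
        ))
    return events


def events_to_frame(events: list[ThermalEvent]) -> pd.DataFrame:
    cols = ["type", "start", "end", "duration", "max_anomaly", "peak_fold",
            "category"]
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([{c: getattr(ev, c) for c in cols} for ev in events])


def summer_statistics(series: pd.DataFrame, events: list[ThermalEvent] | None = None,
                      months: tuple[int, ...] = (6, 7, 8),
                      t_threshold: float = 23.0) -> pd.DataFrame:
    """Per-year summary of the summer (June–August) window.

    Mean ± SD and maximum of the daily means, the T23 count of extreme
    heat days (daily mean ≥ ``t_threshold`` °C), and MHW / MHS counts
    (events starting inside the window).
    """
    series = validate_series(series)
    summer = series[series["date"].dt.month.isin(months)]
    if summer.empty:
        raise ValueError("no data inside the summer window")
    events = events or []
    rows = []
    for year, g in summer.groupby(summer["date"].dt.year):
        expected = pd.date_range(f"{year}-{min(months):02d}-01",
                                 f"{year}-{max(months):02d}-28").size
        t = g["temp_c"].to_numpy(float)
        in_window = [ev for ev in events
                     if ev.start.year == year and ev.start.month in months]
        rows.append({
            "year": int(year),
            "n_days": len(g),
            "missing_days": bool(len(g) < expected),
            "mean_c": t.mean(),
            "sd_c": t.std(ddof=1) if len(t) > 1 else 0.0,
            "max_c": t.max(),
            "t23_days": int((t >= t_threshold).sum()),
            "n_mhw": sum(ev.type == "MHW" for ev in in_window),
            "n_mhs": sum(ev.type == "MHS" for ev in in_window),
        })
    return pd.DataFrame(rows)
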