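"""Discharge baseflow separation and nutrient-sample preparation.

Monitoring samples taken during storm events are dominated by surface
runoff and are unrepresentative of the baseflow conditions under which
periphyton accrues, so daily discharge is split into baseflow and
stormflow with a recursive digital filter (Lyne–Hollick single-parameter
form) and samples taken on days where stormflow makes up ≥25% of the
day's discharge are discarded.  Surviving samples are restricted to the
local growth season (May–October in the temperate/polar Northern
Hemisphere, November–April in the Southern, year-round in the tropics)
and reduced to a per-site median with its supporting observation count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.925
DEFAULT_PASSES = 3
DEFAULT_STORM_THRESHOLD = 0.25
TROPIC_LATITUDE = 23.5


@dataclass(frozen=True)
class MedianRecord:
    site_id: str
    analyte: str
    median_conc: float
    n_obs: int


def _validate_series(series: pd.DataFrame) -> None:
    if series.empty:
        raise ValueError("discharge series is empty")
    dates = pd.to_datetime(series["date"])
    if not dates.is_monotonic_increasing or dates.duplicated().any():
        raise ValueError("discharge dates must be strictly increasing")
    if (series["flow"] < 0).any():
        raise ValueError("discharge flows must be non-negative")


def _lh_pass(flow: np.ndarray, alpha: float) -> np.ndarray:
    # Baseflow form of the Lyne–Hollick recursion, clamped so that
    # 0 <= baseflow <= flow at every step; first value taken as the flow.
    b = np.empty_like(flow)
    b[0] = flow[0]
    c = (1.0 - alpha) / 2.0
    for t in range(1, flow.size):
        bt = alpha * b[t - 1] + c * (flow[t] + flow[t - 1])
        b[t] = min(bt, flow[t])
    return b


def separate_baseflow(
    series: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    passes: int = DEFAULT_PASSES,
) -> pd.DataFrame:
    """Split a daily discharge series into baseflow and stormflow.

    Applies *passes* sweeps of the single-parameter recursive filter,
    alternating direction (forward/backward/forward for the default 3).
    Returns a copy of *series* with ``baseflow`` and ``stormflow`` columns.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if passes < 1 or passes % 2 == 0:
        raise ValueError(f"passes must be odd and >= 1, got {passes}")
    _validate_series(series)

    b = series["flow"].to_numpy(dtype=float)
    for p in range(passes):
        if p % 2 == 0:
            b = _lh_pass(b, alpha)
        else:
            b = _lh_pass(b[::-1], alpha)[::-1]
    # each pass only lowers the series, so the final b is <= flow everywhere
    out = series.copy()
    out["baseflow"] = b
    out["stormflow"] = out["flow"].to_numpy(dtype=float) - b
    return out


def filter_stormflow_samples(
    samples: pd.DataFrame,
    discharge: pd.DataFrame,
    threshold: float = DEFAULT_STORM_THRESHOLD,
) -> pd.DataFrame:
    """Drop samples taken on days where stormflow ≥ *threshold* of discharge.

    *discharge* must carry a ``baseflow`` column (see
    :func:`separate_baseflow`).  Samples whose date is absent from the
    discharge record cannot be attributed to base or storm flow; they are
    dropped with a logged count.  Zero-flow days carry no stormflow and
    are retained.
    """
    if "baseflow" not in discharge.columns:
        raise ValueError("discharge must have a 'baseflow' column")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")

    flow_by_date = discharge.set_index(pd.to_datetime(discharge["date"]))
    sample_dates = pd.to_datetime(samples["date"])
    known = sample_dates.isin(flow_by_date.index)
    n_missing = int((~known).sum())
    if n_missing:
        log.warning(
            "%d sample(s) on dates absent from the discharge record; dropped",
            n_missing,
        )
    kept = samples.loc[known.to_numpy()].copy()
    if kept.empty:
        return kept
    dates = pd.to_datetime(kept["date"])
    flow = flow_by_date.loc[dates, "flow"].to_numpy(dtype=float)
    base = flow_by_date.loc[dates, "baseflow"].to_numpy(dtype=float)
    storm = flow - base
    retain = (flow == 0) | (storm < threshold * flow)
    return kept.loc[retain].copy()


def growth_season_months(
    latitude: float, tropic_latitude: float = TROPIC_LATITUDE
) -> set[int]:
    """Months of likely peak periphyton growth at *latitude*."""
    if abs(latitude) > 90:
        raise ValueError(f"latitude out of range: {latitude}")
    if abs(latitude) < tropic_latitude:
        return set(range(1, 13))
    if latitude > 0:
        return {5, 6, 7, 8, 9, 10}
    return {11, 12, 1, 2, 3, 4}


def site_median(
    samples: pd.DataFrame,
    latitude: float,
    tropic_latitude: float = TROPIC_LATITUDE,
) -> MedianRecord | None:
    """Growth-season median concentration for one site and analyte.

    *samples* must already be stormflow-filtered and belong to a single
    (site, analyte) pair.  Returns ``None`` when no sample falls in the
    growth season (the site is then excluded downstream).  Even counts use
    the mean-of-middle-two convention.
    """
    if samples.empty:
        return None
    sites = samples["site_id"].unique()
    analytes = samples["analyte"].unique()
    if len(sites) != 1 or len(analytes) != 1:
        raise ValueError("site_median expects a single site and analyte")
    months = growth_season_months(latitude, tropic_latitude)
    in_season = pd.to_datetime(samples["date"]).dt.month.isin(months)
    conc = samples.loc[in_season.to_numpy(), "concentration"]
    if conc.empty:
        return None
    return MedianRecord(
        site_id=str(sites[0]),
        analyte=str(analytes[0]),
        median_conc=float(conc.median()),
        n_obs=int(conc.size),
    )


def site_medians(
    samples: pd.DataFrame,
    latitude_by_site: pd.Series | dict,
    tropic_latitude: float = TROPIC_LATITUDE,
) -> pd.DataFrame:
    """Growth-season medians for every (site, analyte) pair in *samples*."""
    records = []
    for (site, analyte), grp in samples.groupby(["site_id", "analyte"], sort=True):
        rec = site_median(grp, float(latitude_by_site[site]), tropic_latitude)
        if rec is not None:
            records.append(rec)
    return pd.DataFrame(
        [r.__dict__ for r in records],
        columns=["site_id", "analyte", "median_conc", "n_obs"],
    )
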