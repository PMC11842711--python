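"""Periphyton (benthic algae) biomass potential and catchment typing.

Maximum benthic chlorophyll-a follows the published regression

    log10(max chl) = 0.349·log10(TN) + 0.256·log10(TP) + 0.722

with TN and TP in µg/L and chlorophyll in mg chl-a/m².  At the total
nitrogen and phosphorus thresholds of 0.800 and 0.046 mg/L this evaluates
to ≈145 mg chl-a/m², the conventional boundary (~150) between acceptable
and undesirable biomass.

Catchments are typed 1–6 by crossing nutrient limitation — the TN:TP mass
ratio banded at <7 (N-limited), 7–15 (co-limited), ≥15 (P-limited) — with
whether the limiting nutrient exceeds its biomass threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CHL_COEF_TN = 0.349
CHL_COEF_TP = 0.256
CHL_INTERCEPT = 0.722


@dataclass(frozen=True)
class Thresholds:
    """Nutrient thresholds (mg/L) and N:P mass-ratio bands."""

    tn_threshold: float = 0.800
    tp_threshold: float = 0.046
    np_low: float = 7.0
    np_high: float = 15.0
    chl_boundary: float = 150.0  # mg chl-a/m², informational

    def __post_init__(self):
        if self.np_low >= self.np_high:
            raise ValueError("np_low must be < np_high")
        if min(self.tn_threshold, self.tp_threshold) <= 0:
            raise ValueError("thresholds must be positive")


CLASS_LABELS = {
    1: "N-limited acceptable",
    2: "N-limited undesirable",
    3: "co-limited acceptable",
    4: "co-limited undesirable",
    5: "P-limited acceptable",
    6: "P-limited undesirable",
}


def max_chlorophyll(tn_ugl, tp_ugl):
    """Maximum benthic chlorophyll-a (mg chl-a/m²) from TN and TP in µg/L."""
    tn = np.asarray(tn_ugl, dtype=float)
    tp = np.asarray(tp_ugl, dtype=float)
    if np.any(tn <= 0) or np.any(tp <= 0):
        raise ValueError("concentrations must be positive")
    out = 10.0 ** (
        CHL_COEF_TN * np.log10(tn) + CHL_COEF_TP * np.log10(tp) + CHL_INTERCEPT
    )
    return float(out) if out.ndim == 0 else out


def classify(tn_mgl, tp_mgl, thresholds: Thresholds = Thresholds()):
    """Catchment type 1–6 from TN and TP medians (mg/L).

    r = TN/TP (mass ratio):
      r < 7        → type 1 if TN < tn_threshold else 2
      7 ≤ r < 15   → type 3 if TN < tn_threshold or TP < tp_threshold else 4
      r ≥ 15       → type 5 if TP < tp_threshold else 6

    Type 4 uses TP ≥ tp_threshold (not the strictly-greater variant) so
    that the six rules partition the whole positive quadrant.
    """
    scalar = np.ndim(tn_mgl) == 0 and np.ndim(tp_mgl) == 0
    tn, tp = np.broadcast_arrays(
        np.atleast_1d(np.asarray(tn_mgl, dtype=float)),
        np.atleast_1d(np.asarray(tp_mgl, dtype=float)),
    )
    if np.any(tn <= 0) or np.any(tp <= 0):
        raise ValueError("concentrations must be positive")
    th = thresholds
    r = tn / tp
    n_ok = tn < th.tn_threshold
    p_ok = tp < th.tp_threshold

    out = np.empty(tn.shape, dtype=int)
    n_lim = r < th.np_low
    p_lim = r >= th.np_high
    co = ~n_lim & ~p_lim
    out[n_lim] = np.where(n_ok[n_lim], 1, 2)
    out[co] = np.where(n_ok[co] | p_ok[co], 3, 4)
    out[p_lim] = np.where(p_ok[p_lim], 5, 6)
    if scalar:
        return int(out[0])
    return out


def class_table(
    catchments: pd.DataFrame,
    tn_mgl,
    tp_mgl,
    scenario: str,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-catchment class assignments for one scenario."""
    cls = classify(tn_mgl, tp_mgl, thresholds)
    return pd.DataFrame(
        {
            "id": catchments["id"].to_numpy(),
            "scenario": scenario,
            "tn": np.asarray(tn_mgl, dtype=float),
            "tp": np.asarray(tp_mgl, dtype=float),
            "catchment_type": cls,
            "label": [CLASS_LABELS[c] for c in np.atleast_1d(cls)],
        }
    )


def aggregate(
    catchments: pd.DataFrame,
    classes: pd.DataFrame,
    scenario: str | None = None,
) -> pd.DataFrame:
    """Share of land area and population in each catchment type.

    Reported per continent plus a World row, excluding catchments flagged
    ``excluded``.  Within each (group, scenario) the six class shares sum
    to 100% for both weightings.
    """
    merged = classes.merge(
        catchments[["id", "continent", "area", "population", "excluded"]],
        on="id",
        how="left",
    )
    merged = merged.loc[~merged["excluded"].astype(bool)]
    if scenario is not None:
        merged = merged.loc[merged["scenario"] == scenario]
    if merged.empty:
        raise ValueError("no catchments to aggregate")

    world = merged.copy()
    world["continent"] = "World"
    both = pd.concat([merged, world], ignore_index=True)

    rows = []
    for (cont, scen), grp in both.groupby(["continent", "scenario"], sort=True):
        tot_area = grp["area"].sum()
        tot_pop = grp["population"].sum()
        for ctype in range(1, 7):
            sub = grp.loc[grp["catchment_type"] == ctype]
            rows.append(
                {
                    "continent": cont,
                    "scenario": scen,
                    "catchment_type": ctype,
                    "label": CLASS_LABELS[ctype],
                    "area_pct": 100.0 * sub["area"].sum() / tot_area,
                    "population_pct": (
                        100.0 * sub["population"].sum() / tot_pop
                        if tot_pop > 0 else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)
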