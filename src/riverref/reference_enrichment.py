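"""Reference-condition predictions, enrichment, and validation.

Reference (pre-disturbance) concentrations are predicted by the same
fitted model after resetting each catchment's anthropogenic inputs to
near-pristine constants: Olsen P of 2 mg/kg (unfertilised soil),
population density of 0.001 persons/km², and no crop, pasture, or urban
land, with the displaced share split equally between forest and
rangeland.  Enrichment is the percent excess of the current over the
reference concentration, relative to reference.  Predicted reference
surfaces are validated against catchments under minimally disturbed
conditions (MDC), and results are summarised as area-weighted means by
biome, continent, or the world.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REFERENCE_OLSEN_P = 2.0      # mg/kg
REFERENCE_POP_DENSITY = 0.001  # persons/km^2

MDC_OLSEN_MAX = 5.0          # mg/kg (a stricter 2.0 variant is configurable)
MDC_POP_MAX = 0.001          # persons/km^2
MDC_NATURAL_MIN = 80.0       # % forest + rangeland
MDC_LOW_CONFIDENCE_N = 5     # <= this many sites: flag the biome


def reference_inputs(catchments: pd.DataFrame) -> pd.DataFrame:
    """Counterfactual pristine version of each catchment.

    Anthropogenic fields are replaced by the reference constants; the
    displaced crop+pasture+urban percentage is reallocated half to forest
    and half to rangeland.  Lentic share and all biophysical fields
    (latitude, biome, slope, runoff, pet, area) are untouched.
    """
    out = catchments.copy()
    displaced = out["crop_pct"] + out["pasture_pct"] + out["urban_pct"]
    out["forest_pct"] = out["forest_pct"] + displaced / 2.0
    out["rangeland_pct"] = out["rangeland_pct"] + displaced / 2.0
    out["crop_pct"] = 0.0
    out["pasture_pct"] = 0.0
    out["urban_pct"] = 0.0
    out["olsen_p"] = REFERENCE_OLSEN_P
    out["pop_density"] = REFERENCE_POP_DENSITY
    return out


def enrichment(current, reference):
    """Percent enrichment: 100·(current − reference)/reference."""
    current = np.asarray(current, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference concentration must be positive")
    out = 100.0 * (current - reference) / reference
    return float(out) if out.ndim == 0 else out


def enrichment_ci(
    current_ci: tuple[float, float],
    reference_ci: tuple[float, float],
    reference_median: float,
) -> tuple[float, float]:
    """Asymmetric enrichment interval.

    Because enrichment is a ratio, the bounds are taken as the current
    lower bound minus the reference upper bound (lower), and the current
    upper bound minus the reference lower bound (upper), both relative to
    the reference median.  The pair is ordered but is not guaranteed to
    bracket the point enrichment.
    """
    cur_lo, cur_hi = current_ci
    ref_lo, ref_hi = reference_ci
    if cur_lo > cur_hi or ref_lo > ref_hi:
        raise ValueError("confidence intervals must be ordered")
    if reference_median <= 0:
        raise ValueError("reference median must be positive")
    lower = 100.0 * (cur_lo - ref_hi) / reference_median
    upper = 100.0 * (cur_hi - ref_lo) / reference_median
    return lower, upper


def is_mdc(
    catchments: pd.DataFrame,
    olsen_max: float = MDC_OLSEN_MAX,
    pop_max: float = MDC_POP_MAX,
    natural_min: float = MDC_NATURAL_MIN,
) -> pd.Series:
    """Minimally-disturbed-condition flag (boundaries inclusive).

    True where Olsen P ≤ *olsen_max*, population density ≤ *pop_max*,
    forest + rangeland ≥ *natural_min* %, and there is no cropland or
    urban land.
    """
    return (
        (catchments["olsen_p"] <= olsen_max)
        & (catchments["pop_density"] <= pop_max)
        & (catchments["forest_pct"] + catchments["rangeland_pct"] >= natural_min)
        & (catchments["crop_pct"] == 0)
        & (catchments["urban_pct"] == 0)
    ).rename("is_mdc")


@dataclass(frozen=True)
class EnrichmentResult:
    catchment_id: str
    analyte: str
    current: float
    current_lower: float
    current_upper: float
    reference: float
    reference_lower: float
    reference_upper: float
    enrichment_pct: float
    enrichment_lower: float
    enrichment_upper: float
    reference_within_current_ci: bool


def enrichment_table(
    catchment_ids: pd.Series,
    analyte: str,
    current_ci: pd.DataFrame,
    reference_ci: pd.DataFrame,
) -> pd.DataFrame:
    """Combine per-catchment current and reference intervals (mg/L scale)
    into an enrichment table with the asymmetric CI rule applied row-wise."""
    cur = current_ci.reset_index(drop=True)
    ref = reference_ci.reset_index(drop=True)
    ids = catchment_ids.reset_index(drop=True)
    pct = enrichment(cur["point"], ref["point"])
    lower = 100.0 * (cur["lower"] - ref["upper"]) / ref["point"]
    upper = 100.0 * (cur["upper"] - ref["lower"]) / ref["point"]
    within = (ref["point"] >= cur["lower"]) & (ref["point"] <= cur["upper"])
    return pd.DataFrame(
        {
            "id": ids,
            "analyte": analyte,
            "current": cur["point"],
            "current_lower": cur["lower"],
            "current_upper": cur["upper"],
            "reference": ref["point"],
            "reference_lower": ref["lower"],
            "reference_upper": ref["upper"],
            "enrichment_pct": pct,
            "enrichment_lower": lower,
            "enrichment_upper": upper,
            "reference_within_current_ci": within,
        }
    )


def mdc_validation(
    reference_predictions: pd.DataFrame,
    catchments: pd.DataFrame,
    observed_medians: pd.DataFrame,
    olsen_max: float = MDC_OLSEN_MAX,
    pop_max: float = MDC_POP_MAX,
    natural_min: float = MDC_NATURAL_MIN,
) -> pd.DataFrame:
    """Check predicted reference conditions against MDC observations.

    *reference_predictions* holds per-catchment reference concentrations
    and intervals on the mg/L scale (columns ``id, point, lower, upper``);
    *observed_medians* holds observed site medians (``site_id,
    median_conc``).  Per biome the report gives the MDC site count, the
    mean observed MDC median, the biome-mean predicted reference with its
    aggregated 95% interval, whether the observation falls inside it, and
    a low-confidence flag for biomes with ≤ 5 MDC sites.
    """
    flags = is_mdc(catchments, olsen_max, pop_max, natural_min)
    mdc = catchments.loc[flags.to_numpy()]
    if mdc.empty:
        log.warning("no catchments satisfy the MDC definition")
        return pd.DataFrame(
            columns=[
                "biome", "n_mdc", "observed_mean", "reference_mean",
                "reference_lower", "reference_upper", "within_ci",
                "low_confidence",
            ]
        )
    preds = reference_predictions.merge(
        catchments[["id", "biome"]], on="id", how="left"
    )
    biome_ref = preds.groupby("biome").agg(
        reference_mean=("point", "mean"),
        reference_lower=("lower", "mean"),
        reference_upper=("upper", "mean"),
    )
    obs = mdc[["id", "biome"]].merge(
        observed_medians.rename(columns={"site_id": "id"}), on="id", how="inner"
    )
    rows = []
    for biome, grp in obs.groupby("biome"):
        if biome not in biome_ref.index:
            continue
        ref = biome_ref.loc[biome]
        observed_mean = float(grp["median_conc"].mean())
        rows.append(
            {
                "biome": biome,
                "n_mdc": int(grp["id"].nunique()),
                "observed_mean": observed_mean,
                "reference_mean": float(ref["reference_mean"]),
                "reference_lower": float(ref["reference_lower"]),
                "reference_upper": float(ref["reference_upper"]),
                "within_ci": bool(
                    ref["reference_lower"] <= observed_mean <= ref["reference_upper"]
                ),
                "low_confidence": bool(
                    grp["id"].nunique() <= MDC_LOW_CONFIDENCE_N
                ),
            }
        )
    return pd.DataFrame(rows)


def summarise(
    enrichments: pd.DataFrame,
    catchments: pd.DataFrame,
    group_by: str = "continent",
) -> pd.DataFrame:
    """Area-weighted enrichment summary by biome, continent, or world.

    Catchments flagged ``excluded`` (desert/xeric, taiga, polar,
    permafrost-origin) are dropped before aggregation.  CI bounds are
    aggregated with the same area weights; the fraction of catchments
    whose reference value falls inside the current-condition interval is
    reported alongside.
    """
    if group_by not in ("biome", "continent", "world"):
        raise ValueError(f"group_by must be biome|continent|world, got {group_by!r}")
    meta_cols = ["id", "area", "biome", "continent", "excluded"]
    merged = enrichments.merge(catchments[meta_cols], on="id", how="left")
    merged = merged.loc[~merged["excluded"].astype(bool)]
    if merged.empty:
        log.warning("all catchments excluded; empty summary")
        return pd.DataFrame(
            columns=[
                "group", "analyte", "n", "enrichment_pct",
                "enrichment_lower", "enrichment_upper",
                "frac_reference_within_current_ci",
            ]
        )
    merged = merged.copy()
    merged["group"] = "World" if group_by == "world" else merged[group_by]

    rows = []
    for (group, analyte), grp in merged.groupby(["group", "analyte"], sort=True):
        w = grp["area"].to_numpy(dtype=float)
        rows.append(
            {
                "group": group,
                "analyte": analyte,
                "n": len(grp),
                "enrichment_pct": float(np.average(grp["enrichment_pct"], weights=w)),
                "enrichment_lower": float(
                    np.average(grp["enrichment_lower"], weights=w)
                ),
                "enrichment_upper": float(
                    np.average(grp["enrichment_upper"], weights=w)
                ),
                "frac_reference_within_current_ci": float(
                    np.average(
                        grp["reference_within_current_ci"].astype(float), weights=w
                    )
                ),
            }
        )
    return pd.DataFrame(rows)
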