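"""Synthetic catchment, discharge, and nutrient-sample generator.

Emulates the structural features of global river monitoring data that the
downstream stages depend on — right-skewed Olsen P and population-density
distributions, compositional land-class shares, a monotone link from
anthropogenic pressure to concentration, baseflow/stormflow structure in
daily discharge, and seasonal log-normal concentration noise — while
recording the ground truth (biome reference surface and true site medians)
so every stage has an oracle.

The concentration model is

    C = reference_level(biome) * exp(slope * H + eps),   eps ~ N(0, sd)

where H is the human-effect composite computed from the catchment's own
anthropogenic inputs with the published weights for the analyte.  The
true (noise-free) median is therefore reference_level * exp(slope * H).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .analytes import ANALYTES, check_analyte
from . import human_effect as he

#: biomes carrying enough monitoring data to estimate a reference surface
DATA_RICH_BIOMES = (
    "Temperate Broadleaf & Mixed Forests",
    "Tropical & Subtropical Moist Broadleaf Forests",
    "Temperate Grasslands, Savannas & Shrublands",
    "Tropical & Subtropical Grasslands, Savannas & Shrublands",
    "Mediterranean Forests, Woodlands & Scrub",
    "Montane Grasslands & Shrublands",
)

#: sparse-data biomes kept only to exercise the exclusion logic
EXCLUDED_BIOMES = (
    "Deserts & Xeric Shrublands",
    "Boreal Forests/Taiga",
)

CONTINENTS = (
    "Africa", "Asia", "Europe", "North America", "Oceania", "South America",
)

# plausible latitude bands (absolute degrees) per biome
_LAT_BANDS = {
    "Temperate Broadleaf & Mixed Forests": (30.0, 55.0),
    "Tropical & Subtropical Moist Broadleaf Forests": (0.0, 23.0),
    "Temperate Grasslands, Savannas & Shrublands": (30.0, 55.0),
    "Tropical & Subtropical Grasslands, Savannas & Shrublands": (0.0, 23.0),
    "Mediterranean Forests, Woodlands & Scrub": (30.0, 45.0),
    "Montane Grasslands & Shrublands": (5.0, 45.0),
    "Deserts & Xeric Shrublands": (15.0, 40.0),
    "Boreal Forests/Taiga": (50.0, 68.0),
}

#: baseline (pristine) concentrations in mg/L per biome and analyte,
#: graded from oligotrophic montane systems to naturally richer grasslands
DEFAULT_REFERENCE_LEVELS: dict[str, dict[str, float]] = {
    "Temperate Broadleaf & Mixed Forests":
        {"DRP": 0.006, "TP": 0.020, "NO3N": 0.10, "TN": 0.25},
    "Tropical & Subtropical Moist Broadleaf Forests":
        {"DRP": 0.008, "TP": 0.030, "NO3N": 0.08, "TN": 0.30},
    "Temperate Grasslands, Savannas & Shrublands":
        {"DRP": 0.012, "TP": 0.045, "NO3N": 0.15, "TN": 0.45},
    "Tropical & Subtropical Grasslands, Savannas & Shrublands":
        {"DRP": 0.015, "TP": 0.050, "NO3N": 0.12, "TN": 0.50},
    "Mediterranean Forests, Woodlands & Scrub":
        {"DRP": 0.010, "TP": 0.035, "NO3N": 0.12, "TN": 0.40},
    "Montane Grasslands & Shrublands":
        {"DRP": 0.004, "TP": 0.015, "NO3N": 0.05, "TN": 0.15},
    "Deserts & Xeric Shrublands":
        {"DRP": 0.020, "TP": 0.060, "NO3N": 0.20, "TN": 0.60},
    "Boreal Forests/Taiga":
        {"DRP": 0.005, "TP": 0.018, "NO3N": 0.06, "TN": 0.20},
}


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of the synthetic world.

    ``human_effect_slope`` scales how strongly the human-effect composite
    lifts concentrations above the biome reference level; the default is
    chosen so that typical developed-land catchments sit a few tens of
    percent above reference, the magnitude seen in real enrichment
    estimates.  ``noise_sd_log`` is the log-scale sampling noise.
    """

    reference_level_by_biome: Mapping[str, Mapping[str, float] | float] = field(
        default_factory=lambda: DEFAULT_REFERENCE_LEVELS
    )
    human_effect_slope: float = 0.08
    noise_sd_log: float = 0.1
    baseflow_index: float = 0.7
    storm_frequency: float = 12.0  # events/year
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.baseflow_index < 1:
            raise ValueError("baseflow_index must be in (0, 1)")
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be >= 0")
        if self.storm_frequency < 0:
            raise ValueError("storm_frequency must be >= 0")
        for biome, level in self.reference_level_by_biome.items():
            vals = level.values() if isinstance(level, Mapping) else [level]
            if any(v <= 0 for v in vals):
                raise ValueError(f"non-positive reference level for {biome!r}")

    def reference_level(self, biome: str, analyte: str) -> float:
        level = self.reference_level_by_biome[biome]
        if isinstance(level, Mapping):
            return float(level[analyte])
        return float(level)


def _rng(truth: TruthParams, *key: int) -> np.random.Generator:
    return np.random.default_rng([truth.seed & 0x7FFFFFFF, *key])


def generate_catchments(
    n: int,
    truth: TruthParams,
    mdc_fraction: float = 0.1,
    biomes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Generate *n* catchment records.

    A ``mdc_fraction`` share of catchments is drawn in a minimally
    disturbed state (no crop/urban/pasture land, Olsen P ≤ 5 mg/kg,
    population density ≤ 0.001 persons/km²) so that reference-condition
    validation has observations to lean on; the rest get log-normal Olsen
    P and population density and Dirichlet land-class shares.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= mdc_fraction <= 1:
        raise ValueError("mdc_fraction must be in [0, 1]")
    if biomes is None:
        biomes = DATA_RICH_BIOMES + EXCLUDED_BIOMES
    rng = _rng(truth, 1)

    # weight data-rich biomes heavily; excluded biomes appear sparsely
    weights = np.array(
        [3.0 if b in DATA_RICH_BIOMES else 0.4 for b in biomes]
    )
    weights /= weights.sum()
    biome = rng.choice(biomes, size=n, p=weights)
    continent = rng.choice(CONTINENTS, size=n)
    is_mdc_site = rng.random(n) < mdc_fraction

    lat_lo = np.array([_LAT_BANDS[b][0] for b in biome])
    lat_hi = np.array([_LAT_BANDS[b][1] for b in biome])
    latitude = rng.uniform(lat_lo, lat_hi) * rng.choice([-1.0, 1.0], size=n)

    olsen = np.exp(rng.normal(np.log(12.0), 0.8, size=n))
    olsen = np.clip(olsen, 0.5, None)
    pop = np.exp(rng.normal(np.log(25.0), 1.4, size=n))

    # land shares: crop, pasture, urban, forest, rangeland, lentic
    shares = rng.dirichlet([2.0, 2.5, 0.6, 4.0, 3.0, 0.15], size=n) * 100.0
    crop, pasture, urban, forest, rangeland, lentic = shares.T

    # overwrite the minimally disturbed subset
    m = is_mdc_site
    olsen[m] = rng.uniform(1.0, 5.0, size=m.sum())
    pop[m] = rng.uniform(0.0002, 0.001, size=m.sum())
    crop[m] = pasture[m] = urban[m] = 0.0
    lentic_m = rng.uniform(0.0, 3.0, size=m.sum())
    lentic[m] = lentic_m
    split = rng.uniform(0.3, 0.7, size=m.sum())
    forest[m] = (100.0 - lentic_m) * split
    rangeland[m] = (100.0 - lentic_m) * (1.0 - split)

    slope = np.exp(rng.normal(np.log(4.0), 0.7, size=n))
    runoff = np.exp(rng.normal(np.log(300.0), 0.7, size=n))
    pet = np.clip(rng.normal(1000.0, 300.0, size=n), 200.0, None)
    area = np.exp(rng.normal(np.log(600.0), 1.0, size=n))
    permafrost = rng.random(n) < np.where(
        biome == "Boreal Forests/Taiga", 0.7, 0.02
    )
    excluded = np.isin(biome, EXCLUDED_BIOMES) | permafrost

    df = pd.DataFrame(
        {
            "id": [f"c{i:05d}" for i in range(n)],
            "biome": biome,
            "continent": continent,
            "latitude": latitude,
            "crop_pct": crop,
            "pasture_pct": pasture,
            "urban_pct": urban,
            "forest_pct": forest,
            "rangeland_pct": rangeland,
            "lentic_pct": lentic,
            "olsen_p": olsen,
            "pop_density": pop,
            "slope": slope,
            "runoff": runoff,
            "pet": pet,
            "area": area,
            "permafrost": permafrost,
            "excluded": excluded,
        }
    )
    df["population"] = df["pop_density"] * df["area"]
    return df


def generate_discharge(
    catchment: pd.Series,
    n_days: int,
    truth: TruthParams,
    start: str = "2005-01-01",
) -> pd.DataFrame:
    """Daily discharge for one catchment: seasonal base + storm pulses.

    The base component is a sinusoid over the year scaled from catchment
    runoff and area; storms arrive as a Poisson process at
    ``truth.storm_frequency`` events/year and decay exponentially (3-day
    time constant), with total storm volume set by ``baseflow_index``.
    """
    if n_days < 30:
        raise ValueError(f"n_days must be >= 30, got {n_days}")
    idx = int(str(catchment["id"]).lstrip("c") or 0)
    rng = _rng(truth, 2, idx)

    dates = pd.date_range(start, periods=n_days, freq="D")
    t = np.arange(n_days)
    # mean flow (m^3/s) from the water balance: runoff (mm/yr) * area (km^2)
    mean_flow = catchment["runoff"] * catchment["area"] / (365.25 * 86.4 * 1000.0)
    phase = rng.uniform(0, 2 * np.pi)
    base = mean_flow * (1.0 + 0.3 * np.sin(2 * np.pi * t / 365.25 + phase))

    flow = base.copy()
    if truth.storm_frequency > 0:
        n_storms = rng.poisson(truth.storm_frequency * n_days / 365.25)
        storm_days = rng.integers(0, n_days, size=n_storms)
        # scale pulse volume so storms contribute (1 - bfi) of total volume
        tau = 3.0
        total_storm_volume = base.sum() * (1.0 - truth.baseflow_index) / truth.baseflow_index
        per_storm = total_storm_volume / max(n_storms, 1)
        for d in storm_days:
            amp = per_storm / tau * rng.lognormal(0.0, 0.3)
            decay = amp * np.exp(-(t[d:] - d) / tau)
            flow[d:] += decay
    return pd.DataFrame({"date": dates, "flow": flow})


def generate_samples(
    catchment: pd.Series,
    discharge: pd.DataFrame,
    truth: TruthParams,
    analyte: str,
    samples_per_month: int = 2,
) -> pd.DataFrame:
    """Dated nutrient samples for one catchment and analyte.

    Sample days are spread evenly through the discharge record so all
    months are covered.  The noise-free growth-season median
    (``reference_level * exp(slope * H)``) is stored in
    ``result.attrs['true_median']`` for oracle checks.
    """
    check_analyte(analyte)
    idx = int(str(catchment["id"]).lstrip("c") or 0)
    rng = _rng(truth, 3, idx, ANALYTES.index(analyte))

    weights = he.published_weights(analyte)
    components = he.transform_components(catchment[list(he.RAW_COLUMNS)].to_dict())
    H = float(he.apply_weights(weights, components).iloc[0])
    ref = truth.reference_level(catchment["biome"], analyte)
    true_median = ref * np.exp(truth.human_effect_slope * H)

    n_days = len(discharge)
    n_samples = max(int(round(samples_per_month * n_days / 30.44)), 12)
    # evenly spaced with a small jitter: spans every month of the record
    pos = np.linspace(0, n_days - 1, n_samples)
    jitter = rng.integers(-5, 6, size=n_samples)
    days = np.clip(np.round(pos + jitter).astype(int), 0, n_days - 1)

    eps = rng.normal(0.0, truth.noise_sd_log, size=n_samples)
    conc = true_median * np.exp(eps)
    out = pd.DataFrame(
        {
            "site_id": catchment["id"],
            "date": pd.to_datetime(discharge["date"]).iloc[days].to_numpy(),
            "analyte": analyte,
            "concentration": conc,
        }
    )
    out.attrs["true_median"] = float(true_median)
    out.attrs["human_effect"] = H
    return out


def true_medians(
    catchments: pd.DataFrame, truth: TruthParams, analyte: str
) -> pd.Series:
    """Noise-free site medians for every catchment (vectorised oracle)."""
    check_analyte(analyte)
    weights = he.published_weights(analyte)
    H = he.human_effect_scores(catchments, weights)
    ref = catchments["biome"].map(
        lambda b: truth.reference_level(b, analyte)
    ).astype(float)
    out = ref.to_numpy() * np.exp(truth.human_effect_slope * H.to_numpy())
    return pd.Series(out, index=catchments.index, name="true_median")
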