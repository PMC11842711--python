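"""Anthropogenic 'human effect' composite.

Eight catchment variables — soil Olsen phosphorus, population density and
six land-class percentages — are transformed onto comparable scales and
combined into a single latent pressure score per analyte, either with the
published coefficient sets or by fitting the first partial-least-squares
(PLS) component against log median concentration.

Transforms
----------
Land classes that grow with human activity (crop, pasture, urban) map as
``asin(sqrt(p/100))``; classes that shrink (forest, rangeland, lentic) map
as ``asin(sqrt((100 - p)/100))`` so every component increases with
anthropogenic pressure.  Olsen P and population density are heavily
right-skewed and are normalised as ``ln(1.8578 * olsen_p)`` and
``ln(0.0282 * pop_density)``, which places their spread within that of the
arcsine-transformed land classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .analytes import check_analyte

COMPONENT_NAMES = (
    "OlsenP",
    "Pasture",
    "Lentic",
    "PopDensity",
    "Forest",
    "Urban",
    "Rangeland",
    "Crop",
)

#: raw catchment column -> transformed component name
RAW_COLUMNS = {
    "olsen_p": "OlsenP",
    "pop_density": "PopDensity",
    "crop_pct": "Crop",
    "pasture_pct": "Pasture",
    "urban_pct": "Urban",
    "forest_pct": "Forest",
    "rangeland_pct": "Rangeland",
    "lentic_pct": "Lentic",
}

OLSEN_P_NORM = 1.8578
POP_DENSITY_NORM = 0.0282
POP_DENSITY_FLOOR = 1e-6  # persons/km^2, applied before the log

_INCREASING = ("Crop", "Pasture", "Urban")
_DECREASING = ("Forest", "Rangeland", "Lentic")

# Published per-analyte coefficient sets for the eight components, with the
# correlation each latent score achieved against its log-median response.
_PUBLISHED = {
    "DRP": {
        "OlsenP": 0.6482, "Pasture": 0.3410, "Lentic": 0.1977,
        "PopDensity": 0.4610, "Forest": 0.3031, "Urban": 0.3113,
        "Rangeland": -0.1323, "Crop": 0.0759,
    },
    "NO3N": {
        "OlsenP": 0.2636, "Pasture": -0.1019, "Lentic": 0.1031,
        "Urban": 0.2264, "Crop": 0.4273, "Rangeland": 0.1119,
        "Forest": 0.3126, "PopDensity": 0.7520,
    },
    "TP": {
        "OlsenP": 0.2468, "Pasture": 0.0537, "PopDensity": 0.6571,
        "Lentic": 0.1068, "Urban": 0.5415, "Forest": 0.4055,
        "Rangeland": 0.0720, "Crop": 0.1736,
    },
    "TN": {
        "OlsenP": 0.6960, "Pasture": 0.2229, "Rangeland": 0.3031,
        "Crop": 0.0401, "Forest": 0.1548, "Urban": 0.3505,
        "Lentic": 0.1513, "PopDensity": 0.4503,
    },
}

_PUBLISHED_CORRELATION = {"DRP": 0.61, "NO3N": 0.48, "TP": 0.57, "TN": 0.53}


@dataclass(frozen=True)
class HumanEffectWeights:
    """Coefficients of the human-effect composite for one analyte."""

    analyte: str
    coefficients: Mapping[str, float]
    correlation_with_response: float | None = None
    source: str = field(default="fitted")

    def __post_init__(self):
        missing = set(COMPONENT_NAMES) - set(self.coefficients)
        if missing:
            raise ValueError(f"missing coefficients for {sorted(missing)}")
        vec = np.array([self.coefficients[c] for c in COMPONENT_NAMES])
        if not np.all(np.isfinite(vec)):
            raise ValueError("coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in COMPONENT_NAMES])


def published_weights(analyte: str) -> HumanEffectWeights:
    """Return the published coefficient set for *analyte*."""
    check_analyte(analyte)
    return HumanEffectWeights(
        analyte=analyte,
        coefficients=dict(_PUBLISHED[analyte]),
        correlation_with_response=_PUBLISHED_CORRELATION[analyte],
        source="published",
    )


def transform_components(raw: pd.DataFrame | Mapping[str, float]) -> pd.DataFrame:
    """Transform raw anthropogenic inputs onto the composite's scale.

    Accepts a DataFrame (one row per catchment) or a mapping for a single
    catchment; returns a DataFrame with the eight component columns.
    """
    if isinstance(raw, Mapping):
        raw = pd.DataFrame([raw])
    missing = set(RAW_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"missing input columns {sorted(missing)}")

    for col in ("crop_pct", "pasture_pct", "urban_pct",
                "forest_pct", "rangeland_pct", "lentic_pct"):
        vals = raw[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError(f"{col} outside [0, 100]")

    olsen = raw["olsen_p"].to_numpy(dtype=float)
    if np.any(olsen <= 0):
        raise ValueError("olsen_p must be positive")
    pop = np.maximum(raw["pop_density"].to_numpy(dtype=float), POP_DENSITY_FLOOR)

    out = pd.DataFrame(index=raw.index)
    out["OlsenP"] = np.log(OLSEN_P_NORM * olsen)
    out["PopDensity"] = np.log(POP_DENSITY_NORM * pop)
    for raw_col, comp in RAW_COLUMNS.items():
        if comp in _INCREASING:
            out[comp] = np.arcsin(np.sqrt(raw[raw_col].to_numpy(dtype=float) / 100.0))
        elif comp in _DECREASING:
            out[comp] = np.arcsin(
                np.sqrt((100.0 - raw[raw_col].to_numpy(dtype=float)) / 100.0)
            )
    return out[list(COMPONENT_NAMES)]


def apply_weights(
    weights: HumanEffectWeights, components: pd.DataFrame | Mapping[str, float]
) -> pd.Series | float:
    """Weighted sum of the eight transformed components."""
    scalar = isinstance(components, Mapping) and not isinstance(components, pd.DataFrame)
    if scalar:
        components = pd.DataFrame([components])
    missing = set(COMPONENT_NAMES) - set(components.columns)
    if missing:
        raise ValueError(f"missing components {sorted(missing)}")
    scores = components[list(COMPONENT_NAMES)].to_numpy(dtype=float) @ weights.as_array()
    if scalar:
        return float(scores[0])
    return pd.Series(scores, index=components.index, name="human_effect")


def human_effect_scores(
    catchments: pd.DataFrame, weights: HumanEffectWeights
) -> pd.Series:
    """Transform raw catchment inputs and apply *weights* in one step."""
    return apply_weights(weights, transform_components(catchments))


def fit_first_pls_component(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    *,
    scale: bool = False,
    analyte: str = "fitted",
) -> HumanEffectWeights:
    """Fit the first PLS latent component of *X* against *y*.

    *X* holds the eight transformed components (one row per site) and *y*
    the natural-log median concentrations.  The returned weight vector has
    unit norm (in the centred/optionally scaled space) and is oriented so
    that the latent score correlates positively with the response.

    Raises ``ValueError`` for fewer than 9 sites, a constant response, or a
    constant component column when ``scale=True``.
    """
    missing = set(COMPONENT_NAMES) - set(X.columns)
    if missing:
        raise ValueError(f"missing components {sorted(missing)}")
    X = X[list(COMPONENT_NAMES)]
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 9:
        raise ValueError(f"need at least 9 sites to fit, got {X.shape[0]}")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; latent component undefined")
    Xv = X.to_numpy(dtype=float)
    if np.all(np.ptp(Xv, axis=0) == 0):
        raise ValueError("component matrix is constant (rank deficient)")

    pls = PLSRegression(n_components=1, scale=scale)
    pls.fit(Xv, y)
    w = pls.x_weights_[:, 0].copy()

    scores = (Xv - Xv.mean(axis=0)) @ (
        w / pls._x_std if scale else w  # scores in the raw component space
    )
    r = np.corrcoef(scores, y)[0, 1]
    if r < 0:
        w = -w
        scores = -scores
        r = -r
    coeffs = dict(zip(COMPONENT_NAMES, w))
    return HumanEffectWeights(
        analyte=analyte,
        coefficients=coeffs,
        correlation_with_response=float(r),
        source="fitted",
    )
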