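"""Nutrient analytes handled throughout the package.

Concentrations are in mg/L everywhere except the periphyton biomass
equation, which takes µg/L (see :mod:`riverref.periphyton_class`).
"""

ANALYTES = ("DRP", "TP", "NO3N", "TN")

ANALYTE_NAMES = {
    "DRP": "dissolved reactive phosphorus",
    "TP": "total phosphorus",
    "NO3N": "nitrate-nitrogen",
    "TN": "total nitrogen",
}


def check_analyte(analyte: str) -> str:
    if analyte not in ANALYTES:
        raise ValueError(
            f"unknown analyte {analyte!r}; expected one of {ANALYTES}"
        )
    return analyte
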