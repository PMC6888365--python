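"""Published reference values for the BC-7 / cisplatin HeLa study.

These are the printed experimental results of the cytotoxicity study this
pipeline models: ICx values for HeLa cells after 48 h (Hoechst 33342/PI
readout), cross-line IC50s used for selectivity, and the CI/DRI grid of the
constant-ratio cisplatin:BC-7 combinations.  They serve as worked-example
inputs and consistency anchors; they are data, not code defaults.

BC-7 is the 5-aminopyrazole derivative
N-[[3-(4-bromophenyl)-1H-pyrazol-5-yl]-carbamothioyl]-4-chloro-benzamide.
"""

from __future__ import annotations

from .median_effect import MedianEffectFit, fit_from_two_effects
from .selectivity import CensoredIC50

__all__ = [
    "HELA_ICX",
    "IC50_BY_LINE",
    "PUBLISHED_CI",
    "PUBLISHED_DRI",
    "COMBINATION_RATIOS",
    "hela_fit",
]

#: HeLa 48 h ICx values in μM, keyed by drug then by fraction affected.
HELA_ICX: dict[str, dict[float, float]] = {
    "cisplatin": {0.10: 0.069, 0.25: 0.342, 0.50: 1.675, 0.75: 8.194},
    "BC-7": {0.10: 18.50, 0.25: 34.83, 0.50: 65.58, 0.75: 123.5},
}

#: 48 h IC50s (μM) across cell lines.  HeLa is the cancer target; Vero and
#: MRHF are the non-tumorigenic comparators; MeWo and HepG2 are other cancer
#: lines.  BC-7 never reached 50% kill on MeWo/HepG2 at the 200 μM top dose.
IC50_BY_LINE: dict[str, dict[str, CensoredIC50]] = {
    "cisplatin": {
        "HeLa": CensoredIC50(1.675),
        "Vero": CensoredIC50(5.921),
        "MRHF": CensoredIC50(6.490),
        "MeWo": CensoredIC50(9.300),
        "HepG2": CensoredIC50(3.525),
    },
    "BC-7": {
        "HeLa": CensoredIC50(65.58),
        "Vero": CensoredIC50(169.5),
        "MRHF": CensoredIC50(111.4),
        "MeWo": CensoredIC50(200.0, censored=True),
        "HepG2": CensoredIC50(200.0, censored=True),
    },
}

#: Constant-ratio designs tested (cisplatin IC50 multiple : BC-7 IC50 multiple).
COMBINATION_RATIOS: tuple[tuple[str, float, float], ...] = (
    ("1:3", 1, 3),
    ("1:2", 1, 2),
    ("1:1", 1, 1),
    ("2:1", 2, 1),
    ("3:1", 3, 1),
)

#: Published CI values, keyed by (ratio label, fa).
PUBLISHED_CI: dict[tuple[str, float], float] = {
    ("1:3", 0.10): 0.21, ("1:3", 0.25): 0.32, ("1:3", 0.50): 0.61, ("1:3", 0.75): 1.38,
    ("1:2", 0.10): 0.27, ("1:2", 0.25): 0.46, ("1:2", 0.50): 0.96, ("1:2", 0.75): 2.45,
    ("1:1", 0.10): 0.71, ("1:1", 0.25): 0.58, ("1:1", 0.50): 0.58, ("1:1", 0.75): 0.72,
    ("2:1", 0.10): 0.54, ("2:1", 0.25): 0.51, ("2:1", 0.50): 0.54, ("2:1", 0.75): 0.70,
    ("3:1", 0.10): 0.78, ("3:1", 0.25): 0.61, ("3:1", 0.50): 0.53, ("3:1", 0.75): 0.55,
}

#: Published DRI pairs (cisplatin, BC-7), keyed by (ratio label, fa).
PUBLISHED_DRI: dict[tuple[str, float], tuple[float, float]] = {
    ("1:3", 0.10): (6.90, 15.7), ("1:3", 0.25): (6.76, 5.86),
    ("1:3", 0.50): (6.56, 2.19), ("1:3", 0.75): (6.37, 0.82),
    ("1:2", 0.10): (4.73, 16.1), ("1:2", 0.25): (3.86, 5.02),
    ("1:2", 0.50): (3.13, 1.56), ("1:2", 0.75): (2.53, 0.49),
    ("1:1", 0.10): (1.62, 11.1), ("1:1", 0.25): (2.38, 6.20),
    ("1:1", 0.50): (3.46, 3.46), ("1:1", 0.75): (5.01, 1.92),
    ("2:1", 0.10): (1.97, 27.0), ("2:1", 0.25): (2.36, 12.3),
    ("2:1", 0.50): (2.79, 5.59), ("2:1", 0.75): (3.30, 2.54),
    ("3:1", 0.10): (1.35, 27.7), ("3:1", 0.25): (1.85, 14.4),
    ("3:1", 0.50): (2.51, 7.52), ("3:1", 0.75): (3.39, 3.92),
}


def hela_fit(drug: str) -> MedianEffectFit:
    """Median-effect model pinned to a drug's printed HeLa IC50 and IC75.

    The two-point construction reproduces the remaining printed ICx values,
    showing the published table is internally consistent with the
    median-effect model.
    """
    icx = HELA_ICX[drug]
    return fit_from_two_effects((0.50, icx[0.50]), (0.75, icx[0.75]), name=drug)
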