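"""Constant-ratio combination analysis: CI and DRI profiling.

Two drugs are mixed at a fixed concentration ratio defined as multiples of
their IC50s (a "1:3" mixture is IC50_a : 3 x IC50_b), the mixture is serially
diluted and treated as a single agent for median-effect fitting, and for each
effect level fa the combination index

    CI = D_1 / Dx_1 + D_2 / Dx_2

compares the component doses D_i in the combination producing fa against the
single-agent doses Dx_i producing the same fa (Loewe additivity reference:
CI < 1 synergism, CI = 1 additive, CI > 1 antagonism).  The dose reduction
index DRI_i = Dx_i / D_i is the fold-reduction of drug i achievable in the
combination at equal effect; DRI > 1 is favourable.  CI = sum of reciprocal
DRIs, an identity used as an internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidInputError
from .median_effect import DoseEffectModel, MedianEffectFit, dose_for_effect

__all__ = [
    "MixtureRatio",
    "ProfileRow",
    "SynergyProfile",
    "DEFAULT_FA_LEVELS",
    "component_doses",
    "combination_index",
    "dose_reduction_index",
    "ci_from_dri",
    "classify_ci",
    "synergy_profile",
]

DEFAULT_FA_LEVELS: tuple[float, ...] = (0.10, 0.25, 0.50, 0.75)


@dataclass(frozen=True)
class MixtureRatio:
    """A constant-ratio two-drug mixture.

    ``multiples`` (k_a, k_b) are the IC50 multiples of each component: a 2:1
    mixture combines 2 x IC50_a with 1 x IC50_b.  ``fraction_a`` is drug a's
    share of the total mixture concentration,
    k_a * IC50_a / (k_a * IC50_a + k_b * IC50_b).
    """

    label: str
    multiples: tuple[float, float]
    fraction_a: float

    def __post_init__(self) -> None:
        k_a, k_b = self.multiples
        if k_a < 0 or k_b < 0 or k_a + k_b == 0:
            raise InvalidInputError("IC50 multiples must be >= 0 and not both 0")
        if not 0 <= self.fraction_a <= 1:
            raise InvalidInputError("fraction_a must lie in [0, 1]")

    @property
    def fraction_b(self) -> float:
        return 1.0 - self.fraction_a

    @classmethod
    def from_ic50s(
        cls,
        k_a: float,
        k_b: float,
        ic50_a: float,
        ic50_b: float,
        label: str | None = None,
    ) -> "MixtureRatio":
        """Build a ratio from IC50 multiples and the two drugs' IC50s (μM)."""
        if ic50_a <= 0 or ic50_b <= 0:
            raise InvalidInputError("IC50s must be > 0")
        wa = k_a * ic50_a
        wb = k_b * ic50_b
        if wa + wb == 0:
            raise InvalidInputError("multiples must not both be 0")
        if label is None:
            label = f"{k_a:g}:{k_b:g}"
        return cls(label=label, multiples=(k_a, k_b), fraction_a=wa / (wa + wb))

    @classmethod
    def from_fractions(cls, fraction_a: float, label: str = "") -> "MixtureRatio":
        """Build a ratio directly from the concentration fraction of drug a."""
        return cls(label=label, multiples=(fraction_a, 1.0 - fraction_a),
                   fraction_a=fraction_a)


def component_doses(total_dose: float, ratio: MixtureRatio) -> tuple[float, float]:
    """Split a total mixture dose into component doses; the sum is exact."""
    if total_dose < 0:
        raise InvalidInputError("total_dose must be >= 0")
    dose_a = ratio.fraction_a * total_dose
    return dose_a, total_dose - dose_a


def combination_index(
    dose_a: float,
    dose_b: float,
    fit_a: DoseEffectModel,
    fit_b: DoseEffectModel,
    fa: float,
) -> float:
    """CI of component doses (dose_a, dose_b) at effect level fa."""
    if dose_a < 0 or dose_b < 0 or dose_a + dose_b == 0:
        raise InvalidInputError("component doses must be >= 0 and not both 0")
    return dose_a / dose_for_effect(fit_a, fa) + dose_b / dose_for_effect(fit_b, fa)


def dose_reduction_index(
    fit: DoseEffectModel, fa: float, dose_in_combo: float
) -> float:
    """DRI = Dx(fa) / dose-in-combination; > 1 is favourable."""
    if dose_in_combo <= 0:
        raise InvalidInputError("dose in combination must be > 0")
    return dose_for_effect(fit, fa) / dose_in_combo


def ci_from_dri(dris: Iterable[float]) -> float:
    """CI as the sum of reciprocal DRIs (identity check helper)."""
    dris = list(dris)
    if not dris:
        raise InvalidInputError("need at least one DRI")
    if any(d <= 0 for d in dris):
        raise InvalidInputError("all DRIs must be > 0")
    return sum(1.0 / d for d in dris)


#: Banded classification: upper CI bound -> label (checked in order).
_BANDS = (
    (0.3, "strong synergism"),
    (0.7, "synergism"),
    (0.9, "moderate/slight synergism"),
    (1.1, "nearly additive"),
    (float("inf"), "antagonism"),
)


def classify_ci(ci: float, scheme: str = "banded", additive_tol: float = 0.05) -> str:
    """Label a CI value.

    ``coarse`` uses the trichotomy synergism / additive / antagonism with an
    additive band |CI - 1| <= ``additive_tol``; ``banded`` refines synergism
    into strong (< 0.3), plain (< 0.7), and moderate/slight (< 0.9), with
    [0.9, 1.1) nearly additive and antagonism above.
    """
    if ci <= 0:
        raise InvalidInputError("CI must be > 0")
    if scheme == "coarse":
        if abs(ci - 1.0) <= additive_tol:
            return "additive"
        return "synergism" if ci < 1.0 else "antagonism"
    if scheme == "banded":
        for upper, label in _BANDS:
            if ci < upper:
                return label
        raise AssertionError("unreachable")
    raise InvalidInputError(f"unknown scheme {scheme!r}")


@dataclass(frozen=True)
class ProfileRow:
    """One effect level of a synergy profile (machine twin of a CI/DRI table row)."""

    fa: float
    dose_a: float
    dose_b: float
    dx_a: float
    dx_b: float
    ci: float
    dri_a: float
    dri_b: float
    label: str
    extrapolated: bool


@dataclass(frozen=True)
class SynergyProfile:
    """CI/DRI profile of one constant-ratio mixture across effect levels."""

    ratio: MixtureRatio
    rows: tuple[ProfileRow, ...]

    def to_frame(self, round_to: int | None = 2) -> pd.DataFrame:
        """Tabular report; CI/DRI rounded to 2 decimals by default, doses kept full."""
        df = pd.DataFrame(
            {
                "ratio": self.ratio.label,
                "fa": [r.fa for r in self.rows],
                "D_a": [r.dose_a for r in self.rows],
                "D_b": [r.dose_b for r in self.rows],
                "Dx_a": [r.dx_a for r in self.rows],
                "Dx_b": [r.dx_b for r in self.rows],
                "CI": [r.ci for r in self.rows],
                "DRI_a": [r.dri_a for r in self.rows],
                "DRI_b": [r.dri_b for r in self.rows],
                "class": [r.label for r in self.rows],
                "extrapolated": [r.extrapolated for r in self.rows],
            }
        )
        if round_to is not None:
            for col in ("CI", "DRI_a", "DRI_b"):
                df[col] = df[col].round(round_to)
        return df


def synergy_profile(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_mix: MedianEffectFit,
    ratio: MixtureRatio,
    fa_levels: Sequence[float] = DEFAULT_FA_LEVELS,
    scheme: str = "banded",
) -> SynergyProfile:
    """Profile CI, DRI and classification across effect levels.

    For each fa the total mixture dose producing that effect comes from the
    mixture fit (the mixture treated as a single agent), is split into
    component doses by the constant ratio, and is compared against each
    single-agent fit.  Rows whose total dose falls outside the mixture's
    fitted dose range are flagged extrapolated.
    """
    rows = []
    for fa in fa_levels:
        if not 0 < fa < 1:
            raise InvalidInputError(f"fa level must lie in (0, 1), got {fa!r}")
        total = dose_for_effect(fit_mix, fa)
        dose_a, dose_b = component_doses(total, ratio)
        dx_a = dose_for_effect(fit_a, fa)
        dx_b = dose_for_effect(fit_b, fa)
        ci = dose_a / dx_a + dose_b / dx_b
        rows.append(
            ProfileRow(
                fa=fa,
                dose_a=dose_a,
                dose_b=dose_b,
                dx_a=dx_a,
                dx_b=dx_b,
                ci=ci,
                dri_a=dx_a / dose_a if dose_a > 0 else float("inf"),
                dri_b=dx_b / dose_b if dose_b > 0 else float("inf"),
                label=classify_ci(ci, scheme=scheme),
                extrapolated=not fit_mix.contains_dose(total),
            )
        )
    return SynergyProfile(ratio=ratio, rows=tuple(rows))
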