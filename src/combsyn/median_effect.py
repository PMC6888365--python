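"""Median-effect (mass-action) dose-response modelling.

The median-effect equation relates the fraction of cells affected (killed)
``fa`` to dose ``D``::

    fa / fu = (D / Dm) ** m,      fu = 1 - fa

where ``Dm`` is the median-effect dose (the IC50 under this model) and ``m``
measures the sigmoidicity of the dose-effect curve (m = 1 is hyperbolic).
Taking log10 of both sides linearizes the relation, and the "median-effect
plot" of log10(fa/fu) against log10(D) is fitted by ordinary least squares:
the slope is ``m``, the intercept is ``-m * log10(Dm)``, and the Pearson
correlation ``r`` of the plot is the conformity check to the mass-action law.

This module converts raw dead/total nuclei counts (Hoechst 33342/PI dual
staining) into fraction-affected values, fits the linearized model, and
interconverts dose and effect via::

    Dx = Dm * (fa / (1 - fa)) ** (1 / m)

All concentrations are in μM; unit conversion is the caller's responsibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Protocol, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InconsistentInputError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "WellRecord",
    "DoseEffectPoint",
    "MedianEffectFit",
    "DoseEffectModel",
    "fraction_affected",
    "pooled_control_death_fraction",
    "points_from_wells",
    "linearize",
    "LinearizedPlot",
    "fit_median_effect",
    "dose_for_effect",
    "effect_for_dose",
    "shape_from_two_effects",
    "fit_from_two_effects",
]


@dataclass(frozen=True)
class WellRecord:
    """One assay well: drug doses (μM) and dead/total cell counts.

    A control (untreated) well has both doses equal to zero.  Counts are
    integers for sampled plates; expectation-mode simulated plates may carry
    fractional expected counts.
    """

    drug_a_dose: float
    drug_b_dose: float
    total_cells: float
    dead_cells: float
    well_label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.drug_a_dose) and math.isfinite(self.drug_b_dose)):
            raise InvalidInputError(f"non-finite dose in well {self.well_label!r}")
        if self.drug_a_dose < 0 or self.drug_b_dose < 0:
            raise InvalidInputError(f"negative dose in well {self.well_label!r}")
        if self.total_cells <= 0:
            raise InvalidInputError(
                f"total_cells must be > 0 in well {self.well_label!r}"
            )
        if not 0 <= self.dead_cells <= self.total_cells:
            raise InvalidInputError(
                f"dead_cells outside [0, total_cells] in well {self.well_label!r}"
            )

    @property
    def is_control(self) -> bool:
        return self.drug_a_dose == 0 and self.drug_b_dose == 0

    @property
    def total_dose(self) -> float:
        """Summed dose of both drugs (the mixture dose for combination wells)."""
        return self.drug_a_dose + self.drug_b_dose


@dataclass(frozen=True)
class DoseEffectPoint:
    """A (dose, fraction-affected) pair.

    ``dose`` is the total mixture dose for combination wells.  ``fu`` is the
    derived fraction unaffected, always consistent with ``fa``.
    """

    dose: float
    fa: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.dose) or self.dose < 0:
            raise InvalidInputError(f"invalid dose {self.dose!r}")
        if not 0 <= self.fa <= 1:
            raise InvalidInputError(f"fa must lie in [0, 1], got {self.fa!r}")

    @property
    def fu(self) -> float:
        return 1.0 - self.fa


class DoseEffectModel(Protocol):
    """Anything exposing median-effect parameters ``m`` and ``Dm``.

    Both :class:`MedianEffectFit` and the simulator's ground-truth drug
    parameters satisfy this, so dose/effect interconversion works on either.
    """

    m: float
    Dm: float


@dataclass(frozen=True)
class MedianEffectFit:
    """Result of fitting the median-effect model.

    Attributes
    ----------
    m : float
        Slope of the median-effect plot (sigmoidicity); positive for any
        accepted fit.
    Dm : float
        Median-effect dose in μM (the model IC50).
    r : float
        Pearson correlation coefficient of the linearized plot.
    n_points : int
        Number of points used in the regression.
    dose_range : tuple of float
        (min, max) dose in μM of the fitted points; doses outside this range
        are extrapolations of the model.
    non_monotone : bool
        Warning flag set when the fitted slope was not positive.
    """

    m: float
    Dm: float
    r: float
    n_points: int
    dose_range: tuple[float, float]
    non_monotone: bool = False
    name: str = ""

    def contains_dose(self, dose: float) -> bool:
        """Whether ``dose`` lies inside the fitted dose range (no extrapolation)."""
        lo, hi = self.dose_range
        return lo <= dose <= hi

    def icx(self, x: float) -> float:
        """Dose producing ``x`` fractional effect (e.g. ``icx(0.5)`` is the IC50)."""
        return dose_for_effect(self, x)


def fraction_affected(
    dead: float, total: float, control_death_fraction: float = 0.0
) -> float:
    """Background-corrected fraction of cells affected.

    Normalizes the raw dead fraction against the untreated-control death
    fraction and clips to [0, 1]::

        fa = (dead/total - c) / (1 - c)

    Reduces to the raw dead fraction when the control death fraction is 0.
    """
    if total <= 0:
        raise InvalidInputError("total must be > 0")
    if not 0 <= dead <= total:
        raise InvalidInputError("dead must lie in [0, total]")
    if not 0 <= control_death_fraction < 1:
        raise InvalidInputError("control_death_fraction must lie in [0, 1)")
    raw = dead / total
    fa = (raw - control_death_fraction) / (1.0 - control_death_fraction)
    return float(min(1.0, max(0.0, fa)))


def pooled_control_death_fraction(wells: Iterable[WellRecord]) -> float:
    """Death fraction of the pooled control wells (0 when there are none)."""
    dead = tot = 0.0
    for w in wells:
        if w.is_control:
            dead += w.dead_cells
            tot += w.total_cells
    return dead / tot if tot > 0 else 0.0


def points_from_wells(
    wells: Sequence[WellRecord],
    control_death_fraction: float | None = None,
) -> list[DoseEffectPoint]:
    """Collapse well records to one dose-effect point per distinct total dose.

    Replicate wells at the same dose are averaged (fa averaged per dose before
    linearization).  Control wells set the background death fraction unless
    one is given explicitly; they never enter the returned points.
    """
    wells = list(wells)
    if control_death_fraction is None:
        control_death_fraction = pooled_control_death_fraction(wells)
    by_dose: dict[float, list[float]] = {}
    for w in wells:
        if w.is_control:
            continue
        fa = fraction_affected(w.dead_cells, w.total_cells, control_death_fraction)
        by_dose.setdefault(w.total_dose, []).append(fa)
    return [
        DoseEffectPoint(dose=d, fa=float(np.mean(fas)))
        for d, fas in sorted(by_dose.items())
    ]


class LinearizedPlot(NamedTuple):
    """Median-effect plot coordinates plus the points excluded from them."""

    x: np.ndarray  # log10 dose
    y: np.ndarray  # log10(fa / fu)
    excluded: list[DoseEffectPoint]


def linearize(
    points: Sequence[DoseEffectPoint], epsilon: float | None = None
) -> LinearizedPlot:
    """Map dose-effect points onto median-effect plot coordinates.

    Points with fa exactly 0 or 1, or with zero dose, have no finite log
    coordinate; they are excluded from the regression and reported in
    ``excluded``.  Passing ``epsilon`` instead clips fa into
    [epsilon, 1 - epsilon] (exploratory use only; default off).
    """
    xs: list[float] = []
    ys: list[float] = []
    excluded: list[DoseEffectPoint] = []
    for p in points:
        fa = p.fa
        if epsilon is not None:
            fa = min(1.0 - epsilon, max(epsilon, fa))
        if p.dose <= 0 or not 0 < fa < 1:
            excluded.append(p)
            continue
        xs.append(math.log10(p.dose))
        ys.append(math.log10(fa / (1.0 - fa)))
    if len(xs) < 2:
        raise InsufficientDataError(
            f"need at least 2 usable points, got {len(xs)} "
            f"({len(excluded)} excluded)"
        )
    return LinearizedPlot(np.asarray(xs), np.asarray(ys), excluded)


def fit_median_effect(
    points: Sequence[DoseEffectPoint],
    epsilon: float | None = None,
    name: str = "",
) -> MedianEffectFit:
    """Fit m, Dm, r by unweighted OLS on the median-effect plot."""
    plot = linearize(points, epsilon=epsilon)
    if np.ptp(plot.x) == 0:
        raise DegenerateDesignError("all doses identical; slope is undefined")
    res = stats.linregress(plot.x, plot.y)
    m = float(res.slope)
    non_monotone = m <= 0
    # Dm from 10^(-intercept/m); undefined direction when slope is flagged,
    # but keep the algebraic value so diagnostics can still be printed.
    Dm = float(10.0 ** (-res.intercept / m)) if m != 0 else float("nan")
    doses = [p.dose for p in points if p not in plot.excluded]
    return MedianEffectFit(
        m=m,
        Dm=Dm,
        r=float(res.rvalue),
        n_points=len(plot.x),
        dose_range=(float(min(doses)), float(max(doses))),
        non_monotone=non_monotone,
        name=name,
    )


def dose_for_effect(fit: DoseEffectModel, fa: float) -> float:
    """Dose Dx producing fraction affected ``fa``: ``Dm * (fa/fu) ** (1/m)``.

    Exactly Dm at fa = 0.5 for every valid model.
    """
    if not 0 < fa < 1:
        raise InvalidInputError(f"fa must lie strictly in (0, 1), got {fa!r}")
    if fit.m <= 0:
        raise InvalidInputError("model has non-positive slope m")
    return float(fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def effect_for_dose(fit: DoseEffectModel, dose: float) -> float:
    """Fraction affected at ``dose``: ``1 / (1 + (Dm/dose) ** m)``.

    The algebraic inverse of :func:`dose_for_effect`; the two round-trip to
    machine precision.
    """
    if dose <= 0:
        raise InvalidInputError(f"dose must be > 0, got {dose!r}")
    if fit.m <= 0:
        raise InvalidInputError("model has non-positive slope m")
    return float(1.0 / (1.0 + (fit.Dm / dose) ** fit.m))


def shape_from_two_effects(
    point1: tuple[float, float], point2: tuple[float, float]
) -> float:
    """Back-derive the slope m from two (fa, dose) pairs.

    ``m = [log10(fa1/fu1) - log10(fa2/fu2)] / [log10 D1 - log10 D2]`` —
    useful for reconstructing a model from two printed ICx values.
    """
    (fa1, d1), (fa2, d2) = point1, point2
    for fa in (fa1, fa2):
        if not 0 < fa < 1:
            raise InvalidInputError(f"fa must lie strictly in (0, 1), got {fa!r}")
    if d1 <= 0 or d2 <= 0:
        raise InvalidInputError("doses must be > 0")
    if fa1 == fa2:
        raise InvalidInputError("effect levels must differ")
    if d1 == d2:
        raise InconsistentInputError("equal doses cannot give unequal effects")
    num = math.log10(fa1 / (1 - fa1)) - math.log10(fa2 / (1 - fa2))
    den = math.log10(d1) - math.log10(d2)
    return num / den


def fit_from_two_effects(
    point1: tuple[float, float], point2: tuple[float, float], name: str = ""
) -> MedianEffectFit:
    """Exact two-point median-effect model from two (fa, dose) pairs.

    The line through two points on the median-effect plot determines m and Dm
    uniquely; r is 1 by construction.
    """
    m = shape_from_two_effects(point1, point2)
    fa1, d1 = point1
    Dm = d1 / (fa1 / (1.0 - fa1)) ** (1.0 / m)
    doses = sorted((point1[1], point2[1]))
    return MedianEffectFit(
        m=m,
        Dm=float(Dm),
        r=1.0,
        n_points=2,
        dose_range=(float(doses[0]), float(doses[1])),
        non_monotone=m <= 0,
        name=name,
    )
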