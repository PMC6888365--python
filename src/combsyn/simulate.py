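"""Synthetic plate-data generator for dual-stain viability assays.

Emulates the statistical structure of Hoechst 33342/PI high-content readouts:
each well yields a total nuclei count and a dead-cell count, with the dead
count driven by a median-effect (Hill-type) ground truth per drug, a
background death rate in untreated controls, and binomial (optionally
beta-binomial) counting noise.  Designs follow serial dilution: 6-point
curves for single drugs, 7-point for constant-ratio combinations.

Combination ground truth is generated on a Loewe-additivity-anchored surface:
the fraction affected at component doses (D_a, D_b) is the unique solution of

    D_a / Dx_a(fa) + D_b / Dx_b(fa) = psi

where Dx_i(fa) is drug i's single-agent dose for effect fa.  By construction
the interaction parameter psi IS the ground-truth combination index, uniform
across effect levels: psi = 1 is exact Loewe additivity, psi < 1 synergy,
psi > 1 antagonism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .combination import MixtureRatio, component_doses
from .errors import InvalidInputError
from .median_effect import WellRecord, effect_for_dose, dose_for_effect

__all__ = [
    "DrugGroundTruth",
    "PlateDesign",
    "NoiseModel",
    "CISPLATIN_LIKE",
    "BC7_LIKE",
    "serial_dilution",
    "simulate_single_drug_plate",
    "loewe_additive_effect",
    "simulate_combination_plate",
]


@dataclass(frozen=True)
class DrugGroundTruth:
    """True median-effect parameters of a simulated drug (m shape, Dm in μM)."""

    name: str
    m: float
    Dm: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.m) and self.m > 0):
            raise InvalidInputError(f"m must be positive and finite, got {self.m!r}")
        if not (math.isfinite(self.Dm) and self.Dm > 0):
            raise InvalidInputError(f"Dm must be positive and finite, got {self.Dm!r}")


#: Default ground truths mimic the study drugs on HeLa cells (shape and IC50
#: back-derived from the printed IC50/IC75 pairs).
CISPLATIN_LIKE = DrugGroundTruth("cisplatin-like", m=0.6919, Dm=1.675)
BC7_LIKE = DrugGroundTruth("BC-7-like", m=1.7356, Dm=65.58)


@dataclass(frozen=True)
class PlateDesign:
    """Serial-dilution plate design.

    Defaults follow the assay conventions this generator emulates: 2-fold
    dilution, 3 replicate wells per dose, and about 2000 analyzed cells per
    well (a stand-in for the post-growth cell number in an imaged well, not a
    measured value).  Use ``n_doses=6`` for single drugs and 7 for
    combinations.
    """

    top_dose: float
    dilution_factor: float = 2.0
    n_doses: int = 6
    replicates: int = 3
    cells_per_well: int = 2000

    def __post_init__(self) -> None:
        if self.top_dose <= 0:
            raise InvalidInputError("top_dose must be > 0")
        if self.dilution_factor <= 1:
            raise InvalidInputError("dilution_factor must be > 1")
        if self.n_doses < 2:
            raise InvalidInputError("n_doses must be >= 2")
        if self.replicates < 1 or self.cells_per_well < 1:
            raise InvalidInputError("replicates and cells_per_well must be >= 1")

    @property
    def doses(self) -> list[float]:
        return serial_dilution(self.top_dose, self.dilution_factor, self.n_doses)


@dataclass(frozen=True)
class NoiseModel:
    """Counting-noise model for dead/total cell counts.

    ``count_noise`` options:

    - ``"binomial"``: dead ~ Binomial(cells, p) per well.
    - ``"beta-binomial"``: well death probability drawn from a Beta with mean
      p and intra-class correlation ``rho``, then binomial — adds
      well-to-well heterogeneity beyond counting error.
    - ``"expectation"``: deterministic mode; dead = p * cells exactly (may be
      fractional).  Separates model correctness from sampling behaviour.

    ``control_death_fraction`` is the spontaneous death rate in untreated
    wells; treated wells die with probability c + (1 - c) * fa_true.
    """

    control_death_fraction: float = 0.05
    count_noise: Literal["binomial", "beta-binomial", "expectation"] = "binomial"
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.control_death_fraction < 1:
            raise InvalidInputError("control_death_fraction must lie in [0, 1)")
        if self.count_noise not in ("binomial", "beta-binomial", "expectation"):
            raise InvalidInputError(f"unknown count_noise {self.count_noise!r}")
        if self.count_noise == "beta-binomial" and not 0 < self.rho < 1:
            raise InvalidInputError("beta-binomial rho must lie in (0, 1)")


def serial_dilution(top_dose: float, factor: float, n: int) -> list[float]:
    """Geometric dose series top, top/factor, ..., length n, strictly decreasing."""
    if top_dose <= 0:
        raise InvalidInputError("top_dose must be > 0")
    if factor <= 1:
        raise InvalidInputError("dilution factor must be > 1")
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    return [top_dose / factor**i for i in range(n)]


def _draw_dead(
    p: float, cells: int, noise: NoiseModel, rng: np.random.Generator
) -> float:
    if noise.count_noise == "expectation":
        return p * cells
    if noise.count_noise == "beta-binomial" and 0 < p < 1:
        # Beta with mean p and intra-class correlation rho.
        s = (1.0 - noise.rho) / noise.rho
        p = rng.beta(p * s, (1.0 - p) * s)
    return int(rng.binomial(cells, p))


def _death_probability(fa_true: float, noise: NoiseModel) -> float:
    c = noise.control_death_fraction
    return c + (1.0 - c) * fa_true


def simulate_single_drug_plate(
    truth: DrugGroundTruth,
    design: PlateDesign,
    noise: NoiseModel,
    drug_slot: Literal["a", "b"] = "a",
) -> list[WellRecord]:
    """Simulate a single-drug serial-dilution plate, controls included.

    Fully reproducible from ``noise.seed``; identical config + seed gives an
    identical plate.
    """
    rng = np.random.default_rng(noise.seed)
    wells: list[WellRecord] = []
    for i, dose in enumerate(design.doses):
        fa_true = effect_for_dose(truth, dose)
        p = _death_probability(fa_true, noise)
        for rep in range(design.replicates):
            dead = _draw_dead(p, design.cells_per_well, noise, rng)
            doses = (dose, 0.0) if drug_slot == "a" else (0.0, dose)
            wells.append(
                WellRecord(
                    drug_a_dose=doses[0],
                    drug_b_dose=doses[1],
                    total_cells=design.cells_per_well,
                    dead_cells=dead,
                    well_label=f"{truth.name}_d{i}_r{rep}",
                )
            )
    wells.extend(_control_wells(design, noise, rng))
    return wells


def _control_wells(
    design: PlateDesign, noise: NoiseModel, rng: np.random.Generator
) -> list[WellRecord]:
    out = []
    for rep in range(design.replicates):
        dead = _draw_dead(noise.control_death_fraction, design.cells_per_well,
                          noise, rng)
        out.append(
            WellRecord(0.0, 0.0, design.cells_per_well, dead,
                       well_label=f"control_r{rep}")
        )
    return out


def loewe_additive_effect(
    truth_a: DrugGroundTruth,
    truth_b: DrugGroundTruth,
    dose_a: float,
    dose_b: float,
    psi: float = 1.0,
) -> float:
    """Fraction affected at (dose_a, dose_b) on the interaction surface.

    Solves D_a/Dx_a(fa) + D_b/Dx_b(fa) = psi for fa by bracketed root finding
    on (0, 1); the left side is strictly decreasing in fa, so the root is
    unique.  psi = 1 is Loewe additivity; the ground-truth CI equals psi at
    every effect level.
    """
    if dose_a < 0 or dose_b < 0 or dose_a + dose_b == 0:
        raise InvalidInputError("doses must be >= 0 and not both 0")
    if psi <= 0:
        raise InvalidInputError("psi must be > 0")

    def excess(fa: float) -> float:
        total = 0.0
        if dose_a > 0:
            total += dose_a / dose_for_effect(truth_a, fa)
        if dose_b > 0:
            total += dose_b / dose_for_effect(truth_b, fa)
        return total - psi

    lo, hi = 1e-12, 1.0 - 1e-12
    f_lo, f_hi = excess(lo), excess(hi)
    if f_lo <= 0:  # even a vanishing effect over-satisfies: fa below bracket
        return lo
    if f_hi >= 0:  # effect saturates: fa above bracket
        return hi
    return float(brentq(excess, lo, hi, xtol=1e-14, rtol=8.9e-16))


def simulate_combination_plate(
    truth_a: DrugGroundTruth,
    truth_b: DrugGroundTruth,
    ratio: MixtureRatio,
    psi: float,
    design: PlateDesign,
    noise: NoiseModel,
) -> list[WellRecord]:
    """Simulate a constant-ratio combination plate on the psi-interaction surface.

    Each total dose of the serial dilution is split into component doses by
    the mixture ratio; the true fraction affected comes from
    :func:`loewe_additive_effect`, and counts are drawn as for single-drug
    plates.  Running the analysis pipeline on noiseless output recovers
    CI = psi (exactly when the components share the shape m).
    """
    rng = np.random.default_rng(noise.seed)
    wells: list[WellRecord] = []
    for i, total in enumerate(design.doses):
        dose_a, dose_b = component_doses(total, ratio)
        fa_true = loewe_additive_effect(truth_a, truth_b, dose_a, dose_b, psi)
        p = _death_probability(fa_true, noise)
        for rep in range(design.replicates):
            dead = _draw_dead(p, design.cells_per_well, noise, rng)
            wells.append(
                WellRecord(
                    drug_a_dose=dose_a,
                    drug_b_dose=dose_b,
                    total_cells=design.cells_per_well,
                    dead_cells=dead,
                    well_label=f"{ratio.label}_d{i}_r{rep}",
                )
            )
    wells.extend(_control_wells(design, noise, rng))
    return wells
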