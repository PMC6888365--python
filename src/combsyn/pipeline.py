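"""Pipeline driver: plates in, fit/ICx/selectivity/synergy tables out.

A run is described by a YAML (or plain dict) config with any of these blocks:

``plates``
    List of plate CSV paths (schema in :mod:`combsyn.plate_io`).
``simulate``
    Synthetic-data block: two drug ground truths, an interaction psi, mixture
    ratios, design and noise settings.  Simulated plates are written next to
    the other outputs so a run is self-documenting.
``two_point_fits``
    Worked-example mode: per drug, two printed (fa, dose) anchors that pin an
    exact median-effect model without raw plate data.
``selectivity``
    Target line, comparator lines, and (optionally) an explicit IC50 table
    with ">" prefixes for censored entries; otherwise IC50s come from the
    fitted Dm values.
``fa_levels``
    Effect levels for the ICx and synergy tables (default 0.10/0.25/0.50/0.75).

Outputs: ``fits.csv``, ``icx.csv``, ``selectivity.csv``, ``synergy.csv``,
``report.txt`` and ``run.log`` in the configured output directory.  The run
is deterministic given config + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .combination import (
    DEFAULT_FA_LEVELS,
    MixtureRatio,
    SynergyProfile,
    synergy_profile,
)
from .errors import CombsynError, InvalidInputError
from .median_effect import (
    MedianEffectFit,
    dose_for_effect,
    fit_from_two_effects,
    fit_median_effect,
    linearize,
    points_from_wells,
)
from .plate_io import PlateTable, plate_from_wells, read_plate_csv, write_plate_csv
from .selectivity import CensoredIC50, selectivity_matrix
from .simulate import (
    DrugGroundTruth,
    NoiseModel,
    PlateDesign,
    simulate_combination_plate,
    simulate_single_drug_plate,
)

__all__ = ["PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineResult:
    """Bundle of the tables a pipeline run produced."""

    fits: pd.DataFrame
    icx: pd.DataFrame
    selectivity: pd.DataFrame | None
    synergy: pd.DataFrame | None
    profiles: list[SynergyProfile] = field(default_factory=list)
    log: list[str] = field(default_factory=list)
    output_dir: Path | None = None


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"config {path} did not parse to a mapping")
    return cfg


def _stage(name: str):
    """Decorator labelling stage errors so failures say where they happened."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CombsynError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc

        return inner

    return wrap


def _parse_ic50(raw: Any) -> CensoredIC50:
    if isinstance(raw, str) and raw.startswith(">"):
        return CensoredIC50(float(raw[1:]), censored=True)
    return CensoredIC50(float(raw))


def _fit_table(fits: Mapping[str, MedianEffectFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": name,
                "m": f.m,
                "Dm": f.Dm,
                "r": f.r,
                "n_points": f.n_points,
                "dose_min": f.dose_range[0],
                "dose_max": f.dose_range[1],
                "non_monotone": f.non_monotone,
            }
            for name, f in fits.items()
        ]
    )


def _icx_table(
    fits: Mapping[str, MedianEffectFit], fa_levels: list[float]
) -> pd.DataFrame:
    rows = []
    for name, f in fits.items():
        row: dict[str, Any] = {"drug": name}
        for fa in fa_levels:
            row[f"IC{round(fa * 100):d}_uM"] = dose_for_effect(f, fa)
        rows.append(row)
    return pd.DataFrame(rows)


@_stage("simulate")
def _run_simulation(block: Mapping[str, Any], seed: int, out_dir: Path | None,
                    log: list[str]) -> list[PlateTable]:
    truth_a = DrugGroundTruth(**block["drug_a"])
    truth_b = DrugGroundTruth(**block["drug_b"]) if "drug_b" in block else None
    psi = float(block.get("psi", 1.0))
    noise_cfg = dict(block.get("noise", {}))
    cell_line = block.get("cell_line", "simulated")
    time_h = float(block.get("time_h", 48))
    design_cfg = dict(block.get("design", {}))
    reps = int(design_cfg.get("replicates", 3))
    cells = int(design_cfg.get("cells_per_well", 2000))
    factor = float(design_cfg.get("dilution_factor", 2.0))

    children = np.random.SeedSequence(seed).spawn(16)
    next_child = iter(children)

    def noise() -> NoiseModel:
        child_seed = int(next(next_child).generate_state(1)[0] % 2**31)
        return NoiseModel(seed=child_seed, **noise_cfg)

    plates: list[PlateTable] = []
    truths = [t for t in (truth_a, truth_b) if t is not None]
    slots = ["a", "b"]
    for truth, slot in zip(truths, slots):
        design = PlateDesign(
            top_dose=float(design_cfg.get("single_top_ic50_multiple", 16)) * truth.Dm,
            dilution_factor=factor,
            n_doses=int(design_cfg.get("single_n_doses", 6)),
            replicates=reps,
            cells_per_well=cells,
        )
        wells = simulate_single_drug_plate(truth, design, noise(), drug_slot=slot)
        drug_a = truth.name if slot == "a" else ""
        drug_b = truth.name if slot == "b" else ""
        plates.append(
            plate_from_wells(wells, f"sim_{truth.name}", cell_line, time_h,
                             drug_a=drug_a, drug_b=drug_b)
        )
        log.append(f"simulated single-drug plate for {truth.name}")

    if truth_b is not None:
        for k_a, k_b in block.get("ratios", []):
            ratio = MixtureRatio.from_ic50s(k_a, k_b, truth_a.Dm, truth_b.Dm)
            unit = k_a * truth_a.Dm + k_b * truth_b.Dm
            design = PlateDesign(
                top_dose=float(design_cfg.get("combo_top_unit_multiple", 4)) * unit,
                dilution_factor=factor,
                n_doses=int(design_cfg.get("combo_n_doses", 7)),
                replicates=reps,
                cells_per_well=cells,
            )
            wells = simulate_combination_plate(truth_a, truth_b, ratio, psi,
                                               design, noise())
            plates.append(
                plate_from_wells(wells, f"sim_combo_{ratio.label}", cell_line,
                                 time_h, drug_a=truth_a.name, drug_b=truth_b.name)
            )
            log.append(f"simulated combination plate at ratio {ratio.label}, psi={psi}")

    if out_dir is not None:
        plate_dir = out_dir / "plates"
        plate_dir.mkdir(parents=True, exist_ok=True)
        for p in plates:
            write_plate_csv(p, plate_dir / f"{p.frame.plate_id.iloc[0]}.csv")
    return plates


@_stage("fit")
def _fit_single_drugs(
    plates: list[PlateTable], log: list[str]
) -> dict[str, MedianEffectFit]:
    fits: dict[str, MedianEffectFit] = {}
    for plate in plates:
        df = plate.frame
        treated = df[(df.dose_a_uM > 0) | (df.dose_b_uM > 0)]
        if len(treated) == 0 or ((treated.dose_a_uM > 0) & (treated.dose_b_uM > 0)).any():
            continue  # combination plate or empty; handled elsewhere
        drug = treated.drug_a.iloc[0] if (treated.dose_a_uM > 0).any() else treated.drug_b.iloc[0]
        points = points_from_wells(plate.records())
        plot = linearize(points)
        for p in plot.excluded:
            log.append(f"excluded point (drug={drug}, dose={p.dose:g} uM, fa={p.fa:g})")
        fit = fit_median_effect(points, name=str(drug))
        fits[str(drug)] = fit
        log.append(
            f"fit {drug}: m={fit.m:.4f} Dm={fit.Dm:.4g} uM r={fit.r:.4f} "
            f"n={fit.n_points}"
        )
    return fits


@_stage("combine")
def _analyze_combinations(
    plates: list[PlateTable],
    fits: Mapping[str, MedianEffectFit],
    fa_levels: list[float],
    log: list[str],
) -> tuple[pd.DataFrame | None, list[SynergyProfile]]:
    frames = []
    profiles = []
    for plate in plates:
        df = plate.frame
        combo = df[(df.dose_a_uM > 0) & (df.dose_b_uM > 0)]
        if len(combo) == 0:
            continue
        drug_a, drug_b = str(combo.drug_a.iloc[0]), str(combo.drug_b.iloc[0])
        if drug_a not in fits or drug_b not in fits:
            raise InvalidInputError(
                f"combination plate needs single-drug fits for {drug_a} and {drug_b}"
            )
        frac = combo.dose_a_uM / (combo.dose_a_uM + combo.dose_b_uM)
        if np.ptp(frac.to_numpy()) > 1e-9:
            raise InvalidInputError(
                f"plate {combo.plate_id.iloc[0]}: not a constant-ratio design "
                "(checkerboard layouts are not supported)"
            )
        fit_a, fit_b = fits[drug_a], fits[drug_b]
        # Express the ratio label as IC50 multiples of the single-agent fits.
        f_a = float(frac.iloc[0])
        k_a, k_b = f_a / fit_a.Dm, (1 - f_a) / fit_b.Dm
        scale = min(k_a, k_b)
        label = f"{k_a / scale:.2g}:{k_b / scale:.2g}"
        ratio = MixtureRatio(label=label, multiples=(k_a, k_b), fraction_a=f_a)
        points = points_from_wells(plate.records())
        plot = linearize(points)
        for p in plot.excluded:
            log.append(
                f"excluded point (mixture {label}, dose={p.dose:g} uM, fa={p.fa:g})"
            )
        fit_mix = fit_median_effect(points, name=f"{drug_a}+{drug_b} {label}")
        profile = synergy_profile(fit_a, fit_b, fit_mix, ratio, fa_levels)
        profiles.append(profile)
        frames.append(profile.to_frame())
        for row in profile.rows:
            if row.extrapolated:
                log.append(
                    f"extrapolated CI (mixture {label}, fa={row.fa:g}): total dose "
                    "outside fitted range"
                )
        log.append(f"synergy profile for mixture {label} vs fits {drug_a}/{drug_b}")
    if not frames:
        return None, []
    return pd.concat(frames, ignore_index=True), profiles


@_stage("selectivity")
def _selectivity(
    block: Mapping[str, Any],
    fits_by_line: Mapping[str, Mapping[str, MedianEffectFit]] | None,
    log: list[str],
) -> pd.DataFrame:
    target = block["target_line"]
    comparators = block.get("comparators")
    if "ic50s" in block:
        table = {
            drug: {line: _parse_ic50(v) for line, v in by_line.items()}
            for drug, by_line in block["ic50s"].items()
        }
    else:
        if not fits_by_line:
            raise InvalidInputError("selectivity needs an ic50s table or per-line fits")
        table = {
            drug: {line: CensoredIC50(fit.Dm) for line, fit in by_line.items()}
            for drug, by_line in fits_by_line.items()
        }
    matrix = selectivity_matrix(table, target_line=target, comparator_lines=comparators)
    log.append(f"selectivity matrix vs {target}: {matrix.shape[0]} treatments")
    return matrix


def run_pipeline(
    config: Mapping[str, Any] | str | Path, output_dir: str | Path | None = None
) -> PipelineResult:
    """Run the full analysis described by ``config``; see module docstring."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    fa_levels = [float(x) for x in cfg.get("fa_levels", DEFAULT_FA_LEVELS)]
    out_dir = Path(output_dir or cfg.get("output_dir", "combsyn_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    log: list[str] = [
        f"combsyn {__version__} (numpy {np.__version__}, pandas {pd.__version__})",
        f"seed: {seed}",
        f"fa_levels: {fa_levels}",
    ]

    plates: list[PlateTable] = [read_plate_csv(p) for p in cfg.get("plates", [])]
    if plates:
        log.append(f"loaded {len(plates)} plate CSV(s)")
    if "simulate" in cfg:
        plates.extend(_run_simulation(cfg["simulate"], seed, out_dir, log))

    fits = _fit_single_drugs(plates, log)
    for drug, anchors in cfg.get("two_point_fits", {}).items():
        fits[drug] = fit_from_two_effects(
            (float(anchors["fa1"]), float(anchors["dose1"])),
            (float(anchors["fa2"]), float(anchors["dose2"])),
            name=drug,
        )
        log.append(f"two-point fit {drug}: m={fits[drug].m:.4f} Dm={fits[drug].Dm:.4g}")

    fits_df = _fit_table(fits)
    icx_df = _icx_table(fits, fa_levels)

    synergy_df, profiles = _analyze_combinations(plates, fits, fa_levels, log)

    sel_df = None
    if "selectivity" in cfg:
        sel_df = _selectivity(cfg["selectivity"], None, log)

    fits_df.to_csv(out_dir / "fits.csv", index=False)
    icx_df.to_csv(out_dir / "icx.csv", index=False)
    if sel_df is not None:
        sel_df.to_csv(out_dir / "selectivity.csv")
    if synergy_df is not None:
        synergy_df.to_csv(out_dir / "synergy.csv", index=False)

    report = ["# combsyn analysis report", "", "## Median-effect fits",
              fits_df.to_string(index=False), "", "## ICx table (uM)",
              icx_df.to_string(index=False)]
    if sel_df is not None:
        report += ["", "## Selectivity indices", sel_df.to_string()]
    if synergy_df is not None:
        report += ["", "## Synergy (CI / DRI) profile", synergy_df.to_string(index=False)]
    (out_dir / "report.txt").write_text("\n".join(report) + "\n", encoding="utf-8")
    (out_dir / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")

    return PipelineResult(
        fits=fits_df, icx=icx_df, selectivity=sel_df, synergy=synergy_df,
        profiles=profiles, log=log, output_dir=out_dir,
    )
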