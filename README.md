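# combsyn

Median-effect dose-response modelling and drug-combination synergy analysis
for cytotoxicity plate data.

`combsyn` is for pharmacology and drug-discovery work that asks whether two
cytotoxic agents act synergistically — the worked examples throughout are
the 5-aminopyrazole derivative BC-7 combined with cisplatin against HeLa
cells. It takes per-well viability counts (total and dead cells from a
Hoechst 33342/PI dual stain, one well per CSV row), and produces:

- **median-effect fits** per drug: shape `m`, median-effect dose `Dm` (the
  IC50), and the plot correlation `r`, from OLS on the linearized plot
  `log10(fa/fu) = m·log10 D − m·log10 Dm` (with `fa` the fraction of cells
  killed, `fu = 1 − fa`);
- **ICx interpolation** via `Dx = Dm (fa/fu)^(1/m)`;
- **combination-index / dose-reduction-index profiles** of constant-ratio
  mixtures: `CI = D₁/Dx₁ + D₂/Dx₂` (CI < 1 synergism, = 1 additive, > 1
  antagonism), `DRIᵢ = Dxᵢ/Dᵢ` (> 1 favourable), with banded classification;
- **selectivity indices** between cell lines, `SI = IC50(comparator) /
  IC50(target)`, with right-censored IC50s (">200 μM") propagated as
  one-sided bounds and SI < 2 flagged as general toxicity;
- a **seeded synthetic plate generator** whose combination surface inverts
  the CI definition, so the ground-truth CI is a single knob `psi` — used to
  validate the whole pipeline end to end.

## Worked example

The published HeLa ICx table regenerates from each drug's printed IC50/IC75
pair alone — evidence the table is internally consistent with the
median-effect model:

```python
from combsyn import fit_from_two_effects, dose_for_effect

cis = fit_from_two_effects((0.50, 1.675), (0.75, 8.194))   # printed IC50, IC75
print(round(cis.m, 4), round(dose_for_effect(cis, 0.25), 3))
```

prints `0.692 0.342` — the back-derived shape and the IC25 in μM (printed
value 0.342). Running `python analysis/01_fit_dose_response.py` prints the
full check:

```
cisplatin: m = 0.6920, Dm = 1.675 uM
  IC25 model 0.3424 vs printed 0.342
  IC10 model 0.06999 vs printed 0.069
BC-7: m = 1.7356, Dm = 65.58 uM
  IC25 model 34.82 vs printed 34.83
  IC10 model 18.49 vs printed 18.5
```

The synergy grid re-derived from the published DRI pairs
(`python analysis/03_synergy_profile.py`) classifies every cisplatin:BC-7
mixture as synergistic at 10–50% kill (e.g. ratio 1:3 at 10% kill: CI 0.21,
strong synergism) and shows the BC-7-heavy mixtures turning antagonistic at
75% kill, where BC-7's DRI falls below 1.

## Analysis scripts

Numbered drivers under `analysis/` reproduce the package's result tables
into `results/`:

| script | writes |
|---|---|
| `01_fit_dose_response.py` | median-effect fits and the regenerated ICx table |
| `02_selectivity.py` | the selectivity matrix across Vero/MRHF/MeWo/HepG2 |
| `03_synergy_profile.py` | the CI/DRI grid with classifications and the constant-ratio consistency check |
| `04_simulation_study.py` | generator/analyzer duality and parameter-recovery error vs replicates |

There is also a CLI (`combsyn simulate | fit | icx | combine | selectivity |
report`) whose stages read and write files so they compose in shell
pipelines, and a YAML-config pipeline driver (`combsyn.pipeline.run_pipeline`)
that emits fits, ICx, selectivity and synergy tables plus a run log in one
call.

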