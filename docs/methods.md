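# Methods

## Scope and model

`combsyn` quantifies cytotoxic drug interactions from dual-stain (total vs
dead nuclei) viability plate counts. The core model is the median-effect
equation of mass-action pharmacodynamics:

    fa / fu = (D / Dm)^m,        fu = 1 - fa

where `fa` is the fraction of cells affected (killed) at dose `D` (μM), `Dm`
is the median-effect dose (the model IC50), and `m` is the sigmoidicity of
the dose-effect curve (`m = 1` hyperbolic, larger is steeper). Taking log10
of both sides gives the median-effect plot, `log10(fa/fu)` vs `log10 D`,
which is fitted by unweighted ordinary least squares; the slope is `m`, the
intercept `-m log10 Dm`, and the Pearson correlation `r` of the plot is the
conformity check to the mass-action law. Dose and effect interconvert via

    Dx = Dm (fa/fu)^(1/m)        and        fa = 1 / (1 + (Dm/D)^m).

Two-drug constant-ratio mixtures (component concentrations fixed at
multiples of the drugs' IC50s, total dose serially diluted) are refit as a
single agent on total concentration. At each effect level `fa` the
combination index

    CI = D_1/Dx_1 + D_2/Dx_2

compares the component doses in the mixture producing `fa` against the
single-agent doses producing the same `fa` (Loewe-additivity reference:
CI < 1 synergism, = 1 additive, > 1 antagonism), and the dose-reduction
index `DRI_i = Dx_i / D_i` is the fold-reduction of drug i achievable at
equal effect (DRI > 1 favourable). `CI = Σ 1/DRI_i` is an algebraic identity
used as an internal consistency check. Selectivity between cell lines is
`SI = IC50(comparator) / IC50(target)`; SI < 2 (strict) flags general
toxicity, and right-censored IC50s (">200 μM": 50% kill never reached)
propagate as one-sided bounds, reported with a ">" prefix, never as point
estimates.

## Data handling choices

- **Background correction.** Fraction affected is normalized against the
  pooled untreated-control death fraction,
  `fa = (dead/total - c) / (1 - c)`, clipped to [0, 1]; this reduces to the
  raw dead fraction when controls show no death. Control wells are pooled
  per plate.
- **Boundary effects.** Points with fa exactly 0 or 1 have no finite
  coordinate on the median-effect plot; they are excluded from the
  regression and logged, rather than clipped (an optional epsilon-clip
  exists for exploratory use but defaults off, to avoid pseudo-count bias in
  the slope).
- **Replicates** are averaged per dose before linearization.
- **Logarithms** are base-10 on both axes; the slope is base-invariant only
  when both axes share the base.
- **No 4PL refit.** One model serves single drugs and mixtures uniformly;
  the published ICx tables this package reproduces are internally consistent
  with the median-effect form (IC25 x IC75 = IC50² holds at printed
  precision), so a separate four-parameter logistic stage would add a second
  dose-response convention without improving the worked examples.
- **Extrapolation.** `Dx` is computed at any `fa` in (0, 1) but rows whose
  dose leaves the fitted dose range are flagged `extrapolated` — the model
  extrapolates silently otherwise.
- **Non-constant-ratio (checkerboard) combination layouts are rejected**
  with an explicit error; the CI machinery here is the constant-ratio
  single-agent-refit method only.
- Two-drug mixtures are the tested scope; the CI sum generalizes to n
  components and `ci_from_dri` accepts any length.

## Synthetic plate generator

The generator emulates the statistical structure of a Hoechst 33342/PI
high-content viability readout, not the images themselves: per well a total
cell count and a binomially sampled dead count. Defaults define the study
conditions:

| parameter | default | meaning |
|---|---|---|
| ground truths | m 0.6919/Dm 1.675 μM; m 1.7356/Dm 65.58 μM | cisplatin-like and BC-7-like HeLa parameters, back-derived from the printed IC50/IC75 pairs |
| `control_death_fraction` | 0.05 | spontaneous death in untreated wells; treated wells die with probability `c + (1-c) fa_true` |
| `dilution_factor` | 2 | serial dilution step (the source protocol states serial dilution without the factor) |
| `n_doses` | 6 single-drug, 7 combination | matches the 6-point single-agent and 7-point combination designs |
| `replicates` | 3 | per-dose wells, matching n = 3 experiment conventions |
| `cells_per_well` | 2000 | analyzed cells per imaged well; a stand-in (the true post-growth count is unknown), chosen as a plausible high-content count after 48 h from 5000 seeded |
| `count_noise` | binomial | per-well dead ~ Binomial(cells, p); `beta-binomial` with intra-class correlation ρ adds well-to-well heterogeneity; `expectation` is the deterministic mode (dead = p·cells exactly, possibly fractional) used to separate model correctness from sampling noise |

Combination ground truth lives on an interaction surface that inverts the CI
definition: `fa(D_a, D_b)` solves `D_a/Dx_a(fa) + D_b/Dx_b(fa) = psi` by
bracketed root finding (Brent, xtol 1e-14) on (0, 1), unique because the
left side is strictly decreasing in fa. By construction the ground-truth CI
equals `psi` at every effect level: psi = 1 is exact Loewe additivity,
psi < 1 synergy, psi > 1 antagonism. All randomness flows through one
integer seed (PCG64); identical config + seed reproduces a plate exactly.

What the generator does **not** emulate: time-dependence of cytotoxicity
(each exposure time is an independent dataset), spatial plate effects (edge
wells, gradients), segmentation errors in imaging, and dose-preparation
error. Passing tests therefore demonstrate correctness of the estimators
under the assumed counting model, not robustness to every failure mode of
real plates.

## Exactness of the generator/analyzer duality

For noiseless data the pipeline returns CI = psi to numerical precision
**when the two components share the shape m**: the constant-ratio mixture is
then itself a median-effect curve (all Dx are proportional), the linearized
fit is exact, and the inverse pair closes. With unequal shapes — including
the study-like pair 0.69 vs 1.74 — the mixture is only approximately
median-effect; the OLS line through the 7-point series carries systematic
curvature error, and the recovered CI tracks psi within about 0.1 at the
25–75% effect levels but can drift by several tenths at the 10% tail
(measured in `analysis/04_simulation_study.py`). This is a property of the
constant-ratio method itself, not of the implementation; the exactness test
uses shared-shape components and the unequal-shape model error is asserted
at its measured bound.

## Numerical choices

- OLS and Pearson r via `scipy.stats.linregress`; root finding via
  `scipy.optimize.brentq`.
- A fitted slope ≤ 0 does not raise: the fit is returned with a
  `non_monotone` warning flag (dose/effect interconversion then refuses to
  run on it). A single distinct dose raises a degenerate-design error.
- CI/DRI values are reported rounded to 2 decimals (table convention) with
  full precision retained internally; re-summing published 2-3 significant
  digit DRIs reproduces published CI values to about one unit in the second
  decimal, the drift coming from rounding before summation.
- The published CI grid is taken in the table's own ratio order; a prose
  passage elsewhere lists the 50%-kill CI values of the 1:1/2:1/3:1 mixtures
  in the opposite order, a discrepancy documented here and not resolved.
- Problem sizes in tests and drivers: parameter recovery uses 100 seeded
  simulations per replicate level, the stochastic CI check 10 seeds — enough
  for stable medians while keeping the default suite around a second.

## Known limitations

- ICx confidence intervals (bootstrap over wells) are not implemented.
- Normal-cell CI profiling (combination selectivity) is out of scope.
- Bliss/HSA/ZIP reference models are deliberately absent; the package is a
  median-effect/Loewe instrument.
- The "n.d." selectivity cell (both IC50s censored, or target censored
  alone) is reported, never silently approximated.
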