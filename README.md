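# maculasum

Spatial-summation modelling of the glaucomatous macula: does functional loss
behave like an enlargement of Ricco's area?

Perimetric sensitivity in the macula depends on how the visual system pools
("summates") retinal input over the stimulus area. Below a critical amount of
total retinal input the log-log slope of sensitivity versus input is 1
(complete summation, the Ricco regime); above it the slope falls to a partial
value. When glaucoma removes retinal ganglion cells (RGCs), two competing
accounts of the measured sensitivity loss exist:

* **H1 — spatial scale changes (Ricco's area enlarges).** The reduced retinal
  input moves the operating point *horizontally* along a fixed summation
  template; the apparent loss then depends on stimulus size.
* **H2 — pure sensitivity loss.** The template shifts *vertically*; the loss
  is the same at every stimulus size.

`maculasum` implements the full analysis as a tested pipeline for
biostatisticians and visual-field researchers:

1. **Summation template** `S(u) = 10α + x − 10(1 − 1/κ)·log₁₀(1 + 10^{x/10})`
   with `x = u − 10·log₁₀τ`, where `u` is the total retinal input in dB
   (10·log₁₀ of stimulus area × duration × parasol-OFF RGC density ×
   cone-to-RGC convergence ratio). `α` is the vertical offset, `τ` the
   complete-to-partial transition input and `1/κ` the partial-summation
   slope. The template is calibrated on young-healthy data by multistart
   Nelder–Mead least squares with eye-level bootstrap CIs.
2. **Structural RGC estimates**: GCL thickness maps → local parasol-OFF
   density (histology profile tables), stimulus footprints displaced and
   distorted for RGC displacement, counts by polygon quadrature — all in
   visual degrees.
3. **Bayesian hierarchical censored fit**: per-location latent density (H1)
   or vertical offset (H2) as nested Gaussian random effects
   (population → eye → location), Tobit-type left-censoring at 0 dB,
   adaptive Metropolis-within-Gibbs sampling with ArviZ convergence
   diagnostics.
4. **Evaluation**: R²/RMSE by severity group, paired subject-level bootstrap
   comparison of H1 vs H2, dynamic ranges (1st–99th percentile width) of
   structural vs functional density estimates, edge-of-scotoma flags, and
   structure-function prediction errors.
5. **Synthetic cohort**: because the clinical data are not public, a
   first-class generator reproduces the study design (29 young healthy eyes,
   20 age-similar controls, 10 glaucoma eyes per MD-staged severity group,
   six 10-2 tests per eye across five Goldmann sizes G-I–G-V, heteroscedastic
   test-retest noise, sharp-edged scotomas, a residual-tissue structural
   floor), so every stage is testable end to end.

## Worked example

```python
from maculasum import RunConfig, StudyConfig, McmcSettings, run_pipeline

config = RunConfig(
    study=StudyConfig(n_young=4, n_controls=4, n_per_glaucoma_stage=2),
    mcmc=McmcSettings(chains=2, warmup=300, samples=300),
    out_dir="example-run", seed=7,
)
run_pipeline(config)
```

This simulates a 14-eye study, calibrates the template on the young cohort,
fits both hypotheses and writes `evaluation.json` (about 20 s on one CPU).
Key numbers from that run:

```
calibration:       alpha=1.14  log10_tau=3.11  kappa=2.27  (residual RMSE 4.36 dB)
goodness of fit:   H1 R²=71.4%, RMSE=4.22 dB   |   H2 R²=70.1%, RMSE=4.32 dB
model comparison:  RMSE improvement 2.3% [1.3, 3.3], p < 0.002 in favour of H1
structure-function RMSE: all locations 6.00 dB, G-I-preserved subset 4.72 dB
dynamic-range ratio (structural/functional): advanced 0.13, moderate 0.19, early 0.46
```

Reading these: the horizontal-shift (Ricco's-area change) model fits the
perimetric data better than the vertical-shift model at every severity, the
paired bootstrap puts the RMSE reduction clearly away from zero, and the
structural estimates retain only a small fraction of the functional dynamic
range in moderate/advanced disease — the residual-tissue floor at work.
Structure-based sensitivity predictions improve markedly when restricted to
locations whose G-I sensitivity shows density still above the floor.

A command-line interface wraps the same stages:

```sh
maculasum run --seed 7 --out example-run
maculasum simulate --seed 3 --out observations.csv
```

## Layout

```
src/maculasum/summation_template.py   template, calibration, bootstrap
src/maculasum/structural_rgc.py       thickness→density, displaced footprints, counts
src/maculasum/synthetic_cohort.py     study generator (truth + observations)
src/maculasum/hierarchical_fit.py     censored hierarchical model + sampler
src/maculasum/evaluation.py           R²/RMSE, bootstrap, dynamic range, edge flags
src/maculasum/io_cli.py               CSV/YAML/JSON interchange, pipeline, CLI
src/maculasum/profiles/               editable eccentricity profile tables (CSV)
docs/methods.md                       model, assumptions, parameter choices
```

See `docs/methods.md` for the model details, the synthetic-data assumptions,
and known limitations.
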