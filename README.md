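# chemcal

A multivariate UV-spectral calibration toolkit for simultaneous
quantification of spectrally overlapped analytes. It covers the full
chemometric workflow for a three-component system (cinnarizine,
domperidone and the degradation product benzophenone as the reference
use case):

- **Experimental design** (`chemcal.design`): cyclic multilevel
  multifactor calibration designs (25 runs for 3 factors at 5 levels),
  D-optimal validation-set selection by Fedorov-type row exchange
  maximising det(X'X), design diagnostics, and exact solution-preparation
  (dissolution/dilution) arithmetic.
- **Spectra simulation** (`chemcal.spectra`): Gaussian-band pure-component
  UV spectra on a 220-300 nm / 1 nm grid (81 points), Beer-Lambert
  bilinear mixing `D = C S + E` with seeded Gaussian noise and baseline,
  and instrument perturbations (wavelength interval, slit bandwidth,
  scan-speed noise) for robustness studies.
- **Calibration engines** (`chemcal.cls_model`, `chemcal.pls_model`,
  `chemcal.mcr`): K-matrix classical least squares with optional
  intercept and cross-validated moving-average window selection; NIPALS
  PLS2 with venetian-blinds / leave-one-out RMSECV latent-variable
  selection (global-minimum and parsimonious-F rules); constrained
  MCR-ALS with evolving-factor-analysis initialisation, non-negativity,
  closure, unimodality, selectivity and reference-spectrum correlation
  constraints, plus an augmented-matrix quantification path.
- **Figures of merit** (`chemcal.fom`): RMSEC/RMSECV/RMSEP, bias, SEC,
  RRMSEP, bias-corrected RMSEP, recovery statistics, recovery t-test,
  net-analyte-signal LOD/LOQ, linearity and one-way ANOVA.
- **Diagnostics** (`chemcal.diagnostics`): elliptical joint confidence
  region for slope/intercept, cosine similarity, rotational-ambiguity
  feasible bands (multi-start optimisation with a dense grid fallback
  for two-component systems) and local-rank mapping.
- **Pipeline + CLI** (`chemcal.pipeline`, `chemcal.cli`): a reproducible
  end-to-end run (design → simulate → fit all three models → validate →
  diagnostics) driven by a YAML config with explicit seeds.

## CLI

```sh
# 25-run calibration design over the working ranges
chemcal design calib --ranges 4:20,3:15,1:5 --levels 5 --out calib.csv

# 13-run D-optimal validation set (full quadratic model, 20 starts)
chemcal design dopt --ranges 4:20,3:15,1:5 --n 13 --model quadratic \
    --starts 20 --seed 1 --out valid.csv

# simulate mixture spectra, then fit and predict
chemcal simulate --design calib.csv --noise-sd 0.003 --seed 1 --out spectra.csv
chemcal fit --model pls --calib-spectra spectra.csv --calib-conc calib.csv \
    --out predictions.csv
chemcal validate --true-conc calib.csv --pred-conc predictions.csv --out fom.json

# full end-to-end run
chemcal run --seed 1 --out run_out
```

## Notes

- Measured spectra for the reference system are not published, so all
  spectral data are synthetic stand-ins generated by `chemcal.spectra`;
  published table values that depend on the measured spectra are not
  reproduction targets.
- The published 25-run calibration table and 13-mixture validation table
  are shipped in `chemcal.reference` and used as fixtures.
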