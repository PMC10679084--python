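# leukomr

Two-sample and multivariable Mendelian randomization (MR) of blood
leukocyte counts on rheumatoid arthritis risk, built as a reusable Python
library plus a numbered analysis pipeline, with a synthetic GWAS
summary-statistics generator so every stage runs and is testable without
downloading GWAS data.

## Who this is for

Genetic epidemiologists who want a transparent, fully tested summary-data
MR stack: instrument selection, harmonization, the standard estimator
suite, outlier diagnostics, and multivariable MR — driven by plain TSV
summary statistics and reproducible seeds.

## The statistical core

For SNP *j* with exposure association β̂<sub>Xj</sub> (SE se<sub>Xj</sub>)
and outcome association β̂<sub>Yj</sub> (SE se<sub>Yj</sub>) on the
log-odds scale, the per-SNP Wald ratio is
θ̂<sub>j</sub> = β̂<sub>Yj</sub>/β̂<sub>Xj</sub> with first-order SE
se<sub>Yj</sub>/|β̂<sub>Xj</sub>|.

* **IVW** — θ̂ = Σw<sub>j</sub>θ̂<sub>j</sub>/Σw<sub>j</sub>,
  w<sub>j</sub> = 1/se<sub>j</sub>²; fixed SE (Σw<sub>j</sub>)<sup>−1/2</sup>;
  Cochran's Q = Σw<sub>j</sub>(θ̂<sub>j</sub> − θ̂)² on J−1 df; the
  random-effects model inflates the SE by φ = max(1, √(Q/(J−1)))
  (multiplicative overdispersion).
* **MR-Egger** — weighted regression of β̂<sub>Yj</sub> on β̂<sub>Xj</sub>
  *with* intercept (weights 1/se<sub>Yj</sub>², rows oriented so
  β̂<sub>Xj</sub> ≥ 0); the intercept estimates average directional
  pleiotropy, the slope the causal effect under InSIDE; t inference on
  J−2 df.
* **Weighted median** — the ratio at cumulative standardized weight 1/2,
  consistent when ≥50% of the weight comes from valid instruments; SE by
  seeded parametric bootstrap.
* **MR-PRESSO** — simulation-based global residual-sum test, per-SNP
  outlier test (Bonferroni across instruments), and distortion test with
  the outlier-corrected IVW estimate.
* **MVMR** — weighted regression of β̂<sub>Yj</sub> on the J×K matrix of
  exposure effects (no intercept), giving *direct* effects per exposure,
  with Q<sub>A</sub> heterogeneity on J−K df and per-exposure conditional
  F statistics.

Instrument selection follows the standard workflow: genome-wide
significance (p < 5×10⁻⁸), greedy LD clumping (r² < 0.01 within
10,000 kb against a supplied LD sidecar), confounder-list exclusion,
unconditional removal of palindromic (A/T, C/G) SNPs, and mean
F = mean{(β̂/se)²} ≥ 10 as the weak-instrument bar. Estimates are reported
as odds ratios with 95% CIs, Bonferroni-corrected at 0.05/6 across the six
leukocyte traits.

## Worked example

The numbered scripts under `analysis/` run the whole design on simulated
data (six correlated leukocyte traits, only the eosinophil analogue truly
causal with θ = 0.3, exposure correlation 0.25):

```bash
python analysis/01_simulate_study.py
python analysis/02_select_instruments.py
python analysis/03_univariable_mr.py
python analysis/04_presso.py
python analysis/05_mvmr.py
python analysis/06_report.py
python analysis/07_operating_characteristics.py
```

Step 03 prints the univariable estimates (random-effects IVW):

```
 eosinophil: OR 1.338 (1.281-1.397), p = 5.74e-40, J = 73, Q p = 0.14, Egger intercept p = 0.384
 lymphocyte: OR 1.015 (0.961-1.072), p = 0.587, J = 79, Q p = 2.08e-11, Egger intercept p = 0.964
 neutrophil: OR 1.087 (1.030-1.148), p = 0.0024, J = 79, Q p = 3.28e-11, Egger intercept p = 0.976
   monocyte: OR 1.065 (1.013-1.120), p = 0.0135, J = 74, Q p = 5.7e-07, Egger intercept p = 0.879
   basophil: OR 1.102 (1.049-1.158), p = 0.000124, J = 75, Q p = 1.37e-09, Egger intercept p = 0.852
        wbc: OR 1.092 (1.035-1.151), p = 0.00114, J = 83, Q p = 8.7e-15, Egger intercept p = 0.666
```

Because the traits are correlated, three null traits inherit significant
univariable (total) effects from the causal one. Step 05 then shows what
multivariable MR adds — holding the other traits fixed, only the truly
causal trait keeps a direct effect:

```
 eosinophil: direct OR 1.369 (1.281-1.462), p = 1.5e-20, conditional F = 119.3
 lymphocyte: direct OR 0.985 (0.934-1.040), p = 0.59,  conditional F = 182.9
 ...
```

and step 06 summarises:

```
Bonferroni threshold: 0.05/6 = 8.333e-03
univariable (IVW) significant: ['basophil', 'eosinophil', 'neutrophil', 'wbc']
MVMR direct effect (p < 0.05):  ['eosinophil']
simulated causal trait:          ['eosinophil']
```

A `leukomr` CLI wraps the same stages for file-level use
(`leukomr simulate | select-instruments | harmonize | mr | presso | mvmr |
run`); `leukomr run --config study.yaml --out-dir out/` drives the full
pipeline from one YAML config.

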