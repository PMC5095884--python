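# lumigrowth

Quantitative modeling of orthotopic breast-tumor growth from longitudinal
bioluminescence imaging, for researchers who monitor tumor burden in
luciferase-expressing xenograft models and want mechanistic parameters —
not just signal curves — out of their imaging data.

## The model

Bioluminescence reports only the living, proliferative cells, while the
caliper measures the whole lesion. The package therefore describes the
tumor as two compartments: a proliferative compartment *P* (photons/sec,
logistic growth) feeding a necrotic compartment *N* that no longer emits
light but still occupies volume:

$$\frac{dP}{dt} = aP\Bigl(1 - \frac{P}{K}\Bigr), \qquad
  \frac{dN}{dt} = \frac{aP^2}{K}, \qquad P(0) = P_0,\; N(0) = 0,$$

with proliferation rate *a* (day⁻¹), carrying capacity *K* (photons/sec)
and the inoculum *P₀* fixed at the injected cell count times the
cells-to-light ratio (88.4 photons/sec/cell from a through-origin
calibration regression). The total volume *V = P + N* grows exponentially,
then linearly with late slope *aK* — the biphasic pattern caliper data
show. Converting signal to volume (10⁹ cells ≅ 1 cm³) and comparing with
caliper measurements yields a proportionality constant λ; its excess over
1 is read as the stromal share of the tumor, 100·(1 − 1/λ) percent.

Inter-animal variability is handled with a nonlinear mixed-effects model:
individual parameters are lognormal around population typical values,
observations carry proportional Gaussian error, and estimation is by SAEM
(Metropolis–Hastings E-step, stochastic-approximation sufficient
statistics, closed-form M-step), with relative standard errors from a
Louis-type observed Fisher information. λ is estimated sequentially on the
caliper data after the bioluminescence fit.

Because no public accession exists for the original animal data, the
package ships a synthetic cohort generator that emulates the study design
(20 mice, twice-weekly imaging days 6–43, 1.5×10⁵ injected cells, 15%
proportional noise) so that every stage is testable by parameter recovery.

## Worked example

The numbered scripts under `analysis/` reproduce the full workflow on a
simulated cohort and write their tables under `results/`:

```bash
python analysis/01_calibration_curve.py      # cells-to-light slope
python analysis/02_simulate_cohort.py        # 20 virtual mice, days 6-43
python analysis/03_fit_tumor_growth.py       # SAEM fit of (a, K)
python analysis/04_volume_scale_and_stroma.py  # lambda and stroma fraction
python analysis/05_recovery_study.py         # 5-seed recovery summary
```

Output of step 3 (seed 1):

```
parameter     estimate  generating_value  cv_percent  rse_percent
        a 4.011551e-01      3.990000e-01   30.685302     6.729712
        K 4.921153e+09      4.350000e+09   52.346869    11.081883
    sigma 1.424568e-01      1.500000e-01         NaN     5.107121
```

The fit recovers the generating proliferation rate (0.399 day⁻¹) within
0.6%, the carrying capacity within the sampling error of a 20-animal
cohort, the inter-animal CVs (31.1% and 55.3% generating) and
single-digit/low-double-digit RSEs. Step 4 then prints

```
lambda: 2.204 (CV 10.9%, RSE 2.60%)  [generating value 2.25]
stroma fraction: 54.6% of total volume
typical caliper volume at day 43: 1.39 cm^3
```

i.e. the caliper-measured lesion is ~2.2× the cell-mass volume, implying
roughly 55% stroma, and the typical animal reaches ~1.3–1.4 cm³ by day 43.

The same workflow is available as a CLI (`lumigrowth simulate | calibrate |
fit | recover | report`) and as a library (`lumigrowth.run_analysis`).

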