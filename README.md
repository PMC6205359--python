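# pollsel

Pollinator-mediated selection analysis for plant cohorts.

Many flowering plants experience natural selection on floral traits, and part
of that selection is generated by the pollinators themselves. `pollsel`
implements the experimental-contrast approach for quantifying it in a
two-morph (distylous) study design: plants of each population x morph are
split between **open pollination (C)** and **supplemental hand pollination
(HP)**, where hand pollination saturates stigmas with compatible cross-pollen
and thereby removes the fitness variation that pollinator behaviour causes.

The package estimates, per population x morph x treatment stratum:

* **Directional selection gradients** β_i — partial regression coefficients of
  relative female fitness w = W / W̄ on traits standardized to mean 0 and
  variance 1 within the stratum (Lande–Arnold multiple regression), with SEs,
  t tests, and VIF multicollinearity screening (optional correlational
  cross-product terms γ_ij);
* **Pollinator-mediated selection** Δβ_poll = β_C − β_HP per trait, with its
  significance from the trait x pollination interaction of a fully
  treatment-interacted model (the two are algebraically identical under
  within-arm standardization — the package verifies this to 1e-10);
* **Pooled ANCOVAs**: Model A (C plants only; trait x population and
  trait x morph interactions test spatial and inter-morph variation in *net*
  selection) and Model B (both arms; trait x ... x pollination interactions
  test variation in *pollinator-mediated* selection), via nested-model F
  tests;
* **Pollen limitation** PL = 1 − W̄_C / W̄_HP per population x morph, with
  95% bootstrap confidence intervals (percentile by default, BCa optional);
* **Descriptive factorial ANOVAs** on log10-transformed traits and fitness.

A **synthetic-cohort generator** reproduces the full study design (4
populations x 2 morphs x 2 treatments, ~80–100 plants per cell) from
published group summaries: traits are multivariate normal with configurable
correlations, and fitness is `W = μ_W (1 + Σ β_i z_i) G` with mean-1 gamma
noise, so the estimation pipeline can be validated by parameter recovery
against known truth.

## Worked example

```python
import pollsel as ps

table = ps.simulate_cohort(ps.default_config(), seed=1)   # field-scale cohort
gradients = ps.estimate_gradients(table)
print(gradients[(gradients.population == "BGTC2") & (gradients.morph == "L")
                & (gradients.treatment == "C")]
      [["trait", "beta", "se", "p", "vif"]].round(3))
```

```
              trait   beta    se     p   vif
    flowering_onset -0.019 0.048 0.695 1.017
       plant_height -0.050 0.050 0.320 1.070
          n_flowers  0.211 0.049 0.000 1.034
corolla_tube_length -0.214 0.051 0.000 1.115
 corolla_tube_width  0.220 0.050 0.000 1.071
```

For open-pollinated L-morph plants in the BGTC2 (syrphid-fly-dominated)
population, one standard deviation more flowers predicts 21% higher relative
seed set, a one-SD *shorter* corolla tube predicts 21% higher seed set, and a
one-SD wider tube 22% higher; onset and height are not under detectable
selection. All VIFs are near 1, so the five linear terms are not collinear.

Pollen limitation for the same cohort:

```python
for e in ps.pollen_limitation_report(table, n_boot=1000, seed=1)[:2]:
    print(e.population, e.morph, round(e.pl, 3), (round(e.ci_low, 3), round(e.ci_high, 3)))
```

```
BGTC1 L 0.716 (0.66, 0.762)
BGTC1 S 0.691 (0.637, 0.735)
```

i.e. open-pollinated plants in BGTC1 set ~70% fewer seeds than the
hand-pollinated baseline. The `examples/` directory has one short narrative
script per capability (pollen limitation, gradients, the pollinator contrast
and ANCOVA, generator recovery); each prints the numbers it computes and a
line on what they mean. A thin CLI covers the same pipeline from the shell:

```bash
pollsel simulate --seed 3 --out sim/
pollsel analyze sim/cohort.csv --out ana/ --seed 4
pollsel report ana/
```

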