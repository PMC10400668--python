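# thermacclim

Thermal acclimation of photosynthesis in warming × elevated-CO2
experiments: a tested pipeline from leaf gas-exchange curves to
treatment inference, for plant ecophysiologists analysing
regression-based warming designs.

Mature trees exposed to years of warming shift the thermal optimum of
net photosynthesis (*T*optA) upward — but do the shifts keep pace with
the warming, and does elevated CO2 change them? Answering that from
field data takes a chain of model fits: biochemical capacities from
A–Ci curves, temperature-response optima per tree, photosynthesis at
the prevailing growth temperature, and a mixed-model regression across
a warming gradient. `thermacclim` implements that chain end to end
and, because the interesting quantities are regression estimates with
no closed-form truth, ships a mechanistic synthetic-data generator
with recorded ground truth so every stage is validated by parameter
recovery.

## The models

**FvCB photosynthesis.** Net CO2 assimilation is the minimum of the
Rubisco-limited, RuBP-regeneration-limited and triose-phosphate-use-
limited rates:

    Ac   = Vcmax (Ci − Γ*) / [Ci + Kc (1 + O/Ko)] − Rday
    Aj   = (Jmax/4) (Ci − Γ*) / (Ci + 2Γ*) − Rday
    ATPU = 3 TPU
    A    = min(Ac, Aj, ATPU)

with Bernacchi temperature scalings of Γ*, Kc, Ko. Vcmax and Jmax are
estimated per curve by the bilinear method (exhaustive changepoint
search over two linear regressions).

**Temperature responses.** Capacities follow the peaked Arrhenius
function with deactivation energy Hd fixed at 200 kJ mol⁻¹, yielding
ToptV, ToptJ and activation energies; net photosynthesis at growth CO2
follows A(T) = Aopt − b (T − ToptA)², yielding the thermal optimum
ToptA, the peak rate Aopt and the curvature b. From these: Ag (net A
at the 10-day mean daytime growth temperature), ΔMeanTg (growth
temperature minus ToptA), and the A70 optimum (A recomputed at
Ci/Ca = 0.7 to remove stomatal variation).

**Inference.** Plot means, warming as a continuous covariate, CO2 as
a factor, campaign month as a candidate random intercept; random
structure chosen by REML AIC, fixed structure by ML AIC (AICc
reported), one-sided tests for directional hypotheses, and a
warming × CO2 ANOVA on ΔMeanTg.

## Worked example

Run the numbered analyses (each writes its tables under `results/`):

```sh
python analysis/01_simulate_experiment.py
python analysis/02_fit_aci_curves.py
python analysis/03_fit_thermal_responses.py
python analysis/04_test_treatment_effects.py
```

which prints, for the default 10-plot, 3-trees/plot, 2-month
experiment (seed 1):

```
seed 1: generated 600 A-Ci curves (10 plots, 2 species, 2 months, 5 leaf temperatures), 120 tree-month truths -> results/synthetic/
fitted 600 curves -> results/aci_fits.csv
Vcmax(25°C) recovery vs truth: median |error| 3.0%, 90th pct 8.4% (curve noise sd 0.5 µmol m-2 s-1)
summarized 120 tree-months -> results/tree_thermal.csv
  black_spruce: ToptA 25.0 ± 1.5 °C, Aopt 7.3 µmol m-2 s-1, ΔMeanTg +1.9 °C (air warmer than optimum when positive)
  tamarack: ToptA 26.0 ± 1.6 °C, Aopt 10.6 µmol m-2 s-1, ΔMeanTg +1.0 °C (air warmer than optimum when positive)
  A70 optimum vs growth-CO2 optimum: median |difference| 0.29 °C (constant Ci/Ca generator -> biochemical control of the optimum)
tested 20 species x response combinations -> results/regression_results.csv
  black_spruce ToptA: slope +0.45 °C/°C (one-sided p=0.000), CO2 shift +0.4 °C [none/interaction]
  tamarack ToptA: slope +0.25 °C/°C (one-sided p=0.000), CO2 shift +2.4 °C [month_intercept/main_effects]
```

Reading this: each species' ToptA rises with the warming treatment
but far less than 1 °C per °C (here 0.25 and 0.45 °C/°C on a single
replicate whose generating truths are 0.26 and 0.35), tamarack shows
an elevated-CO2 upward shift of ToptA (+2.4 °C recovered, truth
+3 °C) while spruce shows none, and the mean daytime air temperature
exceeds the optimum (positive ΔMeanTg) — the leaf operates beyond its
thermal optimum under warming. `05_parameter_recovery.py` repeats the
chain over 50 seeds and tabulates recovered-vs-embedded values for all
headline quantities.

The same pipeline is scriptable via the CLI
(`thermacclim simulate | fit-aci | thermal | infer | run-all`, YAML
config, CSV tables) and as a library (`thermacclim.run_pipeline`).
To analyse real measurements, point `RunConfig.aci_curves_path` /
`climate_path` at CSVs with the documented columns (one row per A–Ci
step: plot, species, CO2 treatment, warming offset, tree, month, leaf
temperature, step index, Ca, Ci, A; climate: plot, timestamp, air
temperature).

## Layout

    src/thermacclim/   fvcb.py        forward model + temperature responses
                       aci.py         bilinear A-Ci fitting, growth-A extraction
                       thermal.py     Arrhenius/quadratic fits, climate, Ag/A70
                       inference.py   plot means, model selection, ANOVA
                       synthetic.py   generator with emergent-truth calibration
                       recovery.py    parameter-recovery protocols
                       pipeline.py    orchestration, validation, manifests
                       cli.py         thermacclim command group
    analysis/          numbered drivers (simulate -> fit -> thermal -> infer -> recover)
    tests/             pytest suite (oracle, property and acceptance tests)
    docs/methods.md    model, generator and validation details
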