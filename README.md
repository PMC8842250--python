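# aggkin

Long-term prediction of monoclonal-antibody (mAb) aggregation at storage
temperature from short-term, high-temperature kinetics.

Aggregates limit the shelf life of therapeutic antibodies, but at the
5 °C storage temperature they take months to years to become measurable.
`aggkin` models size-exclusion chromatography (SEC) stability data with a
**branched two-pathway mass-action mechanism** and extrapolates it in
temperature, so that days-to-months of accelerated data (25–75 °C) yield
a prediction of monomer/dimer/trimer/HMW fractions up to three years at
5 °C, with Monte Carlo prediction intervals.

## The model

Native monomer N leaves through two competing irreversible routes:

```
LT (chemical modification):   N → I          (k_I)
                              N + I → NI     (k_NI)
HT (partial unfolding):       N → D          (k_D)
                              D + D → D2     (k_D2)
                              D2 + D → D3    (k_Dn)
                              D3 + D → HMW   (k_Dn, shared)
```

I and D are monomeric (they co-elute with N on SEC); NI and D2 are the
low- and high-temperature dimers; D3 and the lumped HMW species complete
the high-temperature ladder. Every rate constant obeys Arrhenius
temperature dependence relative to a 5 °C reference,

  k_i(T) = k_{5°C,i} · exp[ −(E_{a,i}/R) (1/T − 1/278.15 K) ],

with E_a in kcal/mol (R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹). The temperature
sets the flux split between the pathways, which is what produces the
familiar curved (biphasic) Arrhenius plot of apparent aggregation rates.

On top of the kinetic core the package provides:

* **Global fitting** of one `(k_{5°C}, E_a)` pair per reaction to all
  (temperature × concentration) subsets at once; the objective is the
  mean over subsets of the per-subset RMS residual in % points.
* **Monte Carlo prediction intervals**: every observed fraction is
  perturbed with the SEC measurement error, the model is refitted per
  replica, and the envelope of the 95 % of replica curves closest to the
  central prediction forms the band.
* A **pseudo-first-order shortcut** (single concentration, two to four
  low temperatures, Arrhenius regression of apparent rates) for rapid
  screening.
* **Thermodynamic linkage**: urea-denaturation fits (linear-extrapolation
  model) give ΔG_d; stability enters the kinetics through the initial
  native/non-native split exp(−ΔG_d/RT)/(1+exp(−ΔG_d/RT)) and through a
  log-linear linkage ln k_I = a + b·ΔG_d. A phase-space map shows where
  the LT or HT pathway dominates over (temperature × stability).
* A **synthetic-data generator** with ground-truth presets, so the whole
  pipeline is testable without proprietary stability data.

## Worked example

```python
import numpy as np
from aggkin import (build_scheme, preset_truth, fit_global, FitOptions,
                    predict_longterm, monte_carlo, prediction_band, Condition)
from aggkin.synth import default_design, generate_study

scheme = build_scheme(4)
truth = preset_truth("mab1like")            # synthetic ground truth

# a noisy accelerated study: 40-75 degC, one concentration
design = default_design(temperatures=(40., 55., 65., 75.),
                        concentrations=(50.,), noise_sd=0.1, seed=7)
study = generate_study(truth, design, scheme)

fit = fit_global(study, scheme, truth.params, options=FitOptions(n_starts=1))
print(f"objective = {fit.objective:.3f} % points")

curve = predict_longterm(fit, scheme, T_storage=5.0, c_total=50.0,
                         horizon=17520.0, eval_times=[0.0, 17520.0])
print(f"predicted 24-month 5C aggregate = {curve.total_aggregate()[-1]:.3f} %")

ens = monte_carlo(study, fit, scheme, n_rep=200, sigma=0.1, seed=7)
band = prediction_band(ens, scheme, Condition(5.0, 50.0), 17520.0)
print(f"95% band = [{band.lower[-1]:.3f}, {band.upper[-1]:.3f}] %")
```

Output:

```
objective = 0.071 % points
predicted 24-month 5C aggregate = 0.032 %
95% band = [0.007, 0.145] %
```

The objective (~0.07 % points) sits at the level of the injected SEC
noise, i.e. the model explains the data to within measurement error. The
central 24-month prediction from this deliberately sparse screening study
is 0.03 % with a 95 % interval of 0.007–0.145 %, which covers the true
value of this preset (0.116 % by direct simulation at 5 °C); richer
designs (more temperatures, concentrations and replicate injections)
tighten both the point estimate and the band — see `docs/methods.md`.

The same pipeline is scriptable from the shell:

```bash
aggkin synth --preset mab1like --temps 40,55,65,75 --concs 50 --seed 7 --out study.csv
aggkin fit --data study.csv --n-starts 1 --seed 7
aggkin predict --fit fit.json --storage 5 --horizon-months 24
aggkin mc --data study.csv --fit fit.json --reps 200 --sigma 0.1 --seed 7
aggkin phasespace --preset mab1like
```

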