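# ctpc — cardiac thermal performance curves for intertidal ectotherms

`ctpc` turns raw heartbeat-versus-temperature recordings of ectotherms
(originally: neritid snails heated on a slow ramp) into per-individual
thermal traits, and then asks the comparative question: **do these traits
track the thermal environment of the habitat once shared evolutionary
history is accounted for?**

It is aimed at thermal ecophysiologists who record cardiac activity with
optical sensors during controlled heating assays and want a reproducible,
testable path from the raw trace to phylogenetically informed statistics —
plus a synthetic-data module that generates traces, environments,
phylogenies and trait cohorts with known ground truth, so every stage can be
validated without any field data.

## The model

Heart rate along the ramp is described by the Sharpe–Schoolfield model in
its high-temperature-inactivation form,

```
r(T) = r_Tref · exp(−E/k · (1/T − 1/Tref)) / (1 + exp(Eh/k · (1/Th − 1/T)))
```

with `T` in Kelvin and `k` the Boltzmann constant (8.617333×10⁻⁵ eV/K):
Arrhenius activation with energy `E` (eV), tempered by enzyme inactivation
with energy `Eh` above the half-inactivation temperature `Th`. When
`Eh > E > 0` the curve is unimodal with optimum

```
Topt = Eh·Th / (Eh + k·Th·ln(Eh/E − 1)).
```

Five traits are extracted per individual:

| trait | meaning | units |
|---|---|---|
| slope gradient | activation energy `E` of the fitted curve | eV |
| slope curvature | `2·c₂` from a quadratic fit to the upslope (T < Topt) | bpm/°C² |
| HRmax | fitted maximum heart rate | bpm |
| Topt | temperature of the fitted maximum | °C |
| ULT | upper lethal temperature: permanent heartbeat flatline | °C |

Species-mean traits are regressed on habitat under three residual
covariance structures — a star phylogeny (λ=0), Brownian motion on the tree
(λ=1), and Pagel's λ estimated by maximum likelihood — and compared by AICc
and Akaike weights. Within habitats, species are compared with Gaussian
linear models, likelihood-ratio tests and Tukey HSD; trait variability is
summarized as CV% (computed on Kelvin for the temperature traits).

## Worked example

Run the full synthetic pipeline (here with a reduced assay — 4 individuals
per species, 1 °C/min at 20 Hz — so it finishes in seconds):

```python
import ctpc

cfg = ctpc.RunConfig(seed=7, n_individuals=4, sample_hz=20.0,
                     ramp_rate_C_per_min=1.0)
ctpc.run_simulate(cfg, "demo")        # traces + ground truth + species tree
ctpc.run_traits(cfg, "demo")          # per-individual trait table
out = ctpc.run_compare(cfg, "demo")   # PGLS + habitat stats + CV summary
print(out["pgls"].round(3).head(3).to_string(index=False))
```

prints (for the slope-gradient trait; `demo/pgls.tsv` holds all five):

```
         trait    model  lambda  beta_habitat     t  df     p  AICc  wAICc
slope_gradient     star   0.000         0.160 2.265   4 0.086 3.245  0.895
slope_gradient brownian   1.000         0.225 1.084   4 0.339 7.533  0.105
slope_gradient    pagel   0.803         0.218 2.544   4 0.064 32.432 0.000
```

`beta_habitat` is the rocky-minus-mangrove contrast: the generator builds in
a higher activation energy (steeper upslope) for the rocky-shore species,
and the recovered contrast is positive under every covariance model. The
Akaike weights (`wAICc`, summing to 1 within a trait) rank the star model
first here; the Pagel model pays an AICc penalty for its extra estimated λ
at n = 6 species. The CV summary from the same run,

```
          trait  mean_cv_pct  sd_cv_pct  kelvin_applied
          t_opt         0.50       0.22            True
            ult         1.25       0.53            True
         hr_max        12.25       4.85           False
 slope_gradient        19.14       5.93           False
slope_curvature       137.82      84.91           False
```

shows the canalization hierarchy: the temperature traits vary least across
individuals (their CV is computed on the Kelvin scale), the performance
traits most.

The same pipeline is available from the shell:

```sh
ctpc simulate --out run --seed 7
ctpc traits   --out run
ctpc pgls     --out run
ctpc stats    --out run --alpha 0.05
```

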