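# taxadyn

Process-model inference of microbial community assembly mechanisms from
time-series data.

Microbial communities are shaped by a mix of deterministic forces
(resource competition, environmental filtering) and stochastic ones
(immigration, demographic drift). `taxadyn` disentangles them at the
level of individual taxa: given a table of amplicon counts (ESVs/OTUs)
over time plus a resource measurement (e.g. volatile solids in an
anaerobic digester), it fits three stochastic/deterministic models of
each taxon's dynamics, selects among them by AIC, and converts the
fitted coefficients into ecological quantities — immigration rates,
source-pool abundances, relative competition strengths, and a
drift-to-noise "determinism" index for taxa and the whole community.

## The models

All dynamics are expressed through the log abundance ratio
`Z_i = log(X_i / X_r)` of a focal taxon *i* against a fixed reference
taxon *r* (the most frequent, most abundant taxon), which removes the
unobservable total community size from the problem.

- **Consumer–resource (CR)** — taxa interact only through competition
  for shared resources `R_j`:

  `dZ_i/dt = k0 + Σ_j k1_j R_j`

  with `k0 = −(m_i − m_r)` the relative maintenance cost and
  `k1_j = b_ij C_ij − b_rj C_rj` the relative competition strength
  (consumption rate × conversion efficiency, relative to the
  reference). Fitted by OLS.

- **Neutral** — a Wright–Fisher diffusion with immigration,
  `dX = λ(p − X) dτ + sqrt(2X(1−X)) dW` on the scaled time
  `τ = t/a`, where `λ` is the immigration rate toward the source-pool
  abundance `p` and `a` is the mean individual replacement time. Ito's
  lemma turns this into the weighted linear model

  `dZ_i/dt = k0 + k2/X_i + k3/X_r + ε`,  `k2 = (λ_i p_i − 1)/a`,

  with per-interval error variance `(2/X_i + 2/X_r)/(a·dt)`, hence WLS
  weights `w = dt/(2/X_i + 2/X_r)` and the residual-scale identity
  `E[(√w ε)²] = 1/a` from which `a` is recovered.

- **Combined** — the neutral SDE with the CR growth term added to the
  drift: `dZ_i/dt = k0 + Σ_j k1_j R_j + k2/X_i + k3/X_r + ε`, same
  weights.

Per taxon, the best model is the one with the lowest AIC. From the
neutral fit, `λ_i p_i = k2·â + 1` and `p_i` is the taxon's mean
relative abundance, so `λ_i` follows. At equilibrium the neutral model
predicts `X_i ~ Beta(λ_i p_i, λ_i(1−p_i))`, usable as a monitoring band.
Determinism at a time point is the inverse coefficient of variation of
the combined SDE,

`|k0 + Σ_j k1_j R_j + k2/X_i + k3/X_r| · sqrt(a / (2/X_i + 2/X_r))`,

averaged over taxa (optionally abundance-weighted) to give community
determinism.

The package also ships a simulator (Wright–Fisher diffusion on the
simplex with immigration and replicator-style resource selection plus
multinomial read sampling) used as the ground-truth oracle for every
estimator, and a phylogenetic-signal analysis correlating pairwise 16S
similarity with competition-strength differences.

## Worked example

```python
from taxadyn import simulate_scenario, relative_abundances
from taxadyn.process_models import fit_all
from taxadyn.neutral_equilibrium import stationary_beta

result = simulate_scenario("strict_neutral", seed=7)   # 30 taxa, 53 samples
abund = relative_abundances(result.count_table)
tables = fit_all(abund, result.resources)

print(tables["best_models"]["best_model"].value_counts().to_string())
npar = tables["neutral_params"].set_index("taxon_id")
print(npar.head(3)[["lambda_i", "p_i", "a_hat"]].round(3).to_string())

row = npar.iloc[0]
pred = stationary_beta(row["lambda_i"], row["p_i"])
print(f"predicted 95% abundance band for {npar.index[0]}: "
      f"[{pred.ppf(0.025):.4f}, {pred.ppf(0.975):.4f}]")
```

prints

```
best_model
neutral              21
combined              7
consumer_resource     1

          lambda_i    p_i      a_hat
taxon_id
ESV02      576.498  0.110  37562.626
ESV03      593.934  0.104  41529.138
ESV04      525.122  0.096  39316.947

predicted 95% abundance band for ESV02: [0.0856, 0.1365]
```

On this strictly neutral community the AIC comparison picks the neutral
model for 21 of 29 fitted taxa; the recovered immigration rates sit
near the generating values (λ = 400, here in per-scaled-time units with
â ≈ 40 000 days), and the Beta band brackets the taxon's observed
abundance range — the kind of fluctuation envelope one would use to
flag anomalous behaviour in a stable reactor.

The same workflow is available from the shell:

```sh
taxadyn simulate --scenario resource_selection --seed 42 --out sim/
taxadyn fit --counts sim/counts.tsv --meta sim/meta.tsv \
            --resources sim/resources.tsv --out fits/
taxadyn determinism --counts sim/counts.tsv --meta sim/meta.tsv \
            --resources sim/resources.tsv --out det/
```

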