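# epiclust

Is network clustering detectable in epidemic transmission trees?

`epiclust` is a simulation pipeline for epidemiologists and network
modellers studying how contact-network structure shapes outbreak data. It
asks a specific question: if two contact networks have *exactly the same
degree for every node* but different levels of clustering (the propensity
for triangles — my contact's contact is also my contact), do the epidemics
they produce look different? The answer matters for statistical inference:
if transmission data carry no clustering signal, clustering parameters
cannot be estimated from outbreak records alone.

## What it does

Each replicate of the experiment:

1. **samples a contact network** — Bernoulli (N = 500, p = 0.014) or
   approximate power-law (N = 600, α = 1.8, built by stub pairing with loop
   removal and multi-edge collapse);
2. **rewires it to two arms**, `Y^hi` and `Y^lo`, by Metropolis–Hastings
   over degree-preserving double-edge swaps targeting the exponential
   random graph density `π(Y) ∝ exp(θ·u(Y;τ))`, where
   `u(Y;τ) = e^τ Σ_{i≥1} [1−(1−e^{−τ})^i] EP_i(Y)` is the geometrically
   weighted edgewise-shared-partner (gwesp) statistic (decay τ = 0.2,
   coefficient θ = +5 for high clustering, −5 for low);
3. **runs paired stochastic SEIR epidemics** from a shared index node
   (per-edge transmission rate β = 0.1/day, gamma latent and infectious
   periods with k_E = k_I = 1 and θ_E = θ_I = 3 days, outbreaks conditioned
   on infecting ≥ 20 hosts);
4. **extracts the transmission tree** — root = index infection, internal
   nodes = who-infected-whom events, leaves = recoveries — and reduces each
   arm to summary statistics: final size, epidemic length, peak prevalence
   and peak time; mean internal and external branch lengths,
   secondary-infection and infective-descendant distributions, and the
   cherry ratio (pairs of leaves on a common internal node, over the
   maximum `floor(leaves/2)`);
5. **compares the per-arm summary distributions** (means, ranges, and a
   range-overlap coefficient).

See `docs/methods.md` for model details, numerical choices and limitations.

## Worked example

Twenty paired Bernoulli replicates at the study conditions:

```python
from epiclust import ExperimentConfig, run_experiment, compare_distributions

config = ExperimentConfig(model="bernoulli", n_replicates=20, seed=1)
table = run_experiment(config)                 # one row per replicate x arm
print(compare_distributions(table).round(3).to_string(index=False))
```

```
           statistic  hi_mean  hi_min  hi_max  lo_mean  lo_min  lo_max  range_overlap
          clustering    0.287   0.270   0.304    0.000   0.000   0.000          0.000
          final_size  259.250  43.000 357.000  328.550 273.000 390.000          0.242
     epidemic_length   97.293  39.536 145.183   94.945  71.022 124.664          0.508
     peak_prevalence   45.600  10.000  73.000   66.600  40.000 109.000          0.333
           peak_time   51.715  17.662  90.623   44.975  23.185  74.500          0.703
mean_internal_branch    2.753   2.187   3.144    2.832   2.580   3.079          0.521
mean_external_branch    3.208   2.559   3.580    3.161   2.854   3.512          0.644
      mean_secondary    0.994   0.977   0.997    0.997   0.996   0.997          0.042
        cherry_ratio    0.502   0.462   0.586    0.525   0.468   0.572          0.838
 prop_giant_infected    0.519   0.086   0.715    0.658   0.547   0.782          0.242
```

Reading the table: the two arms are trivially separable by their
*clustering coefficients* (0.27–0.30 versus exactly 0 — the low arm is
triangle-free), yet the epidemic summaries overlap substantially. The
high-clustering arm produces on average slightly longer epidemics with a
lower peak that occurs later, but the replicate-to-replicate stochastic
spread (the min–max columns) swamps those mean shifts — the signature
finding that clustering is hard to detect from single-outbreak data when
the degree sequence is fixed.

The same machinery is scriptable from the shell:

```sh
epiclust rewire --in net.edgelist --tau 0.2 --theta 5 --burnin 500000 --seed 1 --out net_hi.edgelist
epiclust epidemic --net net_hi.edgelist --seed 2 --out log.tsv
epiclust experiment --config config.yaml --reps 500 --seed 3 --outdir results/
```

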