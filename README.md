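# hoopoeipm

Habitat-stratified integrated population modelling for a declining hoopoe
(*Upupa epops*) population — for population ecologists who want to diagnose
*which* vital rate, in *which* habitat, driven by *which* covariate, is
behind a decline.

The package joins four data sets in one Bayesian state-space likelihood:
annual per-habitat count indices, multistate capture–recapture histories
(latent states = three habitat-quality classes + dead), and the two
components of annual productivity (Bernoulli success, gamma fledgling
numbers of successful females). For habitat h ∈ {H, M, L} the process model
is

    N¹_{h,t+1} ~ Poisson( Σ_src R_src S¹_src ψ¹_{src,h} N^tot_src )
    N²_{h,t+1} ~ Σ_src Binomial( N^tot_src, S²_src ψ²_{src,h} )
    Nⁱ_{h,t+1} ~ Poisson( ω_h N^tot_h ),      y_{h,t} ~ Poisson(N^tot_{h,t})

with R = ½ · p_succ · μ_fled. Three model variants put year random effects
(I), linear trends (II), or environmental/research-activity covariates (III)
on the vital rates. On top of the fits the package provides

* **transient-LTRE decompositions** of var(λ) and of the difference in mean
  log λ between two periods into per-rate, per-habitat contributions
  (λ_t = Σ_h π_h (R_h S¹_h + S²_h + ω_h); movement cancels in the total),
* **backward simplification** of the covariate model by credible-interval
  overlap with zero, and
* **leave-one-covariate-out attribution** of population-size variance and of
  the post-peak growth trend to each retained covariate,

plus a synthetic-data generator with exactly the model's stochastic
structure, so the whole pipeline is testable by simulation–estimation round
trips without the field data. Inference is a seeded adaptive
Metropolis-within-Gibbs sampler built for this model (numba-accelerated
forward algorithm and latent-abundance sweeps); see `docs/methods.md`.

## Worked example

```python
from hoopoeipm import TrueParams, model_I, fit, ltre_from_posterior
from hoopoeipm.synthdata import simulate_bundle

params = TrueParams()                      # default 16-year scenario
bundle, traj = simulate_bundle(params, n_years=16, seed=11)
print(bundle.histories.n_individuals)      # marked individuals

post = fit(model_I(), bundle, seed=5)      # 3 chains x 3000, ~1-2 min
print(post.summary().head(6).to_string(index=False))

res = ltre_from_posterior(post, period_a=(2002, 2005), period_b=(2013, 2016))
s = res["summary"]
top = s[s.quantity == "var_lambda"].nlargest(3, "mean")
print(top.to_string(index=False))
```

Output from this exact run:

```
2537
parameter     mean     lo95     hi95
    s1[H] 0.230465 0.185637 0.292192
    s1[M] 0.222459 0.179268 0.270943
    s1[L] 0.249444 0.189115 0.325759
    s2[H] 0.371533 0.313298 0.454154
    s2[M] 0.383150 0.320806 0.469550
    s2[L] 0.392136 0.319028 0.491822
  quantity parameter habitat     mean          lo95     hi95
var_lambda     omega       H 0.015484 -2.104136e-08 0.041441
var_lambda        s1       H 0.008551 -3.919544e-05 0.023261
var_lambda        s1       L 0.006886  6.561047e-04 0.015267
```

Read: posterior mean apparent first-year survival is ≈ 0.22–0.25 and adult
survival ≈ 0.37–0.39 per habitat (the generating annual means were 0.21 and
0.35), and the largest contributions to the temporal variance of the
realized growth rate come from immigration and first-year survival — exactly
the rates the generating scenario varies most (colonisation-phase
immigration levelling off, first-year survival declining), so the
decomposition points at the right demographic levers.

The command line mirrors the three analysis steps:

```bash
hoopoe-ipm simulate --out data/ --seed 3
hoopoe-ipm fit --data data/ --out fits/ --variant I
hoopoe-ipm ltre --posterior fits/posterior_I.npz --out fits/
hoopoe-ipm explain --data data/ --out fits/
hoopoe-ipm report --config pipeline.yaml --out run/
```

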