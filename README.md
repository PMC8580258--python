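# latentcause

Observer models for latent-cause detection in spatial point patterns.

A classic problem in perceptual decision-making: given `N` points scattered
on a disc, did they all come from a uniform background (`C = 0`), or is a
hidden source present (`C = 1`) around which some of the points cluster?
The generative model is

* `C ~ Bernoulli(0.5)`;
* if `C = 1`, a source location `μ ~ N(0, σ_s² I)` on a disc of radius `R`,
  and each point is independently *affiliated* with the source with
  probability `p_aff`: affiliated points are drawn `N(μ, σ² I)`, the rest
  uniform on the disc;
* if `C = 0`, all points are uniform on the disc.

Experiment defaults: `p_aff = 0.5`, `R = 10`, `σ_s = σ = 2`,
`N ∈ {6, 9, 12, 15}`. Stimuli with any point outside the disc are redrawn.

An ideal observer reports "source present" when the log evidence ratio
`d = log(L1/L0)` exceeds a criterion, with

    L0 = (πR²)^(−N),
    L1 = Σ_z ∫ L(z, μ) p(z) p(μ) dμ,

a marginalisation over all 2^N affiliation patterns `z` *and* the source
location `μ`. That double marginalisation is the computational crux: the
package implements the exact evidence (closed-form Gaussian collapse over
`μ`, vectorised enumeration over `z`), an independent quadrature route, and
a zoo of *point-estimating* observers that commit to `μ̂` and/or `ẑ`
instead of marginalising — including a greedy agglomerative cluster search
that scores seed-grown clusters by their marginal-likelihood ratio and
needs at most `N²` evidence evaluations. Heuristic observers based on
pairwise/nearest-neighbour distances and kernel density round out the set.

Responses are modelled with a criterion `k` (optionally per set size),
Gaussian decision noise `σ_d` and lapse rate `λ`:

    p(report present | d) = λ/2 + (1 − λ) Φ((d − k_N)/σ_d),

and fitted by maximum likelihood; observers are compared with AIC/BIC.
Parameter-recovery and model-recovery harnesses ship with the package.

## Worked example

Simulate a synthetic subject who uses the greedy clustering strategy, then
ask which observer model the choices support:

```python
import numpy as np
from latentcause import (TaskParams, sample_session, InternalModel, CATALOGUE,
                         ObserverParams, simulate_responses, fit_model,
                         compare_models)

rng = np.random.default_rng(7)
task = TaskParams()                       # p_aff=0.5, R=10, sigma_s=sigma=2
trials = sample_session(task, 1000, rng)  # N drawn from {6, 9, 12, 15}

truth = ObserverParams(k=2.0, sigma_d=1.0, lapse=0.05)
responses, d = simulate_responses(CATALOGUE["C_ac"], truth, trials, rng,
                                  model=InternalModel.from_task(task))

fits = [fit_model(m, trials, responses, seed=0) for m in ("A1", "C_ac", "H10")]
print(compare_models(fits, reference="A1")[["model_id", "n_params", "log_lik",
                                            "aic", "delta_aic_vs_ref"]])
print(fits[1].summary())
```

Output:

```
  model_id  n_params     log_lik         aic  delta_aic_vs_ref
0     C_ac         6 -308.129843  628.259686       -212.345859
1      H10         5 -379.315910  768.631821        -71.973724
2       A1         3 -417.302772  840.605544          0.000000

Observer choice model: C_ac
============================================
n trials                                1000
free parameters                            6
log-likelihood                      -308.130
AIC                                  628.260
BIC                                  657.706
restarts                                  11
converged                               True
--------------------------------------------
k_6                                   1.8808
k_9                                   2.1108
k_12                                  1.9762
k_15                                  2.0153
sigma_d                               1.0640
lapse                                 0.0765
```

The generating model wins by >200 AIC points over the exact Bayesian
observer (A1) and the mean-pairwise-distance heuristic (H10), and the
fitted criterion (~2.0), decision noise (~1.06) and lapse (~0.08) recover
the generating values. `fit_model` is a convenience wrapper around
`ObserverChoiceModel(model_id, trials, responses).fit()`, which returns an
`ObserverFitResults` with `.aic`, `.bic`, `.llf` and `.summary()`.

A thin CLI mirrors the library: `latentcause simulate | fit | compare |
recover | summarize | dump-partitions` (see `--help` on each).

Model IDs: `A1`/`A2`/`A3` (exact Bayes; N-dependent criteria; flexible
beliefs about σ, σ_s), `B4`/`B5`/`B6` (commit to μ̂: centroid, peak kernel
density, posterior mean), `C_mml`/`C_mmp`/`C_ac` (commit to ẑ: max marginal
likelihood, max marginal posterior, agglomerative clustering),
`D_mjp`/`D_mjl`/`D_ac`/`D13`/`D14` (commit to both), `H10`–`H14`
(distance/density heuristics). A trailing `P` (e.g. `B6P`) makes the
internal affiliation probability a free parameter per set size.

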