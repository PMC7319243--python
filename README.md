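# funcresp

Estimation of predator–prey interaction strengths from **non-replacement
feeding trials** — the standard comparative functional-response design in
which a single predator is offered prey at a fixed initial density and
eaten prey are not replaced, so prey deplete during the trial.

The package provides, as a tested pipeline:

- classification of the functional-response type (II vs III) from
  logistic regressions of the proportion eaten on prey density;
- maximum-likelihood fitting of **Rogers' random predator equation**,
  the depletion-aware integral of the Holling type II response,

  ```
  Ne = N0 (1 − exp(a (Ne h − T)))
  ```

  where `Ne` is the number of prey eaten, `N0` the initial prey density,
  `a` the attack rate (cage/hr), `h` the handling time (hr/prey) and `T`
  the trial duration (hr).  The equation is implicit in `Ne`; its
  explicit solution uses the Lambert W function,
  `Ne = N0 − W(a h N0 e^{−a(T − h N0)}) / (a h)`.  Type III (Hassell)
  and generalized variants with a density-dependent attack coefficient
  `a(N0) = b N0^q` are supported;
- non-parametric **bootstrap** uncertainty for `(a, h)` per experimental
  group (20 draws by default, floored at 0), and Gamma-GLM comparison of
  draws across species/size factors;
- polynomial regression (degree chosen by AICc) of the bootstrapped
  parameters against **predator–prey body-mass ratios**, recovering
  hump-shaped attack-rate scaling and declining handling times;
- a deterministic **prey-depletion bias study**: prey depletion is
  simulated from the population dynamic model
  `dN/dt = −a N P / (1 + a h N)`, rounded consumption is refit with the
  random predator equation, and the estimates are compared with the
  inputs across durations and parameter grids;
- a seeded **synthetic-data generator** emulating the cage experiment
  (2 predator species × 3 predator sizes × 3 prey sizes, densities
  2–32 plus 64 for small prey, 3 replicates, 1-hr trials) for testing
  every downstream stage without real data.

## Worked example

Fit one experimental group generated from a known type II truth
(`a = 1.0` cage/hr, `h = 0.1` hr/prey):

```python
from funcresp import (FRParams, generate_trials, classify_fr,
                      fit_rogers_mle, bootstrap_fr)
from funcresp.synthetic_data import ExperimentDesign

design = ExperimentDesign(species=("largemouth_bass",),
                          pred_sizes=("small",), prey_sizes=("small",))
truths = {("largemouth_bass", "small", "small"): FRParams(a=1.0, h=0.1)}
trials = generate_trials(design, truths, seed=7)

cls = classify_fr(trials)
print(f"type: {cls.fr_type}  slope: {cls.linear_coef:.4f}  p: {cls.linear_p:.2e}")

fit = fit_rogers_mle(trials)
print(f"a = {fit.a:.3f} +/- {fit.se_a:.3f}   h = {fit.h:.4f} +/- {fit.se_h:.4f}")

bs = bootstrap_fr(trials, n=20, seed=3,
                  group=("largemouth_bass", "small", "small"))
print(f"bootstrap a mean {bs.a.mean():.3f}  h mean {bs.h.mean():.4f}")
```

prints

```
type: II  slope: -0.0167  p: 2.00e-03
a = 0.593 +/- 0.166   h = 0.0637 +/- 0.0190
bootstrap a mean 0.675  h mean 0.0687
```

The significantly negative logistic slope classifies the response as
type II; the maximum-likelihood estimates sit within roughly 2 SE of the
generating values (18 trials is a small experiment — coverage of the
±2 SE intervals across many such groups is about 95%, see the test
suite); the bootstrap spread quantifies the same uncertainty without
relying on the Hessian.

The same stages are available from the shell:

```sh
funcresp simulate --seed 7 --out trials.csv
funcresp classify trials.csv
funcresp fit trials.csv --seed 7
funcresp bias-sim --out bias_study.csv
funcresp run-all --seed 7 --out-dir results/
```

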