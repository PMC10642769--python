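# espd — competing-risks mixture modelling for discrete event simulation

`espd` implements the **event-specific probabilities and distributions**
strategy for modelling competing time-to-event outcomes from right-censored
patient-level data, as used to parameterise discrete event simulations (DES)
in health-economic and epidemiological modelling.

The model assumes events arise in two steps. For an individual with
covariates $x$, one of $k$ mutually exclusive event types is selected with
softmax (multinomial-logit) probabilities

$$\pi(x) = \mathrm{softmax}(\beta_\pi^\top x_\pi),$$

and the event time is then drawn from that event's parametric survival
family (Weibull, Gompertz, exponential, or any registered family), whose
parameters $\theta_j(x)$ may themselves be covariate-linked through log or
identity links. Observation ends either at an event of type $j$ at time $t$
(likelihood contribution $\pi_j f_j(t;\theta_j)$) or at a right-censoring
time (contribution $\sum_j \pi_j S_j(t;\theta_j)$, accumulated in log space).
The package provides:

- closed-form density/survival/quantile/sampling for the survival families
  with covariate links (`espd.distributions`);
- the mixture likelihood, coefficient packing and conditional event-type
  probabilities for censored individuals (`espd.model`);
- maximum-likelihood fitting (quasi-Newton, zero starts, jittered restarts,
  finite-difference variance–covariance, AIC) and Bayesian posterior
  sampling with ensemble MCMC and split-$\hat R$/ESS diagnostics
  (`espd.estimation`);
- the two-step generative simulator, a reference oncology-like population
  (stage and age covariates, Weibull recurrence, Gompertz death) and
  independent exponential censoring calibrated to a target censored
  proportion (`espd.generative`);
- the Monte Carlo performance harness with E/AE/RE/RAE error measures and a
  kernel-density Kullback–Leibler divergence (`espd.evaluation`);
- CSV/config I/O, a synthetic melanoma-like fixture and a CLI
  (`espd.interface`, `espd.cli`).

## Worked example

```python
import numpy as np, espd

spec = espd.study_spec()                 # recurrence vs death, stage + age
truth = espd.true_coefficients()

pop = espd.generate_population(n_sim=200_000, rng=1)
rng = np.random.default_rng(2)
sample = pop.subset(rng.choice(pop.n, 500, replace=False))
censored = espd.apply_censoring(sample, 0.6, rng)   # 60% censored

fit = espd.fit_mle(censored, spec)
print(fit.report())
```

prints (abbreviated):

```
ESPD fit
  events: ('recur', 'death') (reference: death)
  log-likelihood: -750.841986   AIC: 1521.683972
  converged: True (restarts used: 0)
                coefficient  estimate       se        link  natural_scale
         pi.recur.intercept -0.227970 0.265593 logit-score      -0.227970
           pi.recur.stageIB  0.049146 0.347832 logit-score       0.049146
           pi.recur.stageII  0.432383 0.341296 logit-score       0.432383
theta.recur.shape.intercept  0.720553 0.069834         log       2.055570
theta.recur.scale.intercept  1.870118 0.106544         log       6.489063
  theta.recur.scale.stageIB -0.186840 0.140319         log       0.829576
  theta.recur.scale.stageII -0.461822 0.130137         log       0.630135
theta.death.shape.intercept  0.061440 0.022409    identity       0.061440
 theta.death.rate.intercept -3.297254 0.193705         log       0.036985
     theta.death.rate.age_c  0.088929 0.024494         log       1.093003
```

Even with 60% of the 500 observations censored, the estimates sit close to
the generating values (e.g. Weibull log-shape 0.72 vs 0.7, Gompertz shape
0.061 vs 0.1, death-rate intercept −3.30 vs −3.5), with standard errors from
the inverse observed information. `espd.conditional_event_probs` then gives
the probability that a censored individual's latent event is a recurrence,
and `espd.fit_bayes` / `espd.posterior_event_probs` the posterior-averaged
version.

The performance of the whole pipeline under censoring and small samples is
quantified by `espd.run_simulation_study`, which repeatedly samples from a
reference population, censors, refits, simulates from the estimates, and
scores event probability, mean times-to-event (E/AE/RE/RAE) and per-event
KLD against the population truth.

## Command line

```sh
espd simulate --n 1000 --seed 1 --out cohort.csv
espd censor cohort.csv --p-censored 0.3 --seed 2 --out censored.csv
espd fit censored.csv --config model.yaml --out fit.json
espd study --scenario 0.6,50 --n-run 500 --out study.csv
```

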