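# rlpupil

Analysis toolkit for probabilistic reinforcement-learning experiments with a
placebo/drug crossover design and concurrent pupillometry. It provides, as
tested library code:

- **Q-learning core** (`rlpupil.qlearning`): Rescorla–Wagner delta-rule
  updating, softmax choice (learning rate α ∈ [0, 1], inverse temperature
  β ∈ [0, 10], Q0 = 0, outcomes in pounds ±0.50), agent simulation and
  choice log-likelihoods.
- **Synthetic data** (`rlpupil.synth`): block-randomised gain/loss task
  schedules (96 trials, 75/25 contingency), crossover cohorts drawn from
  non-centred hierarchical group distributions with drug offsets (known
  ground truth returned alongside), and synthetic pupil traces with blinks,
  drug-dependent tonic baselines and a biphasic feedback response.
- **Hierarchical Bayesian inference** (`rlpupil.inference`): per-condition
  non-centred hierarchical model (probit transforms, standard-normal priors
  on means/deviations, half-normal(0, 1) on SDs; crossover drug-offset
  parameterisation), fitted with a built-in gradient-based NUTS sampler
  (numba-accelerated analytic gradients, pure-Python fallback), split R-hat
  diagnostics and graphical posterior predictive checks.
- **Posterior analysis** (`rlpupil.analysis`): probability of direction,
  89% HDI, ROPE (0 ± 0.1 × SD) with reject/accept/undecided labels,
  draw-wise drug contrasts, the optimal-(α, β) grid simulation and the
  joint-parameter-space Euclidean distance posterior.
- **Pupillometry** (`rlpupil.pupil`): blink interpolation (<500 ms linear
  with 100 ms anchors; ≥500 ms discards the trial), zero-phase second-order
  Butterworth low-pass (default 4 Hz), 500 ms fixation baseline with ±2 SD
  trial screening and median-baseline correction, first-order temporal
  derivative, within-session z-scoring, and paired cluster-mass permutation
  tests (sign-flip max-statistic null, 2000 permutations).
- **Plausible-values correlation** (`rlpupil.plausible`): per-draw Pearson
  correlations between latent participant drug effects and an observed
  covariate, plus the averaged analytic posterior of the population
  correlation (validated against a brute-force Monte-Carlo posterior).

## Command line

A single `rlpupil` entry point exposes the pipeline stages:

```bash
rlpupil simulate-agent --alpha 0.3 --beta 5 --seed 1 --out trials.csv
rlpupil synth behaviour --n 20 --seed 1 --out cohort
rlpupil synth pupil --seed 1 --out pupil
rlpupil fit --data cohort.trials.csv --condition gain --design crossover \
    --chains 4 --iters 2000 --warmup 1000 --seed 1 --out fit_gain
rlpupil optimal-grid --condition gain --alpha-step 0.05 --beta-step 0.5 \
    --n-agents 500 --seed 1 --out grid_gain
rlpupil analyze --samples fit_gain --optimal-grid grid_gain.json --out report.json
rlpupil pupil preprocess --in pupil.csv --filter-cutoff 4 --out pre
rlpupil pupil cluster --a cond_a.csv --b cond_b.csv --n-perm 2000 --seed 1 \
    --out clusters.json
rlpupil correlate --samples fit_gain --covariate-csv pupil_change.csv \
    --parameter beta --out corr
```

All randomness is seed-controlled; identical seeds reproduce identical
outputs bit-for-bit.

## File formats

Everything is plain text: trial tables and pupil traces are CSV (missing
pupil samples are empty fields), posterior draws are long-format CSV with a
JSON metadata sidecar (loss-free round trip), and cluster/correlation
reports are JSON.
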