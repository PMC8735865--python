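# seqpred

Sequence prediction in stochastic, changing, structured environments:
exact Bayesian observers, classic heuristics, and small gated recurrent
networks, with the full analysis suite comparing them.

## The problem

An agent observes a binary sequence `x_0, x_1, ...` one symbol at a time
and must output, at every step, a prediction `p_t = P(x_{t+1} = 1 |
x_0..x_t)`.  The sequences are generated by latent Bernoulli probabilities
that occasionally jump ("change points", probability `p_c = 1/75` per
step, new value uniform on [0, 1]):

* **changing unigram** — a single base rate p(1);
* **changing bigram** — two transition probabilities p(0|0) and p(1|1),
  each with its own change points (*independent*) or with simultaneous
  change points (*coupled*).

Good prediction requires balancing stability (averaging out noise)
against flexibility (discarding the past after a change), and in the
bigram environments, leveraging the latent transition structure.  The
quality of a prediction series is its log likelihood
`L = sum_t log[x_{t+1} p_t + (1 - x_{t+1})(1 - p_t)]`, reported as the
**% of optimal log likelihood**: `(L - L_chance)/(L_optimal - L_chance) x 100`,
where chance is the constant prediction 0.5 and the optimum is the exact
Bayesian observer for the generating environment (a hidden-Markov forward
filter over a 20-bin discretisation of each latent probability).

## The agents

* **Optimal observer** — forward filtering with the change-point hazard;
  also exposes the posterior mean, SD `sigma_t`, and log precision
  `psi_t = -log sigma_t` of every latent, used as readout targets.
* **Heuristics** — delta rule (Rescorla–Wagner) and leaky counting
  (Beta-mean) estimators of the unigram or bigram probabilities, each
  with a single free parameter fitted by SGD on the cross-entropy.
* **Recurrent networks** — a GRU-style gated network with 11 recurrent
  units, and three ablations: without gating (vanilla tanh RNN), without
  lateral connections (diagonal recurrence), and without recurrent weight
  training (reservoir; output weights only).  Networks are trained
  self-supervised by backpropagation through time with Adam on the same
  cross-entropy, one pass over 160 (unigram) or 400 (bigram) minibatches
  of 20 sequences of length T = 380.

The headline phenomena this package reproduces: gated networks are
quasi-optimal (~99 % unigram, ~98 % bigram) while every ablation costs
double-digit percentage points in the bigram environment; the optimal
log precision can be read linearly from gated recurrent activity and
anticorrelates with the next-step effective learning rate
`alpha_{t+1} = (p_{t+1} - p_t)/(x_{t+1} - p_t)`; precision causally
drives the learning rate (constrained activity perturbations); and
networks trained with coupled change points transfer change suspicion
between bigrams while independently-trained ones do not.

## Worked example

```python
import numpy as np
from seqpred.environments import EnvironmentConfig, generate_batch
from seqpred.workflows import make_training_data, train_group, evaluate_group

train = make_training_data("unigram", n_minibatches=160, seed=1)
group = train_group("unigram", "gated", n_units=11, n_replicates=5,
                    train_sequences=train, base_seed=3)
test = generate_batch(EnvironmentConfig("unigram", seed=2), 250)
report = evaluate_group([r.params for r in group], test,
                        EnvironmentConfig("unigram"))
print(np.round(report.percents, 2), round(report.mean, 2))
```

prints

```
[99.02 99.01 98.54 98.39 98.86] 98.76
```

five trained gated networks score 98–99 % of the optimal log likelihood
on fresh sequences (0 = chance, 100 = the Bayesian observer), i.e. they
are within about one to two percent of exact Bayesian filtering with
eleven units.

The numbered scripts under `analysis/` run each experiment end to end
(performance tables, learning-rate dynamics around locked change points,
precision readouts and mutual information, perturbations, bigram
readouts, higher-level inference, complexity scaling) and write tidy CSV
tables under `results/`.  Each takes `--scale` and `--seed`.  The same
experiments are available as presets through the CLI:

```bash
seqpred reproduce fig2-performance --scale 0.25 --seed 1
```

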