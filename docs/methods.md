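# Methods

This note documents the models, algorithms, default parameters, and
numerical choices implemented in `seqpred`, and what the synthetic
environments do and do not emulate.

## Generative environments

All data are synthetic binary sequences of length T = 380.  A latent
Bernoulli parameter (the unigram base rate p(1), or the two transition
probabilities p(0|0), p(1|1)) is drawn uniformly on [0, 1] at t = 0 and,
from t = 1 on, redrawn uniformly with probability p_c = 1/75 per step
("change point"), otherwise carried over.  Bigram change points are
independent between the two latents or coupled (simultaneous), two
distinct environments.  The observation at t is Bernoulli with parameter
p(1) (unigram) or p(1|1) after a 1 and 1 − p(0|0) after a 0, with the
pre-sequence observation taken to be 0.

Conventions worth making explicit:

* A change point is the redraw *event*; `change_flags` record events even
  if the redrawn value happens to be close to the old one (probability
  zero of exact equality).  t = 0 is the initial draw, never flagged.
* Per step, latents update first, then the observation is sampled from
  the time-t latent.
* Every sequence owns a random stream derived from `(seed, index)`
  (`numpy` `SeedSequence` spawn keys), so datasets are reproducible
  regardless of generation order; within a sequence the draw order is
  change flags, then latent values, then observation uniforms.
* `generate_locked_batch` fixes the redraw times across sequences (used
  for averaging the learning-rate dynamics around changes);
  `generate_streak_probes` builds the 400 fixed-probability prefixes for
  the higher-level inference test (2 observed-bigram identities x 2
  unobserved probabilities x 100 sequences, 74 observations each,
  observed bigram probability 0.2).

What the generator does not emulate: real behavioral or neural data have
drifting (not piecewise-constant) parameters, more than two outcomes,
longer-range dependencies, and observation noise.  Passing tests show
that the agents and analyses behave as designed *under this generative
family*, not that the conclusions transfer to arbitrary natural
sequences.

## Optimal observer

The environment is a hidden Markov model once each latent probability is
discretised into 20 equal-width bins; bin representatives are the centers
(k + 0.5)/20 (the discretisation is the model definition here, not an
approximation knob; 20 bins keeps the bigram joint at 400 cells).  The
observer alternates a Bayes update (multiply each cell by the Bernoulli
likelihood of the observation — conditioned on the previous observation
in the bigram case — and renormalise) with the hazard transition
`mass' = (1 − p_c) mass + p_c uniform` (applied per axis for independent
change points, jointly for coupled).  Filtering is in linear space with
per-step renormalisation; with ≤ 400 cells and bin values strictly inside
(0, 1) underflow cannot occur.  Mass normalisation is maintained to
1e−12 per step.

Per step the trace records, from the *transitioned* (predictive)
posterior: the prediction p_t (posterior-mean probability that the next
observation is 1, conditioned on the current observation in the bigram
case), and each latent's posterior mean, SD σ_t, and log precision
ψ_t = −log σ_t (natural log).  A point-mass posterior would make ψ
infinite and raises an explicit error rather than returning ±inf.

The filter is verified against a brute-force oracle that enumerates all
change-point configurations of short sequences (T ≤ 8) and marginalises
the latents over the same grid, for all three environments, to 1e−12.

## Prediction alignment and scoring

All agents emit p_t after consuming x_t, predicting x_{t+1}; the shared
pre-sequence reference prediction is 0.5.  The sequence log likelihood
sums log[x_{t+1} p_t + (1 − x_{t+1})(1 − p_t)] over t = 0..T−2 (the final
prediction has no target).  Performance is the % of optimal log
likelihood, an affine rescaling with the constant-0.5 agent at 0 and the
exact observer at 100; it is invariant to common shifts of the three log
likelihoods.

## Heuristic agents

Delta rule: `p̂ ← p̂ + α(x − p̂)`, initialised at 0.5.  Leaky counts:
`n_k ← α n_k + 1{event k}` with the Beta-mean estimate
`p̂ = (n_1 + 1)/(n_1 + n_0 + 2)`.  Bigram variants keep separate
estimates (or count tables) per context and update on observed pairs
(x_t, x_{t+1}) only — the first observation initialises the context
without an update.  The emitted prediction is p̂(1|1) after a 1 and
1 − p̂(0|0) after a 0.

The single parameter α is fitted by SGD (learning rate 3e−3, minibatches
of 20 sequences, one pass over the training set) on the same
cross-entropy, with the exact gradient obtained by forward-mode
differentiation through the recursion (checked against central finite
differences to 1e−6 relative).  α is projected to [1e−4, 1 − 1e−4] after
each step to keep the recursion well defined; initial values are drawn
from r ~ log-uniform on [10^−2.5, 10^−0.5], with α = r (delta) or
α = exp(−r) (leaky).

## Recurrent networks

All four architectures share one input unit carrying x_t, N recurrent
units (default 11), and a sigmoid output unit.  The gated step is

    r = σ(w_xr x + b_xr + h W_hr + b_hr)
    z = σ(w_xz x + b_xz + h W_hz + b_hz)
    h' = z ⊙ h + (1 − z) ⊙ tanh(w_xh x + b_xh + r ⊙ (h W_hh) + b_hh)

with h_{−1} = 0.  The reset gate multiplies only the recurrent drive
inside the tanh; b_hh sits outside the gated product.  Ablations:
*no gating* fixes r ≡ 1, z ≡ 0 (vanilla tanh RNN; the r/z parameters do
not exist); *no lateral connections* zeroes all off-diagonal recurrent
weights (enforced at initialisation and on every gradient);
*frozen recurrence* keeps gated dynamics but trains only w_hp and b_hp.
Hidden states are convex combinations of previous states and tanh
outputs, hence always in (−1, 1).

Initialisation: biases ~ Uniform[−1/N, 1/N]; output weights
~ Normal(0, (1/N)²); input weights ~ Normal(0, σ0_x²); recurrent weights
~ Normal(0, σ0_h²) off the diagonal and Normal(μ0_diag, σ0_h²) on it.
σ0_x, σ0_h, μ0_diag and the Adam step size η0 come from a packaged table
(`seqpred/data/hyperparameters.csv`) selected by a prior per-environment,
per-architecture, per-size search; sizes absent from the table resolve to
the nearest tabulated N in log space (used by the complexity sweep).  A
fresh hyperparameter search is out of scope; an optional random-search
utility can be built from `fit_heuristic`-style loops if needed.

Training minimises the minibatch cross-entropy (mean over scored steps
and sequences; the mean-vs-sum choice is absorbed by η0 up to Adam's
epsilon) by backpropagation through time over full sequences, implemented
directly in numpy and verified against central finite differences for
every parameter of small networks (1e−5 relative).  Adam uses β1 = 0.9,
β2 = 0.999, eps = 1e−8.  One gradient update per minibatch of 20
sequences, a single pass over the dataset (160 minibatches unigram, 400
bigram — the loss converges well before the end), no gradient clipping; a
non-finite loss raises a training-failure error rather than being
silently clipped.  A replicate's seed controls its initialisation and its
shuffling of the shared training data.

## Analyses

* **Effective learning rate** `α_{t+1} = (p_{t+1} − p_t)/(x_{t+1} − p_t)`
  with `α_0 = (p_0 − 0.5)/(x_0 − 0.5)`; steps with |x − p| < 1e−6 are
  masked and excluded from averages.  For the delta rule this recovers α
  exactly; for adaptive agents it peaks after change points.
* **Readouts** are OLS fits (with intercept) from hidden activations to a
  target series, pooled over time steps and sequences; fitting uses 900
  sequences, accuracy is the Pearson r on 100 held-out sequences, and the
  precision/learning-rate correlation uses 300 further sequences
  (pairing ψ at t with α at t + 1, the strict next step).  Targets:
  unigram log precision; bigram log odds of the posterior mean and log
  precision, per latent.  Rank-deficient designs are flagged and solved
  by pseudo-inverse.
* **Mutual information** between two continuous series uses 32
  equal-frequency bins per series and the empirical joint distribution,
  in nats.  This estimator saturates at log 32 ≈ 3.47 nats, so only the
  *ordering* across architectures is meaningful, not absolute values.
* **Subspace projection**: states are expressed along the output-weight
  (prediction) axis and the precision-readout axis orthogonalised against
  it by one Gram–Schmidt step.
* **Perturbations**: a vector q with q·w_pred = 0, q·w_prec = δ,
  ‖q‖ = c, built from the projection of w_prec onto the null space of
  w_pred plus a random component affecting neither quantity; constraints
  hold to 1e−10 by construction and are tested against an independent
  quadratic-programming solution.  Defaults (the study conditions leave
  them open): c = 0.1 x the median hidden-state norm at probe points;
  five δ levels spanning ±1 SD of the read precision, capped at 90 % of
  the feasible maximum c·‖q_ψ‖ imposed by the norm; 1000 probe points
  drawn from t ∈ [10, T−2] of 300 sequences (avoiding the initial
  transient), resampled if the unperturbed learning rate is degenerate.
* **Higher-level inference**: each probe prefix is followed by a query
  input (the unobserved bigram's context), m streak repetitions, and a
  second query; the statistic is |p_after − p_before| averaged over the
  400 probes, per m ∈ [2, 75].  Queries advance the agent state, exactly
  as the same observations would for any observer.  Groups trained on
  coupled vs independent change points are compared by a one-tailed
  two-sample t-test on per-agent mean changes.
* **Complexity**: % of optimal per size N over a log-spaced grid, with
  the vanilla-RNN gap fitted as (100 − p) = c (1/N)^a by least squares on
  (log N, log(100 − p)).
* **Group statistics**: Welch t (Satterthwaite dof) two- or one-sided,
  paired one-sided t (zero-variance differences flagged as degenerate),
  and the interaction F of a balanced two-factor linear model; group-mean
  CIs use the Student t interval over replicates (Welch interval for
  two-group differences).

## Problem sizes and defaults

Full scale mirrors the study conditions: 20 replicate seeds per agent
type, 1000 test sequences, readout analyses on 900/100/300 sequences.
The test suite and the acceptance script train 5 and 10 replicate seeds
per group respectively and evaluate on 250 test sequences, keeping the
readout analyses at their full sample sizes (replicate counts dominate
the remaining variance; analysis-sample noise is cheap to remove).
Experiment presets expose a `--scale` factor that shrinks replicate
counts and dataset sizes proportionally but never sequence length,
change probability, or architecture sizes, which would change the
science rather than the precision.

## Known limitations

* The hyperparameter table is taken as given; nearby sizes reuse the
  nearest row, so sweep values between tabulated sizes are mildly
  suboptimal.
* The MI estimator's absolute values are binning-dependent (see above).
* Group means over 5–10 seeds retain visible replicate noise in the
  ablation drops (per-network scatter is several percentage points for
  the no-lateral and frozen groups).
* The LSTM gating variant and >2-symbol alphabets are out of scope.
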