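# Methods

## The model

`lookdyn` implements a process model of gaze allocation in
preferential-looking experiments with two pictures. Gaze is coded into
three areas of interest (AOIs): the target picture (index 1 / label T),
the distractor picture (2 / D), and everything else (3 / M). Each AOI
carries a latent activation a_i(t) > 0 interpreted as saccadic priority;
the model couples four mechanisms:

1. **Saccadic selection.** At the end of a fixation on AOI j, the next
   target is drawn with probability

       pi_i = (a_i^nu + rho * delta_ij) / sum_k (a_k^nu + rho * delta_kj)

   The exponent nu weights relative activations (nu = 1 is Luce's choice
   rule; nu -> infinity approaches winner-takes-all). The additive bias
   rho >= 0 raises the probability of refixating the currently fixated
   AOI, capturing the high empirical prevalence of refixations.

2. **Decay.** Between saccadic events activations relax exponentially to
   fixed baselines a0 = (1.1, 1.0, 0.37):

       da_i/dt = omega * (a0_i - a_i)
       a_i(t + dt) = a_i(t) e^(-omega dt) + a0_i (1 - e^(-omega dt))

   The implementation uses the closed form only — there is no numerical
   integration error anywhere in the dynamics. The baselines are treated
   as constants during inference: baselines and boost factors are poorly
   jointly identified, and the dynamical component is the quantity of
   interest. The target/distractor baseline asymmetry encodes a static
   preference; the outside region's low baseline encodes its low appeal.

3. **Boost.** At each fixation onset (including refixations) the fixated
   AOI's activation is multiplied by its boost factor lambda_i >= 1.
   This is the dynamic component of differentiation: an individual who
   recognises the target has lambda_1 > lambda_2, so looking at the
   target transiently raises its priority and begets more target looks,
   until decay erases the advantage.

4. **Timing.** The duration of a fixation is gamma distributed with
   shape sigma and rate sigma / mu', where the effective mean

       mu' = mu_t * (1 + gamma_mod * a)

   is modulated by the activation a of the fixated AOI measured at
   fixation onset, immediately *after* the boost. The post-boost
   convention matters: it is what separates target from distractor
   duration distributions when lambda_1 > lambda_2, even at equal
   pre-boost activations. With gamma_mod = 0 the timing law collapses to
   a single gamma distribution for all AOIs, with CV = 1/sqrt(sigma).

Saccade durations are neglected: fixations tile the trial contiguously,
and the final fixation is truncated at the trial boundary and flagged.

## Parameters

Nine free parameters, in the canonical vector order used everywhere:

| name   | meaning                         | unit  | default | bounds |
|--------|---------------------------------|-------|---------|--------|
| nu     | selection exponent              | —     | 1.0     | > 0    |
| rho    | refixation bias                 | act.  | 0.3     | >= 0   |
| omega  | activation decay rate           | 1/ms  | 1.5e-3  | > 0    |
| lam1   | target boost                    | —     | 1.4     | >= 1   |
| lam2   | distractor boost                | —     | 1.1     | >= 1   |
| lam3   | outside boost                   | —     | 1.1     | >= 1   |
| gamma  | duration-modulation gain        | —     | 0.5     | >= 0   |
| mu_t   | nominal mean fixation duration  | ms    | 200     | > 0    |
| sigma  | duration shape (CV^-2)          | —     | 8       | > 0    |

Defaults are the strong-target-differentiation regime: lam = (1.4, 1.1,
1.1), sigma = 8 and mu_t = 200 ms with gamma = 0.5 mirror the regimes
used throughout the package's own illustrations and tests. nu = 1 (the
plain Luce rule), rho = 0.3 and omega = 1.5e-3 /ms (decay half-life
~0.46 s, comfortably between a fixation and a trial) are package
choices on the scale of the phenomena being modelled; all are plain
constructor arguments.

Time is milliseconds throughout; omega is per ms.

## Likelihood

Given an observed scan path, the state dynamics are deterministic: the
likelihood replays boost and decay along the data and accumulates, per
fixation, the log gamma density of the observed duration and the log
selection probability of the observed next AOI. Conventions:

- The first fixation's AOI is **conditioned on** (no selection factor):
  the model does not specify an initial-selection rule, and the
  simulator's default baseline-sampled first AOI is correspondingly not
  scored. Its duration is scored.
- The truncated final fixation enters through the gamma log survival
  function (right censoring at the trial boundary).
- All accumulation is in log space with stable log-gamma forms;
  selection weights are max-rescaled so the winner-takes-all regime
  (large nu) cannot overflow.
- Durations are continuous; no binning.
- Illegal parameters raise, they never return -inf: -inf is reserved for
  genuinely zero-probability data.

Two code paths compute the same quantity: a numpy implementation
vectorised over parameter vectors (the reference, used by the public
log-likelihood and profile functions) and a numba-compiled scalar path
used inside MCMC. A test asserts agreement to 1e-9 on random draws.

## Inference

Per-individual posteriors are sampled with the emcee affine-invariant
ensemble sampler on an unconstrained scale: log for nu, omega, mu_t,
sigma; log(x + 0.01) for rho and gamma_mod; log(lambda - 1 + 0.01) for
the boosts. Priors are independent normals on that scale (log-normal on
the natural scale), weakly informative: centred at nu ~ 1.5, rho ~ 0.5,
omega ~ 1.5e-3 /ms, lambda - 1 ~ 0.2, gamma ~ 0.3, mu_t ~ 250 ms, sigma
~ 6, with log-sds 0.4–1.0 (roughly an order of magnitude each).

Numerical choices:

- Walkers start in a small ball (sd 0.02) around a Nelder-Mead MAP
  estimate found from the prior mean; short chains then only need to
  explore the mode, not find it. Everything is deterministic given the
  seed.
- Moves: 80% differential-evolution, 20% DE-snooker. These mix far
  faster than the default stretch move on this correlated 9-d posterior
  (R-hat < 1.05 and ESS > 200 per parameter at the default 32 walkers x
  2500 steps with 50% burn-in; the short test configuration of 24 x 800
  trades diagnostics for speed and is flagged, not hidden, via
  `PosteriorChain.converged`).
- Diagnostics are rank-normalised R-hat and ESS (arviz), treating
  walkers as chains — conservative for an interacting ensemble.
- Prior-only mode drops the likelihood so sampler correctness can be
  validated against the prior's quantiles.

The packaged recovery experiment simulates one individual's data volume
(32 trials x 5 s, configurable — the exact real-world per-infant count
is not fixed by the package) and refits. Under the default regime, 90%
credible intervals cover the generating value for 8–9 of 9 parameters
in a typical replicate.

## Synthetic cohorts

`generate_cohort` draws ages uniformly on 12–18 months and sets each
individual's parameters to a linear age trend times log-normal
between-individual noise (boosts are trended on lambda - 1 so the
lambda >= 1 bound is respected; draws violating any bound are resampled,
capped at 100 attempts before a configuration error). Default trend
directions encode the developmental pattern the model expresses: mu_t
260 -> 200 ms, omega 1.0e-3 -> 2.0e-3 /ms, rho 0.6 -> 0.2, sigma 7 -> 9,
lam2 1.4 -> 1.05, with lam1 (1.4) and lam3 (1.1) flat. Magnitudes are
free configuration; the defaults were calibrated so that a 60-individual
cohort exhibits a clearly visible increase of target looking with age
(Spearman rho ~ 0.4–0.6) — the distractor-boost decline is the dominant
driver, with the refixation-bias decline contributing. Age enters
generation only; all fits are per-individual and age-blind, so any
recovered age trend in fitted parameters is an out-of-sample check.

What the generator does **not** emulate: dropout and trial attrition,
calibration loss, blinks/off-screen epochs beyond the outside AOI,
saccade durations, within-AOI gaze position, and any trial-level
stimulus structure. Passing tests therefore demonstrate internal
consistency of model, likelihood and sampler under the model's own
assumptions — not robustness to the messiness of real infant data.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` use: 100 randomized decay
configurations against an RK integration (agreement < 1e-6); 1e5
simulated selection events against the analytic rule (3 Monte-Carlo SE);
1e4 sampled durations against the gamma law (KS, alpha = 0.01); a
hand-replayed likelihood oracle (1e-9); profile scans on 200-trial
datasets (median over 3 replicates, since single-dataset peak-location
counts are noisy for the weakly informed parameters rho and lam3);
10 recovery replicates at 32 trials with short chains; 500-trial
contrasts for the boost effect; and a 10-individual cohort for
posterior-predictive calibration. These sizes keep a full run in a few
minutes while leaving every Monte-Carlo margin comfortably wide.

## Known limitations

- The initial-fixation rule (baseline-probability sampling) and the
  censoring of the final fixation are package conventions; other
  treatments (e.g., scoring the first selection) would change absolute
  log-likelihoods slightly.
- rho and lam3 are weakly informed at single-individual data volume;
  their profiles are shallow and their posteriors lean on the prior more
  than the other parameters.
- Baselines a0 are fixed, so misfit in overall AOI attractiveness is
  absorbed by the boosts.
- The cohort's age trends are linear with log-normal noise; real
  developmental trajectories need not be either.
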