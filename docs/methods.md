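# Methods

## Task model and correctness assumption

A trial presents a hidden island whose predominant animal appears
i.i.d. with probability q ∈ {0.6, 0.8} per draw; the participant draws
n ∈ [0, 20] animals at c ∈ {0, 1, 4} credits each and earns 100 credits
for a correct two-alternative judgment.  We model the judgment as the
majority of the seen draws with a fair coin on ties; p(0|q) = 1/2
exactly.  Under this rule the correctness probability is an exact
binomial tail plus half the tie mass.  We compute it by direct binomial
summation (n ≤ 20 needs no asymptotics).  Two consequences worth
keeping in mind:

- **Parity**: an even 2k-th draw adds no accuracy over 2k−1, so
  p(2k|q) = p(2k−1|q) exactly.  At zero cost this makes n = 19 and
  n = 20 exact ties in expected gain; the argmax breaks ties toward the
  smaller n (fewer draws weakly dominate at equal gain) and treats
  gains within 1e−9 credits as tied, since float summation separates
  the mathematically equal pair by ~1e−14.
- Efficiency is expected gain at the observed n over the maximum;
  signed deviation is n − argmax; both therefore inherit the exact
  binomial model, and the behavioral module computes them through the
  same functions (single source of truth).

## Stopping models

Decision points run j = 0..19 (a judgment with zero samples is a real
option) and j = 20 is a forced, probability-free stop.  One-stage
models pass a linear combination of decision variables through a
logistic; two-stage models combine two stage hazards with a
second-thought probability p_sec conditioned on the cost or the
evidence condition, p = p1 + (1−p1)·p_sec·p2.

DV families: cost = {low/high-cost dummies (zero-cost reference), draws
j, cumulative cost c·j}; evidence = {unit log evidence ln(q/(1−q)),
decayed |CI|, their product (total log evidence), last trial's sample
count, last trial's correctness coded ±1}.  Within-trial cumulative
information follows CI_j = α·CI_{j−1} ± 1 and resets to 0 at each trial
start.  Choices made where the source material is underdetermined:

- The one-stage cost-plus-evidence model carries a single intercept;
  each stage of a two-stage model has its own intercept within its DV
  family.
- Last-trial DVs at the first trial (and, when carryover across blocks
  is disabled, at block boundaries) are 0; correctness coding is
  +1/−1/0.  `carryover_across_blocks` defaults to on, since trials are
  consecutive in experiment order.
- Decision variables enter raw (no z-scoring); a `standardize_dvs`
  flag on the likelihood layer exists for fitting experiments but the
  simulator always uses raw DVs, so the flag should not be combined
  with posterior predictive checks.
- The sign convention of CI (+1 dog, −1 cat) is irrelevant to the
  models, which only use |CI|.

Trial likelihood is the discrete-hazard likelihood: a voluntary stop at
n < 20 contributes Σ_{j<n} log(1−p_j) + log p_n, the forced stop at 20
only the continuation factors.  The analytic stopping distribution
P(N=n) = p_n·Π_{j<n}(1−p_j) (with the forced-stop remainder at 20) is
used as an oracle against the Monte-Carlo agent, and for posterior
predictive checks it is evaluated on the full pregenerated 20-symbol
sequences, including draws the agent never saw.

## Synthetic cohorts (study conditions)

The generator reproduces the experiment structure: three cost blocks in
seed-permuted order, two evidence mini-blocks nested per block in
random order, 16 trials per mini-block (96 trials; 8 per mini-block
gives the 48-trial short form used for children who found the session
long).  Stimuli are i.i.d. Bernoulli(q) draws of the predominant
animal, generated to the full length of 20 (no urn depletion — the task
shows animals one at a time from fixed island ratios).

Child-level parameters are drawn from group-level normals on the
unconstrained scale (log-odds for α and p_sec), mirroring the
hierarchical model.  The two presets were chosen once, by pilot
simulation, to reproduce the reported behavioral profile of each group
and then frozen:

- **NT-like** (neurotypical): zero-cost mean samples ≈ 11, overall
  efficiency ≈ 0.93–0.94, negative last-trial carryover
  (β_LastDraw = −0.05) stabilizing sample counts, near-uniform evidence
  weighting (α ≈ 0.90).
- **ASD-like**: lower baseline stopping tendency (zero-cost mean
  samples ≈ 15.5), stronger nominal cost offsets, weaker within-trial
  dynamic sensitivity (β_Draw, β_CumuCost, β_|CumuInfo| closer to 0),
  last-trial carryover near zero, faster evidence decay (α ≈ 0.60) —
  yielding higher inter-trial sampling variation under cost and lower
  high-cost efficiency.

What the generator does *not* emulate: learning across blocks (beyond
the last-trial DVs), reaction times, lapses/attention failures, and any
within-child nonstationarity.  Passing recovery tests on these cohorts
therefore demonstrates that the inference machinery is correct and well
calibrated for the model class, not that the model class captures every
feature of real child data.

## Hierarchical inference

Each group is fitted separately.  Priors (the defaults of the
`PriorSpec`): group means ~ Normal(0, 2) on the unconstrained scale,
group SDs ~ half-Normal(1), α and p_sec fitted on the log-odds scale.
The posterior is sampled with an in-package Hamiltonian Monte Carlo
sampler: analytic gradients of the joint density (verified against
finite differences for all six models), non-centered parameterization
by default (a centered variant exists and is cross-checked on small
cohorts), dual-averaging step-size adaptation targeting 0.8 acceptance,
a diagonal mass matrix estimated in a middle warm-up window, jittered
leapfrog path lengths, and an energy-error divergence threshold.

Presets: `full` reproduces the study configuration — 4 chains, 5,000
warm-up and 10,000 sampling iterations each, hence exactly 40,000
retained draws per parameter; `desk` (2 × 1,000/1,000) is the scale
used by the test suite and the acceptance script so that a 40-child fit
completes in a few minutes on one CPU; `smoke` (2 × 150/150) drives
CI-sized checks.  At desk scale some group-level SDs mix slowly (split
R-hat can exceed 1.01); diagnostics are always computed (arviz split
R-hat and bulk ESS per parameter, divergence counts) and a failed check
warns rather than silently passing.  Parameter recovery — the quantity
the desk preset is used for — is robust at this scale (rank
correlations ≈ 0.9 for child-level draw sensitivity, ≈ 0.99 for group
means in the recovery harness).

## Model comparison

Pointwise per-trial log-likelihoods (leave-one-trial-out resolution,
the default; a leave-one-participant-out variant would sum within
child) are evaluated over evenly thinned posterior draws.  PSIS
smoothing of the importance weights is delegated to arviz; ELPD, its
SE, the paired SE of ELPD differences, and pseudo-BMA+ weights (flat
Dirichlet Bayesian bootstrap over trials, softmax per replicate,
averaged) are computed in-package.  Pareto k > 0.7 flags unreliable
points (standard PSIS practice).  Comparison is always within one
group.

## Simulation-based calibration

SBC draws group-level parameters from the prior, simulates a cohort,
refits, and ranks each true value within D evenly thinned posterior
draws; ranks must be uniform on [0, D].  Because the original procedure
relied on visual inspection, a formal check was added: a chi-square
goodness-of-fit over 20 near-equal rank bins plus an ECDF-distance
diagnostic.  A conjugate normal-mean toy with an analytic posterior
validates the rank machinery in both directions (calibrated inference
passes; a posterior with its SD halved is rejected).  The published
scale is N = 1000 replicates with D = 400 draws after thinning by 10
across two chains; the desk default is N = 50 with a reduced design.
Parameters of interest default to the group-level means and SDs.

## Behavioral statistics

Outcomes per child × condition: trial count, mean samples, mean
credits, accuracy, mean efficiency, mean signed deviation, and
inter-trial SD of samples (undefined below two trials; such cells are
flagged and excluded from variation analyses rather than imputed).
Group contrasts fit outcome ~ group × cost × evidence with a
per-participant random intercept via statsmodels MixedLM — the
parsimonious simplification of the maximal within-participant
structure; if even that is singular the model falls back to fixed
effects with participant-clustered covariance and records the
simplification.  Estimated marginal means come from the fixed-effect
design; contrasts (overall group difference and per-condition-level
differences) carry a single-step max-|z| multiplicity adjustment
simulated from the joint normal distribution of the estimates.  Degrees
of freedom use the between-subject approximation (children − groups)
rather than a Satterthwaite correction, so p-values for small samples
are mildly anti-conservative; effect sizes are contrast estimates
standardized by the total outcome SD.  Parameter–behavior associations
use Spearman correlations with Benjamini–Hochberg FDR adjustment.

## Numerical choices and limitations

- Binomial probabilities via scipy's binomial pmf; no normal
  approximation anywhere in the task math.
- Likelihood evaluations flatten all trials to decision-point rows;
  gradients are exact (chain rule through the decay recursion via a
  parallel recurrence for dCI/dα; the |CI| kink uses the sign
  subgradient, 0 at CI = 0).
- Two-stage continuation probabilities are computed in log space as
  log(1−p1) + log1p(−p_sec·p2); divisions in gradients floor their
  denominators at tiny positive values.
- The sampler uses static trajectories with jittered lengths rather
  than a dynamic no-U-turn criterion; for these posteriors (a few
  hundred dimensions, logistic likelihoods) this trades some sampling
  efficiency for simplicity, which is why the full preset's long chains
  remain the reference configuration.
- Problem sizes in the test and acceptance harnesses (40-child desk
  recovery; 10-child, 48-trial cohorts with 2 × 250/250 chains for
  model recovery; N = 50 toy SBC) were chosen as the smallest scales at
  which the pilot studies showed the checks to be stable.
- The OSF-deposited child data are not bundled; all benchmarks run on
  synthetic cohorts.  `read_trials`'s `column_map` adapts the deposit's
  schema when available.
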