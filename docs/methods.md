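# Methods

This note documents the model, its numerical choices, the synthetic data,
and the limits of what the tests demonstrate.

## Decision problem

The world is a discrete-turn MDP with four real states — nest, cautious
object, confident object, retreat — and three imagined ones — cautious
detect, confident detect, dead. A bout is nest → approach → 2–4 turns at
the object → retreat → nest. The approach action fixes the bout's type; the
first object turn (τ = 1) is the approach itself and carries no detection
risk (θ₁ = 0), and a stay is forced there so that every bout lasts at least
2 turns. At τ = 4 retreat is forced. Retreat occupies one turn and returns
deterministically to the nest.

Rewards are: the imagined exploration bonus at the object states
(state-dependent, deterministic given the pool), a travel cost on each
approach and retreat edge, and a dying cost on the transition into the
absorbing dead state; the nest pays nothing.

### Fixed constants

| constant | default | meaning |
|---|---|---|
| travel cost | −0.8 | per nest↔object traversal |
| dying cost | −10 | on expiring after detection |
| p₁ | 0.6 | failed-escape probability, confident detect |
| p₂ | 0.3 | failed-escape probability, cautious detect |
| γ | 0.98 | per-turn discount |
| R | 1.1 | confident harvest scale: ω_confident = R/G₀ |
| K | 0.89 | cautious/confident harvest ratio |
| n¹₀, n⁰₀ | 1, 1 | reward-belief pseudocounts (never updated here) |

R, K and the reward pseudocounts are part of the model specification. The
costs, escape probabilities and γ are free constants of the decision
problem; these defaults were chosen (once, by pilot simulation over a
coarse grid) so that cautious approach strictly dominates confident
approach under a pessimistic hazard belief and all three phenotypes are
reachable within the fitted parameter ranges. Two properties of this
economy are worth making explicit. First, a peak-to-steady frequency
transition requires the per-cycle travel cost to outweigh the constant
n¹/(n¹+n⁰) = 0.5 per-turn reward floor once the pool is depleted; with a
much smaller travel cost the agent never slows down. Second, because the
nested distortion compounds across the five backup stages and a bout
commits to at least one hazard roll, approach collapses entirely once ᾱ
falls much below ~0.85 at these costs — trait risk aversion in this model
lives in a narrow band, and "low ᾱ" means low relative to the risk-neutral
1.0. All constants are config-overridable.

## Hazard belief

Detection by τ is the noisy-or of per-turn Bernoulli causes with Beta
priors, parameterized by mean and variance for fitting (the variance must
lie strictly inside (0, μ−μ²); the moment-to-pseudocount transform is
a = −μ(μ²−μ+v)/v, b = (μ−1)(μ²−μ+v)/v). Only negative observations occur —
there is no predator — so the posterior update is conjugate: a completed
bout of length τ increments b_j for every j ≤ τ. Within a bout the same
update is applied incrementally (surviving the stay into turn j increments
b_j), which composes exactly to the bout-level update and is what planner
branches condition on. The per-turn conditional detection probability used
by the transition model is the survival-conditional hazard increment
[h(τ+1) − h(τ)]/[1 − h(τ)], which equals the posterior mean of θ_{τ+1};
chaining these along the safe branch reproduces the cumulative h exactly
(tested). Positive (detection) observations have no tractable posterior and
never arise; the imagined escape branch carries the belief unchanged.

## Planner

Receding-horizon tree search over hyperstates (state, belief, pool) with
the nested-CVaR backup: at every stage the successor values are reweighted
by the worst-case ξ in the CVaR envelope, solved in sorted-greedy form
(an LP solves the same program in the test oracle only). The distortion is
applied per stage — time-consistent nested CVaR, not precommitted CVaR —
and acts only on realizable transition outcomes weighted by their
posterior-expected probabilities.

Numerical choices:

* depth 5 (one complete nest→object→nest cycle); leaf value 0 at real
  states. Imagined detect chance nodes are resolved even when the depth
  budget is exhausted, so the dying cost is never truncated out of a
  shallow evaluation. Without this, approach values *fall* with depth
  while deferral hides the retreat cost, and the planner procrastinates
  indefinitely for any marginal configuration (verified numerically); the
  budget applies to real time steps, not to the instantaneous imagined
  resolution.
* ties are broken in the fixed order stay-nest, approach-cautious,
  approach-confident, stay-object, retreat, making every simulation
  bitwise reproducible.
* values are memoized on the full hyperstate; repeated steady-state
  decisions in long rollouts are cache hits.
* the bonus pool advances inside imagined branches exactly as in reality
  (deplete-then-regenerate-then-clamp at object states, regenerate
  elsewhere), so planned and realized pool trajectories coincide on the
  no-detection path.

## Simulation and phase statistics

Rollouts are 200 turns (= 100 minutes at 2 turns per minute); reality
always takes the no-detection branch. Bouts are maximal runs of object
states; a final bout censored by the session end is excluded from
statistics. The cautious→confident transition is the first confident bout;
the peak→steady transition is the first wait of more than one consecutive
nest turn that the agent subsequently returns from (a trailing nest run at
the session end is censoring, not a transition). Group assignment for model
runs is structural: confident bouts plus a post-transition slowdown →
brave; confident bouts without one → intermediate; cautious-only with a
slowdown → timid; anything else is degenerate and unfittable.

Durations map to animal seconds by d = 0.75 + 1.5·(d_turns − 2) on the
realizable range [2, 4]; phase durations are means over the phase's bouts.
Phase frequency is the inverse mean start-to-start period between
consecutive bouts *within* the phase; a phase holding a single bout falls
back to that bout's period to its successor. Periods therefore include the
retreat turn on the nest side of the cycle.

Animal records (minute resolution: % time in cautious and confident
approach, mean bout duration, bouts/min) are segmented by least-squares
boxcar fits with exhaustive change-point search — one change point per
curve, fitted sequentially (cautious collapse gives t₁; for brave animals
the confident curve after t₁ gives t₂). Phase levels are segment means.
Classification uses confident-approach time: none at all → timid;
otherwise the ratio y of confident time in the first 10 minutes after
confident onset to the last 10 minutes of the session separates brave
(y > 1) from intermediate (y ≤ 1, boundary inclusive).

## Fitting

ABC-SMC in the standard weighted-particle scheme: adaptive threshold at
the 30th percentile of the previous generation's distances (monotone
non-increasing by construction), uniform priors (μ ∈ (0.01, 0.99), v
conditionally uniform on (0, μ−μ²), ᾱ ∈ (0.05, 1], G₀ ∈ (2, 40),
f ∈ (0, 2)), diagonal Gaussian kernel with per-dimension Silverman
bandwidths 0.9·min(sd, IQR/1.34)·B^(−1/5) floored at 1e−6, and importance
weights π(θ)/Σ w_j K(θ|θ_j). The distance is the normalized L1 with
kind-specific normalizers evaluated at the simulated value (durations 4.0 s;
transition times min(30, 10+0.8·max(x−5,0)); frequency ratios
min(20, 2+(18/19)·max(x−1,0))); a simulated particle whose phase structure
belongs to a different group than the target is infinitely distant.
Generation 0 is rejection sampling restricted to group-matching draws so
the first threshold is finite. A bounded retry budget per generation
(default 50 proposals per accepted particle; tests and the CLI use 150)
ends a stalled run early with the populations collected so far. Simulation
is deterministic, so all randomness is in the particle sampling, and
particle evaluations are order-independent.

The full protocol is 30 generations of 100 particles. The test suite runs
a reduced protocol (16 particles, 5 generations, fixed seed) sized for a
laptop-scale run: it verifies threshold monotonicity, distance contraction
relative to generation 0, and — as a qualitative smoke property, not a
calibrated bound — a positive rank correlation between ᾱ and μ₂ in the
final population when fitting a timid target, the model's risk-aversion /
prior-pessimism trade-off. At this scale that correlation is a weak signal
with substantial seed-to-seed variability; the reduced run demonstrates
the machinery, not a measurement of the ridge.

## Synthetic data

The generator emulates minute-resolution bout records as boxcar phase
profiles (per-group levels, durations, frequencies, change points) with
additive Gaussian noise truncated to valid ranges (percentages clipped to
[0, 100] and jointly to ≤ 100; durations and frequencies to ≥ 0). The
archetype numbers sketch plausible open-field sessions and are fixtures,
not measurements. What passing the round-trip tests shows is that the
segmentation, classification and extraction pipeline is exact on data that
satisfy its piecewise-constant assumptions; real records have drifting
levels, gradual transitions, within-phase trends and correlated noise, so
exact recovery there is not implied. Model-derived fit targets
(simulate a known θ*, extract its statistics) are reproducible bit for bit
because the simulator is deterministic.

## Reference phenotype configurations

Frozen after a one-time pilot grid search; fixtures of the model's
repertoire, not fits to animals:

| | μ₂ | μ₃=μ₄ | v/(μ−μ²) | ᾱ | G₀ | f |
|---|---|---|---|---|---|---|
| brave | 0.20 | 0.10 | 0.7 / 0.5 | 1.0 | 30 | 0.10 |
| intermediate | 0.30 | 0.06 | 0.5 | 1.0 | 40 | 0.30 |
| timid | 0.25 | 0.35 | 0.03 | 0.9 | 32 | 0.05 |

Brave: flexible lower-mean prior, risk-neutral — cautious bouts for ~6.5
minutes, a persistent confident switch, slowdown at ~42 minutes. Timid:
higher-mean, inflexible prior with ᾱ < 1 — only 2-turn cautious bouts and
an early slowdown. Intermediate: fast forgetting and a large pool — the
switch without a slowdown.

## Known limitations

* Bout durations and frequencies can only grow and shrink, respectively,
  along the paths the exploration economy allows: frequency never
  increases across a transition (hence the clamped intermediate ratio),
  and within a phase bout length is essentially constant — duration
  contrasts are expressed across phenotypes and phases rather than as
  within-phase drift.
* The hazard support stops at τ = 4 and the environment's costs are free
  constants, not measured quantities; conclusions about fitted parameter
  values are conditional on that economy.
* The receding horizon is exactly one cycle; longer-range trade-offs
  (e.g. saving pool for later sessions) are outside the model.
* The ᾱ–μ₂ ridge is demonstrated qualitatively at reduced scale only.
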