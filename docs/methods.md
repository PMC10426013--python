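# Methods

## The model

Each individual carries two state variables on [0, 1]: an **action**
`x` (binary in the sharing and protest applications, a continuous
donation share in the Dictator application) and an **attitude** or
personal norm `y`, the action the individual privately considers most
appropriate. Time is discrete; all individuals act and then all update
attitudes, synchronously.

**Decisions.** An individual chooses `x` to maximise

    u(x) = pi(x) + v * V(x, y)
           - k1 (x - y)^2          (cognitive dissonance)
           - k2 (x - xbar)^2       (conformity with the peer mean)
           - k3 F (x - G)^2        (conformity with an authority)

where `pi` is the material payoff, `V` the normative value of the
action (weighted by `v`), `xbar` the mean peer action, and the
authority promotes action `G` with messaging efficiency `F`. For a
binary action the decision reduces to the sign of the utility gap

    du = u(1) - u(0)
       = -c + v y + k1 (2y - 1) + k2 (2 xbar - 1) + k3 F (2G - 1),

with `c` the material cost of acting. Decision stochasticity is a
logit (quantal-response) rule: `P(x = 1) = 1 / (1 + exp(-lam * du))`,
with precision `lam` (0 = coin flip, infinity = strict best response,
exact ties broken by a fair coin). The source text calls `lam` a
precision parameter without printing the choice rule; the logit form is
the standard quantal-response reading of that description and is the
one implemented.

**Attitudes.** After acting, with probability `u_y` per round, the
attitude takes a linear step toward the own action, the peer mean, and
the authority's message:

    y' = clip[0,1]( y + alpha (x - y) + beta (xbar - y)
                      + gamma F (G - y) + eps ),   eps ~ N(0, sigma^2).

Individuals who faced no decision this round (e.g. hunters who caught
nothing) have no fresh action to feel dissonant about, so their
`alpha` term is dropped while the peer and authority pulls still apply.
Clipping to [0, 1] is our choice (the attitude scale is bounded and the
source leaves the boundary behaviour unstated).

`F` multiplies both the decision weight (`k3 F`) and the attitude
weight (`gamma F`). This keeps one code path for all three
applications and reproduces the identity-salience composites
`eps_x = k1/(k1 + k3 F)` and `eps_y = alpha/(alpha + gamma F)`; the
printed one-authority forms correspond to `F = 1`.

## Applications

### Food sharing (`coevo.food_sharing`)

100 groups of 10 exchange migrants at rate `m = 0.1` (island model,
implemented as size-preserving pairwise swaps of the selected agents so
the stated group size is conserved exactly). Per round each agent
hunts successfully with probability `s = 0.15`; successful hunters
decide whether to share (cost `c = 1`, normative value `v y` with
`v = 1`) under an authority of elders promoting `G = 1`. The peer
frequency each agent observes is group-local: the fraction of sharers
among the most recent round's successful hunters in the own group
(initialised at 0 — nobody shares at the outset). Only hunters face
the decision, which is why the observed frequency is defined over them;
groups are small enough that a round's hunters are common knowledge.
Round order: hunt, decide, refresh group frequency, update attitudes
(using the refreshed frequency), migrate.

Reference noise values: `lam = 10`, `sigma = 0.05`, `u_y = 0.5`.
Heterogeneity: `(k1, k2, k3)` and `(alpha, beta, gamma)` are
independent broken-stick draws per agent (break the unit interval at
two uniform points; the three segment lengths, in left-to-right order
— exchangeability makes ordering irrelevant in distribution, so the
unsorted assignment is used). Initial attitudes are log-normal with
mean 0.2 and sd 0.1 **on the attitude scale** (moment-matched before
clipping; draws above 1, about an 8-sigma event at these moments, are
clipped rather than redrawn).

### Political protest (`coevo.protests`)

A well-mixed population of `n = 1000` with `pi = 0`, `V = 0` (`v = 0`):
the decision trades only dissonance, conformity with the known global
protest frequency, and propaganda. The classical fixed-preference
model is the `attitudes_fixed` flag (equivalently
`alpha = beta = gamma = 0`). Decisions condition on the previous
round's frequency; attitude updates use the frequency realised this
round. Everyone starts acquiescent (`p0 = 0`).

Several authorities (a revolutionary leader with `G = 1`, a government
with `G = 0`, ...) compose exactly into one:
`G* = sum(F_i G_i)/sum(F_i)`, `F* = sum(F_i)` — completing the square
shows the summed quadratic costs differ from the composed cost by an
`x`-independent constant, and the summed linear attitude pulls are
identical. The simulator composes the list at setup, so a
multi-authority run is bit-identical to its composed counterpart; the
algebraic identity itself is verified in tests by direct summation.

### Social identity / Dictator game (`coevo.identity`)

The "authority" is the identity group: `G` the stereotypical donation,
`F` its salience. Peers are absent (`k2 = beta = 0`), the material
payoff is `b (1 - x)`, and the normative-value term is set to zero —
all attitude pull runs through the dissonance term, matching the
best-response weights, which involve only `k1` and `k3 F`. Best
responses are deterministic here; stochasticity (if any) enters through
the attitude noise. The closed forms

    x = clip( eps_x y + (1 - eps_x) G - b_bar ),  b_bar = b / (2 (k1 + k3 F))
    x* = G - b_bar / (1 - eps_x eps_y),  y* = G - eps_y b_bar / (1 - eps_x eps_y)

are validated against a grid argmax of the quadratic utility and
against fixed-point iteration of the coupled dynamics. At `F = 0` with
`b > 0` there is no interior equilibrium: the attitude chases the
falling donation and both decay to zero.

## Equilibrium analysis (`coevo.equilibria`)

In the noiseless limit the binary models split into actor and non-actor
classes whose stationary attitudes are

    y_share = (alpha + beta p + gamma F G) / (alpha + beta + gamma F)
    y_not   = (beta p + gamma F G) / (alpha + beta + gamma F)

separated by exactly `alpha / (alpha + beta + gamma F)`. Any frequency
`p` at which actors are content to act and non-actors content not to is
stationary — a line of equilibria, reported on a grid of `p`. Corner
stability uses strict inequalities: universal action is stable iff
`v + k1 + k2 + k3 F > c` (at `G = 1`). The source prints the corner
attitudes without the update rule's denominator ("y = alpha+beta+gamma"
and "y = gamma"); the implemented values are the stationary ones, 1 and
`gamma F G / (alpha + beta + gamma F)`, which reduce to the printed
forms up to that evident omission and are validated by fixed-point
iteration.

Perturbation checks of corner stability nudge one agent's attitude by
`delta = 1e-3` rather than forcing an action flip: a forced flip moves
the deviant's attitude by about `alpha`, large enough to strand the
population on a nearby interior equilibrium of the line even when the
corner is locally stable. The sweep margins (+/-0.01 in `c`) dominate
the `delta`-induced utility shift, so the classification is sharp.

Two numerical caveats. The deterministic attitude map contracts only
when `alpha + beta + gamma F < 2`; above that it amplifies round-off,
so stationarity tests use weight triples scaled below the threshold
(the equilibrium set depends only on their ratios). And because lines
of equilibria are structurally unstable, the analyzer claims
stationarity, not attractivity, for interior points.

## Parameter recovery (`coevo.inference`)

Both model sides are linear in their coefficients, so simulated panels
(actions recorded simultaneously with elicited attitudes) identify
them by regression:

* attitude side — OLS without intercept of `y_{t+1} - y_t` on
  `(x - y)`, `(xbar - y)`, `(G - y)` over records where the update
  fired and did not hit the [0, 1] boundary (clipped records are
  censored observations and would bias OLS). Exact on noiseless
  panels; at `sigma = 0.05` with 100 agents over 200 rounds the
  estimates land within a few thousandths of truth.
* action side — logistic regression of the binary action on
  `(2y - 1)` and `(2 xbar - 1)` with intercept, recovering
  `lam k1`, `lam k2`, and the composite `lam (k3 F (2G - 1) - c)`.
  The peer regressor must be the **predetermined** frequency the
  decision conditioned on (the previous round's); regressing on the
  realised frequency — which contains the very actions being explained
  — produces a strong simultaneity bias, which is why panels record
  both. For the Dictator model, OLS of the donation on `y` recovers
  `eps_x` (slope) and `(1 - eps_x) G - b_bar` (intercept).

`gamma` and `F` (and `k3` and `F`, and `lam` against the decision
weights) enter only as products; estimates expose the composites and
refuse to split them. Recovery panels are generated in a neutral
regime (`G = 0.5`, initial attitudes around 0.5) where actions keep
varying and attitudes stay interior; in saturated regimes (everyone
acting, attitudes pinned at a boundary) the regressors degenerate and
the clipping exclusion truncates the noise, and the fits degrade
accordingly — a caution that applies equally to real panel data.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions: broken-stick
heterogeneity in sensitivities, log-normal initial attitudes, binomial
hunting success, island-model migration, logit decision noise, gated
Gaussian attitude noise. It does not emulate kin structure,
reputation, repeated-partner reciprocity, network-structured influence,
payoff-dependent attitude change, time-varying authority messaging, or
measurement error in elicited attitudes. Passing tests therefore
certify the internal consistency of the framework and the
recoverability of its parameters from ideal panels, not the fit of the
model to any empirical population.

## Problem sizes and defaults

Simulations in the test suite and the acceptance script use the
reference populations (1000 agents) over 300 rounds with the final 75
rounds ("final quarter") as the plateau, 5-10 replicate seeds per
configuration, 100,000 draws for sampler moments, and panels of up to
100,000 records; these sizes give replicate standard errors well below
the effect sizes being asserted. The fixed-vs-updating protest
contrast is evaluated at `F = 0.5` and the bistability demonstration at
`F = 0.4` with homogeneous weights `1/3`: the figure-level source
states the phenomena but not the propaganda strengths at which they
were drawn, so these regimes were chosen from a mean-field analysis of
the reference configuration (at much larger `F` even fixed attitudes
ignite; at much smaller `F` neither run does).

## Known limitations

* The logit choice rule is an interpretation of the stated precision
  parameter, not a printed formula (see above).
* Heterogeneous-population equilibrium structure is characterised only
  through simulation; the analytic module covers homogeneous
  parameters.
* The migration scheme preserves group sizes exactly by pairwise
  swapping; schemes that move agents independently would let sizes
  drift and are not implemented.
* With `alpha + beta + gamma F >= 2` the deterministic attitude
  iteration is not a contraction; the stochastic simulators remain
  well-behaved (clipping bounds the state), but deterministic
  fixed-point iteration should not be used there.
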