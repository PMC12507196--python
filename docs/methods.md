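# Model and methods

`marscrew` simulates the behavioral health of a six-person crew over a
long-duration (default 500-day) Mars-class mission with a daily
discrete-time agent-based model. This note documents the model, the
parameters that matter, the calibration, and the limits of what the
simulations show.

## Agents

Each astronaut agent carries:

* a fixed Big Five personality profile (openness O, conscientiousness C,
  extraversion E, agreeableness A, neuroticism N, each on [0, 1]), drawn at
  crew construction from per-trait truncated normals (rejection sampling on
  [0, 1]). Baseline means follow typical astronaut-selection profiles
  (O 0.5, C 0.8, E 0.5, A 0.7, N 0.3); homogeneous compositions use SD 0.05
  for every trait, heterogeneous compositions SD 0.2 for O and E and 0.1
  for C, A and N. Named scenarios (`high_C_low_N`, `balanced`,
  `high_E_high_A`) replace the means with the midpoints of their trait
  ranges.
* a role and a proficiency vector over four operational domains
  (engineering, medical, science, piloting). Uniform crews share a
  generalist engineer vector [0.85, 0.30, 0.40, 0.30]; differentiated crews
  cycle engineer, medic, scientist, pilot, engineer, scientist with
  specialist vectors (own domain 0.85–0.90, off-domain 0.20–0.40).
* mutable daily state: stress S, performance P, health H, sleep hours SH,
  effective fatigue EF, cumulative workload CW, social support SSU,
  conflict CL.

The 2x2 factorial crosses personality heterogeneity (low/high trait SD)
with role heterogeneity (uniform/differentiated): condition A is uniform in
both, B differentiated in roles only, C heterogeneous in personality only,
D heterogeneous in both.

Initial state (all conditions): S = 0.2, P = 1.0, H = 0.9, SSU = 0.5,
CL = 0, CW = 0, pairwise cohesion 0.7. Note that P = 1.0 at S = 0.2 forces
the optimal stress level S_opt = 0.2 — the performance curve attains 1 only
at its optimum.

## Daily stress and performance

Per agent and day (all quantities dimensionless unless noted):

* personality factor `PF = N − 0.5 C` (fixed per agent; in [−0.5, 1]);
* task-demand stress `ES = NT_i / mean(NT)` (0 on a crew-wide no-task day);
* time pressure `TP = T_required / T_available`, with T_available = 8 h;
* social stress `SS = (CL/CL_max)(1 − A) − (SSU/SSU_max) A` (in [−1, 1]);
* environmental stress `EnvS = max(0, base + N(0, σ)) + event surcharge`,
  a persistent habitat/isolation load with minor fluctuation;
* sleep `SH = clamp(8 − 2 (S_prev − 0.2), 4, 8)` h. The printed linear form
  would exceed 8 h below baseline stress, so an 8 h ceiling is applied; the
  4 h floor would bind only at S > 2.2 and is never reached on [0, 1];
* effective fatigue `EF = (8 − SH)/8 + CW/CW_max`, unclamped;
* overall stress `S = clamp01(w_ES·ES + w_TP·TP + w_EF·EF + w_SS·SS +
  w_EnvS·EnvS + PF)`, with the five weights summing to 1 and PF entering
  unweighted;
* performance `P = exp(−k (S − S_opt)²)`, the inverted-U
  (Yerkes–Dodson-style) stress-performance curve, on (0, 1].

The sleep/stress circularity (sleep needs stress, stress needs fatigue
needs sleep) is broken by lagging sleep one day: the night before day t is
governed by S at day t−1, so day 1 sleeps the full 8 h.

## Tasking

A crew-total task count is drawn Poisson(24) daily; each task gets a domain
from an engineering-heavy mix (0.55/0.15/0.15/0.15 — maintenance dominates
a Mars transit workload). A task routed to an agent with proficiency p
takes `base_hours / (0.25 + p)` hours (base 1 h). Routing prefers the
highest-proficiency agent but (a) discounts proficiency by 0.3 per task an
agent leads the least-loaded crew member (load balancing) and (b) is
softmax-stochastic with temperature 0.8, reflecting that real task routing
tracks competence only imperfectly; temperature 0 recovers a greedy argmax.
Cumulative workload decays 5 %/night and accrues the day's hours
(steady-state near 100 h against CW_max = 150).

The routing parameters matter for the factorial contrast: with perfectly
greedy routing a differentiated crew's specialists absorb their domains so
efficiently that role diversity *lowers* workload stress, whereas with the
calibrated imperfect routing and an engineering-heavy mix, the all-engineer
uniform crew holds a comparative advantage on the dominant domain and role
diversity carries a small stress cost — the regime the calibration targets
exhibit.

## Social dynamics and cultural adaptation

Each day every agent, in random order, draws two distinct partners; the
deduplicated pair set (2–4 interactions per agent) is the day's social
schedule. A pair's interaction is positive with probability
`clamp01(0.5 + 0.4·mean(A) − 0.4·mean(N))`. Positive interactions add 0.04
support and decay conflict by 10 % for both members; negative ones add 0.05
conflict and decay support by 10 % (caps SSU_max = CL_max = 1). A symmetric
pairwise cohesion matrix updates by a bounded EMA (rate 0.02): ties grow
toward 1 on positive and shrink toward 0 on negative interactions; effects
are always bidirectional. Team cohesion is
`TC = clamp01(mean(SSU) − mean(CL))`.

In personality-heterogeneous crews (C, D) an openness-based cultural
adaptation factor `1 − γ·O` (γ = 0.32) multiplies each agent's
environmental stress and the positive part of their social stress: open
agents absorb the friction of a psychologically diverse crew. Homogeneous
crews have no modeled cultural gap (factor 1). This channel is what makes
personality diversity protective at the crew level.

## Mission events and health

Four event classes fire independently each day (equipment failure p 0.020,
magnitude 0.50, 5 days; comm delay 0.020/0.30/3; environmental hazard
0.010/0.60/4; health incident 0.015/0.40/3). Active events add their
magnitudes to everyone's environmental stress; if the crew holds the
event's matched role (engineer, pilot, scientist, medic respectively) the
surcharge is halved — the specialist absorbs part of the disruption.

Health follows a stress-gated first-order rule,
`H ← clamp01(H − η_d·max(0, S − θ_H) + η_r·max(0, θ_H − S)(1 − H))`,
with decline rate η_d = 0.0025/day, saturating recovery η_r = 0.01/day and
threshold θ_H = 0.45. The rule is this package's own (the dynamics it
reproduces are reported only as trajectories); it is deliberately the
simplest form that declines under chronic overload and recovers below
threshold.

## Calibration and the frozen reference set

The model's weights, rates and caps are not individually identified by any
published value, so a single reference vector was fixed by calibrating the
free scalars against the published factorial Monte Carlo summary (twelve
mean final-day crew metrics across conditions A–D) with one shared
parameter vector for all four conditions — per-condition fitting would void
the factorial comparison. Calibration used reduced-size Monte Carlo
(n = 48, verified at n = 200; worst absolute deviation 0.026) and the
result is frozen as `reference_parameters()`: weights
(w_ES, w_TP, w_EF, w_SS, w_EnvS) = (0.20, 0.15, 0.25, 0.20, 0.20),
EnvS base 2.50 (fluctuation SD 0.10), k = 2.30, S_opt = 0.2, γ = 0.32,
θ_H = 0.45, plus the tasking and interaction constants above.
`calibrate_reference()` exposes the same machinery (seeded random search
with common random numbers, full evaluation log) for refitting against
other targets.

One tension in the targets is not reproducible under this model family:
the published health means put the role-differentiated homogeneous crew (B,
0.43) above the fully homogeneous crew (A, 0.41) even though B's stress is
higher, while the health rule here is monotone in the stress path.
Calibration therefore centers A and B between their health targets
(A ≈ 0.43, B ≈ 0.41); both stay inside the ±0.05 reproduction band, and
the condition-group orderings ({C, D} healthier than {A, B}) hold.

## Monte Carlo protocol

`monte_carlo` replays the mission with child seeds derived counter-style
from a master seed (`SeedSequence(master, spawn_key=(i,))`), takes each
run's final-day crew mean of stress, performance and health, and reports
mean/SD/min–max across runs. Run-level crew means (not individual agents)
define the ranges. The headline experiment is n = 1000 runs per condition;
examples and tests use smaller n where only directions or identities are
checked (the pooling identity makes scaling exact in expectation).

## What the simulations do and do not show

The generator *is* the study design: there is no external data, so the
simulations characterize the model, not any real crew. The synthetic
conditions reproduce the intended stylized facts — chronic stress
accumulation to a high plateau, personality diversity buffering stress
through cultural adaptation, role diversity alone carrying little benefit —
but real-mission features are absent: no dynamic trait change, no
leadership or subgroup structure, no conflict spirals, no coupling of
performance back into task capacity, no resource or habitat modeling, and
health influences nothing downstream (performance depends on stress only,
to preserve the initial S = 0.2 / P = 1.0 / H = 0.9 triple). Cohesion
trajectories are qualitative: the EMA steady state tracks the positive-
interaction rate, not validated sociometry.

## Numerical choices

* Truncated-normal sampling by rejection: exact support, distributionally
  reproducible across implementations (not bit-wise).
* Tie-breaks in task routing randomized daily (scan-order permutation) so
  no agent index is systematically favored.
* All bounded quantities are clamped exactly once per day, at their defined
  update; EF is intentionally unclamped (only overall stress is).
* Events decrement before new fires, so a duration-1 event is active
  exactly on its firing day.
* Mission runs are bit-reproducible given (config, parameters, seed); the
  factorial gives each condition its own child-seed stream.
* Runtime: one 500-day, 6-agent run ≈ 0.15 s on one CPU; the full
  4 × 1000-run factorial ≈ 10 minutes.
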