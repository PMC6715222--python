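# Methods

## The model

`smokesim` simulates current (30-day) use of conventional cigarettes (CC)
and e-cigarettes (EC) in a closed cohort of US high-school students. Each
agent occupies one of four states — non-user, CC only, EC only, dual use —
and revisits the choice every decision cycle. Twelve cycles make a
calendar year, matching the survey instrument's 30-day "current use"
window; the default horizon is 2011–2014 (36 cycles). Updating is
synchronous: all agents evaluate the previous cycle's social environment,
all choices are drawn, and the new states become the next cycle's
environment. The cohort is closed (no school entry/exit) and the
friendship network is static for the whole run.

### Social structure

The friendship graph is a Barabási–Albert preferential-attachment network
(default m = 2, so mean degree ≈ 4, consistent with the "four closest
friends" survey item). Each agent designates up to four neighbours as
close friends, chosen greedily so the number of designated friends who
smoke cigarettes equals the agent's survey response whenever the
neighbourhood composition allows; the residual is recorded per agent.
Because each agent's designation is independent of everyone else's, the
greedy per-agent choice is already optimal and no repair pass is needed.
With the packaged marginals the population mean absolute residual is
≈ 0.4 friends: about half the agents have only 2–3 neighbours, so some
reported counts are structurally unsatisfiable. Peer prevalence is
computed over the designated close friends (a configuration switch in the
engine's inputs — supplying a full-neighbourhood close-friend map — uses
all neighbours instead).

### Choice rule

Utilities are linear (see README for the algebra): intrinsic taste μ_X,
habituation η for a currently used product, use-frequency reinforcement
φ·freq_X, and social influence (w_peer·peer_X + w_soc·pop_X) amplified by
the agent's dynamic openness factor (1 + o_X). Openness is the
survey-derived base attitude plus the scenario offset θ_X plus γ times
perceived exposure (an α-weighted blend of peer and population
prevalence), clamped to [0, 1]. The crossover χ acts one way — EC
exposure raises CC openness and adds χ·(EC social utility) to the CC
alternative — through both an openness channel and a direct utility
channel; either can be disabled by flag. Dual use is worth
V_CC + V_EC − κ.

Unobserved taste is an i.i.d. Gumbel shock per alternative per decision,
so single-cycle choice probabilities are multinomial logit,
softmax(U/tasteScale): this gives a closed-form oracle that the test
suite checks against Monte-Carlo frequencies. tasteScale = 0 degenerates
to a deterministic argmax with a fixed tie-break order.

**Dual-use interaction.** κ may be negative. The packaged calibration uses
κ ≈ −1.75: for a current user of one product, dependence raises the
marginal attraction of the other (cross-product habituation). This sign is
essential empirically: with κ ≥ 0 the simulated 2014 dual-use prevalence
cannot exceed ≈ 2% while the other eight trajectory constraints hold,
because nothing else in the utility gives current smokers a sufficiently
higher e-cigarette uptake rate than non-smokers (the observed 2014 pattern
needs roughly 3–5× selectivity; openness and peer-network correlations
supply only ≈ 1.5×). Since the dual bonus applies only on top of
V_CC + V_EC, and both V's are deeply negative for non-users, it does not
create spontaneous dual initiation.

### Frequency dynamics

freq_X rises by 0.25 per cycle of continued use (capped at 1) and resets
to 0 on quitting — a simple bounded habituation that makes recent adopters
easier to dislodge than established users.

## Synthetic initial population

No survey microdata is bundled. `PopulationMarginals` holds the marginal
distributions and is fully overridable; the packaged defaults emulate the
2011 survey wave:

- smoking state: 14.8% CC only, 0.5% EC only, 1.0% dual (so 15.8% any-CC,
  1.5% any-EC);
- "How many of your four closest friends smoke cigarettes?": Binomial(4,
  0.158), i.e. consistent with independent mixing at the CC prevalence;
- openness: two 4-point attitude items scored {0, ⅓, ⅔, 1} and averaged;
  item response probabilities (0.55, 0.18, 0.13, 0.14), giving mean base
  openness ≈ 0.29 with a substantial susceptible tail;
- 30-day use-day fraction given use: a bucketed mix with 35% near-daily
  users (current users are mostly established, not one-off experimenters);
- age: 13–19, mass concentrated at 14–18 (age is carried on the profile
  but does not enter the utility).

A Gaussian rank-correlation copula couples smoking state, smoking-friend
count and openness (ρ = 0.55, 0.90, 0.30 respectively, with openness
toward the two products sharing one latent attitude) while preserving
every marginal exactly. The correlations express two robust survey facts —
smokers report far more smoking friends, and current smokers are by
construction "open" to smoking. The openness item probabilities, the
use-day mix and the copula strengths are calibration-era choices: the
published survey reports give the headline prevalences but not these joint
tables, so they were fixed together with the utility weights (below) and
then frozen. Setting `copula: null` gives fully independent draws.

What the generator does **not** emulate: survey weights, item non-response,
grade/sex structure, any age dependence of smoking, or homophily beyond
the three modelled correlations. Passing tests therefore show the pipeline
reproduces the *aggregate* dynamics under these stylised conditions, not
that it captures individual-level survey joint distributions.

## Seeding and reproducibility

A scenario's replicate r uses seed `baseSeed + r`; from it, independent
child streams drive profile generation, network topology, close-friend
assignment and choice shocks. Agents are always processed in agentId
order and replicate aggregation is in replicate order, so results are
bit-reproducible for a given spec.

## Calibration

Free parameters are fitted to the yearly observed prevalences of any-CC
and any-EC use (2011–2014, point estimates with 95% CIs packaged as a
CSV; the CI bounds are approximations at the published precision). The
loss is Σ ((sim − obs)/halfCI)², each simulated point a replicate mean;
candidates are evaluated with common random numbers so the objective is
deterministic given the seed. The search is Latin-hypercube seeding (60%
of the budget) plus Nelder–Mead refinement.

The packaged defaults (μ_CC −10.731, μ_EC −7.422, η 11.732, φ 1.017,
w_peer 3.974, w_soc 3.48, γ 2.996, κ −1.75, α 0.407, tasteScale 1) were
obtained this way, with the counterfactual scenario responses used as
additional moments when selecting among near-equivalent trajectory fits
(an indirect-inference style choice). α = 0.407 is itself a calibrated
value rather than the neutral 0.5. At these defaults, 100-replicate means
put six of the eight year × product points inside the 95% CIs; the two
misses are 2012 EC (by ≈ 0.4 pp) and 2013 EC — the upswing year that the
original survey comparison also failed to bracket. The 2014 baseline is
≈ 4.6% CC-only / 8.6% EC-only / 5.3% dual.

Self-calibration (fitting targets generated by the model at known
parameters) recovers the societal weight to within a few percent when the
free set is {μ_CC, w_soc}; freeing μ_EC together with w_soc exposes a
near-collinear ridge (a stronger intrinsic EC taste can mimic a stronger
societal feedback over a short horizon), so recovery experiments should
hold one of the pair fixed.

## Counterfactual scenarios

The scenario grid moves the openness offset θ (applied jointly to both
products) and the crossover χ over {0, 0.1, 0.2, 0.3}. At the corners,
100-replicate means give: openness +0.3 → EC-only ≈ 12.6%, dual ≈ 6.7%,
CC-only ≈ 4.4%; crossover +0.3 → CC-only ≈ 4.9%, dual ≈ 6.6%. All the
qualitative orderings are robust: more openness raises EC-only and dual
use and lowers CC-only; more crossover raises CC-only and dual use while
leaving EC-only essentially flat.

Known limitation: under θ = +0.3 the simulated *decline* in sole
conventional smoking is weaker than the level reported for comparable
counterfactuals elsewhere (ours stays near 4.4% rather than falling to
≈ 2.5%), and the crossover scenario overshoots dual use by ≈ 1.4 pp. In
this algebra the same openness offset that accelerates e-cigarette uptake
also props up cigarette retention and initiation, while the openness
clamp that keeps the e-cigarette response bounded also mutes extra
smoker-to-dual conversion; a wide structural search did not find a
parameterisation that removes the tension. Treat the θ-scenario CC-only
level as qualitative.

## Numerical choices

- Monthly cycles (12/year); horizon endpoints are sampled at the survey
  anniversaries (cycle 0, 12, 24, 36).
- The engine is a vectorised numpy implementation of the per-agent
  functions; the suite asserts exact agreement with the scalar path under
  deterministic choice.
- Ties under tasteScale = 0 break in state order none < CC-only <
  EC-only < dual.
- Isolated agents (no close friends) perceive zero peer prevalence.
- Probability vectors must sum to 1 within 1e-9; openness and prevalence
  are clamped/validated to [0, 1].
- Problem sizes in the test suite: unit tests use 60–400 agents and a
  handful of replicates; the end-to-end tests use the full study
  configuration (3000 agents × 36 cycles × 100 replicates, ≈ 20 s per
  scenario) and a 1000-agent, 200-evaluation budget for the
  parameter-recovery experiment.
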