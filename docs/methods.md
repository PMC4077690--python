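# Methods

## Model

A probabilistic Boolean network over nodes `V = (x_1, …, x_n)` assigns each
non-input node `i` a set of Boolean predictors `f_1^(i), …, f_l(i)^(i)` with
selection probabilities `c_ij ≥ 0`, `Σ_j c_ij = 1`. We use the
*instantaneously random, independent* variant: at every synchronous step
each node independently draws a predictor and applies it to the current
state. Equivalently, one of the `Π_i l(i)` deterministic constituent
networks is drawn with product probability. Input nodes carry no predictor;
an experiment clamps them to 0/1 and they are exempt from perturbation.
Unclamped inputs hold their value (identity update) but remain perturbable.

**Perturbation.** Each non-clamped node flips with probability `p` per
step, independently; if at least one flip fires, the flipped state *is* the
next state and no update function is applied ("flip wins"). This is the
standard construction that makes every clamped subchain irreducible and
aperiodic, hence possessing a unique stationary distribution. The one-step
matrix over the `m` non-clamped nodes is

    P(s,t) = p^h (1-p)^(m-h) · [h ≥ 1]  +  (1-p)^m · Π_i P(x_i' = t_i | s),

`h` the Hamming distance. Note the diagonal receives no perturbation mass,
so `P(s,s)` can be exactly 0 when the update functions force a move; the
chain is ergodic because all off-diagonal entries are positive. The paper
default `p = 0.001` is small enough that clamped-condition marginals are
within O(p) of the unperturbed limit, which is what the bundled data use.

**Rule grammar.** `target = expr [: prob | : ?]` with `& | ~ ( ) 0 1`,
`#` comments; rules for one node may appear in any order. Truth tables are
stored with the first parent as the most significant row-index bit; state
strings render the first declared node leftmost. Serialisation emits the
original expression text (or a DNF reconstruction) with `repr`-precision
probabilities so rule files round-trip exactly.

## Exact oracle

For `m ≤ 10` non-clamped nodes (cap on matrix entries 2^20, configurable)
the stationary distribution is solved from the eigenvector of `Pᵀ` at
eigenvalue 1, refined by power iteration if the eigen solve is
ill-conditioned (residual tolerance 1e-10); a non-simple unit eigenvalue
raises a reducibility error rather than returning an arbitrary member of
the stationary simplex. Attractors of the unperturbed dynamics are the
bottom strongly connected components of the positive-transition digraph
(networkx condensation). The influence of node `k` on node `j` is
`Σ_i c_ij · P_π(f_i^(j)(x) ≠ f_i^(j)(x ⊕ e_k))` under a supplied stationary
distribution.

## Two-state run-length method

To estimate `π = P(node = 1)` at stationarity, the trajectory is projected
onto the two meta-states {0, 1} and modelled as a two-state Markov chain
with rates `α = P(0→1)`, `β = P(1→0)`:

    m0 = max(0, ceil( log(ε(α+β)/max(α,β)) / log|1−α−β| ))   (m0 = 1 if λ = 0)
    N  = ceil( αβ(2−α−β)/(α+β)³ · (Φ⁻¹((s+1)/2)/r)² )

`m0` is the burn-in after which the start state's influence is below ε, `N`
the run length for precision `r` at confidence `s`. Two details matter:
`|1−α−β|` (an oscillatory chain with α+β > 1 forgets its start just as
fast), and the *inverse* normal CDF in `N`. Defaults: `p = 0.001`,
`r = 0.025`, `ε = 0.01`, `s = 0.95`, initial `(m0, N) = (0, 100)`, safety
cap 10⁶ steps.

**Protocol.** Simulate `m0+N` steps; re-estimate α, β from the last `N`
states; recompute `(m0, N)`; while the requirement grows, extend the *same*
trajectory (the simulation object is checkpointable, so re-estimating at a
tighter `r` can also continue an existing trajectory). On termination the
estimate is the ON-frequency over the final `N` states. Numerical choices:
ceil on both `m0` and `N`, `N` floored at 2 (a window must contain a
transition pair), `α, β ∈ (0, 1]` accepted (`β = 1` is a legitimate
deterministic reset; a rate of exactly 0 means the window never saw one
transition type and is treated as degenerate). A constant window triggers
doubling of the trajectory with the node's window covering all of it, at
most 10 times; a node whose requirement is already satisfied keeps its
last valid rates when a later tiny window happens to be constant.
Multi-node estimation shares one trajectory and extends it until every
node's requirement fits.

**What the guarantee does and does not cover.** The `(r, s)` guarantee is
conditional on the two-state projection being approximately Markov. On the
bundled signalling models this holds and calibration matches `s` (the
example chain calibrates at ≈ 96/100). On unstructured random networks the
full chain can be metastable — regimes switching at rate ~`p` that the
locally-estimated α, β cannot see — and there the achieved coverage drops
(≈ 82% over the test suite's 200-run random ensemble) with occasional
errors far beyond `r`. This is the documented failure mode of run-length
diagnostics generally, not a property of the implementation; the robustness
check below is the practical mitigation.

## Inference

The objective is `SSE(c) = Σ_experiments Σ_measured (π̂_node(c) − y)²` with
one clamped condition per experiment. Two marginal backends: `exact`
(stationary solve, default `p = 0` matching the unperturbed limit the
bundled data are computed in) and `simulation` (the run-length method; the
per-evaluation RNG seed derives deterministically from (global seed,
iteration, experiment), so runs are reproducible).

*Discrete mode*: each free predictor is on/off; the selected predictors of
a node split its probability mass equally; a node with nothing selected
makes the candidate invalid (cost +∞, recorded, never repaired). Up to 2^20
candidates are enumerated exhaustively, beyond that a generational GA
(tournament selection, uniform crossover, 1/k bit mutation, elitism) runs
within the evaluation budget. *Continuous mode*: raw variables live in
[0,1]^k and each node's block is normalised to its mass — chosen over a
"last = 1 − rest" decoding because it treats predictors symmetrically; an
all-zero block decodes to uniform. Optimiser: scipy differential evolution
(rand/1/bin, F = 0.8, CR = 0.9, polish off); if it converges before the
budget, the remainder is spent on uniform random samples so the ensemble
always contains the requested number of evaluated candidates. The optimiser
is deliberately pluggable — the objective, not the search algorithm, is the
scientific content.

Partially free nodes (some `c` fixed, some `?`) keep their declared fixed
values; the free predictors share the remaining mass `1 − Σ fixed`. All
bundled case studies have fully free nodes, so this rule only affects the
general API. No model-size penalty is applied.

**Ensemble statistics.** `top_k` (ties by iteration order) and
per-parameter mean / population SD / min / max over the best K = 500
samples, plus long-format scatter exports. A tight cluster (SD small
against the mean) marks an identifiable, output-sensitive parameter; no
hypothesis test is attached — the judgement is left to inspection, which is
all the evidence supports.

## Bundled case studies (synthetic benchmarks)

All three bundles are *generated*, with data equal to the exact stationary
marginals of a known truth model in the `p → 0` limit (verified to 1e-9 in
the tests), so recovery has a ground truth. The published input tables are
figures, not text, so the condition letterings are reconstructions from the
per-condition consistency patterns and worked arithmetic; they reproduce
every printed number but are not guaranteed to match the figures
cell-for-cell.

1. **Rule selection** — NFkB with five candidates {OR, AND, PI3K, TNFa,
   constant-0} over inputs (PI3K, TNFa); conditions (0,0)→0, (1,0)→0,
   (0,1)→0, (1,1)→1; truth = AND only. Discrete inference reproduces the
   per-condition consistency shares (1/5, 1/3, 1/3, 1/4) and the unique
   all-condition survivor with probability 1.
2. **Weight recovery** — PIP3 with candidates {PI, PT, PI & ~PT, 0}, truth
   (0.6, 0, 0.4, 0); the four input combinations give data (0, 1, 0, 0.6).
   The A,D-only subset leaves the non-identifiable ridge c_PI + c_PT = 0.6.
3. **Weighted toy signalling model with inhibitors** — 8 nodes; TGFa
   activates PI3K and Raf; NFkB = 0.7·PI3K + 0.3·TNFa; ERK = 0.6·Raf +
   0.4·NFkB; inhibitor treatments remove 70% of the target's activation.
   Inhibitors are encoded as input nodes: the target gets predictors
   {TGFa: 0.3, TGFa & ~inhibitor: 0.7}, which with the inhibitor clamped ON
   is identical to an extra constant-0 predictor with selection probability
   equal to the efficacy, and with it OFF collapses to plain activation.
   This keeps every condition a pure clamp assignment. The ERK weights and
   the 0.7 efficacy are inferred from the published best fit and worked
   example (condition D: NFkB = 0.3·0.7 + 0.3 = 0.51).

The apoptosis study is represented only by its printed 6-condition ×
3-output table of model variants and measurements (72 values embedded
verbatim) and the SSE arithmetic over it; the 96-node model itself is out
of scope.

**Random generator.** `random_pbn` draws 1–3 predictors per node over ≤ 3
parents with *non-constant* random truth tables and Dirichlet(1) weights: a
constant row encodes no interaction at all and produces frozen traces whose
run-length requirement explodes, which is not what "a random interaction"
should mean. Every node has a function set (no inputs), so unclamped
chains are ergodic for any `p > 0`. What the generator does **not**
emulate: canalising rule structure typical of curated biological rules,
measurement noise (bundled data are exact marginals), or condition designs
with partial input coverage. Passing recovery tests on these fixtures
therefore shows correctness of the machinery, not robustness to noisy or
confounded real data.

## Problem sizes

The test suite and the acceptance script use the sizes the methodology
itself recommends for small models: ≥ 5000 optimiser evaluations per
continuous fit, exhaustive enumeration for the 5-rule discrete problem,
200 seeded runs for the calibration study, and a 20-check battery for the
`r = 0.025` vs `r = 0.01` robustness comparison (run by extending the same
trajectory; the mean absolute change is the reported statistic, since the
per-estimate sampling noise at `r = 0.025` is itself ≈ 0.013).

## Known limitations

- Exact solves are dense and capped at 2^20 matrix entries; large models
  are simulation-only territory.
- The run-length method under-covers on metastable chains (see above);
  comparing runs from different initial conditions or precisions is the
  recommended diagnostic.
- Context-sensitive PBNs, asynchronous updating, multi-valued logic and
  per-experiment local parameters are out of scope.
- The influence computation needs an exact stationary distribution and is
  therefore restricted to small networks.
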